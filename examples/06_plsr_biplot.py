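"""PLSR decomposition of the interaction on climatic covariates.

Extracts two NIPALS latent factors linking the (standardized) covariate
matrix to the interaction, prints the percent of interaction SS each
factor carries, and the biplot coordinates for environments, covariates
and genotypes.
"""

from metstab import (
    SimulationSpec,
    center_covariates,
    compute_ge_means,
    fit_plsr,
    generate_covariate_linked,
    plsr_biplot_coords,
)
from metstab.simulate import default_covariate_link

spec = SimulationSpec(seed=42, covariate_link=default_covariate_link(g=16))
data, cov, _ = generate_covariate_linked(spec)
means = compute_ge_means(data)

x = center_covariates(cov, standardize=True)
model = fit_plsr(x, means.interaction.T, n_factors=2, genotypes=means.genotypes)

print("percent of interaction SS per factor:", [round(float(v), 2) for v in model.percent_y_explained])
coords = plsr_biplot_coords(model)
print(coords.round(3).to_string(index=False))

# Reading the biplot: an environment and a covariate pointing the same
# way means that covariate was high there; a genotype near them gains
# yield under those conditions.  Genotypes near the origin are
# insensitive to the measured climate variables.
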