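"""Generate a synthetic multi-environment chickpea-style trial.

Builds a 16-genotype x 8-environment x 3-replicate RCBD trial with known
ground truth and prints the design summary and the true interaction
spectrum.  Every downstream example starts from a dataset like this one.
"""

import numpy as np

from metstab import SimulationSpec, generate_met

spec = SimulationSpec(seed=42)
data, truth = generate_met(spec)

print(f"plots: {data.n_plots}  ({data.n_genotypes} genotypes x "
      f"{data.n_environments} environments x {data.uniform_replicate_count()} blocks)")
print(f"mean plot yield: {data.frame['yield'].mean():.1f} kg/ha")
print("true interaction singular values:", np.round(truth.singular_values, 1))
print("true share of axis 1:",
      round(100 * truth.singular_values[0] ** 2 / (truth.singular_values ** 2).sum(), 1), "%")

# The singular values are the sizes of the multiplicative interaction
# axes on the cell-means scale; the first axis carrying ~85 % of the
# interaction mirrors a strongly one-dimensional G x E pattern.
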