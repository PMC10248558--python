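"""Combined ANOVA and AMMI decomposition of a simulated trial.

Prints the variance partition (percent of total SS per source), the
share of interaction SS on each principal axis, and the number of axes
Gollob's F-test declares significant.
"""

import numpy as np

from metstab import SimulationSpec, ammi_analysis, generate_met

data, _ = generate_met(SimulationSpec(seed=42))
means, anova, am = ammi_analysis(data, alpha=0.05)

print(anova.table[["df", "SS", "MS", "F", "p", "percent_of_total"]].round(2))
print()
print("theta (% of interaction SS per IPC):", np.round(am.percent_explained, 2))
print("significant axes N' (Gollob, alpha=0.05):", am.n_significant)

# Environment, genotype and interaction percentages are the shares a
# breeder reads first: a large interaction share is what motivates the
# stability analysis at all.  theta_1 near 80 % says a single
# multiplicative axis describes most of how genotypes re-rank across
# environments.
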