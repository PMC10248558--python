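"""Seven AMMI stability indices, ranks, and simultaneous selection.

Lower index = more stable; ssi adds the stability rank to the yield rank
so the best genotypes combine both.  Prints the four best genotypes by
ssi on the AMMI stability value.
"""

from metstab import SimulationSpec, ammi_analysis, generate_met, stability_table

data, _ = generate_met(SimulationSpec(seed=42))
means, _, am = ammi_analysis(data)
table = stability_table(am, means)

cols = ["mean_yield", "ASV", "rank_ASV", "RY", "ssi_ASV", "ssi_WAAS", "ssi_D"]
print(table[cols].round(2).to_string())
print()
best = table.sort_values("ssi_ASV").index[:4].tolist()
print("best four by ssi_ASV (stable AND high-yielding):", ", ".join(best))

# A genotype with rank_ASV 1 sits nearest the interaction origin; a
# genotype with RY 1 has the highest mean yield; ssi = rank + RY, so the
# minimum achievable is 2.
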