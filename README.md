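# metstab

Stability analysis for multi-environment yield trials (MET): the full
analysis chain a plant breeder runs on a genotype × environment ×
replicate yield table, implemented as a tested Python library with a thin
command-line interface and a synthetic-trial generator with known ground
truth.

## Who this is for and what it does

Breeding programs test candidate genotypes across several site-year
environments and must pick entries that are both **high yielding** and
**stable** — insensitive to genotype-by-environment interaction (GEI).
`metstab` implements both families of approaches used for that decision:

**Experimental (empirical) approaches**

- **Combined RCBD ANOVA** over environments (environment,
  replicate-within-environment, genotype, G×E, pooled error).
- **AMMI** — additive main effects and multiplicative interaction:

  Y<sub>ij</sub> = μ + α<sub>i</sub> + β<sub>j</sub> +
  Σ<sub>n</sub> λ<sub>n</sub> γ<sub>in</sub> δ<sub>jn</sub> + ρ<sub>ij</sub>

  The doubly-centered interaction matrix is decomposed by SVD into
  interaction principal components (IPCs); λ<sub>n</sub> is the singular
  value of axis *n*, θ<sub>n</sub> = λ<sub>n</sub>²/Σλ<sub>m</sub>² its
  share of interaction SS, and Gollob's F-test (df = g + e − 1 − 2n)
  picks the number of significant axes N′. AMMI1 (mean vs IPC1) and
  AMMI2 (IPC1 vs IPC2) biplot coordinates are exported.
- **Seven AMMI stability indices** (smaller = more stable): ASV, SIPC,
  EV, Za, D (AMMI distance), WAAS and MASV, plus per-index **simultaneous
  selection indices** ssi = stability rank + yield rank.
- **BLUP / HMRPGV** — a mixed model with random genotype and G×E effects
  fitted by EM-REML gives genotypic values GV<sub>ij</sub> = u<sub>j</sub> +
  g<sub>i</sub> + ge<sub>ij</sub>, summarized by HMGV (harmonic mean),
  RPGV (relative performance) and HMRPGV (harmonic mean of relative
  performance; × μ returns it to kg ha⁻¹).

**Analytical (biological) approaches**

- **Factorial regression (FR)**: GEI ≈ Σ<sub>k</sub> ξ<sub>ik</sub>
  z̃<sub>jk</sub> — per-genotype sensitivities to centered environmental
  covariates (seasonal rainfall, seasonal mean temperature), with
  forward covariate selection by AIC.
- **PLSR**: NIPALS partial least squares linking the covariate matrix X
  to the interaction (X = TP′ + E, Y = TQ′ + F), with per-factor percent
  of GEI SS and biplot coordinates for environments, covariates and
  genotypes.

Because raw trial data of this kind are rarely published, the package
ships a first-class **synthetic-trial generator** (`metstab.simulate`)
whose defaults emulate a published 16-genotype × 8-environment × 3-block
rainfed chickpea trial (grand mean 1069.25 kg ha⁻¹, environment ≈ 37 %,
genotype ≈ 17 % and GEI ≈ 31 % of total SS), with exactly known main
effects, interaction spectrum, covariate sensitivities and noise.

## Worked example

```sh
python examples/02_anova_and_ammi.py
```

```
                               df           SS  ...    p  percent_of_total
environment                     7   5835076.32  ...  0.0             35.72
replicate_within_environment   16    232765.88  ...  0.1              1.42
genotype                       15   2035117.25  ...  0.0             12.46
genotype_x_environment        105   5898396.22  ...  0.0             36.10
error                         240   2335706.06  ...  NaN             14.30
total                         383  16337061.73  ...  NaN               NaN

theta (% of interaction SS per IPC): [76.43  8.57  6.15  4.55  2.66  0.92  0.72]
significant axes N' (Gollob, alpha=0.05): 4
```

Environments and GEI dominate the variance partition, which is what
makes a stability analysis worthwhile; the first interaction axis
carries ~76 % of GEI SS, so genotype re-ranking across environments is
essentially one-dimensional here. Continuing with
`examples/03_stability_indices.py` ranks the genotypes:

```
best four by ssi_ASV (stable AND high-yielding): G11, G12, G14, G4
```

and `examples/04_blup_hmrpgv.py` gives the mixed-model view:

```
sigma_g = 57.6, sigma_ge = 124.4, sigma_e = 98.7 kg/ha  (39 EM iterations)
mean HMRPGV*mu of top 4: 1139 kg/ha (6.48 % over the grand mean 1070.08)
```

The remaining examples cover the covariate analyses
(`05_factorial_regression.py` — AIC selects the two truly active
variables, autumn temperature and spring rainfall, explaining 70 % of
the interaction SS; `06_plsr_biplot.py` — PLSR factor coordinates) and
the one-command pipeline (`07_full_pipeline_cli.py`).

The same stages are available from the shell:

```sh
metstab simulate --spec spec.yaml --out-dir sim/
metstab ammi --trials sim/trials.csv --out-dir out/
metstab stability --trials sim/trials.csv --out stability.csv
metstab blup --trials sim/trials.csv --out-dir out/
metstab fr   --trials sim/trials.csv --covariates sim/covariates.csv --out-dir out/
metstab plsr --trials sim/trials.csv --covariates sim/covariates.csv --out-dir out/
metstab run  --simulate-spec spec.yaml --seed 7 --out-dir out/   # everything + report.json
```

Input format: a long CSV `genotype,environment,replicate,yield` (kg ha⁻¹)
plus an optional covariate CSV `environment,<var1>,<var2>,...`.

## Layout

- `src/metstab/core.py` — data model, validation, CSV I/O, G×E means.
- `src/metstab/simulate.py` — seeded trial generator with ground truth.
- `src/metstab/ammi.py` — combined ANOVA, AMMI, Gollob test, biplots.
- `src/metstab/stability.py` — the seven indices, ranks and ssi.
- `src/metstab/blup.py` — EM-REML mixed model, HMGV/RPGV/HMRPGV.
- `src/metstab/covariates.py` — factorial regression + AIC, NIPALS PLSR.
- `src/metstab/pipeline.py`, `src/metstab/cli.py` — orchestration and CLI.
- `docs/methods.md` — models, assumptions, numerical choices, limits.
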