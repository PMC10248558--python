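# Methods

This note documents the models implemented in `metstab`, the choices
made where the methodology is genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model

A trial is a long table of plots: genotype × environment × replicate →
yield (kg ha⁻¹). Environments are site-year combinations; within an
environment the design is a randomized complete block (every genotype
appears once per block). Replicate counts must be equal within an
environment but may differ between environments; cell counts then stay
proportional, so the main-effect/interaction partition of sums of
squares remains orthogonal. Missing genotype × environment cells are a
hard error by default; an optional `impute="cell-mean"` policy fills a
missing cell with the additive prediction (genotype mean + environment
mean − grand mean over the observed cells) before AMMI, which biases
the interaction toward zero for those cells and should be used only for
a handful of cells.

## Combined ANOVA

Sources: environment, replicate-within-environment, genotype, G×E, and
pooled error, computed from group means by the textbook definitions.
Genotype and G×E are tested against the pooled error; environments
against the replicate-within-environment mean square (environments and
blocks share plot-level structure). Percent-of-total columns divide
each SS by the total SS; they are the shares a MET paper prints.

## AMMI

AMMI is computed on the genotype × environment **means** matrix: the
doubly-centered interaction is decomposed by SVD, and axis sums of
squares are returned to the plot scale as r·λ², where r is the
replicate count. With unequal replication across environments the
rounded mean count is used; the exact conservation identity
r·Σλ² = SS(G×E) then holds only for uniform r. Scores are symmetrically
scaled (√λ to both genotype and environment sides) so the score inner
product reconstructs the interaction; retaining all p = min(g−1, e−1)
axes reconstructs the means matrix to machine precision. SVD sign
ambiguity is resolved per axis by making the genotype with the largest
absolute loading positive, so outputs are stable across runs and
platforms.

Axis significance uses Gollob's approximate F-test: axis n has
df = g + e − 1 − 2n and mean square r·λₙ²/df against the pooled error.
N′ counts axes from the first until the first non-significant one, with
a floor of one. Two caveats are worth knowing: the test is **liberal**
— in a 16 × 8 table the leading axis of pure noise concentrates enough
SS that a second or third axis is routinely declared significant at
α = 0.05 — and no cross-validation alternative is provided. For a
strict rank-1 detection check, small tables (e.g. 5 × 3) keep the false
second-axis rate near nominal.

## Stability indices

With sᵢₙ the √λ-scaled genotype score, γᵢₙ the unit eigenvector
loading, SSₙ = r·λₙ², θₙ the axis share of GEI SS, and N′ the retained
axis count:

| index | formula | axes used by default |
|---|---|---|
| ASV   | √(((SS₁/SS₂)·sᵢ₁)² + sᵢ₂²) | axes 1–2 |
| SIPC  | Σₙ \|sᵢₙ\| | N′ |
| EV    | Σₙ γᵢₙ²/N′ | N′ |
| Za    | Σₙ \|θₙ·γᵢₙ\| (θ as proportion) | N′ |
| D     | √(Σₙ sᵢₙ²) | N′ |
| WAAS  | Σₖ \|sᵢₖ\|θₖ / Σₖθₖ | all p axes |
| MASV  | √(Σₙ<ₙ′ ((SSₙ/SSₙ₊₁)·sᵢₙ)² + sᵢN′²) | max(N′, 2) |

MASV is implemented as the multi-axis generalization of ASV — the
consecutive-SS ratio multiplies the score *inside* the square — so that
MASV with two axes is exactly ASV. (The alternative reading, with the
ratio outside the square, breaks that collapse; the generalization
property was preferred since MASV's published motivation is extending
ASV.) MASV ratios divide by trailing axis SS, so it must not be pushed
deeper than the numerical rank of the interaction. WAAS deliberately
uses all axes — its own weights suppress minor axes — while the
N′-based indices follow the Gollob test; every function takes an
explicit axis-count override. Za is computed with θ as proportions;
only ranks matter downstream, so the scale choice is immaterial.

Ranking: stability ranks ascend in the index (1 = most stable), the
yield rank RY descends in mean yield (1 = highest), and
ssi = rank + RY. Ties share the minimum ("competition") rank so ssi
stays a sum of small integers. On a flagged zero interaction all
indices are exactly 0 and all stability ranks are 1.

## Mixed model and HMGV / RPGV / HMRPGV

Model: y = environment + block-within-environment (fixed) + genotype +
G×E (random) + residual, with independent N(0, σ²) random effects.
Fixed blocks keep the model identified with as few as two replicates.
Variance components are estimated by EM-REML on Henderson's mixed-model
equations (updates guarantee non-negativity); BLUPs come from the final
solve. Numerical details that matter:

- The residual update y′ê/(n−p) is computed as ê′ê + fitted′ê, never as
  y′y − sol′W′y, which loses all precision when the noise is small.
- A minimum shrinkage ridge (1e-8 of the mean random-effect diagonal)
  keeps the constant direction shared by the environment fixed effects
  and the genotype random effects numerically identified at extreme
  variance ratios.
- A pinned (zero) component is **removed** from the equations rather
  than given a huge ridge, which would destroy the conditioning of the
  remaining blocks.
- Convergence: relative change of every component < 1e-8 (measured
  against max(component, 1e-6·var(y))), with a 500-iteration budget.
  Aitken extrapolation accelerates the coarse phase and detects
  components whose geometric limit is at or below zero; a component
  that keeps moving below 1e-4·var(y) after 50 iterations is treated as
  a boundary (zero) estimate and flagged. Because EM can also crawl
  along an almost flat likelihood ridge (missing information near one),
  a stalled restricted log-likelihood (change < 1e-8 over 40
  iterations) is accepted as convergence and reported as
  `stopped_on="loglik"`. Extreme signal-to-noise ratios beyond ~10⁴ can
  still exhaust the budget; realistic MET regimes converge in tens of
  iterations.

Genotypic values GVᵢⱼ = uⱼ + gᵢ + geᵢⱼ use the observed environment
means uⱼ (the BLUE under within-environment balance). Then
HMGV = harmonic mean of GV across environments, RPGV = mean of GV/uⱼ,
HMRPGV = harmonic mean of GV/uⱼ, and HMRPGV×μ rescales to kg ha⁻¹. All
require positive genotypic values — guaranteed in practice for yields —
and are ranked descending. The harmonic mean penalizes genotypes with
poor environments (instability), which is the statistic's point.

## Factorial regression and AIC selection

Each genotype's interaction row is regressed on centered covariate
columns by ordinary least squares, jointly over genotypes; ξ columns
inherit zero sums across genotypes from the doubly-centered response.
Sequential explained SS (in selection order) plus residual SS equals
the total interaction SS. Forward selection minimizes
AIC = N·ln(RSS/N) + 2P with N = g·e cells and P = g·k sensitivity
parameters (Gaussian profile likelihood up to constants); selection
stops when no candidate lowers AIC, with a perfect-fit guard at RSS = 0
and first-in-column-order tie-breaking. Forward-only, no drop steps.
Near saturation (k approaching e−1) the criterion tends to admit weak
covariates — each additional variable absorbs 1/(e−1−k) of the
remaining residual — which is inherent to AIC in this small-e setting,
so the selection *order* is the trustworthy output.

## PLSR

X is the environment × covariate matrix, centered and (by default)
scaled to unit sample sd — the covariates mix mm and °C, so unscaled
PLSR would be rainfall-dominated; a `--no-scale` flag preserves the
centered-only variant. Y is the doubly-centered interaction transposed
to environments × genotypes: the per-factor "% of Y explained" is then
a share of the GEI sum of squares, which is the quantity of interest
(raw yields would mix in main effects). Factors come from classical
NIPALS PLS2 with X- and Y-deflation by the X-scores; the inner loop
starts from the largest-variance Y column and iterates to 1e-10 (10⁴
iteration cap). Per-factor signs make the dominant covariate loading
positive. Factor-1 recovery of a rank-1 response is exact only when the
driving direction is an eigendirection of XX′ (e.g. orthogonal
covariate columns or a single covariate); for a generic column PLS2
mixes directions and factor 1 captures slightly less than 100 %.

## Synthetic data generator

Yields are built as μ + αᵢ + βⱼ + Σλₙγᵢₙδⱼₙ [+ unstructured doubly
centered interaction] + block + noise, with main effects drawn normal
then centered exactly, and interaction vectors obtained by
QR-orthogonalization of normal draws against the ones vector — so the
generated interaction has an exactly known spectrum. The
covariate-linked variant instead uses ξ·z̃ᵀ with centered sensitivities
and covariate draws, plus an optional unstructured residual. Draws
occur in one documented order from a single seeded generator, so equal
seeds give bit-identical datasets. Plots whose simulated yield falls
below zero are clipped to zero (failed plots); at the default
magnitudes this is rare to absent.

Defaults are the study conditions the generator emulates: g = 16,
e = 8, r = 3, grand mean 1069.25 kg ha⁻¹, and effect scales
(σ_G = 90, σ_E = 170, λ = (1240, 330, 145, 95, 65), σ_e = 100 kg ha⁻¹)
calibrated numerically so the expected ANOVA shares match a published
chickpea MET (environment ≈ 37 %, genotype ≈ 17 %, GEI ≈ 31 % of total
SS). One trade-off is unavoidable at these dimensions: with ~15 % of
the total SS in blocks + error, the noise floor spread over the seven
interaction axes caps the *observed* leading-axis share near 80 %, so
the generator reproduces the ANOVA shares exactly and the observed
θ₁/θ₂ ≈ 79.6/9.2 % rather than the ~85/10 % a lower-noise trial would
show; the true low-rank spectrum carries ~85/10 %. Default climatic
covariates are seasonal rainfall (mm) and mean temperature (°C) with
means and spreads typical of west-Iranian rainfed sites; the default
link makes autumn temperature and spring rainfall the truly active
drivers, with sensitivities scaled so the linked interaction matches
the calibrated interaction variance.

What the generator does **not** emulate: spatial field trends,
heteroscedastic errors across environments, genotype-specific error
variances, non-Gaussian yield distributions, weather time series
(covariates are seasonal aggregates drawn independently), and missing
plots. Passing tests therefore demonstrate correctness of the
*computations* under the stated generative model, not robustness to
those real-data features.

## Pipeline and reproducibility

`run_pipeline` executes means → ANOVA → AMMI (+ Gollob) → stability →
BLUP/HMRPGV and, when covariates exist, FR and PLSR; stages that cannot
run are skipped with a logged notice, a failed stage names itself and
leaves a manifest of completed stages. `report.json` carries every
stage's numbers at full precision plus a two-decimal display mirror,
serialized with sorted keys so identical seeds give byte-identical
reports. Simulation problem sizes used by the test-suite recovery
studies (200 seeds for REML coverage and FR selection) keep the whole
suite in well under a minute of compute while leaving Monte-Carlo error
on the checked rates below about two percentage points.

## Known limitations

- Gollob's test over-declares axes in large tables (above); N′-based
  indices inherit that choice, so axis-count overrides are exposed.
- AMMI assumes a complete means table; the imputation path is a
  convenience, not a missing-data model.
- The mixed model has homoscedastic residuals and no kinship structure.
- FR admits only environmental covariates (no genotypic ones), and the
  number of PLSR factors is user-chosen, not cross-validated.
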