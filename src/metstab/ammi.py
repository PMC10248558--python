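"""AMMI analysis: combined ANOVA and SVD of the G x E interaction.

The additive-main-effects and multiplicative-interaction (AMMI) model

    Y_ij = mu + alpha_i + beta_j + sum_n lambda_n gamma_in delta_jn + rho_ij

first fits additive genotype and environment main effects by ANOVA and
then decomposes the doubly-centered interaction matrix by singular value
decomposition into interaction principal components (IPCs).  lambda_n is
the singular value of IPC n (lambda_n^2 its eigenvalue); gamma and delta
are unit eigenvectors for genotypes and environments.

Conventions used throughout this package:

* AMMI runs on the G x E *means* matrix; IPC sums of squares are put back
  on the plot-data scale by multiplying the means-scale eigenvalue by the
  replicate count r (SS_n = r * lambda_n^2).
* Scores are symmetrically scaled: genotype score s_in = sqrt(lambda_n) *
  gamma_in and environment score sqrt(lambda_n) * delta_jn, so the inner
  product of score rows reconstructs the interaction.
* Per-axis signs are fixed by requiring the genotype with the largest
  absolute loading on the axis to have a positive loading (the SVD sign
  is otherwise arbitrary).
* IPC significance uses Gollob's approximate F-test with
  df_n = g + e - 1 - 2n against the pooled error mean square; the number
  of significant axes N' scans from the first axis and stops at the first
  non-significant one, with a floor of one axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import GEMeansMatrix, METDataset, METValidationError, compute_ge_means

__all__ = [
    "CombinedAnova",
    "AMMIResult",
    "combined_anova",
    "ammi_decompose",
    "gollob_test",
    "ammi1_coords",
    "ammi2_coords",
    "ammi_analysis",
]

SOURCE_ENV = "environment"
SOURCE_REP = "replicate_within_environment"
SOURCE_GEN = "genotype"
SOURCE_GEI = "genotype_x_environment"
SOURCE_ERR = "error"
SOURCE_TOT = "total"


@dataclass
class CombinedAnova:
    """ANOVA of an RCBD repeated over environments.

    ``table`` rows: environment, replicate-within-environment, genotype,
    genotype x environment, error, total; columns df, SS, MS, F, p,
    percent_of_total.  F-ratios: genotype and interaction against the
    pooled error; environments against the replicate-within-environment
    mean square; blocks against pooled error.
    """

    table: pd.DataFrame
    has_error_term: bool

    @property
    def error_ms(self) -> float:
        return float(self.table.loc[SOURCE_ERR, "MS"])

    @property
    def error_df(self) -> int:
        return int(self.table.loc[SOURCE_ERR, "df"])

    def ss(self, source: str) -> float:
        return float(self.table.loc[source, "SS"])


def combined_anova(data: METDataset) -> CombinedAnova:
    """Partition plot-level sums of squares for the combined RCBD trial.

    Within-environment replication must be balanced (enforced by
    :class:`METDataset`); replicate counts may differ between environments,
    which keeps main effects orthogonal (cell counts stay proportional).
    With a single replicate everywhere the pooled error is undefined: the
    table is returned without F/p and ``has_error_term`` is False.
    """
    if not data.is_complete():
        compute_ge_means(data)  # raises IncompleteTableError with the cells
    df = data.frame
    y = df["yield"].to_numpy()
    n = y.size
    grand = y.mean()

    env_groups = df.groupby("environment", sort=False)["yield"]
    env_means = env_groups.mean()
    env_sizes = env_groups.size()
    ss_env = float((env_sizes * (env_means - grand) ** 2).sum())

    rep_groups = df.groupby(["environment", "replicate"], sort=False)["yield"]
    rep_means = rep_groups.mean()
    rep_sizes = rep_groups.size()
    ss_rep = float(
        (rep_sizes * (rep_means - env_means.reindex(rep_means.index.get_level_values(0)).to_numpy()) ** 2).sum()
    )

    gen_groups = df.groupby("genotype", sort=False)["yield"]
    gen_means = gen_groups.mean()
    gen_sizes = gen_groups.size()
    ss_gen = float((gen_sizes * (gen_means - grand) ** 2).sum())

    cell_groups = df.groupby(["genotype", "environment"], sort=False)["yield"]
    cell_means = cell_groups.mean()
    cell_sizes = cell_groups.size()
    ss_cells = float((cell_sizes * (cell_means - grand) ** 2).sum())
    ss_gei = ss_cells - ss_env - ss_gen

    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_env - ss_rep - ss_gen - ss_gei

    g, e = data.n_genotypes, data.n_environments
    reps = data.replicates_per_environment
    df_env = e - 1
    df_rep = sum(r - 1 for r in reps.values())
    df_gen = g - 1
    df_gei = (g - 1) * (e - 1)
    df_err = sum((g - 1) * (r - 1) for r in reps.values())
    df_tot = n - 1

    rows = {
        SOURCE_ENV: (df_env, ss_env),
        SOURCE_REP: (df_rep, ss_rep),
        SOURCE_GEN: (df_gen, ss_gen),
        SOURCE_GEI: (df_gei, ss_gei),
        SOURCE_ERR: (df_err, ss_err),
        SOURCE_TOT: (df_tot, ss_tot),
    }
    table = pd.DataFrame(
        {
            "df": {k: v[0] for k, v in rows.items()},
            "SS": {k: max(v[1], 0.0) for k, v in rows.items()},
        }
    ).loc[list(rows)]
    with np.errstate(invalid="ignore", divide="ignore"):
        table["MS"] = table["SS"] / table["df"].replace(0, np.nan)
    table.loc[SOURCE_TOT, "MS"] = np.nan

    has_error = df_err > 0 and df_rep > 0
    table["F"] = np.nan
    table["p"] = np.nan
    if has_error:
        err_ms = table.loc[SOURCE_ERR, "MS"]
        rep_ms = table.loc[SOURCE_REP, "MS"]
        for src, denom_ms, denom_df in (
            (SOURCE_ENV, rep_ms, df_rep),
            (SOURCE_REP, err_ms, df_err),
            (SOURCE_GEN, err_ms, df_err),
            (SOURCE_GEI, err_ms, df_err),
        ):
            if denom_ms > 0:
                f = table.loc[src, "MS"] / denom_ms
                table.loc[src, "F"] = f
                table.loc[src, "p"] = stats.f.sf(f, table.loc[src, "df"], denom_df)

    table["percent_of_total"] = np.where(
        table.index == SOURCE_TOT, np.nan, 100.0 * table["SS"] / ss_tot if ss_tot > 0 else 0.0
    )
    return CombinedAnova(table=table, has_error_term=bool(has_error))


@dataclass
class AMMIResult:
    """SVD of the interaction matrix with scaled scores and axis diagnostics.

    ``genotype_scores`` / ``environment_scores`` are the symmetrically
    scaled coordinates sqrt(lambda_n) * (gamma, delta); ``genotype_vectors``
    / ``environment_vectors`` are the unit eigenvectors themselves.
    ``ipc_ss`` is r * lambda_n^2, the plot-scale SS of each axis.
    """

    genotypes: list[str]
    environments: list[str]
    singular_values: np.ndarray      # length p, descending
    genotype_scores: np.ndarray      # g x p
    environment_scores: np.ndarray   # e x p
    genotype_vectors: np.ndarray     # g x p (unit gamma)
    environment_vectors: np.ndarray  # e x p (unit delta)
    percent_explained: np.ndarray    # theta_n in %
    cumulative_percent: np.ndarray
    ipc_ss: np.ndarray               # r * lambda_n^2
    replicate_count: float
    zero_interaction: bool
    gollob: Optional[pd.DataFrame] = None
    n_significant: Optional[int] = None

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.singular_values**2

    @property
    def n_axes(self) -> int:
        return self.singular_values.size

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"IPC{n + 1}" for n in range(self.n_axes)]
        gdf = pd.DataFrame(self.genotype_scores, index=self.genotypes, columns=cols)
        gdf.insert(0, "kind", "genotype")
        edf = pd.DataFrame(self.environment_scores, index=self.environments, columns=cols)
        edf.insert(0, "kind", "environment")
        out = pd.concat([gdf, edf])
        out.index.name = "name"
        return out


def ammi_decompose(means: GEMeansMatrix, replicate_count: float = 1) -> AMMIResult:
    """SVD the doubly-centered interaction into interaction principal components.

    All p = min(g-1, e-1) axes are retained; theta_n is reported in
    percent of the interaction SS.  A numerically zero interaction is
    flagged and returns zero scores with theta = 0.
    """
    ge = means.interaction
    g, e = ge.shape
    p = min(g - 1, e - 1)
    u, s, vt = np.linalg.svd(ge, full_matrices=False)
    u, s, v = u[:, :p], s[:p], vt[:p].T

    # axis-wise sign fix: dominant genotype loading positive
    for n_ax in range(p):
        i = int(np.argmax(np.abs(u[:, n_ax])))
        if u[i, n_ax] < 0:
            u[:, n_ax] = -u[:, n_ax]
            v[:, n_ax] = -v[:, n_ax]

    total = float((s**2).sum())
    scale = max(1.0, abs(means.grand_mean))
    zero = total <= (1e-10 * scale) ** 2 * g * e
    if zero:
        theta = np.zeros(p)
    else:
        theta = 100.0 * s**2 / total
    root = np.sqrt(s)
    return AMMIResult(
        genotypes=list(means.genotypes),
        environments=list(means.environments),
        singular_values=s,
        genotype_scores=u * root,
        environment_scores=v * root,
        genotype_vectors=u,
        environment_vectors=v,
        percent_explained=theta,
        cumulative_percent=np.cumsum(theta),
        ipc_ss=replicate_count * s**2,
        replicate_count=float(replicate_count),
        zero_interaction=bool(zero),
    )


def gollob_test(ammi: AMMIResult, anova: CombinedAnova, alpha: float = 0.05) -> AMMIResult:
    """Attach Gollob F-tests per IPC and the significant-axis count N'.

    Axis n has df = g + e - 1 - 2n and mean square r * lambda_n^2 / df,
    tested against the pooled error MS.  N' counts axes from the first
    until the first non-significant one and is floored at 1.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not anova.has_error_term:
        raise METValidationError("Gollob test needs a pooled error term (>= 2 replicates somewhere)")
    g = len(ammi.genotypes)
    e = len(ammi.environments)
    err_ms, err_df = anova.error_ms, anova.error_df

    rows = []
    for n_ax in range(ammi.n_axes):
        dfn = g + e - 1 - 2 * (n_ax + 1)
        if dfn <= 0:
            break
        ms = ammi.ipc_ss[n_ax] / dfn
        if err_ms > 0:
            f = ms / err_ms
        else:
            f = np.inf if ms > 0 else 0.0
        pval = float(stats.f.sf(f, dfn, err_df))
        rows.append(
            {"axis": n_ax + 1, "df": dfn, "SS": ammi.ipc_ss[n_ax], "MS": ms, "F": f, "p": pval,
             "significant": pval < alpha}
        )
    gollob = pd.DataFrame(rows).set_index("axis") if rows else pd.DataFrame(
        columns=["df", "SS", "MS", "F", "p", "significant"]
    )

    n_sig = 0
    for sig in gollob["significant"]:
        if not sig:
            break
        n_sig += 1
    n_sig = max(n_sig, 1)
    return replace(ammi, gollob=gollob, n_significant=n_sig)


def ammi1_coords(means: GEMeansMatrix, ammi: AMMIResult) -> pd.DataFrame:
    """AMMI1 biplot coordinates: mean yield on the abscissa, IPC1 on the ordinate.

    One row per genotype (its mean over environments) and per environment
    (its mean over genotypes).  The grand mean — the vertical reference
    line of the biplot — is carried in ``attrs['grand_mean']``.
    """
    if ammi.n_axes < 1:
        raise METValidationError("AMMI1 needs at least one interaction axis")
    rows = [
        {"kind": "genotype", "name": gname, "mean": m, "IPC1": s}
        for gname, m, s in zip(ammi.genotypes, means.genotype_means(), ammi.genotype_scores[:, 0])
    ] + [
        {"kind": "environment", "name": ename, "mean": m, "IPC1": s}
        for ename, m, s in zip(ammi.environments, means.environment_means(), ammi.environment_scores[:, 0])
    ]
    out = pd.DataFrame(rows)
    out.attrs["grand_mean"] = means.grand_mean
    return out


def ammi2_coords(ammi: AMMIResult) -> pd.DataFrame:
    """AMMI2 biplot coordinates: (IPC1, IPC2) per genotype and environment.

    ``distance_from_origin`` (genotype interaction magnitude; environment
    vector length) supports the usual stability / discrimination reading.
    """
    if ammi.n_axes < 2:
        raise METValidationError("AMMI2 needs two interaction axes; use ammi1_coords for rank-1 problems")
    rows = []
    for kind, names, scores in (
        ("genotype", ammi.genotypes, ammi.genotype_scores),
        ("environment", ammi.environments, ammi.environment_scores),
    ):
        for name, sc in zip(names, scores):
            rows.append(
                {
                    "kind": kind,
                    "name": name,
                    "IPC1": sc[0],
                    "IPC2": sc[1],
                    "distance_from_origin": float(np.hypot(sc[0], sc[1])),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["percent_explained"] = tuple(ammi.percent_explained[:2])
    return out


def ammi_analysis(data: METDataset, alpha: float = 0.05, impute: str | None = None):
    """Convenience chain: means -> combined ANOVA -> AMMI -> Gollob.

    Returns (GEMeansMatrix, CombinedAnova, AMMIResult).  When the trial has
    no error term (single replicate everywhere) the Gollob step is skipped
    and ``n_significant`` defaults to the number of axes.
    """
    means = compute_ge_means(data, impute=impute)
    anova = combined_anova(data)
    ammi = ammi_decompose(means, replicate_count=data.uniform_replicate_count())
    if anova.has_error_term:
        ammi = gollob_test(ammi, anova, alpha=alpha)
    else:
        ammi = replace(ammi, n_significant=ammi.n_axes)
    return means, anova, ammi
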