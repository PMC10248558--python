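"""Mixed-model genotypic values and harmonic-mean stability statistics.

The MET mixed model treats environments and blocks-within-environments as
fixed and genotype and genotype x environment effects as random:

    y_ijk = env_j + block_jk + g_i + ge_ij + e_ijk,
    g_i ~ N(0, sigma2_g),  ge_ij ~ N(0, sigma2_ge),  e_ijk ~ N(0, sigma2_e).

Variance components are estimated by REML with EM updates on Henderson's
mixed-model equations, which keeps every estimate non-negative; BLUPs of
g and ge are read off the equations at the final estimates.  The
genotypic value of genotype i in environment j is

    GV_ij = u_j + g_i + ge_ij,

with u_j the environment mean.  Three summary statistics combine yield
level, stability and adaptability on the genotypic-value scale:

    HMGV_i   = e / sum_j (1 / GV_ij)              (harmonic mean)
    RPGV_i   = (1/e) sum_j GV_ij / u_j            (relative performance)
    HMRPGV_i = e / sum_j (u_j / GV_ij)            (harmonic mean of the
                                                   relative values)

HMRPGV * mu puts the last statistic back on kg ha^-1.  Genotypes are
ranked descending (larger = better) on all three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import METDataset, METValidationError, compute_ge_means

__all__ = [
    "VarianceComponents",
    "GenotypicValues",
    "fit_met_mixed_model",
    "hmgv",
    "rpgv",
    "hmrpgv",
    "hmrpgv_table",
    "REMLConvergenceError",
]


class REMLConvergenceError(RuntimeError):
    """EM-REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: pd.DataFrame):
        super().__init__(message)
        self.trace = trace


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    loglik_reml: float
    n_iterations: int
    converged: bool
    boundary: tuple[str, ...] = ()   # components pinned at the zero boundary
    stopped_on: str = "parameters"   # 'parameters' or 'loglik'

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "sigma2_g": self.sigma2_g,
                "sigma2_ge": self.sigma2_ge,
                "sigma2_e": self.sigma2_e,
                "loglik_reml": self.loglik_reml,
                "n_iterations": self.n_iterations,
                "converged": self.converged,
            }
        )


@dataclass
class GenotypicValues:
    genotypes: list[str]
    environments: list[str]
    environment_means: np.ndarray  # u_j
    g_blup: np.ndarray             # shrunken genotype effects
    ge_blup: np.ndarray            # g x e shrunken interaction effects
    gv: np.ndarray                 # g x e, u_j + g_i + ge_ij

    def gv_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gv, index=self.genotypes, columns=self.environments)


def _design_matrices(data: METDataset):
    df = data.frame
    gcat = pd.Categorical(df["genotype"], categories=data.genotypes)
    ecat = pd.Categorical(df["environment"], categories=data.environments)
    gi = np.asarray(gcat.codes)
    ej = np.asarray(ecat.codes)
    n = len(df)
    g, e = data.n_genotypes, data.n_environments

    # fixed effects: environment cell means + treatment-coded blocks within env
    env_X = np.zeros((n, e))
    env_X[np.arange(n), ej] = 1.0
    block_cols = []
    for env in data.environments:
        reps = sorted(df.loc[df["environment"] == env, "replicate"].unique())
        for rep in reps[1:]:
            col = ((df["environment"] == env) & (df["replicate"] == rep)).to_numpy(dtype=float)
            block_cols.append(col)
    X = np.column_stack([env_X] + block_cols) if block_cols else env_X

    Zg = np.zeros((n, g))
    Zg[np.arange(n), gi] = 1.0
    Zge = np.zeros((n, g * e))
    Zge[np.arange(n), gi * e + ej] = 1.0
    return X, Zg, Zge


def fit_met_mixed_model(
    data: METDataset,
    tolerance: float = 1e-8,
    max_iterations: int = 500,
) -> tuple[VarianceComponents, GenotypicValues]:
    """Fit the MET mixed model by EM-REML and assemble genotypic values.

    Convergence requires the relative change in every variance component
    to drop below ``tolerance`` (changes are measured against
    max(component, 1e-6 * var(y)) so components that collapse to the zero
    boundary cannot stall the loop; such components are pinned at 0 and
    reported in ``boundary``).  Raises :class:`REMLConvergenceError` with
    the iteration trace when ``max_iterations`` is exhausted.
    """
    if not data.is_complete():
        compute_ge_means(data)  # raises with the missing cells
    if all(r < 2 for r in data.replicates_per_environment.values()):
        raise METValidationError("mixed model needs >= 2 replicates in at least one environment")

    y = data.frame["yield"].to_numpy(dtype=float)
    X, Zg, Zge = _design_matrices(data)
    n, p = X.shape
    g = data.n_genotypes
    e = data.n_environments
    q_g, q_ge = g, g * e

    Z = np.hstack([Zg, Zge])
    W = np.hstack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y

    vary = float(np.var(y)) or 1.0
    floor = 1e-8 * vary
    denom_floor = 1e-6 * vary
    dg = np.arange(p, p + q_g)
    dge = np.arange(p + q_g, p + q_g + q_ge)

    # smallest admissible shrinkage ridge: far above the fp noise of the
    # normal equations (which would otherwise leave the constant direction
    # shared by X and Zg numerically unidentified at huge variance ratios),
    # far below any statistically meaningful amount of shrinkage
    lam_floor = 1e-8 * float(np.mean(np.diag(WtW)[p:]))

    def solve_mme(s2g, s2ge, s2e):
        """Solve Henderson's equations over the active blocks only.

        A pinned (zero-variance) random factor is dropped from the system
        entirely — an 'infinite ridge' stand-in would wreck the
        conditioning of the remaining blocks.  Returns the full-length
        solution (zeros in pinned blocks) and the inverse over the kept
        columns.
        """
        keep = list(range(p))
        lam = np.zeros(p)
        if s2g > 0:
            keep += list(dg)
            lam = np.concatenate([lam, np.full(q_g, max(s2e / s2g, lam_floor))])
        if s2ge > 0:
            keep += list(dge)
            lam = np.concatenate([lam, np.full(q_ge, max(s2e / s2ge, lam_floor))])
        keep = np.asarray(keep)
        M = WtW[np.ix_(keep, keep)].copy()
        M[np.diag_indices_from(M)] += lam
        Minv = np.linalg.inv(M)
        sol = np.zeros(WtW.shape[0])
        sol[keep] = Minv @ Wty[keep]
        return sol, Minv, keep

    def em_step(s2g, s2ge, s2e):
        sol, Minv, keep = solve_mme(s2g, s2ge, s2e)
        # EM residual update is y'e_hat/(n-p); expand y = fitted + e_hat so
        # no large-number cancellation occurs at tiny noise (the classical
        # y'y - sol'W'y form loses all precision there)
        fitted = W @ sol
        resid = y - fitted
        s2e_new = (float(resid @ resid) + float(fitted @ resid)) / (n - p)
        s2g_new, s2ge_new = 0.0, 0.0
        pos = {int(i): int(j) for j, i in enumerate(keep)}
        if s2g > 0:
            ug = sol[dg]
            jg = [pos[int(i)] for i in dg]
            s2g_new = (float(ug @ ug) + s2e_new * float(np.trace(Minv[np.ix_(jg, jg)]))) / q_g
        if s2ge > 0:
            uge = sol[dge]
            jge = [pos[int(i)] for i in dge]
            s2ge_new = (float(uge @ uge) + s2e_new * float(np.trace(Minv[np.ix_(jge, jge)]))) / q_ge
        # defensive clamps: at extreme variance ratios floating-point error
        # can push an update out of the parameter space
        s2e_new = max(s2e_new, 1e-12 * vary)
        return max(s2g_new, 0.0), max(s2ge_new, 0.0), s2e_new

    s2g, s2ge, s2e = vary / 4, vary / 4, vary / 2
    history: list[tuple[float, float, float]] = []
    trace_rows = []
    converged = False
    stopped_on = "parameters"
    last_ll = None
    it = 0
    for it in range(1, max_iterations + 1):
        s2g_new, s2ge_new, s2e_new = em_step(s2g, s2ge, s2e)

        changes = [
            abs(s2g_new - s2g) / max(abs(s2g), denom_floor),
            abs(s2ge_new - s2ge) / max(abs(s2ge), denom_floor),
            abs(s2e_new - s2e) / max(abs(s2e), denom_floor),
        ]
        trace_rows.append({"iteration": it, "sigma2_g": s2g_new, "sigma2_ge": s2ge_new, "sigma2_e": s2e_new})
        s2g, s2ge, s2e = s2g_new, s2ge_new, s2e_new

        # direct boundary hit
        if s2g > 0 and s2g < floor:
            s2g = 0.0
        if s2ge > 0 and s2ge < floor:
            s2ge = 0.0
        # stall in the flat region near zero: EM approaches an exact-zero
        # REML maximum only hyperbolically, so a component that is still
        # moving but has fallen far below the statistical noise floor is a
        # boundary estimate
        if it > 50:
            if s2g > 0 and s2g < 1e-4 * vary and changes[0] > tolerance:
                s2g = 0.0
            if s2ge > 0 and s2ge < 1e-4 * vary and changes[1] > tolerance:
                s2ge = 0.0

        # Aitken extrapolation of the (linearly convergent) EM sequence:
        # a component whose geometric limit is <= 0 is collapsing to the
        # boundary and is pinned there; interior components may jump to
        # the extrapolated fixed point (safeguarded) to accelerate EM
        # Aitken acceleration during the coarse phase only (near the fixed
        # point the extrapolation would just chase numerical noise); a
        # geometric limit at or below zero pins the component
        history.append((s2g, s2ge, s2e))
        if it % 8 == 0 and len(history) >= 3 and max(changes) > 1e-4:
            prev2, prev1, cur = history[-3], history[-2], history[-1]
            accel = [s2g, s2ge, s2e]
            for comp in range(2):  # only the pinnable variance components
                if cur[comp] <= 0:
                    continue
                d1 = prev1[comp] - prev2[comp]
                d2 = cur[comp] - prev1[comp]
                if abs(d1) < 1e-300 or abs(d2) >= abs(d1):
                    continue
                c = d2 / d1
                if not (0 < c < 1):
                    continue
                limit = cur[comp] + d2 * c / (1.0 - c)
                if limit < floor:
                    accel[comp] = 0.0
                else:
                    accel[comp] = limit
            s2g, s2ge = accel[0], accel[1]

        if max(changes) < tolerance:
            converged = True
            break

        # EM can crawl along a nearly flat likelihood ridge (missing
        # information close to one) long after the fit has stopped
        # improving; a stalled restricted likelihood is convergence too
        if it % 40 == 0:
            ll = _reml_loglik(y, X, Zg, Zge, s2g, s2ge, s2e)
            if last_ll is not None and abs(ll - last_ll) < 1e-8 * (1.0 + abs(ll)):
                converged = True
                stopped_on = "loglik"
                break
            last_ll = ll

    trace = pd.DataFrame(trace_rows)
    if not converged:
        raise REMLConvergenceError(
            f"EM-REML did not converge in {max_iterations} iterations "
            f"(last relative change {max(changes):.3e})",
            trace,
        )

    # final solve at the converged estimates
    sol, _, _ = solve_mme(s2g, s2ge, s2e)
    ug = sol[dg]
    uge = sol[dge].reshape(g, e)

    loglik = _reml_loglik(y, X, Zg, Zge, s2g, s2ge, s2e)
    boundary = tuple(name for name, act in (("sigma2_g", s2g == 0.0), ("sigma2_ge", s2ge == 0.0)) if act)
    vc = VarianceComponents(
        sigma2_g=float(s2g),
        sigma2_ge=float(s2ge),
        sigma2_e=float(s2e),
        loglik_reml=float(loglik),
        n_iterations=it,
        converged=converged,
        boundary=boundary,
        stopped_on=stopped_on,
    )

    env_means = (
        data.frame.groupby("environment", sort=False)["yield"].mean().reindex(data.environments).to_numpy()
    )
    gv = env_means[None, :] + ug[:, None] + uge
    gvals = GenotypicValues(
        genotypes=list(data.genotypes),
        environments=list(data.environments),
        environment_means=env_means,
        g_blup=ug,
        ge_blup=uge,
        gv=gv,
    )
    return vc, gvals


def _reml_loglik(y, X, Zg, Zge, s2g, s2ge, s2e) -> float:
    from scipy import linalg as sla

    n = y.size
    V = s2e * np.eye(n)
    if s2g > 0:
        V += s2g * (Zg @ Zg.T)
    if s2ge > 0:
        V += s2ge * (Zge @ Zge.T)
    try:
        chol = sla.cho_factor(V, lower=True)
    except sla.LinAlgError:
        # extreme variance ratios: lift the smallest eigenvalues a hair
        V[np.diag_indices_from(V)] += 1e-12 * float(np.trace(V)) / n
        chol = sla.cho_factor(V, lower=True)
    logdet_v = 2.0 * float(np.log(np.diag(chol[0])).sum())
    Vinv_y = sla.cho_solve(chol, y)
    Vinv_X = sla.cho_solve(chol, X)
    XtVinvX = X.T @ Vinv_X
    _, logdet_x = np.linalg.slogdet(XtVinvX)
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    resid = y - X @ beta
    return -0.5 * (logdet_v + logdet_x + float(resid @ sla.cho_solve(chol, resid)))


def _check_positive(values: np.ndarray, what: str) -> None:
    bad = np.argwhere(values <= 0)
    if bad.size:
        raise ValueError(f"{what} must be positive; first offending entry at index {tuple(bad[0])}")


def hmgv(gv: GenotypicValues) -> np.ndarray:
    """Harmonic mean of each genotype's genotypic values across environments."""
    _check_positive(gv.gv, "genotypic values")
    e = gv.gv.shape[1]
    return e / (1.0 / gv.gv).sum(axis=1)


def rpgv(gv: GenotypicValues) -> np.ndarray:
    """Mean of genotypic values expressed relative to their environment mean."""
    _check_positive(gv.environment_means, "environment means")
    return (gv.gv / gv.environment_means[None, :]).mean(axis=1)


def hmrpgv(gv: GenotypicValues, grand_mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic mean of relative genotypic values, and its kg ha^-1 rescaling."""
    _check_positive(gv.environment_means, "environment means")
    ratios = gv.gv / gv.environment_means[None, :]
    _check_positive(ratios, "genotypic value / environment mean ratios")
    e = ratios.shape[1]
    h = e / (1.0 / ratios).sum(axis=1)
    return h, h * grand_mean


def hmrpgv_table(gv: GenotypicValues, grand_mean: float) -> pd.DataFrame:
    """HMGV / RPGV / HMRPGV per genotype with descending-value ranks."""
    h = hmgv(gv)
    r = rpgv(gv)
    hr, hr_mu = hmrpgv(gv, grand_mean)
    out = pd.DataFrame(
        {"HMGV": h, "RPGV": r, "HMRPGV": hr, "HMRPGV_x_mu": hr_mu},
        index=gv.genotypes,
    )
    for col in ("HMGV", "RPGV", "HMRPGV"):
        out[f"rank_{col}"] = rankdata(-out[col].to_numpy(), method="min").astype(int)
    out.index.name = "genotype"
    return out
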