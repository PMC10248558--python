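"""Interpreting the G x E interaction with environmental covariates.

Two complementary decompositions of the doubly-centered interaction
matrix in terms of measured environment covariates (seasonal rainfall,
seasonal mean temperature):

* **Factorial regression (FR)** regresses each genotype's interaction row
  on centered covariate columns, giving per-genotype sensitivities xi_ik
  (kg ha^-1 per covariate unit); covariates enter by forward selection on
  the Akaike information criterion.
* **Partial least squares regression (PLSR)** extracts paired latent
  factors from the covariate matrix X (environments x variables,
  centered, standardized by default) and the interaction transposed to
  environments x genotypes, Y = T Q' + F and X = T P' + E, via the
  NIPALS algorithm.  Factor scores/loadings feed a biplot relating
  environments, covariates and genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CovariateMatrix

__all__ = [
    "FRModel",
    "PLSRModel",
    "fit_factorial_regression",
    "stepwise_fr_aic",
    "fit_plsr",
    "plsr_biplot_coords",
]


@dataclass
class FRModel:
    """Least-squares fit of interaction rows on selected covariates."""

    genotypes: list[str]
    selected_variables: list[str]
    xi: np.ndarray                   # g x K_selected sensitivities
    fitted_interaction: np.ndarray   # g x e
    residual_ss: float
    total_ss: float
    explained_ss_per_variable: np.ndarray  # sequential, in selection order
    aic_trace: pd.DataFrame = field(default_factory=pd.DataFrame)
    perfect_fit: bool = False

    @property
    def explained_ss(self) -> float:
        return self.total_ss - self.residual_ss

    def xi_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.xi, index=self.genotypes, columns=self.selected_variables)
        out.index.name = "genotype"
        return out


def _prepare(interaction: np.ndarray, cov: CovariateMatrix):
    ge = np.asarray(interaction, dtype=float)
    if ge.shape[1] != cov.n_environments:
        raise ValueError(
            f"interaction has {ge.shape[1]} environments, covariates have {cov.n_environments}"
        )
    if not cov.centered:
        raise ValueError("covariates must be centered first (see center_covariates)")
    return ge


def fit_factorial_regression(
    interaction: np.ndarray,
    cov: CovariateMatrix,
    variables: list[str] | None = None,
    genotypes: list[str] | None = None,
) -> FRModel:
    """Estimate genotype sensitivities xi to the given covariates.

    For each genotype i the interaction row ge_i (length e) is regressed
    on the centered covariate columns Z: ge_i ~ Z xi_i, solved jointly by
    ordinary least squares.  The sequential (in the given variable order)
    SS decomposition satisfies explained + residual = total.  An empty
    variable list yields the null model (fitted 0 everywhere).
    """
    ge = _prepare(interaction, cov)
    g, e = ge.shape
    if variables is None:
        variables = list(cov.variable_names)
    unknown = [v for v in variables if v not in cov.variable_names]
    if unknown:
        raise ValueError(f"unknown covariate variables: {unknown}")
    if len(variables) >= e:
        raise ValueError(f"{len(variables)} covariates with e = {e} environments over-saturates the fit")
    genotypes = genotypes if genotypes is not None else [f"G{i + 1}" for i in range(g)]
    total_ss = float((ge**2).sum())

    cols = [cov.variable_names.index(v) for v in variables]
    Z = cov.values[:, cols]
    k = Z.shape[1]
    if k == 0:
        return FRModel(
            genotypes=list(genotypes),
            selected_variables=[],
            xi=np.zeros((g, 0)),
            fitted_interaction=np.zeros_like(ge),
            residual_ss=total_ss,
            total_ss=total_ss,
            explained_ss_per_variable=np.zeros(0),
        )
    if np.linalg.matrix_rank(Z) < k:
        raise ValueError(f"collinear covariate columns among {variables}: design matrix is rank-deficient")

    xi, *_ = np.linalg.lstsq(Z, ge.T, rcond=None)
    xi = xi.T  # g x k
    fitted = xi @ Z.T
    residual_ss = float(((ge - fitted) ** 2).sum())

    # sequential SS: successive RSS drops as variables enter in order
    explained = np.zeros(k)
    prev_rss = total_ss
    for j in range(1, k + 1):
        coef, *_ = np.linalg.lstsq(Z[:, :j], ge.T, rcond=None)
        rss = float(((ge.T - Z[:, :j] @ coef) ** 2).sum())
        explained[j - 1] = prev_rss - rss
        prev_rss = rss

    return FRModel(
        genotypes=list(genotypes),
        selected_variables=list(variables),
        xi=xi,
        fitted_interaction=fitted,
        residual_ss=residual_ss,
        total_ss=total_ss,
        explained_ss_per_variable=explained,
    )


def stepwise_fr_aic(
    interaction: np.ndarray,
    cov: CovariateMatrix,
    genotypes: list[str] | None = None,
) -> FRModel:
    """Forward-select covariates for factorial regression by AIC.

    AIC = N ln(RSS/N) + 2 P with N = g*e interaction cells and P = g * k
    sensitivity parameters for k selected covariates.  At each step the
    candidate lowering AIC the most enters (ties broken by covariate
    column order); selection stops when no candidate lowers AIC, or — with
    a perfect-fit flag — when the residual vanishes.
    """
    ge = _prepare(interaction, cov)
    g, e = ge.shape
    n_cells = g * e
    total_ss = float((ge**2).sum())
    eps = 1e-12 * max(total_ss, 1.0)

    def aic_of(rss: float, n_vars: int) -> float:
        rss = max(rss, eps)
        return n_cells * np.log(rss / n_cells) + 2.0 * g * n_vars

    selected: list[str] = []
    current_aic = aic_of(total_ss, 0)
    current_rss = total_ss
    trace = [{"step": 0, "variable": None, "AIC": current_aic, "RSS": current_rss}]
    perfect = False

    remaining = list(cov.variable_names)
    while remaining and len(selected) < e - 1:
        best = None
        for v in remaining:
            try:
                m = fit_factorial_regression(ge, cov, selected + [v], genotypes=genotypes)
            except ValueError:
                continue  # collinear with what's already in — skip candidate
            cand_aic = aic_of(m.residual_ss, len(selected) + 1)
            if best is None or cand_aic < best[1] - 1e-12:
                best = (v, cand_aic, m.residual_ss)
        if best is None or best[1] >= current_aic:
            break
        selected.append(best[0])
        remaining.remove(best[0])
        current_aic, current_rss = best[1], best[2]
        trace.append({"step": len(selected), "variable": best[0], "AIC": current_aic, "RSS": current_rss})
        if current_rss <= eps:
            perfect = True
            break

    model = fit_factorial_regression(ge, cov, selected, genotypes=genotypes)
    model.aic_trace = pd.DataFrame(trace)
    model.perfect_fit = perfect
    return model


@dataclass
class PLSRModel:
    """NIPALS partial-least-squares factors linking covariates to interaction."""

    environments: list[str]
    variable_names: list[str]
    genotypes: list[str]
    x_scores: np.ndarray      # T, e x A
    x_loadings: np.ndarray    # P, K x A
    y_loadings: np.ndarray    # Q, g x A
    weights: np.ndarray       # W, K x A
    percent_y_explained: np.ndarray
    percent_x_explained: np.ndarray
    x_residual: np.ndarray    # E
    y_residual: np.ndarray    # F

    @property
    def n_factors(self) -> int:
        return self.x_scores.shape[1]


def fit_plsr(
    x: CovariateMatrix,
    y: np.ndarray,
    n_factors: int,
    genotypes: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> PLSRModel:
    """Extract ``n_factors`` PLS2 factors by NIPALS.

    ``x`` must be centered (standardization recommended when columns mix
    units); ``y`` is the interaction transposed to environments x
    genotypes.  Per factor: pick the Y column of largest variance as the
    starting u, iterate w = X'u/|X'u|, t = Xw, q = Y't/t't, u = Yq/q'q to
    convergence of t, then p = X't/t't and deflate both matrices by t.
    Percent of Y (and X) SS explained is measured against the undeflated
    input.  Signs are fixed per factor so the covariate with the largest
    absolute loading is positive.
    """
    if not x.centered:
        raise ValueError("X covariates must be centered (and usually standardized) before PLSR")
    X = x.values.copy()
    Y = np.asarray(y, dtype=float).copy()
    e, k = X.shape
    if Y.shape[0] != e:
        raise ValueError(f"Y must be environments x genotypes with {e} rows, got {Y.shape}")
    g = Y.shape[1]
    a_max = min(e - 1, k)
    if not (1 <= n_factors <= a_max):
        raise ValueError(f"n_factors must be in [1, {a_max}], got {n_factors}")
    genotypes = genotypes if genotypes is not None else [f"G{i + 1}" for i in range(g)]

    ss_y = float((Y**2).sum())
    ss_x = float((X**2).sum())
    T = np.zeros((e, n_factors))
    P = np.zeros((k, n_factors))
    Q = np.zeros((g, n_factors))
    Wmat = np.zeros((k, n_factors))
    pct_y = np.zeros(n_factors)
    pct_x = np.zeros(n_factors)

    for a in range(n_factors):
        if float((Y**2).sum()) <= 1e-14 * max(ss_y, 1.0):
            break  # response exhausted; remaining factors stay zero
        u = Y[:, int(np.argmax((Y**2).sum(axis=0)))].copy()
        t_old = np.zeros(e)
        for _ in range(max_iter):
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise RuntimeError(f"NIPALS degenerate weight vector at factor {a + 1}")
            w /= norm
            t = X @ w
            tt = float(t @ t)
            if tt == 0:
                raise RuntimeError(f"NIPALS zero score vector at factor {a + 1}")
            q = Y.T @ t / tt
            qq = float(q @ q)
            u = Y @ q / qq if qq > 0 else t.copy()
            if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        else:
            raise RuntimeError(f"NIPALS did not converge within {max_iter} iterations at factor {a + 1}")

        p_load = X.T @ t / tt
        # deterministic sign: dominant covariate loading positive
        i = int(np.argmax(np.abs(p_load)))
        if p_load[i] < 0:
            w, t, p_load, q = -w, -t, -p_load, -q
        T[:, a], P[:, a], Q[:, a], Wmat[:, a] = t, p_load, q, w
        pct_y[a] = 100.0 * float(((np.outer(t, q)) ** 2).sum()) / ss_y if ss_y > 0 else 0.0
        pct_x[a] = 100.0 * float(((np.outer(t, p_load)) ** 2).sum()) / ss_x if ss_x > 0 else 0.0
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, q)

    return PLSRModel(
        environments=list(x.environments),
        variable_names=list(x.variable_names),
        genotypes=list(genotypes),
        x_scores=T,
        x_loadings=P,
        y_loadings=Q,
        weights=Wmat,
        percent_y_explained=pct_y,
        percent_x_explained=pct_x,
        x_residual=X,
        y_residual=Y,
    )


def plsr_biplot_coords(model: PLSRModel) -> pd.DataFrame:
    """Coordinates on the first two PLSR factors.

    Environments plot at their factor scores (t1, t2), covariates at
    their X-loadings (p1, p2) and genotypes at their Y-loadings (q1, q2);
    the per-factor percent of interaction SS explained is carried in
    ``attrs['percent_y_explained']``.
    """
    if model.n_factors < 2:
        raise ValueError("biplot needs at least two extracted factors")
    rows = []
    for name, t in zip(model.environments, model.x_scores):
        rows.append({"kind": "environment", "name": name, "factor1": t[0], "factor2": t[1]})
    for name, p_load in zip(model.variable_names, model.x_loadings):
        rows.append({"kind": "covariate", "name": name, "factor1": p_load[0], "factor2": p_load[1]})
    for name, q in zip(model.genotypes, model.y_loadings):
        rows.append({"kind": "genotype", "name": name, "factor1": q[0], "factor2": q[1]})
    out = pd.DataFrame(rows)
    out.attrs["percent_y_explained"] = tuple(model.percent_y_explained[:2])
    return out
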