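"""AMMI-based stability indices, ranks and simultaneous selection indices.

Seven per-genotype indices summarize how far a genotype sits from the
origin of the interaction-principal-component space; for all of them a
smaller value means a more stable genotype.

With s_in the sqrt(lambda)-scaled genotype score on axis n, gamma_in the
unit eigenvector loading, SS_n the plot-scale axis sum of squares,
theta_n the share of interaction SS on axis n, and N' the number of
significant axes:

    ASV_i  = sqrt( ((SS_1/SS_2) s_i1)^2 + s_i2^2 )
    SIPC_i = sum_{n<=N'} |s_in|
    EV_i   = sum_{n<=N'} gamma_in^2 / N'
    Za_i   = sum_{n<=N'} |theta_n * gamma_in|        (theta as proportion)
    MASV_i = sqrt( sum_{n<N'} (SS_n/SS_{n+1}) s_in^2 + s_iN'^2 )
    D_i    = sqrt( sum_{n<=N'} s_in^2 )
    WAAS_i = sum_k |s_ik| theta_k / sum_k theta_k    (all axes by default)

The simultaneous selection index adds the genotype's stability rank on an
index to its yield rank RY (rank 1 = highest mean yield), so small ssi
flags genotypes that are simultaneously stable and high yielding.  Ties
take the minimum ("competition") rank so that ssi stays a sum of small
integers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ammi import AMMIResult
from .core import GEMeansMatrix

__all__ = [
    "asv",
    "sipc",
    "ev",
    "za",
    "masv",
    "ammi_distance",
    "waas",
    "rank_and_ssi",
    "stability_table",
    "INDEX_NAMES",
]

INDEX_NAMES = ("ASV", "SIPC", "EV", "Za", "D", "WAAS", "MASV")


def _scores(scores: np.ndarray) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    return s[:, None] if s.ndim == 1 else s


def asv(scores: np.ndarray, ss_ipc1: float, ss_ipc2: float) -> np.ndarray:
    """AMMI stability value from the first two axis scores.

    The first-axis score is weighted by SS_IPC1 / SS_IPC2 before taking
    the Euclidean length, compensating for the first axis explaining more
    of the interaction.
    """
    s = _scores(scores)
    if s.shape[1] < 2:
        raise ValueError("ASV needs scores on at least two axes")
    if ss_ipc2 <= 0:
        raise ValueError("ASV undefined: SS of IPC2 is zero (rank-1 interaction)")
    w = ss_ipc1 / ss_ipc2
    return np.sqrt((w * s[:, 0]) ** 2 + s[:, 1] ** 2)


def sipc(scores: np.ndarray, n_axes: int) -> np.ndarray:
    """Sum of absolute IPC scores over the first ``n_axes`` axes."""
    s = _scores(scores)
    _check_axes(n_axes, s.shape[1])
    return np.abs(s[:, :n_axes]).sum(axis=1)


def ev(gamma: np.ndarray, n_axes: int) -> np.ndarray:
    """Averaged squared eigenvector loadings over the first ``n_axes`` axes.

    ``gamma`` must hold unit eigenvector columns (sum of squares one per
    axis), so the index values over genotypes sum to one.
    """
    gm = _scores(gamma)
    _check_axes(n_axes, gm.shape[1])
    return (gm[:, :n_axes] ** 2).sum(axis=1) / n_axes


def za(gamma: np.ndarray, theta: np.ndarray, n_axes: int) -> np.ndarray:
    """Absolute contribution of a genotype to the explained interaction.

    ``theta`` gives each axis' share of the interaction SS as a
    proportion in [0, 1]; the index is sum_n |theta_n * gamma_in|.
    """
    gm = _scores(gamma)
    _check_axes(n_axes, gm.shape[1])
    th = np.asarray(theta, dtype=float)[:n_axes]
    return np.abs(gm[:, :n_axes] * th[None, :]).sum(axis=1)


def masv(scores: np.ndarray, ss_per_ipc: np.ndarray, n_axes: int) -> np.ndarray:
    """Modified AMMI stability value over ``n_axes`` >= 2 axes.

    The multi-axis generalization of ASV: each axis score up to N'-1 is
    weighted by the ratio of consecutive axis sums of squares before the
    Euclidean length is taken, so with N' = 2 MASV is exactly ASV.
    """
    s = _scores(scores)
    if n_axes < 2:
        raise ValueError("MASV needs at least two axes")
    _check_axes(n_axes, s.shape[1])
    ss = np.asarray(ss_per_ipc, dtype=float)[:n_axes]
    if np.any(ss[1:] <= 0):
        raise ValueError("MASV undefined: zero axis SS inside the retained axes")
    ratios = ss[:-1] / ss[1:]
    acc = ((ratios[None, :] * s[:, : n_axes - 1]) ** 2).sum(axis=1) + s[:, n_axes - 1] ** 2
    return np.sqrt(acc)


def ammi_distance(scores: np.ndarray, n_axes: int) -> np.ndarray:
    """Euclidean distance of the genotype from the IPC-space origin (D)."""
    s = _scores(scores)
    _check_axes(n_axes, s.shape[1])
    return np.sqrt((s[:, :n_axes] ** 2).sum(axis=1))


def waas(scores: np.ndarray, theta: np.ndarray, n_axes: int | None = None) -> np.ndarray:
    """Weighted average of absolute scores, weights = per-axis explained variance."""
    s = _scores(scores)
    if n_axes is None:
        n_axes = s.shape[1]
    _check_axes(n_axes, s.shape[1])
    th = np.asarray(theta, dtype=float)[:n_axes]
    denom = th.sum()
    if denom <= 0:
        raise ValueError("WAAS undefined: axis weights sum to zero")
    return (np.abs(s[:, :n_axes]) * th[None, :]).sum(axis=1) / denom


def _check_axes(n_axes: int, available: int) -> None:
    if not (1 <= n_axes <= available):
        raise ValueError(f"n_axes must be in [1, {available}], got {n_axes}")


def rank_and_ssi(indices: pd.DataFrame, mean_yields: pd.Series) -> pd.DataFrame:
    """Rank genotypes per index, add yield ranks, and form ssi columns.

    ``indices``: one row per genotype, one column per stability index
    (smaller = more stable).  Output columns per index X: ``X``,
    ``rank_X``, ``ssi_X``; plus ``mean_yield`` and ``RY``.  Ties share the
    minimum rank.
    """
    out = pd.DataFrame(index=indices.index)
    out["mean_yield"] = mean_yields
    out["RY"] = rankdata(-mean_yields.to_numpy(), method="min").astype(int)
    for col in indices.columns:
        vals = indices[col].to_numpy(dtype=float)
        rk = rankdata(vals, method="min").astype(int)
        out[col] = vals
        out[f"rank_{col}"] = rk
        out[f"ssi_{col}"] = rk + out["RY"]
    return out


def stability_table(
    ammi: AMMIResult,
    means: GEMeansMatrix,
    n_axes: int | None = None,
    waas_axes: int | None = None,
) -> pd.DataFrame:
    """Compute all seven indices, ranks, RY and ssi for every genotype.

    ``n_axes`` defaults to the Gollob significant-axis count N' carried by
    ``ammi`` (or all axes when no test was run).  ASV always uses axes 1-2;
    MASV uses max(N', 2); WAAS uses all axes unless ``waas_axes`` says
    otherwise.  On a flagged zero interaction every index is exactly zero.
    """
    gnames = ammi.genotypes
    p = ammi.n_axes
    if n_axes is None:
        n_axes = ammi.n_significant if ammi.n_significant is not None else p
    n_axes = int(min(max(n_axes, 1), p))

    if ammi.zero_interaction:
        idx = pd.DataFrame(0.0, index=gnames, columns=list(INDEX_NAMES))
    else:
        s = ammi.genotype_scores
        gm = ammi.genotype_vectors
        theta_prop = ammi.percent_explained / 100.0
        n_masv = min(max(n_axes, 2), p)
        idx = pd.DataFrame(
            {
                "ASV": asv(s, ammi.ipc_ss[0], ammi.ipc_ss[1]) if p >= 2 else np.abs(s[:, 0]),
                "SIPC": sipc(s, n_axes),
                "EV": ev(gm, n_axes),
                "Za": za(gm, theta_prop, n_axes),
                "D": ammi_distance(s, n_axes),
                "WAAS": waas(s, ammi.percent_explained, waas_axes),
                "MASV": masv(s, ammi.ipc_ss, n_masv) if p >= 2 else np.abs(s[:, 0]),
            },
            index=gnames,
        )[list(INDEX_NAMES)]

    yields = pd.Series(means.genotype_means(), index=gnames, name="mean_yield")
    table = rank_and_ssi(idx, yields)
    table.index.name = "genotype"
    table.attrs["n_axes"] = n_axes
    table.attrs["tie_policy"] = "competition (minimum rank)"
    return table
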