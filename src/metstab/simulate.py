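"""Synthetic multi-environment trials with known ground truth.

The generator emulates the design of a rainfed chickpea variety trial:
16 genotypes x 8 site-year environments in an RCBD with 3 blocks, plot
yields in kg ha^-1.  Yields follow the additive-main-effects /
multiplicative-interaction generative form

    y_ijk = mu + alpha_i + beta_j + sum_n lambda_n gamma_in delta_jn
            + b_jk + eps_ijk

with exactly zero-sum main effects, an exactly low-rank interaction built
from random orthonormal vectors orthogonal to the ones vector, optional
block effects, and i.i.d. Gaussian plot noise.  A covariate-linked
variant instead builds the interaction from per-genotype sensitivities to
environmental covariates (seasonal rainfall and temperature), the
structure factorial regression and PLSR are designed to recover.

Default magnitudes are calibrated so that the expected shares of the
total sum of squares contributed by environments, genotypes, interaction
and noise match a published chickpea MET (environment ~37 %, genotype
~17 %, interaction ~31 % of total; overall mean 1069.25 kg ha^-1).  The
true low-rank spectrum puts ~85 %/10 % of the interaction on the first
two axes; the plot-noise floor spread over all axes caps the *observed*
leading-axis share near 80 % (see docs/methods.md).

Draw order within one seeded generator stream is fixed and documented:
genotype effects, environment effects, genotype interaction vectors,
environment interaction vectors, (covariates, interaction residual when
covariate-linked), block effects, plot noise.  Equal seeds give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import CovariateMatrix, METDataset

__all__ = [
    "CovariateLink",
    "SimulationSpec",
    "GroundTruth",
    "generate_met",
    "generate_covariate_linked",
    "default_covariate_link",
    "DEFAULT_SINGULAR_VALUES",
]

# Interaction spectrum (means scale, kg ha^-1): leading axes carry
# ~85 % and ~10 % of the true interaction SS, with a small tail.
DEFAULT_SINGULAR_VALUES: tuple[float, ...] = (1240.0, 330.0, 145.0, 95.0, 65.0)

DEFAULT_COVARIATE_NAMES = ("FallR", "WinterR", "SpringR", "FallT", "WinterT", "SpringT")
# Seasonal rainfall (mm) and mean temperature (degC) typical of rainfed
# chickpea sites in western Iran.
DEFAULT_COVARIATE_MEANS = (160.0, 230.0, 110.0, 14.0, 7.0, 17.0)
DEFAULT_COVARIATE_SDS = (55.0, 70.0, 45.0, 2.5, 2.0, 2.2)


@dataclass
class CovariateLink:
    """Covariate-driven interaction structure: ge_ij = sum_k xi_ik * z~_jk.

    ``xi_true`` (g x K) holds per-genotype sensitivities; its columns are
    centered across genotypes on construction so the implied interaction
    is doubly centered and directly comparable with factorial-regression
    estimates.  ``residual_sd`` adds an unstructured doubly-centered
    interaction component on top of the covariate-linked part.
    """

    xi_true: np.ndarray
    covariate_means: tuple[float, ...] = DEFAULT_COVARIATE_MEANS
    covariate_sds: tuple[float, ...] = DEFAULT_COVARIATE_SDS
    variable_names: tuple[str, ...] = DEFAULT_COVARIATE_NAMES
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        self.xi_true = np.asarray(self.xi_true, dtype=float)
        if self.xi_true.ndim != 2:
            raise ValueError("xi_true must be a g x K matrix")
        k = self.xi_true.shape[1]
        if not (len(self.covariate_means) == len(self.covariate_sds) == len(self.variable_names) == k):
            raise ValueError("covariate means/sds/names must all have length K")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        # center sensitivities so the linked interaction is doubly centered
        self.xi_true = self.xi_true - self.xi_true.mean(axis=0, keepdims=True)

    @property
    def n_variables(self) -> int:
        return self.xi_true.shape[1]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic trial.

    Defaults reproduce the 16 x 8 x 3 chickpea design with variance
    magnitudes calibrated as described in the module docstring.
    """

    g: int = 16
    e: int = 8
    r: int = 3
    grand_mean: float = 1069.25
    genotype_effect_sd: float = 90.0
    environment_effect_sd: float = 170.0
    interaction_singular_values: Optional[tuple[float, ...]] = None  # default spectrum, truncated to fit
    interaction_sd: float = 0.0
    plot_noise_sd: float = 100.0
    block_effect_sd: float = 0.0
    covariate_link: Optional[CovariateLink] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.g, self.e, self.r) < 1 or self.g < 2 or self.e < 2:
            raise ValueError("need g >= 2, e >= 2, r >= 1")
        for name in (
            "genotype_effect_sd",
            "environment_effect_sd",
            "interaction_sd",
            "plot_noise_sd",
            "block_effect_sd",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.interaction_singular_values is None:
            self.interaction_singular_values = DEFAULT_SINGULAR_VALUES[: min(self.g - 1, self.e - 1)]
        lams = tuple(float(v) for v in self.interaction_singular_values)
        if any(v < 0 for v in lams):
            raise ValueError("singular values must be >= 0")
        if len(lams) > min(self.g - 1, self.e - 1):
            raise ValueError(
                f"requested interaction rank {len(lams)} exceeds min(g-1, e-1) = {min(self.g - 1, self.e - 1)}"
            )
        self.interaction_singular_values = lams


@dataclass
class GroundTruth:
    """Everything the generator drew, for downstream recovery checks."""

    grand_mean: float
    genotype_effects: np.ndarray
    environment_effects: np.ndarray
    singular_values: np.ndarray
    genotype_vectors: np.ndarray      # g x p, orthonormal, orthogonal to ones
    environment_vectors: np.ndarray   # e x p
    interaction: np.ndarray           # g x e
    block_effects: np.ndarray         # e x r, centered within environment
    xi_true: Optional[np.ndarray] = None
    covariates: Optional[np.ndarray] = None  # e x K, uncentered
    covariate_residual: Optional[np.ndarray] = None


def _double_center(m: np.ndarray) -> np.ndarray:
    return m - m.mean(axis=0, keepdims=True) - m.mean(axis=1, keepdims=True) + m.mean()


def _centered_normal(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    x = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    return x - x.mean()


def _orthonormal_offset_ones(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    """p orthonormal columns in R^n, each orthogonal to the all-ones vector."""
    if p == 0:
        return np.zeros((n, 0))
    raw = rng.normal(size=(n, p))
    raw -= raw.mean(axis=0, keepdims=True)  # project out ones
    q, rmat = np.linalg.qr(raw)
    # fix QR sign so the decomposition is unique given the draw
    q = q * np.sign(np.diag(rmat))
    # re-project: QR preserves the column space, already orthogonal to ones
    return q


def _assemble(
    spec: SimulationSpec,
    rng: np.random.Generator,
    alpha: np.ndarray,
    beta: np.ndarray,
    interaction: np.ndarray,
) -> tuple[METDataset, np.ndarray]:
    g, e, r = spec.g, spec.e, spec.r
    blocks = np.zeros((e, r))
    if spec.block_effect_sd > 0:
        blocks = rng.normal(0.0, spec.block_effect_sd, (e, r))
        blocks -= blocks.mean(axis=1, keepdims=True)
    noise = rng.normal(0.0, spec.plot_noise_sd, (g, e, r)) if spec.plot_noise_sd > 0 else np.zeros((g, e, r))
    y = (
        spec.grand_mean
        + alpha[:, None, None]
        + beta[None, :, None]
        + interaction[:, :, None]
        + blocks[None, :, :]
        + noise
    )
    # a plot whose simulated yield falls below zero is a failed plot
    np.maximum(y, 0.0, out=y)
    gen_names = [f"G{i + 1}" for i in range(g)]
    env_names = [f"E{j + 1}" for j in range(e)]
    rep_names = [f"R{k + 1}" for k in range(r)]
    idx = pd.MultiIndex.from_product(
        [gen_names, env_names, rep_names], names=["genotype", "environment", "replicate"]
    )
    # genotype-major record order fixes first-appearance ordering at
    # G1..Gg / E1..Ee, matching the index order of every truth array
    frame = pd.DataFrame({"yield": y.reshape(-1)}, index=idx).reset_index()
    data = METDataset.from_frame(frame)
    return data, blocks


def generate_met(spec: SimulationSpec) -> tuple[METDataset, GroundTruth]:
    """Generate one trial with an exactly low-rank interaction.

    Returns the dataset and the ground truth (drawn effects, singular
    values, orthonormal interaction vectors, block effects).  Determinism:
    identical specs produce bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    g, e = spec.g, spec.e
    alpha = _centered_normal(rng, g, spec.genotype_effect_sd)
    beta = _centered_normal(rng, e, spec.environment_effect_sd)
    lams = np.asarray(spec.interaction_singular_values, dtype=float)
    p = lams.size
    gamma = _orthonormal_offset_ones(rng, g, p)
    delta = _orthonormal_offset_ones(rng, e, p)
    interaction = (gamma * lams) @ delta.T if p else np.zeros((g, e))
    if spec.interaction_sd > 0:
        # unstructured i.i.d. interaction (the mixed-model generative form),
        # doubly centered so the decomposition identities stay exact
        interaction = interaction + _double_center(rng.normal(0.0, spec.interaction_sd, (g, e)))
    data, blocks = _assemble(spec, rng, alpha, beta, interaction)
    truth = GroundTruth(
        grand_mean=spec.grand_mean,
        genotype_effects=alpha,
        environment_effects=beta,
        singular_values=lams,
        genotype_vectors=gamma,
        environment_vectors=delta,
        interaction=interaction,
        block_effects=blocks,
    )
    return data, truth


def generate_covariate_linked(spec: SimulationSpec) -> tuple[METDataset, CovariateMatrix, GroundTruth]:
    """Generate a trial whose interaction is driven by environmental covariates.

    The interaction is ``xi_true @ z~.T`` with ``z~`` the column-centered
    covariate draws, plus an optional unstructured doubly-centered residual
    of per-cell sd ``residual_sd``.  Requires ``spec.covariate_link``.
    """
    link = spec.covariate_link
    if link is None:
        raise ValueError("spec.covariate_link must be provided")
    if link.xi_true.shape[0] != spec.g:
        raise ValueError(f"xi_true has {link.xi_true.shape[0]} rows, expected g = {spec.g}")
    k = link.n_variables
    if k >= spec.e:
        raise ValueError(f"K = {k} covariates with e = {spec.e} environments is unidentifiable (need K < e)")

    rng = np.random.default_rng(spec.seed)
    alpha = _centered_normal(rng, spec.g, spec.genotype_effect_sd)
    beta = _centered_normal(rng, spec.e, spec.environment_effect_sd)
    z = np.asarray(link.covariate_means) + np.asarray(link.covariate_sds) * rng.normal(size=(spec.e, k))
    zc = z - z.mean(axis=0, keepdims=True)
    interaction = link.xi_true @ zc.T
    residual = None
    if link.residual_sd > 0:
        raw = rng.normal(0.0, link.residual_sd, (spec.g, spec.e))
        residual = raw - raw.mean(axis=0, keepdims=True) - raw.mean(axis=1, keepdims=True) + raw.mean()
        interaction = interaction + residual
    data, blocks = _assemble(spec, rng, alpha, beta, interaction)
    cov = CovariateMatrix(
        environments=list(data.environments),
        variable_names=list(link.variable_names),
        values=z,
    )
    u, s, vt = np.linalg.svd(interaction, full_matrices=False)
    truth = GroundTruth(
        grand_mean=spec.grand_mean,
        genotype_effects=alpha,
        environment_effects=beta,
        singular_values=s,
        genotype_vectors=u,
        environment_vectors=vt.T,
        interaction=interaction,
        block_effects=blocks,
        xi_true=link.xi_true.copy(),
        covariates=z,
        covariate_residual=residual,
    )
    return data, cov, truth


def default_covariate_link(
    g: int = 16,
    seed: int = 12345,
    active: tuple[int, ...] = (3, 2),
    sensitivity_sds: tuple[float, ...] = (35.0, 1.0),
    residual_sd: float = 40.0,
) -> CovariateLink:
    """A realistic six-covariate link with a few active variables.

    ``active`` indexes the covariates that truly drive the interaction
    (default: autumn temperature and spring rainfall, echoing the drivers
    a rainfed chickpea crop responds to); sensitivities for the remaining
    covariates are zero.  ``sensitivity_sds`` are in kg ha^-1 per covariate
    unit (mm or degC).
    """
    rng = np.random.default_rng(seed)
    xi = np.zeros((g, len(DEFAULT_COVARIATE_NAMES)))
    for col, sd in zip(active, sensitivity_sds):
        xi[:, col] = rng.normal(0.0, sd, g)
    return CovariateLink(xi_true=xi, residual_sd=residual_sd)
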