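"""Data model, validation and CSV I/O for multi-environment trial (MET) data.

A MET dataset is a long table of plot yields from a randomized complete
block design (RCBD) repeated over several environments (site-year
combinations): one record per plot, identified by genotype, environment
and replicate (block).  The two-way genotype x environment table of cell
means, split into the grand mean, additive main effects and the
doubly-centered interaction, is the substrate of every downstream
analysis (AMMI, stability indices, factorial regression, PLSR).

Environment-level climatic covariates (seasonal rainfall in mm, seasonal
mean temperature in degC) live in a separate environment x variable
matrix that can be centered, and optionally standardized, per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METValidationError",
    "IncompleteTableError",
    "TrialRecord",
    "METDataset",
    "GEMeansMatrix",
    "CovariateMatrix",
    "read_met_csv",
    "write_met_csv",
    "compute_ge_means",
    "read_covariates_csv",
    "write_covariates_csv",
    "center_covariates",
    "write_ge_means_csv",
]

DEFAULT_COLUMNS = {
    "genotype": "genotype",
    "environment": "environment",
    "replicate": "replicate",
    "yield": "yield",
}


class METValidationError(ValueError):
    """Raised when trial or covariate data violate a structural invariant."""


class IncompleteTableError(METValidationError):
    """Raised when the genotype x environment table has empty cells."""

    def __init__(self, missing_cells: Sequence[tuple[str, str]]):
        self.missing_cells = list(missing_cells)
        shown = ", ".join(f"({g}, {e})" for g, e in self.missing_cells[:10])
        more = "" if len(self.missing_cells) <= 10 else f" (+{len(self.missing_cells) - 10} more)"
        super().__init__(f"incomplete genotype x environment table; missing cells: {shown}{more}")


@dataclass(frozen=True)
class TrialRecord:
    """A single plot observation: yield of one genotype in one block of one environment."""

    genotype: str
    environment: str
    replicate: str
    yield_kg_ha: float

    def __post_init__(self) -> None:
        for name in ("genotype", "environment", "replicate"):
            if not str(getattr(self, name)):
                raise METValidationError(f"{name} identifier must be non-empty")
        y = self.yield_kg_ha
        if not np.isfinite(y):
            raise METValidationError(f"yield must be finite, got {y!r}")
        if y < 0:
            raise METValidationError(f"yield must be non-negative, got {y!r}")


@dataclass
class METDataset:
    """Validated long-format trial table plus genotype/environment ordering.

    ``frame`` holds one row per plot with columns
    ``genotype, environment, replicate, yield`` (kg ha^-1).  Ordering of
    ``genotypes`` and ``environments`` is first appearance in the input and
    is preserved in every derived table.  Within an environment every
    genotype must have the same number of replicates; replicate counts may
    differ between environments (site-years with different designs).
    """

    frame: pd.DataFrame
    genotypes: list[str]
    environments: list[str]
    replicates_per_environment: dict[str, int]

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @property
    def n_plots(self) -> int:
        return len(self.frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "METDataset":
        """Validate a long-format frame and derive ordering metadata.

        Raises :class:`METValidationError` on duplicate
        (genotype, environment, replicate) triples, non-finite or negative
        yields, empty identifiers, or unequal replicate counts within an
        environment.
        """
        required = ["genotype", "environment", "replicate", "yield"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise METValidationError(f"missing required columns: {missing}")
        df = frame.loc[:, required].copy()
        for c in ("genotype", "environment", "replicate"):
            df[c] = df[c].astype(str)
            if (df[c].str.len() == 0).any():
                row = int(np.flatnonzero(df[c].str.len() == 0)[0])
                raise METValidationError(f"empty {c} identifier at row {row}")
        y = pd.to_numeric(df["yield"], errors="coerce")
        bad = ~np.isfinite(y.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise METValidationError(f"non-numeric or non-finite yield at row {row}: {df['yield'].iloc[row]!r}")
        if (y < 0).any():
            row = int(np.flatnonzero((y < 0).to_numpy())[0])
            raise METValidationError(f"negative yield at row {row}: {y.iloc[row]}")
        df["yield"] = y.astype(float)

        dup = df.duplicated(subset=["genotype", "environment", "replicate"], keep=False)
        if dup.any():
            g, e, r = df.loc[dup, ["genotype", "environment", "replicate"]].iloc[0]
            raise METValidationError(f"duplicate plot record for (genotype={g}, environment={e}, replicate={r})")

        genotypes = list(dict.fromkeys(df["genotype"]))
        environments = list(dict.fromkeys(df["environment"]))

        reps: dict[str, int] = {}
        for env, sub in df.groupby("environment", sort=False):
            counts = sub.groupby("genotype", sort=False).size()
            if counts.nunique() != 1:
                raise METValidationError(
                    f"unequal replicate counts within environment {env}: "
                    f"{dict(counts[counts != counts.iloc[0]].head(5))} vs {int(counts.iloc[0])}"
                )
            reps[str(env)] = int(counts.iloc[0])

        if len(genotypes) < 2 or len(environments) < 2:
            raise METValidationError("need at least 2 genotypes and 2 environments")

        return cls(
            frame=df.reset_index(drop=True),
            genotypes=genotypes,
            environments=environments,
            replicates_per_environment=reps,
        )

    @classmethod
    def from_records(cls, records: Sequence[TrialRecord]) -> "METDataset":
        frame = pd.DataFrame(
            {
                "genotype": [r.genotype for r in records],
                "environment": [r.environment for r in records],
                "replicate": [r.replicate for r in records],
                "yield": [r.yield_kg_ha for r in records],
            }
        )
        return cls.from_frame(frame)

    def uniform_replicate_count(self) -> int:
        """Replicate count if uniform across environments, else the rounded mean."""
        counts = list(self.replicates_per_environment.values())
        if len(set(counts)) == 1:
            return counts[0]
        return int(round(float(np.mean(counts))))

    def is_complete(self) -> bool:
        cells = self.frame.groupby(["genotype", "environment"], sort=False).size()
        return len(cells) == self.n_genotypes * self.n_environments


@dataclass
class GEMeansMatrix:
    """Genotype x environment cell means and their additive decomposition.

    means[i, j] = grand_mean + genotype_effects[i] + environment_effects[j]
                  + interaction[i, j]

    Genotype and environment effects each sum to zero; the interaction
    matrix is doubly centered (every row and column sums to zero).
    """

    genotypes: list[str]
    environments: list[str]
    means: np.ndarray            # g x e, kg ha^-1
    grand_mean: float
    genotype_effects: np.ndarray   # length g
    environment_effects: np.ndarray  # length e
    interaction: np.ndarray      # g x e, doubly centered

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    def validate(self, tol_scale: float = 1e-9) -> None:
        tol = tol_scale * max(1.0, abs(self.grand_mean))
        if abs(self.genotype_effects.sum()) > tol:
            raise METValidationError("genotype effects do not sum to zero")
        if abs(self.environment_effects.sum()) > tol:
            raise METValidationError("environment effects do not sum to zero")
        if np.abs(self.interaction.sum(axis=0)).max() > tol or np.abs(self.interaction.sum(axis=1)).max() > tol:
            raise METValidationError("interaction matrix is not doubly centered")
        recon = (
            self.grand_mean
            + self.genotype_effects[:, None]
            + self.environment_effects[None, :]
            + self.interaction
        )
        if np.abs(recon - self.means).max() > tol:
            raise METValidationError("means do not equal grand mean + effects + interaction")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.genotypes, columns=self.environments)

    def genotype_means(self) -> np.ndarray:
        """Per-genotype mean over environments (unweighted over cells)."""
        return self.means.mean(axis=1)

    def environment_means(self) -> np.ndarray:
        return self.means.mean(axis=0)


@dataclass
class CovariateMatrix:
    """Environment-level covariates (rows follow the trial's environment order)."""

    environments: list[str]
    variable_names: list[str]
    values: np.ndarray  # e x K
    centered: bool = False
    standardized: bool = False

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.environments, columns=self.variable_names)


def read_met_csv(path: str | Path, column_map: Mapping[str, str] | None = None) -> METDataset:
    """Read a long-format trial CSV into a validated :class:`METDataset`.

    ``column_map`` maps the canonical names (genotype, environment,
    replicate, yield) to the file's column names when they differ.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(
        path,
        dtype={colmap[k]: str for k in ("genotype", "environment", "replicate")},
        float_precision="round_trip",
    )
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise METValidationError(f"columns {missing} not found in {path}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    return METDataset.from_frame(df)


def write_met_csv(data: METDataset, path: str | Path) -> None:
    """Write the long table back out; round-trips through :func:`read_met_csv`."""
    data.frame.to_csv(path, index=False)


def compute_ge_means(data: METDataset, impute: str | None = None) -> GEMeansMatrix:
    """Average plot yields into the genotype x environment means table.

    The cell means are decomposed into the grand mean, zero-sum genotype
    and environment main effects, and the doubly-centered interaction.

    Empty cells are a hard error unless ``impute='cell-mean'``, which fills
    each missing cell with (genotype mean + environment mean - grand mean)
    computed from the observed cells, i.e. the purely additive prediction.
    """
    cell = data.frame.groupby(["genotype", "environment"], sort=False)["yield"].mean()
    table = cell.unstack("environment").reindex(index=data.genotypes, columns=data.environments)
    missing_mask = table.isna()
    if missing_mask.to_numpy().any():
        missing = [(g, e) for g in data.genotypes for e in data.environments if missing_mask.loc[g, e]]
        if impute is None:
            raise IncompleteTableError(missing)
        if impute != "cell-mean":
            raise ValueError(f"unknown impute policy {impute!r}")
        m = table.to_numpy()
        grand = np.nanmean(m)
        gmeans = np.nanmean(m, axis=1)
        emeans = np.nanmean(m, axis=0)
        fill = gmeans[:, None] + emeans[None, :] - grand
        m = np.where(np.isnan(m), fill, m)
        table = pd.DataFrame(m, index=table.index, columns=table.columns)

    means = table.to_numpy(dtype=float)
    grand_mean = float(means.mean())
    genotype_effects = means.mean(axis=1) - grand_mean
    environment_effects = means.mean(axis=0) - grand_mean
    interaction = means - grand_mean - genotype_effects[:, None] - environment_effects[None, :]
    out = GEMeansMatrix(
        genotypes=list(data.genotypes),
        environments=list(data.environments),
        means=means,
        grand_mean=grand_mean,
        genotype_effects=genotype_effects,
        environment_effects=environment_effects,
        interaction=interaction,
    )
    out.validate()
    return out


def read_covariates_csv(
    path: str | Path,
    environments: Sequence[str],
    strict: bool = True,
) -> CovariateMatrix:
    """Read an environment x covariate CSV, reconciling row order by name.

    The first column must hold environment identifiers.  Every trial
    environment must appear; extra environments in the file are an error
    in strict mode and are dropped with a row-order warning otherwise.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    env_col = df.columns[0]
    df[env_col] = df[env_col].astype(str)
    if df[env_col].duplicated().any():
        dup = df.loc[df[env_col].duplicated(), env_col].iloc[0]
        raise METValidationError(f"duplicate environment row {dup!r} in covariate file")
    file_envs = set(df[env_col])
    missing = [e for e in environments if e not in file_envs]
    if missing:
        raise METValidationError(f"covariate file is missing environments: {missing}")
    extra = [e for e in df[env_col] if e not in set(environments)]
    if extra:
        if strict:
            raise METValidationError(f"covariate file has environments absent from the trial: {extra}")
        import warnings

        warnings.warn(f"dropping covariate rows for unknown environments: {extra}", stacklevel=2)
        df = df[df[env_col].isin(set(environments))]
    df = df.set_index(env_col).loc[list(environments)]
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise METValidationError("covariate values must be finite numbers")
    names = [str(c) for c in df.columns]
    if len(set(names)) != len(names):
        raise METValidationError("covariate variable names must be unique")
    return CovariateMatrix(environments=list(environments), variable_names=names, values=values)


def write_covariates_csv(cov: CovariateMatrix, path: str | Path) -> None:
    cov.to_frame().rename_axis("environment").to_csv(path)


def center_covariates(cov: CovariateMatrix, standardize: bool = False) -> CovariateMatrix:
    """Center each covariate column to mean zero; optionally scale to unit sd.

    Standardization uses the sample standard deviation (ddof=1) and puts
    rainfall (mm) and temperature (degC) columns on a common scale, as
    required before PLSR.  Centering is idempotent.
    """
    values = cov.values - cov.values.mean(axis=0, keepdims=True)
    standardized = cov.standardized
    if standardize:
        sd = values.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise METValidationError(
                f"cannot standardize zero-variance covariate column(s): {[cov.variable_names[i] for i in zero]}"
            )
        values = values / sd
        standardized = True
    return replace(cov, values=values, centered=True, standardized=standardized)


def write_ge_means_csv(gem: GEMeansMatrix, path: str | Path) -> None:
    """Tidy export of the means table with main effects appended.

    Columns: genotype, then one column per environment, then
    ``genotype_effect`` and ``genotype_mean``; a final ``_environment``
    block row carries environment effects.
    """
    df = gem.to_frame().copy()
    df["genotype_effect"] = gem.genotype_effects
    df["genotype_mean"] = gem.genotype_means()
    eff = pd.DataFrame(
        [list(gem.environment_effects) + [np.nan, np.nan]],
        index=["_environment_effect"],
        columns=df.columns,
    )
    out = pd.concat([df, eff])
    out.index.name = "genotype"
    out.to_csv(path)
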