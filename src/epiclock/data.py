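"""Core data containers and delimited-text IO for the methylation pipeline.

The universal currency is the *beta value*: the fraction of molecules
methylated at a CpG site, a proportion in [0, 1].  Betas travel as a
samples x CpGs matrix (:class:`BetaMatrix`); per-sample metadata travels as a
:class:`SampleTable`; per-CpG genomic context as a :class:`CpGAnnotation`.

All tabular formats are delimited text, tab-separated by default with the
delimiter sniffed on read, so every artifact in a run directory is directly
inspectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance within which values slightly outside [0, 1] are clamped rather
#: than rejected (floating-point round-off from upstream normalisation)
BETA_ROUNDING_TOL = 1e-9

SEX_ALIASES = {
    "f": "female", "female": "female",
    "m": "male", "male": "male",
}
POPULATIONS = ("TF", "CH")
REGION_CLASSES = ("promoter", "5'UTR", "exon", "intron", "3'UTR", "intergenic/other")
ISLAND_STATUSES = ("island", "non-island")


class LifeStage(str, Enum):
    """Survivorship-based life stage of a deer, derived from age alone."""

    JUVENILE = "juvenile"
    PRIME_AGE = "prime_age"
    SENESCENT = "senescent"


def derive_stage(age_years: float) -> LifeStage:
    """Map a positive age in years to its life stage.

    Juveniles are animals under one year of age, prime-age adults span one
    to eight years inclusive, and senescent animals are older than eight.
    """
    if age_years <= 0:
        raise ValueError(f"age must be positive, got {age_years}")
    if age_years < 1.0:
        return LifeStage.JUVENILE
    if age_years <= 8.0:
        return LifeStage.PRIME_AGE
    return LifeStage.SENESCENT


class ValidationError(ValueError):
    """A table violated one of the pipeline's data contracts."""


def _sniff_read(path, **kwargs) -> pd.DataFrame:
    # TSV is the house format; sep=None lets pandas sniff commas as well.
    return pd.read_csv(path, sep=None, engine="python", **kwargs)


# ---------------------------------------------------------------------------
# BetaMatrix


@dataclass
class BetaMatrix:
    """Samples x CpGs matrix of methylation fractions.

    ``values`` is a float DataFrame indexed by sample id with CpG ids as
    columns.  Entries are proportions in [0, 1]; NaN marks a missing
    measurement and is propagated to downstream operations, each of which
    states its own missing-data policy.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        validate_beta_frame(self.values)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = set(sample_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        return BetaMatrix(self.values.loc[list(sample_ids)])

    def to_file(self, path, orientation: str = "samples_in_rows") -> None:
        frame = self.values if orientation == "samples_in_rows" else self.values.T
        frame.to_csv(path, sep="\t")


def validate_beta_frame(frame: pd.DataFrame) -> None:
    if frame.size == 0:
        raise ValidationError("beta matrix is empty")
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated sample ids: {dups}")
    if frame.columns.duplicated().any():
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated CpG ids: {dups}")
    arr = frame.to_numpy()
    with np.errstate(invalid="ignore"):
        low = arr < 0.0
        high = arr > 1.0
    bad = (low & (arr < -BETA_ROUNDING_TOL)) | (high & (arr > 1.0 + BETA_ROUNDING_TOL))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value out of [0,1]: {arr[i, j]!r} at sample "
            f"{frame.index[i]!r}, cpg {frame.columns[j]!r}"
        )
    clampable = low | high
    if clampable.any():
        n = int(clampable.sum())
        logger.warning("clamped %d beta value(s) within %g of [0,1]", n, BETA_ROUNDING_TOL)
        frame.iloc[:, :] = np.clip(arr, 0.0, 1.0)


def read_beta_matrix(path, orientation: str = "samples_in_rows") -> BetaMatrix:
    """Read a delimited beta matrix; ``orientation`` names what the rows hold."""
    if orientation not in ("samples_in_rows", "cpgs_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = _sniff_read(path, index_col=0)
    if orientation == "cpgs_in_rows":
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in beta matrix: {exc}") from exc
    return BetaMatrix(frame)


# ---------------------------------------------------------------------------
# SampleTable


REQUIRED_SAMPLE_COLUMNS = ("sample_id", "animal_id", "age_years", "sex", "population")


@dataclass
class SampleTable:
    """Per-sample metadata: animal identity, age, sex, population, mass.

    An animal may contribute several samples (repeat captures across
    years); ``sample_id`` is unique, ``animal_id`` need not be.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"sample table missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicated sample_id in sample table")
        df["sex"] = df["sex"].map(normalize_sex)
        bad_pop = ~df["population"].isin(POPULATIONS)
        if bad_pop.any():
            raise ValidationError(
                f"unknown population token(s): {sorted(df.loc[bad_pop, 'population'].unique())}"
            )
        df["age_years"] = df["age_years"].astype(float)
        if (df["age_years"] <= 0).any():
            bad = df.loc[df["age_years"] <= 0, "sample_id"].tolist()
            raise ValidationError(f"non-positive age for sample(s) {bad}")
        if "body_mass_kg" in df.columns:
            df["body_mass_kg"] = df["body_mass_kg"].astype(float)
            if (df["body_mass_kg"].dropna() <= 0).any():
                raise ValidationError("non-positive body mass")
        df["stage"] = [derive_stage(a).value for a in df["age_years"]]
        self.frame = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def ages(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        sub = self.frame if sample_ids is None else self.frame.loc[list(sample_ids)]
        return sub["age_years"]

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.frame.loc[mask].reset_index(drop=True))

    def to_file(self, path) -> None:
        self.frame.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def normalize_sex(token) -> str:
    key = str(token).strip().lower()
    if key not in SEX_ALIASES:
        raise ValidationError(f"unknown sex token {token!r}")
    return SEX_ALIASES[key]


def read_sample_table(path) -> SampleTable:
    frame = _sniff_read(path, dtype={"sample_id": str, "animal_id": str})
    return SampleTable(frame)


# ---------------------------------------------------------------------------
# CpGAnnotation


@dataclass
class CpGAnnotation:
    """Per-CpG genomic context: scaffold, 1-based position, nearest gene,
    region class relative to the closest TSS, and CpG-island status."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("cpg_id", "scaffold", "position", "nearest_gene",
                    "region_class", "island_status"):
            if col not in df.columns:
                raise ValidationError(f"annotation missing required column {col!r}")
        if df["cpg_id"].duplicated().any():
            raise ValidationError("duplicated cpg_id in annotation")
        bad_region = ~df["region_class"].isin(REGION_CLASSES)
        if bad_region.any():
            raise ValidationError(
                f"unknown region_class: {sorted(df.loc[bad_region, 'region_class'].unique())}"
            )
        bad_island = ~df["island_status"].isin(ISLAND_STATUSES)
        if bad_island.any():
            raise ValidationError(
                f"unknown island_status: {sorted(df.loc[bad_island, 'island_status'].unique())}"
            )
        df["position"] = df["position"].astype(int)
        self.frame = df.set_index("cpg_id", drop=False)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.frame["cpg_id"])

    def to_file(self, path) -> None:
        self.frame.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> CpGAnnotation:
    return CpGAnnotation(_sniff_read(path, dtype={"cpg_id": str, "scaffold": str}))


# ---------------------------------------------------------------------------
# Sample QC: inter-array correlation outliers


@dataclass(frozen=True)
class QCFlag:
    sample_id: str
    reason: str
    mean_corr: float | None = None


def qc_interarray_outliers(beta: BetaMatrix, min_mean_corr: float = 0.85) -> list[QCFlag]:
    """Flag samples whose methylation profile disagrees with the cohort.

    Computes the pairwise Pearson correlation between sample profiles and
    iteratively flags the sample with the lowest mean correlation to the
    remaining samples while that mean falls below ``min_mean_corr``
    (worst-first peeling, so one severe outlier does not drag its
    neighbours below the threshold).  A constant profile has no defined
    correlation and is flagged outright with reason ``"zero variance"``.

    The flag set is invariant to sample and CpG ordering.
    """
    if beta.shape[0] < 3:
        raise ValueError("inter-array QC needs at least 3 samples")
    arr = beta.values.to_numpy()
    sample_ids = np.asarray(beta.sample_ids)
    sds = np.nanstd(arr, axis=1)
    flags: list[QCFlag] = []
    degenerate = sds == 0
    for sid in sample_ids[degenerate]:
        flags.append(QCFlag(sample_id=str(sid), reason="zero variance"))
    keep = np.flatnonzero(~degenerate)
    while keep.size >= 2:
        corr = np.corrcoef(arr[keep])
        np.fill_diagonal(corr, np.nan)
        # mean correlation with the other retained samples
        mean_corr = np.nanmean(corr, axis=1)
        worst = int(np.argmin(mean_corr))
        if mean_corr[worst] >= min_mean_corr:
            break
        # deterministic tie-break toward the lexicographically first id
        ties = np.flatnonzero(mean_corr == mean_corr[worst])
        worst = min(ties, key=lambda i: str(sample_ids[keep[i]]))
        flags.append(QCFlag(sample_id=str(sample_ids[keep[worst]]),
                            reason="low mean correlation",
                            mean_corr=float(mean_corr[worst])))
        keep = np.delete(keep, worst)
    flags.sort(key=lambda f: f.sample_id)
    return flags


# ---------------------------------------------------------------------------
# Clock serialization (structured key-value text, JSON-compatible)


@dataclass
class ClockModel:
    """Sparse linear age predictor: intercept plus per-CpG weights.

    Weights are on the original beta scale (years per unit beta); the
    elastic-net mixing parameter ``alpha`` and selected penalty ``lambda_``
    are kept for provenance, as are the training sample ids and seed.
    """

    intercept: float
    weights: dict[str, float]
    alpha: float = 0.5
    lambda_: float = 0.0
    sex_scope: str = "all"
    training_sample_ids: list[str] = field(default_factory=list)
    seed: int | None = None
    training_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0,1], got {self.alpha}")
        if self.lambda_ < 0:
            raise ValidationError(f"lambda must be >= 0, got {self.lambda_}")

    @property
    def n_weights(self) -> int:
        return len(self.weights)


def _reject_duplicate_keys(pairs):
    d = {}
    for k, v in pairs:
        if k in d:
            raise ValidationError(f"duplicate key in clock file: {k!r}")
        d[k] = v
    return d


def write_clock(model: ClockModel, path) -> None:
    payload = {
        "intercept": model.intercept,
        "alpha": model.alpha,
        "lambda": model.lambda_,
        "weights": dict(sorted(model.weights.items())),
        "training": {
            "n": len(model.training_sample_ids),
            "sample_ids": list(model.training_sample_ids),
            "sex_scope": model.sex_scope,
            "seed": model.seed,
            "means": dict(sorted(model.training_means.items())),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_clock(path) -> ClockModel:
    with open(path) as fh:
        payload = json.load(fh, object_pairs_hook=_reject_duplicate_keys)
    training = payload.get("training", {})
    return ClockModel(
        intercept=float(payload["intercept"]),
        weights={str(k): float(v) for k, v in payload.get("weights", {}).items()},
        alpha=float(payload.get("alpha", 0.5)),
        lambda_=float(payload.get("lambda", 0.0)),
        sex_scope=str(training.get("sex_scope", "all")),
        training_sample_ids=[str(s) for s in training.get("sample_ids", [])],
        seed=training.get("seed"),
        training_means={str(k): float(v) for k, v in training.get("means", {}).items()},
    )
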