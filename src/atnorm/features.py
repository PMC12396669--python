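"""Feature-table I/O, session selection, covariate engineering and scaling.

The analysis operates on one row per subject-session: seven regional mean
apparent-diffusion-coefficient (ADC) values, six regional mean cerebral-
blood-flow (CBF) values, and seven demographic/volumetric covariates.
ADC is recorded in 1e-6 mm^2/s and divided by 3000; CBF is recorded in
mL/100 g/min and divided by 100, so all imaging features live on a
comparable ~[0, 1] quantitative scale.  Covariates are min-max scaled with
bounds fitted on the training controls and are deliberately NOT clipped:
a subject outside the training range (e.g. an older patient) keeps its
out-of-range normalized value, which is part of the anomaly signal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Canonical region and feature ordering (fixed; shared by every stage).
PERFUSION_ROIS: tuple[str, ...] = (
    "caudate", "hippocampus", "pallidum", "putamen", "thalamus", "cgm",
)
DIFFUSION_ROIS: tuple[str, ...] = PERFUSION_ROIS + ("cwm",)
COVARIATE_NAMES: tuple[str, ...] = (
    "age", "sex", "cerebral_volume", "cerebellar_volume",
    "age_sq", "age_sex", "age_sq_sex",
)
PERFUSION_FEATURES: tuple[str, ...] = tuple(f"cbf_{r}" for r in PERFUSION_ROIS)
DIFFUSION_FEATURES: tuple[str, ...] = tuple(f"adc_{r}" for r in DIFFUSION_ROIS)
#: 13 imaging features the model reconstructs, in canonical order.
OUTPUT_FEATURES: tuple[str, ...] = PERFUSION_FEATURES + DIFFUSION_FEATURES
#: 20 model inputs: 6 perfusion, 7 diffusion, 7 covariates.
INPUT_FEATURES: tuple[str, ...] = OUTPUT_FEATURES + COVARIATE_NAMES

NEST_SCORES: tuple[str, ...] = ("ataxia", "hypermotor", "bradykinesia", "dystonia")

DIFFUSION_SCALE = 3000.0  # 1e-6 mm^2/s
PERFUSION_SCALE = 100.0  # mL/100 g/min

#: per-feature multiplicative scale mapping normalized -> physical units
FEATURE_SCALES: np.ndarray = np.array(
    [PERFUSION_SCALE] * len(PERFUSION_FEATURES)
    + [DIFFUSION_SCALE] * len(DIFFUSION_FEATURES)
)

CSV_COLUMNS: tuple[str, ...] = (
    "subject_id", "dataset", "group", "session_id", "age_years", "sex",
    "cerebral_volume_ml", "cerebellar_volume_ml",
    *(f"adc_{r}" for r in DIFFUSION_ROIS),
    *(f"cbf_{r}" for r in PERFUSION_ROIS),
    *(f"nest_{s}" for s in NEST_SCORES),
)
_MANDATORY_COLUMNS = CSV_COLUMNS[: len(CSV_COLUMNS) - len(NEST_SCORES)]


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected numeric type."""


class DataError(ValueError):
    """The table content is inconsistent (e.g. duplicate sessions)."""


class DegenerateNormalizerError(ValueError):
    """A covariate has zero spread on the fitted training set."""


@dataclass
class SubjectRecord:
    """One subject-session with covariates, imaging features and optional
    clinical sub-scores (A-T NEST; lower = more severe)."""

    subject_id: str
    dataset: str  # CATNAP | Calgary | synthetic
    group: str  # control | AT
    session_id: str
    age: float  # years
    sex: int  # 0 = male, 1 = female
    cerebral_volume: float  # mL
    cerebellar_volume: float  # mL
    adc: dict[str, float]  # ROI -> mean ADC, 1e-6 mm^2/s (7 ROIs)
    cbf: dict[str, float]  # ROI -> mean CBF, mL/100 g/min (6 ROIs)
    nest: dict[str, float] | None = None
    severity: float | None = None  # synthetic-only latent disease severity

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise SchemaError(f"age must be positive, got {self.age}")
        if self.sex not in (0, 1):
            raise SchemaError(f"sex must be 0 or 1, got {self.sex}")
        if self.cerebral_volume <= 0 or self.cerebellar_volume <= 0:
            raise SchemaError("volumes must be positive")
        if set(self.adc) != set(DIFFUSION_ROIS):
            raise SchemaError(
                f"adc must cover exactly {DIFFUSION_ROIS}, got {sorted(self.adc)}"
            )
        if set(self.cbf) != set(PERFUSION_ROIS):
            raise SchemaError(
                f"cbf must cover exactly {PERFUSION_ROIS}, got {sorted(self.cbf)}"
            )
        if any(v <= 0 for v in self.adc.values()):
            raise SchemaError("ADC values must be positive")
        if any(v < 0 for v in self.cbf.values()):
            raise SchemaError("CBF values must be nonnegative")


@dataclass(frozen=True)
class CovariateVector:
    """The seven covariates entering the model: age, sex, cerebral and
    cerebellar volume, age^2, age*sex, age^2*sex."""

    age: float
    sex: int
    cerebral_volume: float
    cerebellar_volume: float
    age_sq: float
    age_sex: float
    age_sq_sex: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COVARIATE_NAMES], dtype=float)


@dataclass(frozen=True)
class ModelInput:
    """Ordered normalized 20-vector: 6 perfusion, 7 diffusion, 7 covariates."""

    values: np.ndarray
    feature_names: tuple[str, ...] = INPUT_FEATURES

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"ModelInput must have 20 entries, got {len(self.values)}")


@dataclass(frozen=True)
class ModelOutput:
    """Ordered normalized 13-vector reconstruction of the imaging features."""

    values: np.ndarray
    feature_names: tuple[str, ...] = OUTPUT_FEATURES

    def __post_init__(self) -> None:
        if len(self.values) != 13:
            raise ValueError(f"ModelOutput must have 13 entries, got {len(self.values)}")


@dataclass
class Normalizer:
    """Feature scaling: fixed quantitative scales for imaging features and
    min-max bounds (fitted on training controls) for covariates."""

    covariate_min: np.ndarray
    covariate_max: np.ndarray
    diffusion_scale: float = DIFFUSION_SCALE
    perfusion_scale: float = PERFUSION_SCALE

    def __post_init__(self) -> None:
        self.covariate_min = np.asarray(self.covariate_min, dtype=float)
        self.covariate_max = np.asarray(self.covariate_max, dtype=float)
        if self.diffusion_scale <= 0 or self.perfusion_scale <= 0:
            raise ValueError("scales must be strictly positive")
        if np.any(self.covariate_max <= self.covariate_min):
            bad = [
                COVARIATE_NAMES[i]
                for i in np.nonzero(self.covariate_max <= self.covariate_min)[0]
            ]
            raise DegenerateNormalizerError(
                f"covariates with zero spread on the training set: {bad}"
            )

    def to_dict(self) -> dict:
        return {
            "covariate_min": self.covariate_min.tolist(),
            "covariate_max": self.covariate_max.tolist(),
            "diffusion_scale": self.diffusion_scale,
            "perfusion_scale": self.perfusion_scale,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Normalizer":
        return cls(
            covariate_min=np.asarray(d["covariate_min"], dtype=float),
            covariate_max=np.asarray(d["covariate_max"], dtype=float),
            diffusion_scale=float(d["diffusion_scale"]),
            perfusion_scale=float(d["perfusion_scale"]),
        )


def engineer_covariates(record: SubjectRecord) -> CovariateVector:
    """Derive the interaction covariates (age^2, age*sex, age^2*sex)."""
    return CovariateVector(
        age=record.age,
        sex=record.sex,
        cerebral_volume=record.cerebral_volume,
        cerebellar_volume=record.cerebellar_volume,
        age_sq=record.age**2,
        age_sex=record.age * record.sex,
        age_sq_sex=record.age**2 * record.sex,
    )


def raw_feature_vector(record: SubjectRecord) -> np.ndarray:
    """The 13 imaging features in canonical order, physical units."""
    return np.array(
        [record.cbf[r] for r in PERFUSION_ROIS]
        + [record.adc[r] for r in DIFFUSION_ROIS]
    )


def fit_normalizer(training: Sequence[SubjectRecord]) -> Normalizer:
    """Fit covariate min-max bounds on a training set.

    Imaging-feature scales are fixed constants and do not depend on the data.
    Raises :class:`DegenerateNormalizerError` if any covariate is constant.
    """
    if not training:
        raise ValueError("training set must be non-empty")
    cov = np.array([engineer_covariates(r).as_array() for r in training])
    return Normalizer(covariate_min=cov.min(axis=0), covariate_max=cov.max(axis=0))


def normalize(record: SubjectRecord, norm: Normalizer) -> ModelInput:
    """Build the normalized 20-vector model input for one subject.

    Covariate values outside the fitted [min, max] are NOT clipped; they map
    outside [0, 1], preserving out-of-range signal for anomaly detection.
    """
    raw = raw_feature_vector(record)
    imaging = raw / FEATURE_SCALES
    cov = engineer_covariates(record).as_array()
    cov_n = (cov - norm.covariate_min) / (norm.covariate_max - norm.covariate_min)
    return ModelInput(values=np.concatenate([imaging, cov_n]))


def normalize_many(records: Sequence[SubjectRecord], norm: Normalizer) -> np.ndarray:
    """Stacked normalized inputs, shape (n_subjects, 20)."""
    return np.array([normalize(r, norm).values for r in records])


def signed_physical_errors(output: ModelOutput, inp: ModelInput) -> np.ndarray:
    """Per-feature signed reconstruction errors in physical units.

    error_i = (reconstructed_i - observed_i) * scale_i; positive values mean
    the normative model over-estimates the feature.
    """
    if tuple(output.feature_names) != tuple(inp.feature_names[:13]):
        raise ValueError("output feature order does not match input")
    diff = np.asarray(output.values, dtype=float) - np.asarray(inp.values[:13], dtype=float)
    return diff * FEATURE_SCALES


def select_session(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Keep one session per subject.

    CATNAP (and synthetic) subjects keep their youngest session; Calgary
    subjects keep their oldest — the choice that minimizes the age-range gap
    between the two source datasets.  Age ties break on the lexicographically
    smallest session_id.  Output order follows first appearance of each
    subject, so the operation is idempotent and row-order independent in its
    result set.
    """
    seen_pairs: set[tuple[str, str]] = set()
    for r in records:
        key = (r.subject_id, r.session_id)
        if key in seen_pairs:
            raise DataError(f"duplicate (subject_id, session_id) pair: {key}")
        seen_pairs.add(key)

    by_subject: dict[str, list[SubjectRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.subject_id not in by_subject:
            order.append(r.subject_id)
        by_subject.setdefault(r.subject_id, []).append(r)

    selected = []
    for sid in sorted(order):
        sessions = by_subject[sid]
        newest_first = sessions[0].dataset == "Calgary"
        key = (lambda s: (-s.age, s.session_id)) if newest_first else (
            lambda s: (s.age, s.session_id)
        )
        selected.append(min(sessions, key=key))
    return selected


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Serialize records to the canonical tabular schema."""
    rows = []
    for r in records:
        row: dict = {
            "subject_id": r.subject_id,
            "dataset": r.dataset,
            "group": r.group,
            "session_id": r.session_id,
            "age_years": r.age,
            "sex": r.sex,
            "cerebral_volume_ml": r.cerebral_volume,
            "cerebellar_volume_ml": r.cerebellar_volume,
        }
        for roi in DIFFUSION_ROIS:
            row[f"adc_{roi}"] = r.adc[roi]
        for roi in PERFUSION_ROIS:
            row[f"cbf_{roi}"] = r.cbf[roi]
        for s in NEST_SCORES:
            row[f"nest_{s}"] = r.nest.get(s, np.nan) if r.nest else np.nan
        if r.severity is not None:
            row["severity"] = r.severity
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(records: Sequence[SubjectRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_feature_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[SubjectRecord]:
    """Read a canonical-schema feature CSV into records.

    ``column_map`` maps nonstandard source headers to canonical names
    (source -> canonical), to ingest externally produced spreadsheets.
    Clinical-score columns are optional; empty score cells leave ``nest``
    unset.  Row count is logged; no rows are silently dropped.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    numeric_cols = [
        c
        for c in df.columns
        if c not in ("subject_id", "dataset", "group", "session_id")
    ]
    for c in numeric_cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            raise ParseError(
                f"non-numeric value in column {c!r} at row index {list(bad)[:5]}"
            ) from None

    records = []
    for _, row in df.iterrows():
        nest = None
        scores = {
            s: float(row[f"nest_{s}"])
            for s in NEST_SCORES
            if f"nest_{s}" in df.columns and pd.notna(row[f"nest_{s}"])
        }
        if scores:
            nest = scores
        severity = (
            float(row["severity"])
            if "severity" in df.columns and pd.notna(row.get("severity"))
            else None
        )
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                dataset=str(row["dataset"]),
                group=str(row["group"]),
                session_id=str(row["session_id"]),
                age=float(row["age_years"]),
                sex=int(row["sex"]),
                cerebral_volume=float(row["cerebral_volume_ml"]),
                cerebellar_volume=float(row["cerebellar_volume_ml"]),
                adc={r_: float(row[f"adc_{r_}"]) for r_ in DIFFUSION_ROIS},
                cbf={r_: float(row[f"cbf_{r_}"]) for r_ in PERFUSION_ROIS},
                nest=nest,
                severity=severity,
            )
        )
    logger.info("read %d subject-session rows from %s", len(records), path)
    return records
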