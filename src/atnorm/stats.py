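"""Anomaly statistics on reconstruction-error profiles.

Per-subject profiles (normalized-scale MSE plus signed per-feature errors
in physical units), seeded permutation inference for group and per-feature
comparisons, the z-score heatmap with complete-linkage feature ordering,
and a 2-D embedding of the latent space.

Permutation p-values use the add-one estimator
p = (#{|t_perm| >= |t_obs|} + 1) / (iterations + 1), two-sided throughout,
so the attainable floor is 1/(iterations + 1).  No multiple-testing
correction is applied anywhere in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .features import (
    OUTPUT_FEATURES,
    SubjectRecord,
    normalize,
    normalize_many,
    signed_physical_errors,
)
from .model import TrainedModel, encode_latent_many, reconstruct, subject_mse

logger = logging.getLogger(__name__)


@dataclass
class ErrorProfile:
    """One subject's anomaly profile: normalized-scale MSE and signed
    per-feature errors in physical units (positive = over-estimation)."""

    subject_id: str
    group: str
    mse: float
    signed_errors: np.ndarray  # length 13, canonical feature order

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be nonnegative")
        if len(self.signed_errors) != len(OUTPUT_FEATURES):
            raise ValueError("signed_errors must have 13 entries")


@dataclass
class GroupComparison:
    statistic: float  # observed pooled t statistic
    p_perm: float
    p_ranksum: float
    median_control: float
    median_at: float
    n_iterations: int


@dataclass
class HeatmapMatrix:
    """Z-scored signed errors against the control reference, with the
    feature (column) order from complete-linkage clustering."""

    z: np.ndarray  # (n_subjects, 13), canonical column order
    subject_ids: list[str]
    groups: list[str]
    column_order: np.ndarray  # permutation of range(13)
    reference_mean: np.ndarray
    reference_sd: np.ndarray

    @property
    def ordered_features(self) -> list[str]:
        return [OUTPUT_FEATURES[i] for i in self.column_order]


class DegenerateReferenceError(ValueError):
    """The control reference has zero spread for some feature."""


def error_profiles(
    model: TrainedModel, records: Sequence[SubjectRecord]
) -> list[ErrorProfile]:
    """Reconstruct each subject and collect its anomaly profile."""
    if model.normalizer is None:
        raise ValueError("model carries no fitted normalizer")
    profiles = []
    for rec in records:
        inp = normalize(rec, model.normalizer)
        out = reconstruct(model, inp)
        profiles.append(
            ErrorProfile(
                subject_id=rec.subject_id,
                group=rec.group,
                mse=subject_mse(out, inp),
                signed_errors=signed_physical_errors(out, inp),
            )
        )
    return profiles


def profiles_frame(profiles: Sequence[ErrorProfile]) -> pd.DataFrame:
    """Tidy per-subject x feature table of signed errors plus MSE."""
    rows = []
    for p in profiles:
        for feat, err in zip(OUTPUT_FEATURES, p.signed_errors):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "group": p.group,
                    "feature": feat,
                    "signed_error": err,
                    "mse": p.mse,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ permutation


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def permutation_t_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    iterations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided permutation test on the pooled two-sample t statistic.

    Returns (t_observed, p).  Group labels are permuted ``iterations``
    times with a seeded generator; with zero pooled variance and equal
    means p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    t_obs = _pooled_t(a, b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    if np.isinf(t_obs):
        # maximal separation (zero within-group variance, unequal means):
        # the most extreme attainable configuration, p at the floor
        return t_obs, 1.0 / (iterations + 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 51]))
    na, n = len(a), len(pooled)
    # vectorized: rows of independently permuted indices
    perm = np.argsort(rng.random((iterations, n)), axis=1)
    permuted = pooled[perm]
    pa, pb = permuted[:, :na], permuted[:, na:]
    va = pa.var(axis=1, ddof=1)
    vb = pb.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (n - na - 1) * vb) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = (pa.mean(axis=1) - pb.mean(axis=1)) / np.sqrt(
            sp2 * (1 / na + 1 / (n - na))
        )
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
    exceed = np.sum(np.abs(t_perm) >= abs(t_obs)) if np.isfinite(t_obs) else np.sum(
        np.isinf(t_perm)
    )
    p = (exceed + 1) / (iterations + 1)
    return t_obs, float(p)


def compare_groups_mse(
    profiles: Sequence[ErrorProfile], iterations: int = 1000, seed: int = 0
) -> GroupComparison:
    """Compare per-subject MSEs between A-T and control profiles.

    Reports group medians, the permutation-t p-value and the two-sided
    rank-sum (Wilcoxon) p-value.
    """
    mse_c = np.array([p.mse for p in profiles if p.group == "control"])
    mse_at = np.array([p.mse for p in profiles if p.group == "AT"])
    if len(mse_c) < 2 or len(mse_at) < 2:
        raise ValueError("need at least 2 subjects per group")
    t_obs, p_perm = permutation_t_test(mse_at, mse_c, iterations, seed)
    p_rank = float(scipy.stats.ranksums(mse_at, mse_c).pvalue)
    return GroupComparison(
        statistic=t_obs,
        p_perm=p_perm,
        p_ranksum=p_rank,
        median_control=float(np.median(mse_c)),
        median_at=float(np.median(mse_at)),
        n_iterations=iterations,
    )


def per_feature_bias(
    profiles: Sequence[ErrorProfile], iterations: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Within-group over/under-estimation per feature.

    For each of the 13 features: the group-mean signed error (physical
    units) and a two-sided sign-flip permutation p-value against zero mean.
    """
    errs = np.array([p.signed_errors for p in profiles])
    if len(errs) < 2:
        raise ValueError("group must have at least 2 subjects")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 61]))
    n = len(errs)
    obs = errs.mean(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(iterations, n))
    # (iterations, 13): mean of sign-flipped errors per feature
    perm_means = signs @ errs / n
    exceed = np.sum(np.abs(perm_means) >= np.abs(obs)[None, :], axis=0)
    p = (exceed + 1) / (iterations + 1)
    return pd.DataFrame(
        {"feature": OUTPUT_FEATURES, "mean_signed_error": obs, "p_value": p}
    )


# ------------------------------------------------------------ heatmap


def zscore_heatmap(
    profiles: Sequence[ErrorProfile], reference: Sequence[ErrorProfile]
) -> HeatmapMatrix:
    """Z-score signed errors against the control reference and order the
    feature columns by complete-linkage (Lance-Williams maximum linkage)
    hierarchical clustering on Euclidean distances."""
    if len(reference) < 2:
        raise ValueError("reference must have at least 2 subjects")
    ref = np.array([p.signed_errors for p in reference])
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [OUTPUT_FEATURES[i] for i in np.nonzero(sd == 0)[0]]
        raise DegenerateReferenceError(f"zero reference SD for {bad}")
    errs = np.array([p.signed_errors for p in profiles])
    z = (errs - mu) / sd
    lw = linkage(z.T, method="complete", metric="euclidean")
    order = np.asarray(leaves_list(lw))
    return HeatmapMatrix(
        z=z,
        subject_ids=[p.subject_id for p in profiles],
        groups=[p.group for p in profiles],
        column_order=order,
        reference_mean=mu,
        reference_sd=sd,
    )


# ------------------------------------------------------------ embedding


def latent_embedding(
    model: TrainedModel,
    records: Sequence[SubjectRecord],
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """2-D UMAP embedding of the width-4 latent codes, one row per subject.

    If the cohort is smaller than the neighborhood size the neighbor count
    is shrunk (with a logged warning) so the embedding stays defined.
    """
    import umap  # deferred: JIT-compiled import is slow

    if model.normalizer is None:
        raise ValueError("model carries no fitted normalizer")
    X = normalize_many(records, model.normalizer)
    latent = encode_latent_many(model, X)
    k = n_neighbors
    if len(records) <= k:
        k = max(2, len(records) - 1)
        logger.warning("n_neighbors shrunk from %d to %d (n=%d)", n_neighbors, k, len(records))
    reducer = umap.UMAP(
        n_components=2, n_neighbors=k, min_dist=min_dist, random_state=seed
    )
    return np.asarray(reducer.fit_transform(latent), dtype=float)
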