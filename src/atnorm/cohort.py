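"""Synthetic cohort generator for controls and A-T-like subjects.

The generator emulates the tabular structure the analysis consumes: a
pediatric control cohort with right-skewed ages, age- and sex-dependent
cerebral/cerebellar volumes, regional ADC and CBF features that follow a
linear normative law in (age, sex, cerebellar volume) with additive
Gaussian noise, and an A-T-like group produced by drawing a subject from
the same control law and shifting it along disease directions scaled by a
latent per-subject severity.  Clinical sub-scores (A-T NEST; lower = more
severe) are linked to the same severity, giving the association stage a
recoverable signal.

Default directions: raised cerebellar ADC (gray and white matter), mildly
lowered hippocampal/caudate ADC, lowered caudate/putamen perfusion, raised
pallidum perfusion, and reduced cerebral and (strongly) cerebellar volume.
Under a normative model these produce under-estimation of raised features
and over-estimation of lowered ones — the anomaly signature the pipeline
is designed to detect.

This is a deliberately simple emulation: noise is independent across
features by default (an equicorrelation knob exists), and no spatial or
longitudinal structure is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import (
    DIFFUSION_ROIS,
    NEST_SCORES,
    OUTPUT_FEATURES,
    PERFUSION_ROIS,
    SubjectRecord,
)

__all__ = [
    "SyntheticConfig",
    "generate_controls",
    "generate_at_subjects",
    "generate_clinical_scores",
    "generate_cohort",
]


def _default_volume_model() -> dict:
    # intercept + slope_age*age + slope_sex*sex + N(0, sd); mL
    return {
        "cerebral": {"intercept": 1053.0, "slope_age": 8.0, "slope_sex": -25.0, "sd": 60.0},
        "cerebellar": {"intercept": 115.0, "slope_age": 4.0, "slope_sex": -8.0, "sd": 10.0},
    }


def _default_normative() -> dict:
    # feature = intercept + b_age*age + b_sex*sex + b_cbl*cerebellar_volume
    # ADC in 1e-6 mm^2/s, CBF in mL/100 g/min; pediatric ADC falls and CBF
    # declines mildly with age over this range.
    coeffs = {}
    adc_base = {
        "caudate": 760.0, "hippocampus": 860.0, "pallidum": 745.0,
        "putamen": 740.0, "thalamus": 765.0, "cgm": 820.0, "cwm": 790.0,
    }
    for roi in DIFFUSION_ROIS:
        coeffs[f"adc_{roi}"] = {
            "intercept": adc_base[roi], "b_age": -6.0, "b_sex": 5.0, "b_cbl": 0.2,
        }
    cbf_base = {
        "caudate": 70.0, "hippocampus": 60.0, "pallidum": 55.0,
        "putamen": 67.0, "thalamus": 65.0, "cgm": 60.0,
    }
    for roi in PERFUSION_ROIS:
        coeffs[f"cbf_{roi}"] = {
            "intercept": cbf_base[roi], "b_age": -0.8, "b_sex": 1.0, "b_cbl": 0.05,
        }
    return coeffs


def _default_noise_sd() -> dict:
    sd = {f"adc_{r}": 18.0 for r in DIFFUSION_ROIS}
    sd.update({f"cbf_{r}": 2.5 for r in PERFUSION_ROIS})
    return sd


def _default_perturbation() -> dict:
    # signed shifts at severity 1, physical units
    return {
        "adc_cgm": 500.0,
        "adc_cwm": 200.0,
        "adc_hippocampus": -100.0,
        "adc_caudate": -90.0,
        "cbf_caudate": -8.0,
        "cbf_putamen": -3.5,
        "cbf_pallidum": 7.0,
        "cerebral_volume": -105.0,
        "cerebellar_volume": -89.0,
    }


def _default_score_model() -> dict:
    # score = baseline - slope*severity + N(0, sd), truncated to bounds
    return {
        "ataxia": {"baseline": 28.0, "slope": 12.0, "sd": 2.5, "bounds": (0.0, 30.0)},
        "hypermotor": {"baseline": 9.0, "slope": 3.5, "sd": 1.0, "bounds": (0.0, 10.0)},
        "bradykinesia": {"baseline": 9.0, "slope": 4.0, "sd": 1.0, "bounds": (0.0, 10.0)},
        "dystonia": {"baseline": 9.0, "slope": 3.0, "sd": 1.2, "bounds": (0.0, 10.0)},
    }


@dataclass
class SyntheticConfig:
    """Generator parameters.  Defaults reproduce the cohort scale the
    analysis was designed for: 110 controls (median age ~5.5 y, median
    cerebellar volume ~133 mL) and 16 A-T-like subjects (median age ~12 y,
    median cerebellar volume ~70 mL)."""

    n_controls: int = 110
    n_at: int = 16
    seed: int = 0
    age_range_control: tuple[float, float] = (2.9, 16.3)
    age_range_at: tuple[float, float] = (4.6, 17.8)
    # Beta shape parameters placing the age medians at ~5.5 y / ~12.0 y
    age_beta_control: tuple[float, float] = (1.5, 5.0)
    age_beta_at: tuple[float, float] = (2.0, 1.7)
    sex_prob: float = 0.48  # P(sex = 1 = female)
    volume_model: dict = field(default_factory=_default_volume_model)
    normative_coefficients: dict = field(default_factory=_default_normative)
    noise_sd: dict = field(default_factory=_default_noise_sd)
    noise_correlation: float = 0.0  # equicorrelation across the 13 features
    at_perturbation: dict = field(default_factory=_default_perturbation)
    severity_mean: float = 1.0
    severity_sd: float = 0.35
    score_model: dict = field(default_factory=_default_score_model)

    def __post_init__(self) -> None:
        if self.n_controls <= 0 or self.n_at <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 <= self.sex_prob <= 1.0:
            raise ValueError("sex_prob must be a probability")
        for lo, hi in (self.age_range_control, self.age_range_at):
            if not 0 < lo < hi:
                raise ValueError("age ranges must be ordered and positive")
        if any(v <= 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be positive")
        if not 0.0 <= self.noise_correlation < 1.0:
            raise ValueError("noise_correlation must be in [0, 1)")

    def perturbed_imaging_features(self) -> dict[str, float]:
        """Imaging features shifted by the default disease direction."""
        return {
            k: v for k, v in self.at_perturbation.items() if k in OUTPUT_FEATURES
        }


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per generation stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _draw_base_subject(
    config: SyntheticConfig,
    rng: np.random.Generator,
    age_range: tuple[float, float],
    age_beta: tuple[float, float],
) -> dict:
    lo, hi = age_range
    age = lo + (hi - lo) * rng.beta(*age_beta)
    sex = int(rng.random() < config.sex_prob)
    vols = {}
    for name, m in config.volume_model.items():
        vols[name] = (
            m["intercept"] + m["slope_age"] * age + m["slope_sex"] * sex
            + rng.normal(0.0, m["sd"])
        )
    return {"age": age, "sex": sex, **vols}


def _feature_values(
    config: SyntheticConfig, base: dict, rng: np.random.Generator
) -> dict[str, float]:
    rho = config.noise_correlation
    shared = rng.normal() if rho > 0 else 0.0
    values = {}
    for feat in OUTPUT_FEATURES:
        c = config.normative_coefficients[feat]
        mean = (
            c["intercept"] + c["b_age"] * base["age"] + c["b_sex"] * base["sex"]
            + c["b_cbl"] * base["cerebellar"]
        )
        eps = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.normal()
        values[feat] = mean + config.noise_sd[feat] * eps
    return values


def _to_record(
    config: SyntheticConfig, idx: int, group: str, base: dict,
    values: dict[str, float], severity: float | None,
) -> SubjectRecord:
    prefix = "CTRL" if group == "control" else "AT"
    return SubjectRecord(
        subject_id=f"{prefix}{idx:04d}",
        dataset="synthetic",
        group=group,
        session_id="ses-01",
        age=float(base["age"]),
        sex=base["sex"],
        cerebral_volume=float(base["cerebral"]),
        cerebellar_volume=float(base["cerebellar"]),
        # floors keep records valid under extreme severity configs; far
        # below the plausible bands so defaults are unaffected
        adc={r: float(max(values[f"adc_{r}"], 50.0)) for r in DIFFUSION_ROIS},
        cbf={r: float(max(values[f"cbf_{r}"], 0.0)) for r in PERFUSION_ROIS},
        severity=severity,
    )


def generate_controls(config: SyntheticConfig) -> list[SubjectRecord]:
    """Draw ``n_controls`` healthy subjects from the normative law."""
    rng = _rng(config, stream=1)
    records = []
    for i in range(config.n_controls):
        base = _draw_base_subject(
            config, rng, config.age_range_control, config.age_beta_control
        )
        values = _feature_values(config, base, rng)
        records.append(_to_record(config, i, "control", base, values, None))
    return records


def generate_at_subjects(config: SyntheticConfig) -> list[SubjectRecord]:
    """Draw ``n_at`` A-T-like subjects: a control draw from the A-T age
    distribution, shifted by ``severity * at_perturbation``."""
    rng = _rng(config, stream=2)
    records = []
    for i in range(config.n_at):
        base = _draw_base_subject(config, rng, config.age_range_at, config.age_beta_at)
        severity = max(0.0, rng.normal(config.severity_mean, config.severity_sd))
        values = _feature_values(config, base, rng)
        for feat, shift in config.at_perturbation.items():
            if feat in values:
                values[feat] += severity * shift
            elif feat == "cerebral_volume":
                base["cerebral"] += severity * shift
            elif feat == "cerebellar_volume":
                base["cerebellar"] += severity * shift
            else:
                raise KeyError(f"unknown perturbation target {feat!r}")
        base["cerebellar"] = max(base["cerebellar"], 20.0)
        base["cerebral"] = max(base["cerebral"], 400.0)
        records.append(_to_record(config, i, "AT", base, values, severity))
    return records


def generate_clinical_scores(
    subjects: list[SubjectRecord], config: SyntheticConfig
) -> list[SubjectRecord]:
    """Attach NEST sub-scores linked to severity (lower = more severe).

    Each score is ``baseline - slope*severity + noise`` truncated to its
    bounds, so the severity-score correlation is negative in expectation.
    Subjects without a severity (controls) are returned unchanged.
    """
    rng = _rng(config, stream=3)
    out = []
    for rec in subjects:
        if rec.severity is None:
            out.append(rec)
            continue
        nest = {}
        for s in NEST_SCORES:
            m = config.score_model[s]
            raw = m["baseline"] - m["slope"] * rec.severity + rng.normal(0.0, m["sd"])
            lo, hi = m["bounds"]
            nest[s] = float(np.clip(raw, lo, hi))
        out.append(replace(rec, nest=nest))
    return out


def generate_cohort(config: SyntheticConfig) -> list[SubjectRecord]:
    """Controls plus scored A-T-like subjects, one call."""
    controls = generate_controls(config)
    at = generate_clinical_scores(generate_at_subjects(config), config)
    return controls + at
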