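"""Shapley-value attribution of reconstructions to input features.

A model-agnostic Kernel SHAP estimator: for one subject, coalitions of
"present" input features are sampled from the Shapley kernel distribution,
absent features are filled in from background (control) samples, and the
attributions solve a least-squares problem constrained so that
base + sum(attributions) equals the model output exactly (local accuracy
holds by construction).  For models linear in the inputs the estimate
coincides with the closed form w_i * (x_i - E[x_i]).

Self-effects — the attribution of each imaging input onto its own
reconstruction — are masked before summarization, so the stacked
summaries show cross-feature influence only.  Covariate inputs have no
corresponding output and are never masked.  Attributions live on the
normalized model scale; helpers convert to physical units via the fixed
feature scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import (
    FEATURE_SCALES,
    INPUT_FEATURES,
    OUTPUT_FEATURES,
    PERFUSION_FEATURES,
)
from .model import TrainedModel, reconstruct_many

N_INPUTS = len(INPUT_FEATURES)  # 20
N_OUTPUTS = len(OUTPUT_FEATURES)  # 13
DEFAULT_N_SAMPLES = 2 * N_INPUTS + 2048


@dataclass
class ShapAttribution:
    """Mean attribution of the 20 inputs onto the 13 outputs with
    self-effect entries masked."""

    matrix: np.ndarray  # (13, 20) mean attributions
    base_values: np.ndarray  # (13,) expected reconstruction over background
    mask: np.ndarray  # (13, 20) boolean, True = excluded self-effect

    def __post_init__(self) -> None:
        if self.matrix.shape != (N_OUTPUTS, N_INPUTS):
            raise ValueError(f"matrix must be {(N_OUTPUTS, N_INPUTS)}")
        if int(self.mask.sum()) != N_OUTPUTS:
            raise ValueError("exactly 13 self-effect entries must be masked")

    def masked_matrix(self) -> np.ndarray:
        """Attribution matrix with self-effects zeroed out."""
        out = self.matrix.copy()
        out[self.mask] = 0.0
        return out


@dataclass
class StackedSummary:
    """Per-input stacked totals of signed mean attributions for one output
    family (perfusion or diffusion), decomposed by output feature."""

    family: str
    per_output: pd.DataFrame  # input_feature, output_feature, mean_value
    totals: pd.DataFrame  # input_feature, positive_total, negative_total, net


def _shapley_kernel_sizes(m: int) -> tuple[np.ndarray, np.ndarray]:
    sizes = np.arange(1, m)
    probs = (m - 1) / (sizes * (m - sizes))
    return sizes, probs / probs.sum()


def kernel_shap(
    predict: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Shapley attributions of one input vector for a multi-output model.

    Parameters
    ----------
    predict : callable mapping (k, m) inputs to (k, p) outputs.
    x : the (m,) input to explain.
    background : (n_bg, m) reference samples defining feature absence.
    n_samples : number of sampled coalitions.
    seed : coalition-sampling seed.

    Returns
    -------
    (phi, base) where phi is (p, m) and base is the (p,) background-mean
    prediction; base + phi.sum(axis=1) equals predict(x) exactly.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    m = len(x)
    n_bg = len(background)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))

    sizes, size_probs = _shapley_kernel_sizes(m)
    drawn = rng.choice(sizes, size=n_samples, p=size_probs)
    Z = np.zeros((n_samples, m), dtype=bool)
    for row, s in enumerate(drawn):
        Z[row, rng.choice(m, size=s, replace=False)] = True

    # masked inputs: coalition features from x, the rest from each
    # background sample; f(z) = mean over background
    tiled_bg = np.repeat(background[None, :, :], n_samples, axis=0)  # (S, n_bg, m)
    masked = np.where(Z[:, None, :], x[None, None, :], tiled_bg)
    preds = predict(masked.reshape(n_samples * n_bg, m))
    preds = np.asarray(preds, dtype=float).reshape(n_samples, n_bg, -1)
    fz = preds.mean(axis=1)  # (S, p)

    base = np.asarray(predict(background), dtype=float).mean(axis=0)  # (p,)
    fx = np.asarray(predict(x[None, :]), dtype=float)[0]  # (p,)
    excess = fx - base

    # least squares with the efficiency constraint sum(phi) = fx - base,
    # eliminating the last coefficient
    Zf = Z.astype(float)
    A = Zf[:, :-1] - Zf[:, -1:]
    B = (fz - base) - Zf[:, -1:] * excess[None, :]
    phi_rest, *_ = np.linalg.lstsq(A, B, rcond=None)  # (m-1, p)
    phi_last = excess - phi_rest.sum(axis=0)
    phi = np.vstack([phi_rest, phi_last[None, :]]).T  # (p, m)
    return phi, base


def _predict_fn(model: TrainedModel) -> Callable[[np.ndarray], np.ndarray]:
    return lambda X: reconstruct_many(model, X)


def compute_attributions_all(
    model: TrainedModel,
    background: np.ndarray,
    evaluation: np.ndarray,
    seed: int = 0,
    n_samples: int = DEFAULT_N_SAMPLES,
    max_background: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject attribution tensor for all 13 outputs.

    Returns (tensor, base) with tensor shape (n_eval, 13, 20).  The
    background is subsampled (seeded) to ``max_background`` rows.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    evaluation = np.atleast_2d(np.asarray(evaluation, dtype=float))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 72]))
    if len(background) > max_background:
        keep = rng.choice(len(background), size=max_background, replace=False)
        background = background[keep]
    predict = _predict_fn(model)
    rows = []
    base = None
    for i, x in enumerate(evaluation):
        phi, base = kernel_shap(predict, x, background, n_samples, seed=seed + i)
        rows.append(phi)
    return np.array(rows), base


def compute_attributions(
    model: TrainedModel,
    background: np.ndarray,
    evaluation: np.ndarray,
    output_index: int,
    seed: int = 0,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> np.ndarray:
    """Per-subject attribution rows (n_eval, 20) for one output feature."""
    if not 0 <= output_index < N_OUTPUTS:
        raise ValueError(f"output_index must be in 0..{N_OUTPUTS - 1}")
    tensor, _ = compute_attributions_all(
        model, background, evaluation, seed=seed, n_samples=n_samples
    )
    return tensor[:, output_index, :]


def self_effect_mask() -> np.ndarray:
    """Boolean (13, 20) mask of the identity pairings (output i, input i).

    The first 13 inputs are the imaging features in the same order as the
    outputs, so the mask is the leading diagonal; cross-modality same-ROI
    pairs (e.g. caudate ADC on caudate CBF) are intentionally NOT masked.
    """
    mask = np.zeros((N_OUTPUTS, N_INPUTS), dtype=bool)
    mask[np.arange(N_OUTPUTS), np.arange(N_OUTPUTS)] = True
    return mask


def exclude_self_effect(
    matrix: np.ndarray, base_values: np.ndarray | None = None
) -> ShapAttribution:
    """Flag self-effect entries of a mean attribution matrix as excluded."""
    matrix = np.asarray(matrix, dtype=float)
    if base_values is None:
        base_values = np.zeros(N_OUTPUTS)
    return ShapAttribution(
        matrix=matrix, base_values=np.asarray(base_values, float), mask=self_effect_mask()
    )


def attribution_matrix(tensor: np.ndarray) -> np.ndarray:
    """Mean over evaluation subjects: (n, 13, 20) -> (13, 20)."""
    return np.asarray(tensor, dtype=float).mean(axis=0)


def stacked_summary(attr: ShapAttribution, family: str) -> StackedSummary:
    """Stacked positive/negative totals of mean attributions per input.

    ``family`` selects the output features summarized: "perfusion" (6
    outputs) or "diffusion" (7 outputs).  Masked self-effect entries are
    excluded from all sums; positive_total + negative_total equals the net
    mean attribution of the input onto that family.
    """
    if family == "perfusion":
        out_idx = np.arange(len(PERFUSION_FEATURES))
    elif family == "diffusion":
        out_idx = np.arange(len(PERFUSION_FEATURES), N_OUTPUTS)
    else:
        raise ValueError("family must be 'perfusion' or 'diffusion'")
    rows = []
    for j in out_idx:
        for i in range(N_INPUTS):
            if attr.mask[j, i]:
                continue
            rows.append(
                {
                    "input_feature": INPUT_FEATURES[i],
                    "output_feature": OUTPUT_FEATURES[j],
                    "mean_value": attr.matrix[j, i],
                }
            )
    per_output = pd.DataFrame(rows)
    g = per_output.groupby("input_feature", sort=False)["mean_value"]
    totals = pd.DataFrame(
        {
            "positive_total": g.apply(lambda v: v[v > 0].sum()),
            "negative_total": g.apply(lambda v: v[v < 0].sum()),
            "net": g.sum(),
        }
    ).reset_index()
    return StackedSummary(family=family, per_output=per_output, totals=totals)


def to_physical_units(attr: ShapAttribution) -> np.ndarray:
    """Attribution matrix rescaled so each output row is in its physical
    unit (mL/100 g/min for perfusion rows, 1e-6 mm^2/s for diffusion)."""
    return attr.matrix * FEATURE_SCALES[:, None]
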