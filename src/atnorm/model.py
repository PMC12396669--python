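"""Normative autoencoder over the 20 -> 13 feature map.

Seven asymmetric fully connected layers with widths 20-15-10-4-8-10-13 and
rectifier activations between layers; the output layer is linear so
reconstructions of anomalous subjects may leave the nominal [0, 1] band.
The network reconstructs the 13 imaging features only — covariates enter
as inputs but are not reconstructed, so the model learns the conditional
normative law of imaging features given demographics.

The median over per-subject mean squared errors is the evaluation and
model-selection metric throughout; as a *training* objective the batch
median (``Hyperparameters.loss = "median"``) is also implemented — its
subgradient is taken at the median-defining subject, using the lower-
median element for even-sized batches so the subgradient is unique — but
the default objective is the batch mean, which uses every subject's
gradient and fits markedly better at these cohort sizes.

Everything is plain numpy with explicit backpropagation and an Adam
optimizer: the network is tiny (792 trainable parameters) and a fully
deterministic, dependency-light implementation is worth more here than
framework speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import ModelInput, ModelOutput, Normalizer

DEFAULT_WIDTHS: tuple[int, ...] = (20, 15, 10, 4, 8, 10, 13)
_LATENT_LAYER = 3  # activation index of the width-4 bottleneck


class ArchitectureError(ValueError):
    """Layer widths differ from the canonical architecture."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class AEArchitecture:
    """Layer widths of the asymmetric autoencoder."""

    layer_widths: tuple[int, ...] = DEFAULT_WIDTHS

    def validate(self, allow_nonstandard: bool = False) -> None:
        if tuple(self.layer_widths) != DEFAULT_WIDTHS and not allow_nonstandard:
            raise ArchitectureError(
                f"expected widths {DEFAULT_WIDTHS}, got {tuple(self.layer_widths)}; "
                "pass allow_nonstandard=True to override"
            )
        if len(self.layer_widths) < 2 or any(w <= 0 for w in self.layer_widths):
            raise ArchitectureError("invalid layer widths")


@dataclass(frozen=True)
class Hyperparameters:
    """Training configuration.

    The default objective is the mean over per-subject MSEs: the per-batch
    median variant (``loss="median"``) back-propagates only the median-
    defining subject and measurably underfits on cohorts of this size;
    the median remains the evaluation/report metric either way.  Weight
    decay is on by default — a normative model must extrapolate to
    covariates outside the healthy range, and the L2 penalty keeps that
    extrapolation tame.
    """

    learning_rate: float = 5e-3
    batch_size: int = 16
    epochs: int = 500
    weight_decay: float = 1e-3
    optimizer_name: str = "adam"
    loss: str = "mean"  # "mean" | "median" over per-subject MSEs
    patience: int = 50  # early-stopping patience on validation loss

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if self.loss not in ("median", "mean"):
            raise ValueError("loss must be 'median' or 'mean'")


@dataclass
class TrainedModel:
    architecture: AEArchitecture
    weights: list[np.ndarray]  # W_0..W_{L-1}, shape (in, out)
    biases: list[np.ndarray]
    normalizer: Normalizer | None
    hyperparameters: Hyperparameters
    seed: int
    loss_history: dict = field(default_factory=lambda: {"train": [], "val": []})

    def parameter_count(self) -> int:
        return int(sum(w.size + b.size for w, b in zip(self.weights, self.biases)))

    # -- persistence --------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(directory / "weights.npz", **arrays)
        manifest = {
            "layer_widths": list(self.architecture.layer_widths),
            "hyperparameters": dataclasses_asdict(self.hyperparameters),
            "normalizer": self.normalizer.to_dict() if self.normalizer else None,
            "seed": self.seed,
            "loss_history": self.loss_history,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        data = np.load(directory / "weights.npz")
        n_layers = len(manifest["layer_widths"]) - 1
        weights = [data[f"W{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
        norm = manifest["normalizer"]
        return cls(
            architecture=AEArchitecture(tuple(manifest["layer_widths"])),
            weights=weights,
            biases=biases,
            normalizer=Normalizer.from_dict(norm) if norm else None,
            hyperparameters=Hyperparameters(**manifest["hyperparameters"]),
            seed=manifest["seed"],
            loss_history=manifest["loss_history"],
        )


def dataclasses_asdict(hp: Hyperparameters) -> dict:
    return {
        "learning_rate": hp.learning_rate,
        "batch_size": hp.batch_size,
        "epochs": hp.epochs,
        "weight_decay": hp.weight_decay,
        "optimizer_name": hp.optimizer_name,
        "loss": hp.loss,
        "patience": hp.patience,
    }


def build_model(
    arch: AEArchitecture = AEArchitecture(),
    seed: int = 0,
    normalizer: Normalizer | None = None,
    hyperparameters: Hyperparameters = Hyperparameters(),
    allow_nonstandard: bool = False,
) -> TrainedModel:
    """Deterministically initialize an untrained model (He-scaled init)."""
    arch.validate(allow_nonstandard=allow_nonstandard)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    widths = arch.layer_widths
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return TrainedModel(
        architecture=arch,
        weights=weights,
        biases=biases,
        normalizer=normalizer,
        hyperparameters=hyperparameters,
        seed=seed,
    )


# ---------------------------------------------------------------- forward


def _forward(weights, biases, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; ReLU between layers, linear output."""
    acts = [X]
    a = X
    last = len(weights) - 1
    for i, (w, b) in enumerate(zip(weights, biases)):
        z = a @ w + b
        a = z if i == last else np.maximum(z, 0.0)
        acts.append(a)
    return acts


def reconstruct_many(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Forward pass for a (n, 20) batch; returns (n, 13) reconstructions."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.architecture.layer_widths[0]:
        raise ValueError(
            f"input width {X.shape[1]} != {model.architecture.layer_widths[0]}"
        )
    return _forward(model.weights, model.biases, X)[-1]


def reconstruct(model: TrainedModel, inp: ModelInput) -> ModelOutput:
    """Deterministic reconstruction of one subject's imaging features."""
    out = reconstruct_many(model, inp.values[None, :])[0]
    return ModelOutput(values=out)


def encode_latent_many(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return _forward(model.weights, model.biases, X)[_LATENT_LAYER]


def encode_latent(model: TrainedModel, inp: ModelInput) -> np.ndarray:
    """Activations at the width-4 bottleneck."""
    return encode_latent_many(model, inp.values[None, :])[0]


def subject_mse(output, target) -> float:
    """Per-subject mean squared reconstruction error over features."""
    y_hat = output.values if isinstance(output, ModelOutput) else np.asarray(output, float)
    y = target.values[:13] if isinstance(target, ModelInput) else np.asarray(target, float)
    if len(y_hat) != len(y):
        raise ValueError(f"length mismatch: {len(y_hat)} vs {len(y)}")
    d = y - y_hat
    return float(np.mean(d * d))


def batch_mse(Y_hat: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-subject MSEs for stacked reconstructions/targets."""
    d = Y - Y_hat
    return np.mean(d * d, axis=1)


# ---------------------------------------------------------------- training


def split_controls(
    records: Sequence,
    fractions: tuple[float, float, float] = (80 / 110, 20 / 110, 10 / 110),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Disjoint train/validation/test partition of the control cohort.

    Default fractions give the 80/20/10 split on a 110-subject cohort.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    idx = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = max(1, min(n_train, n - 2))
    n_val = max(1, min(n_val, n - n_train - 1))
    parts = (idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :])
    return tuple([records[i] for i in p] for p in parts)  # type: ignore[return-value]


def _loss_and_weights(mses: np.ndarray, kind: str) -> tuple[float, np.ndarray]:
    """Batch loss plus the per-subject weights c with loss = sum c_j mse_j."""
    c = np.zeros_like(mses)
    if kind == "mean":
        c[:] = 1.0 / len(mses)
        return float(np.mean(mses)), c
    order = np.argsort(mses, kind="stable")
    j = order[(len(mses) - 1) // 2]  # lower median for even batches
    c[j] = 1.0
    return float(mses[j]), c


def evaluate_loss(model: TrainedModel, X: np.ndarray, kind: str | None = None) -> float:
    """Median (or mean) per-subject MSE of a model on a normalized set."""
    kind = kind or model.hyperparameters.loss
    mses = batch_mse(reconstruct_many(model, X), np.asarray(X)[:, :13])
    return float(np.median(mses) if kind == "median" else np.mean(mses))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, wd: float):
        self.lr, self.wd = lr, wd
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.wd:
                g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params, lr: float, wd: float):
        self.lr, self.wd = lr, wd

    def step(self, params, grads) -> None:
        for p, g in zip(params, grads):
            if self.wd:
                g = g + self.wd * p
            p -= self.lr * g


def _backward(weights, biases, acts, dY: np.ndarray):
    """Gradients of sum-over-batch loss wrt weights/biases, given dL/d(output)."""
    gW = [None] * len(weights)
    gb = [None] * len(weights)
    delta = dY
    for i in range(len(weights) - 1, -1, -1):
        a_in = acts[i]
        gW[i] = a_in.T @ delta
        gb[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ weights[i].T) * (acts[i] > 0)
    return gW, gb


def train(
    model: TrainedModel,
    train_X: np.ndarray,
    val_X: np.ndarray,
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Train on normalized control inputs; return the best-validation model.

    Mini-batches are reshuffled each epoch from a seeded generator; the
    returned model carries the weights from the epoch with minimum
    validation loss and the full per-epoch train/validation loss history.
    Fully deterministic given (model weights, hp, seed).
    """
    hp = hp or model.hyperparameters
    train_X = np.asarray(train_X, dtype=float)
    val_X = np.asarray(val_X, dtype=float)
    if train_X.size == 0 or val_X.size == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    weights = [w.copy() for w in model.weights]
    biases = [b.copy() for b in model.biases]
    n_out = model.architecture.layer_widths[-1]
    opt_cls = _Adam if hp.optimizer_name.lower() == "adam" else _SGD
    opt = opt_cls(weights + biases, hp.learning_rate, hp.weight_decay)

    history: dict = {"train": [], "val": []}
    best_val = np.inf
    best = ([w.copy() for w in weights], [b.copy() for b in biases])
    stale = 0

    def _set_eval(m: TrainedModel):  # evaluation snapshot, no copies
        m.weights, m.biases = weights, biases
        return m

    eval_model = replace(model)
    for epoch in range(hp.epochs):
        order = rng.permutation(len(train_X))
        epoch_losses = []
        for start in range(0, len(order), hp.batch_size):
            batch = train_X[order[start : start + hp.batch_size]]
            acts = _forward(weights, biases, batch)
            Y_hat, Y = acts[-1], batch[:, :n_out]
            mses = batch_mse(Y_hat, Y)
            loss, c = _loss_and_weights(mses, hp.loss)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            epoch_losses.append(loss)
            dY = (2.0 / n_out) * c[:, None] * (Y_hat - Y)
            gW, gb = _backward(weights, biases, acts, dY)
            opt.step(weights + biases, gW + gb)

        val_loss = evaluate_loss(_set_eval(eval_model), val_X, hp.loss)
        history["train"].append(float(np.mean(epoch_losses)))
        history["val"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best = ([w.copy() for w in weights], [b.copy() for b in biases])
            stale = 0
        else:
            stale += 1
            if hp.patience and stale >= hp.patience:
                break

    return TrainedModel(
        architecture=model.architecture,
        weights=best[0],
        biases=best[1],
        normalizer=model.normalizer,
        hyperparameters=hp,
        seed=seed,
        loss_history=history,
    )


def grid_search(
    X: np.ndarray,
    grid: Sequence[Hyperparameters],
    k: int = 5,
    seed: int = 0,
    arch: AEArchitecture = AEArchitecture(),
) -> list[tuple[Hyperparameters, float]]:
    """Rank hyperparameter configurations by k-fold CV validation loss.

    Every grid point is trained on each of the k folds' complements and
    scored on the held-out fold; configurations are returned best-first by
    mean validation loss.  The top five form the "best models" report.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    idx = rng.permutation(len(X))
    folds = np.array_split(idx, k)
    results = []
    for gi, hp in enumerate(grid):
        losses = []
        for fi in range(k):
            val_idx = folds[fi]
            tr_idx = np.concatenate([folds[j] for j in range(k) if j != fi])
            m0 = build_model(arch, seed=seed + 1000 * gi + fi, hyperparameters=hp)
            fitted = train(m0, X[tr_idx], X[val_idx], hp, seed=seed + 1000 * gi + fi)
            losses.append(evaluate_loss(fitted, X[val_idx], hp.loss))
        results.append((hp, float(np.mean(losses))))
    results.sort(key=lambda t: t[1])
    return results


def best_models_report(
    ranked: Sequence[tuple[Hyperparameters, float]]
) -> list[tuple[Hyperparameters, float]]:
    """Top-five configurations (fewer if the grid is smaller)."""
    return list(ranked[:5])
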