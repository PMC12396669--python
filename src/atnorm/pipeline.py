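"""End-to-end orchestration: simulate -> split -> train -> evaluate ->
embed -> explain -> associate, under one config with reproducible seeding.

Every stage writes plain CSV/JSON artifacts into the run directory and is
recorded in ``manifest.json`` (config hash, stage sub-seeds, outputs).
Wall-clock timings go to a separate ``timings.json`` so the manifest is
bit-identical across reruns with the same config and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import cohort as cohort_mod
from . import explain as explain_mod
from . import stats as stats_mod
from .features import (
    INPUT_FEATURES,
    OUTPUT_FEATURES,
    SubjectRecord,
    fit_normalizer,
    normalize_many,
    read_feature_table,
    select_session,
    write_feature_table,
)
from .model import (
    AEArchitecture,
    Hyperparameters,
    TrainedModel,
    best_models_report,
    build_model,
    grid_search,
    split_controls,
    train,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "split", "train", "evaluate", "embed", "explain", "associate")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    out_dir: str = "atnorm_run"
    features_path: str | None = None  # when None, simulate a cohort
    synthetic: cohort_mod.SyntheticConfig | None = None
    fractions: tuple[float, float, float] = (80 / 110, 20 / 110, 10 / 110)
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)
    grid: list[Hyperparameters] | None = None
    cv_folds: int = 5
    permutation_iterations: int = 1000
    shap_samples: int = explain_mod.DEFAULT_N_SAMPLES
    shap_background: int = 50
    report_threshold: float = 0.1
    skip: tuple[str, ...] = ()

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # hash the analysis, not its destination
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all (non-skipped) stages; returns the run directory.

    A stage failure aborts the run but still writes a manifest naming the
    stages completed so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "stages": {},
    }
    timings: dict = {}
    state: dict = {}
    try:
        for stage in STAGES:
            if stage in config.skip:
                manifest["stages"][stage] = {"status": "skipped"}
                logger.info("stage %s skipped", stage)
                continue
            t0 = time.perf_counter()
            outputs = _STAGE_FN[stage](config, out, state)
            timings[stage] = round(time.perf_counter() - t0, 3)
            manifest["stages"][stage] = {"status": "done", "outputs": outputs}
            logger.info("stage %s done (%d outputs)", stage, len(outputs))
    finally:
        _write_json(out / "manifest.json", manifest)
        _write_json(out / "timings.json", timings)
    return out


# ------------------------------------------------------------------ stages


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> list[str]:
    if config.features_path:
        records = select_session(read_feature_table(config.features_path))
        sc = None
    else:
        sc = config.synthetic or cohort_mod.SyntheticConfig(
            seed=config.stage_seed("simulate")
        )
        records = cohort_mod.generate_cohort(sc)
    state["records"] = records
    state["synthetic_config"] = sc
    write_feature_table(records, out / "cohort.csv")
    cfg = dataclasses.asdict(sc) if sc else {"features_path": config.features_path}
    _write_json(out / "cohort_config.json", cfg)
    return ["cohort.csv", "cohort_config.json"]


def _stage_split(config: RunConfig, out: Path, state: dict) -> list[str]:
    records = state["records"]
    controls = [r for r in records if r.group == "control"]
    at = [r for r in records if r.group == "AT"]
    tr, va, te = split_controls(controls, config.fractions, config.stage_seed("split"))
    state.update(train_set=tr, val_set=va, test_set=te, at_set=at)
    _write_json(
        out / "split.json",
        {
            "train": [r.subject_id for r in tr],
            "val": [r.subject_id for r in va],
            "test": [r.subject_id for r in te],
            "at": [r.subject_id for r in at],
        },
    )
    return ["split.json"]


def _stage_train(config: RunConfig, out: Path, state: dict) -> list[str]:
    seed = config.stage_seed("train")
    norm = fit_normalizer(state["train_set"])
    X_tr = normalize_many(state["train_set"], norm)
    X_va = normalize_many(state["val_set"], norm)
    hp = config.hyperparameters
    outputs = []
    if config.grid:
        ranked = grid_search(
            np.vstack([X_tr, X_va]), config.grid, k=config.cv_folds, seed=seed
        )
        hp = ranked[0][0]
        report = [
            {"hyperparameters": dataclasses.asdict(h), "cv_loss": loss}
            for h, loss in best_models_report(ranked)
        ]
        _write_json(out / "grid_search.json", report)
        outputs.append("grid_search.json")
    m0 = build_model(AEArchitecture(), seed=seed, normalizer=norm, hyperparameters=hp)
    model = train(m0, X_tr, X_va, hp, seed=seed)
    model.save(out / "model")
    state["model"] = model
    outputs += ["model/weights.npz", "model/manifest.json"]
    return outputs


def _stage_evaluate(config: RunConfig, out: Path, state: dict) -> list[str]:
    model: TrainedModel = state["model"]
    seed = config.stage_seed("evaluate")
    iters = config.permutation_iterations
    test, at = state["test_set"], state["at_set"]
    profiles = stats_mod.error_profiles(model, test + at)
    state["profiles"] = profiles
    stats_mod.profiles_frame(profiles).to_csv(out / "profiles.csv", index=False)
    comp = stats_mod.compare_groups_mse(profiles, iterations=iters, seed=seed)
    _write_json(out / "group_comparison.json", dataclasses.asdict(comp))
    ctrl = [p for p in profiles if p.group == "control"]
    atp = [p for p in profiles if p.group == "AT"]
    stats_mod.per_feature_bias(ctrl, iters, seed).to_csv(
        out / "feature_bias_control.csv", index=False
    )
    stats_mod.per_feature_bias(atp, iters, seed).to_csv(
        out / "feature_bias_at.csv", index=False
    )
    hm = stats_mod.zscore_heatmap(profiles, reference=ctrl)
    hm_df = pd.DataFrame(hm.z, columns=OUTPUT_FEATURES)
    hm_df.insert(0, "subject_id", hm.subject_ids)
    hm_df.insert(1, "group", hm.groups)
    hm_df.to_csv(out / "heatmap.csv", index=False)
    _write_json(out / "heatmap_column_order.json", hm.ordered_features)
    return [
        "profiles.csv",
        "group_comparison.json",
        "feature_bias_control.csv",
        "feature_bias_at.csv",
        "heatmap.csv",
        "heatmap_column_order.json",
    ]


def _stage_embed(config: RunConfig, out: Path, state: dict) -> list[str]:
    model = state["model"]
    records = state["test_set"] + state["at_set"]
    coords = stats_mod.latent_embedding(
        model, records, seed=config.stage_seed("embed")
    )
    df = pd.DataFrame(coords, columns=["umap_1", "umap_2"])
    df.insert(0, "subject_id", [r.subject_id for r in records])
    df.insert(1, "group", [r.group for r in records])
    df.to_csv(out / "embedding.csv", index=False)
    return ["embedding.csv"]


def _stage_explain(config: RunConfig, out: Path, state: dict) -> list[str]:
    model = state["model"]
    seed = config.stage_seed("explain")
    background = normalize_many(state["train_set"], model.normalizer)
    evaluation = normalize_many(state["at_set"], model.normalizer)
    tensor, base = explain_mod.compute_attributions_all(
        model,
        background,
        evaluation,
        seed=seed,
        n_samples=config.shap_samples,
        max_background=config.shap_background,
    )
    rows = []
    subject_ids = [r.subject_id for r in state["at_set"]]
    for si, sid in enumerate(subject_ids):
        for j, of in enumerate(OUTPUT_FEATURES):
            for i, inf in enumerate(INPUT_FEATURES):
                rows.append(
                    {
                        "subject_id": sid,
                        "output_feature": of,
                        "input_feature": inf,
                        "value": tensor[si, j, i],
                    }
                )
    pd.DataFrame(rows).to_csv(out / "shap_attributions.csv", index=False)
    attr = explain_mod.exclude_self_effect(
        explain_mod.attribution_matrix(tensor), base
    )
    summary = {}
    for family in ("perfusion", "diffusion"):
        s = explain_mod.stacked_summary(attr, family)
        summary[family] = s.totals.to_dict(orient="records")
    _write_json(out / "shap_summary.json", summary)
    state["attribution"] = attr
    return ["shap_attributions.csv", "shap_summary.json"]


def _stage_associate(config: RunConfig, out: Path, state: dict) -> list[str]:
    profiles = state.get("profiles") or stats_mod.error_profiles(
        state["model"], state["at_set"]
    )
    matrix = assoc_mod.association_matrix(
        profiles,
        state["at_set"],
        seed=config.stage_seed("associate"),
    )
    matrix.to_csv(out / "associations.csv")
    reported = {
        outcome: {
            k: float(v)
            for k, v in matrix.loc[outcome].items()
            if abs(v) > config.report_threshold
        }
        for outcome in matrix.index
    }
    _write_json(
        out / "associations.json",
        {"threshold": config.report_threshold, "reported": reported},
    )
    return ["associations.csv", "associations.json"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "split": _stage_split,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "embed": _stage_embed,
    "explain": _stage_explain,
    "associate": _stage_associate,
}
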