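import numpy as np
import pytest

from atnorm.cohort import SyntheticConfig, generate_cohort
from atnorm.features import fit_normalizer, normalize_many
from atnorm.model import Hyperparameters, build_model, split_controls, train


@pytest.fixture(scope="session")
def default_setup():
    """One default synthetic cohort with a trained normative model.

    Shared across test modules: 110 controls / 16 A-T (seed 1), 80/20/10
    control split, default training.
    """
    cfg = SyntheticConfig(seed=1)
    records = generate_cohort(cfg)
    controls = [r for r in records if r.group == "control"]
    at = [r for r in records if r.group == "AT"]
    tr, va, te = split_controls(controls, seed=1)
    norm = fit_normalizer(tr)
    hp = Hyperparameters()
    m0 = build_model(seed=1, normalizer=norm, hyperparameters=hp)
    model = train(m0, normalize_many(tr, norm), normalize_many(va, norm), hp, seed=1)
    return {
        "config": cfg,
        "records": records,
        "controls": controls,
        "at": at,
        "train": tr,
        "val": va,
        "test": te,
        "normalizer": norm,
        "model": model,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
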