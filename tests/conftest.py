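"""Shared fixtures: small synthetic sessions, feature tables, and the
end-to-end evaluation results reused by several slow tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import drowseeg as dg

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TWO_CH = ("Fp1", "Oz")

#: Strong injected band-power effect used for recovery experiments.
STRONG_DROWSY = {"delta": 1.0, "theta": 3.0, "alpha": 3.0, "beta": 1 / 3, "gamma": 0.5}


def small_config(**kwargs) -> dg.SimConfig:
    base = dict(
        n_channels=2,
        channel_labels=TWO_CH,
        duration_s=1500.0,
        seed=7,
    )
    base.update(kwargs)
    return dg.SimConfig(**base)


@pytest.fixture(scope="session")
def short_session():
    """A 2-channel 25-min session with the default state effect."""
    return dg.generate_session(small_config())


def gaussian_table(
    n_rows: int,
    n_features: int,
    separation: float,
    seed: int,
    n_informative: int = 1,
) -> dg.FeatureTable:
    """Balanced two-class Gaussian feature table; the first
    ``n_informative`` features have class means ``separation`` sd apart."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n_rows // 2)
    rng.shuffle(labels)
    x = rng.standard_normal((n_rows, n_features))
    x[:, :n_informative] += separation * labels[:, None]
    frame = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_features)])
    return dg.FeatureTable(frame, labels)


E2E_K_GRID = [1, 2, 3, 5, 8, 13, 21, 34, 42]
E2E_SEEDS = list(range(10))
NULL_SEEDS = list(range(5))


def _effect_config(seed: int) -> dg.SimConfig:
    return dg.SimConfig(
        n_channels=1,
        channel_labels=("Oz",),
        duration_s=2400.0,
        state_band_weights={
            "awake": dict(dg.synthetic.DEFAULT_AWAKE_WEIGHTS),
            "drowsy": dict(STRONG_DROWSY),
        },
        seed=1000 + seed,
    )


def _null_config(seed: int) -> dg.SimConfig:
    weights = dict(dg.synthetic.DEFAULT_AWAKE_WEIGHTS)
    return dg.SimConfig(
        n_channels=1,
        channel_labels=("Oz",),
        duration_s=2400.0,
        state_band_weights={"awake": dict(weights), "drowsy": dict(weights)},
        seed=2000 + seed,
    )


def _evaluate(config: dg.SimConfig, seed: int, feature_sets, models) -> list[dict]:
    recording, timeline = dg.generate_session(config)
    full = dg.extract_feature_table(recording, timeline, 30, None, "S+N")
    rows = []
    for fs_name in feature_sets:
        table = dg.select_feature_columns(full, fs_name)
        k_grid = sorted({min(k, len(table.feature_names)) for k in E2E_K_GRID})
        for model in models:
            spec = dg.ModelSpec(family=model, seed=seed)
            res = dg.run_protocol(table, spec, seed, k_grid, fs_name)
            rows.append(
                {
                    "seed": seed,
                    "model": model,
                    "feature_set": fs_name,
                    "accuracy": res.accuracy_overall,
                    "n_test": int(res.confusion.sum()),
                    "n_correct": int(res.confusion.trace()),
                }
            )
    return rows


@pytest.fixture(scope="session")
def e2e_results() -> dict[str, pd.DataFrame]:
    """Full-pipeline accuracies on effect and no-effect sessions.

    Effect sessions inject a strong drowsy band-power shift (theta/alpha x3,
    beta /3) into a single posterior channel; null sessions use identical
    band weights for both states, so labels carry no signal.
    """
    effect_rows: list[dict] = []
    for seed in E2E_SEEDS:
        effect_rows += _evaluate(_effect_config(seed), seed, ("S", "S+N"), ("rf", "svm"))
    null_rows: list[dict] = []
    for seed in NULL_SEEDS:
        null_rows += _evaluate(_null_config(seed), seed, ("S+N",), ("rf", "svm"))
    return {"effect": pd.DataFrame(effect_rows), "null": pd.DataFrame(null_rows)}
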