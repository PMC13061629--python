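"""Shared fixtures: a small fast study and the full demo pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from pirslice.pipeline import run_all
from pirslice.simulate import SimConfig, demo_config, simulate_all


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A scaled-down study for fast structural tests."""
    return SimConfig(seed=7, n_pirnas=30, n_transcripts=60,
                     smallrna_depth=20_000, degradome_depth=200_000,
                     n_strong=5, n_weak=10, n_control_targets=5, n_decoys=5)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_all(small_cfg)


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    """Full pipeline on the demo configuration, seed 42 (shared, read-only)."""
    out = tmp_path_factory.mktemp("demo42")
    return run_all(42, out, demo_config(42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
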