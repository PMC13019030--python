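"""Shared fixtures: a small rendered synthetic study reused by the
extraction-level tests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pytest

from dyadscope import SyntheticConfig, run_extract, run_simulate
from dyadscope.synthetic_dyads import reported_effect_matrix


@pytest.fixture(scope="session")
def small_study(tmp_path_factory) -> dict:
    """Three dyads, three 120 s topics, trait effects from the reported
    pattern, one participant without ECG."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = SyntheticConfig(
        n_dyads=3,
        topic_duration_s=120.0,
        effect_matrix=reported_effect_matrix(),
        missing_ecg_fraction=1.0 / 6.0,
        seed=11,
    )
    manifest = run_simulate(cfg, outdir)
    summary = run_extract(outdir)
    return {
        "dir": Path(outdir),
        "config": cfg,
        "manifest": manifest,
        "summary": summary,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
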