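"""Shared fixtures: one emitted default bundle + one full pipeline run.

The default synthetic bundle (seed 7) and its end-to-end run are session
fixtures so the recovery-style tests share a single ~10 s computation.
"""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from ploidyscan import pipeline as pl
from ploidyscan.simulate import SimConfig, TruthRecord, emit_dataset

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_bundle_dir(tmp_path_factory) -> Path:
    outdir = tmp_path_factory.mktemp("bundle")
    emit_dataset(SimConfig(seed=DEFAULT_SEED), outdir)
    return outdir


@pytest.fixture(scope="session")
def default_truth(default_bundle_dir) -> TruthRecord:
    return TruthRecord.from_json(default_bundle_dir / "truth.json")


@pytest.fixture(scope="session")
def default_run(default_bundle_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    config = pl.PipelineConfig(
        bundle_dir=str(default_bundle_dir),
        output_dir=str(outdir),
        seed=DEFAULT_SEED,
    )
    manifest = pl.run_all(config)
    return outdir, manifest, config
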