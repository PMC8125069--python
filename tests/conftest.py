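"""Shared fixtures: synthetic communities and one full pipeline run."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from effectornet.config import RunConfig
from effectornet.simulate import (default_community_spec, generate_community,
                                  immunity_demo_spec)


@pytest.fixture(scope="session")
def demo_community():
    """Small 5-genome community for immunity/cooccurrence checks."""
    return generate_community(immunity_demo_spec(seed=11))


@pytest.fixture(scope="session")
def default_community():
    """The default 20-genome community (6 toxin, 3 VgrG families)."""
    return generate_community(default_community_spec(seed=3))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default community; returns
    (run directory, manifest)."""
    from effectornet import pipeline
    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(seed=101)
    manifest = pipeline.run_all(outdir, cfg)
    return outdir, manifest
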