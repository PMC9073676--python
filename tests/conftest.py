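"""Shared fixtures: small simulated scenarios and one mid-size pipeline run.

Session scope keeps the expensive pieces (read simulation, alignment, the
full pipeline) to a single execution each; individual tests only inspect
the results.
"""

from __future__ import annotations

import numpy as np
import pytest

from transgenemap.align import ScoringScheme, build_index
from transgenemap.pipeline import PipelineConfig, run_all
from transgenemap.simulate import paper_scenario


@pytest.fixture(scope="session")
def scenario_small():
    """Smallest legal paper-style scenario (60 kb host, 20x)."""
    return paper_scenario(seed=1, host_length=60_000, depth=20.0)


@pytest.fixture(scope="session")
def index_small(scenario_small):
    return build_index(scenario_small.reference, k=21)


@pytest.fixture(scope="session")
def scoring():
    return ScoringScheme()


@pytest.fixture(scope="session")
def pipeline_200k(tmp_path_factory):
    """One full real-aligner pipeline run at 200 kb, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline200k")
    return run_all(PipelineConfig(seed=1, host_length=200_000, depth=20.0), out), out


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
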