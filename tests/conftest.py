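"""Shared fixtures: synthetic bundles at two scales.

The small bundle exercises every pipeline stage quickly; the default-scale
bundle reproduces the study conditions (1 Mb reference, 20 outgroups, two
screened clades of 4 and 3 plus two singleton lineages) and is shared
session-wide because conservation scoring dominates its cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from condelscan import SimulationConfig, simulate_study, load_inputs
from condelscan.pipeline import (ScreenInputs, ScreenState,
                                 prepare_screen_state, run_scan)


@dataclass
class PreparedBundle:
    bundle: object
    inputs: ScreenInputs
    state: ScreenState


def _prepare(tmpdir, config: SimulationConfig) -> PreparedBundle:
    bundle = simulate_study(config, tmpdir)
    inputs = load_inputs(tmpdir)
    state = prepare_screen_state(inputs)
    return PreparedBundle(bundle=bundle, inputs=inputs, state=state)


@pytest.fixture(scope="session")
def small_prepared(tmp_path_factory) -> PreparedBundle:
    cfg = SimulationConfig(seed=11, reference_length=200_000, n_genes=8,
                           n_true_condels=3, n_decoys=1)
    return _prepare(tmp_path_factory.mktemp("small_bundle"), cfg)


@pytest.fixture(scope="session")
def default_prepared(tmp_path_factory) -> PreparedBundle:
    cfg = SimulationConfig(seed=20260110)
    return _prepare(tmp_path_factory.mktemp("default_bundle"), cfg)


@pytest.fixture(scope="session")
def default_result(default_prepared):
    return run_scan(default_prepared.inputs, default_prepared.state)
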