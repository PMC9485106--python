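"""Shared fixtures: small simulated worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fearlfp import SessionPlan, SessionSpec, SimulationConfig, simulate_dafc_dataset
from fearlfp.simulate import default_coupling_table, default_gain_table, simulate_sessions


def make_plan(
    session_specs=(("Hab", "A", 2, 2, False), ("ACQ", "A", 2, 2, True)),
    lead_in_s: float = 20.0,
) -> SessionPlan:
    return SessionPlan(
        sessions=tuple(SessionSpec(*s) for s in session_specs),
        lead_in_s=lead_in_s,
    )


def make_config(plan: SessionPlan, seed: int = 7, fs: float = 500.0, **kwargs) -> SimulationConfig:
    kwargs.setdefault("cs_gain_table", default_gain_table(plan))
    kwargs.setdefault("coupling_table", default_coupling_table(plan))
    kwargs.setdefault("iti_range_s", (16.0, 20.0))
    return SimulationConfig(sampling_rate_hz=fs, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def tiny_plan() -> SessionPlan:
    return make_plan()


@pytest.fixture(scope="session")
def tiny_config(tiny_plan) -> SimulationConfig:
    return make_config(tiny_plan)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory, tiny_config, tiny_plan):
    """A small two-session dataset written in the on-disk layout."""
    out = tmp_path_factory.mktemp("data") / "tiny"
    simulate_dafc_dataset(tiny_config, tiny_plan, out)
    return out


@pytest.fixture(scope="session")
def default_world():
    """The full default protocol simulated in memory (38 CS+ / 38 CS-).

    Session-scoped because the full-scale simulation is the most expensive
    fixture in the suite; structural tests and the protocol acceptance
    check share it.
    """
    config = SimulationConfig(seed=2026)
    signals, events, gt, _ = simulate_sessions(config)
    return config, signals, events, gt


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
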