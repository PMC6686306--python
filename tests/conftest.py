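"""Shared fixtures: small synthetic objects built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from pelagis.activity import ImmersionSeries
from pelagis.simulate import BehaviorSequence, SimulationConfig, TruePath


@pytest.fixture
def colony():
    return (-51.85, -61.30)


@pytest.fixture
def stationary_path(colony):
    """A bird sitting at the colony through mid-December (far from equinox)."""
    t0 = np.datetime64("2012-12-01T00:00:00")
    times = np.arange(t0, t0 + np.timedelta64(11, "D"), np.timedelta64(600, "s"))
    n = len(times)
    return TruePath("stationary", times, np.full(n, colony[0]), np.full(n, colony[1]), colony, [])


def _offsets(durations_s: np.ndarray) -> np.ndarray:
    if len(durations_s) == 0:
        return np.array([])
    return np.concatenate([[0.0], np.cumsum(durations_s)[:-1]])


def make_immersion(states, durations_min, start="2013-01-01T00:00:00", individual_id="t"):
    """Build an alternating ImmersionSeries from state/duration lists."""
    durations_s = np.asarray(durations_min, dtype=float) * 60.0
    starts = np.datetime64(start, "s") + _offsets(durations_s).astype("timedelta64[s]")
    return ImmersionSeries(individual_id, np.asarray(states, dtype=object), starts, durations_s)


def make_behavior(states, durations_min, start="2013-01-01T00:00:00", individual_id="t"):
    durations_s = np.asarray(durations_min, dtype=float) * 60.0
    return BehaviorSequence(
        individual_id, np.datetime64(start, "s"), np.asarray(states, dtype=object), _offsets(durations_s), durations_s
    )


def random_alternating_series(rng, n_events=200, individual_id="r"):
    """Random alternating wet/dry series mixing short, medium and very long events."""
    states = np.empty(n_events, dtype=object)
    states[::2], states[1::2] = ("wet", "dry") if rng.random() < 0.5 else ("dry", "wet")
    kind = rng.choice(3, size=n_events, p=[0.6, 0.3, 0.1])
    durations_min = np.where(
        kind == 0,
        rng.exponential(5.0, n_events),
        np.where(kind == 1, rng.exponential(120.0, n_events), rng.exponential(900.0, n_events)),
    ) + 0.05
    return make_immersion(states, durations_min, individual_id=individual_id)


@pytest.fixture
def small_sim_config():
    return SimulationConfig(n_successful=3, n_failed=2, seed=7)
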