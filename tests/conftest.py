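"""Shared fixtures: synthetic cohorts and hand-buildable patient states."""

from __future__ import annotations

import numpy as np
import pytest

from icusac.mdp import NORMAL_RANGES, CompositeAction, PatientState
from icusac.simulator import SimulatorConfig, simulate_cohort

#: mid-range value for every ranged vital, plus nominal weight/age
MID_STATE_KWARGS = {
    name: (lo + hi) / 2.0 for name, (lo, hi) in NORMAL_RANGES.items()
} | {"weight": 80.0, "age": 65.0}


def make_state(vent_status: int = 1, **overrides) -> PatientState:
    """A patient state with all vitals at range midpoints unless overridden."""
    kwargs = dict(MID_STATE_KWARGS)
    kwargs.update(overrides)
    return PatientState(**kwargs, vent_status=vent_status)


@pytest.fixture(scope="session")
def benchmark_cohort():
    """The 200-admission benchmark cohort at default study conditions."""
    return simulate_cohort(SimulatorConfig(n_admissions=200, seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 20-admission cohort for loop-level tests."""
    return simulate_cohort(SimulatorConfig(n_admissions=20, seed=7))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """100 admissions with noise-free clinician labels (expert-only cohort)."""
    return simulate_cohort(SimulatorConfig(n_admissions=100, seed=2, clinician_noise=0.0))


@pytest.fixture
def any_action() -> CompositeAction:
    return CompositeAction(vent=0, sedative_bin=1)


def finite_difference_grad(fn, params: dict, h: float = 1e-5) -> dict:
    """Central-difference gradient of a scalar function of a params dict."""
    grads = {}
    for key, arr in params.items():
        g = np.zeros_like(arr)
        flat = arr.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            f_plus = fn(params)
            flat[i] = orig - h
            f_minus = fn(params)
            flat[i] = orig
            gflat[i] = (f_plus - f_minus) / (2.0 * h)
        grads[key] = g
    return grads


def max_relative_grad_error(analytic: dict, numeric: dict) -> float:
    """max over parameters of |analytic - numeric| / (|analytic| + |numeric| + 1e-8)."""
    worst = 0.0
    for key in analytic:
        a, f = analytic[key], numeric[key]
        rel = np.abs(a - f) / (np.abs(a) + np.abs(f) + 1e-8)
        worst = max(worst, float(rel.max()))
    return worst
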