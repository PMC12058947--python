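import numpy as np
import pandas as pd
import pytest

import trajsplit as ts


@pytest.fixture
def geometry():
    """Canonical-frame layout: 100 px start at the origin, 140 px targets
    600 px to either side and 500 px above."""
    return ts.DisplayGeometry(
        start=ts.Rect(0.0, 0.0, 100.0, 100.0),
        target_left=ts.Rect(-600.0, 500.0, 140.0, 140.0),
        target_right=ts.Rect(600.0, 500.0, 140.0, 140.0),
        frame="canonical",
    ).validate()


@pytest.fixture
def screen_geometry():
    """The same layout expressed in screen coordinates (origin top-left, y down)."""
    return ts.DisplayGeometry(
        start=ts.Rect(640.0, 620.0, 100.0, 100.0),
        target_left=ts.Rect(40.0, 120.0, 140.0, 140.0),
        target_right=ts.Rect(1240.0, 120.0, 140.0, 140.0),
        frame="screen",
    ).validate()


def make_canonical(t, x, y, *, correct_side="right", flipped=False, condition=None,
                   participant="p1", trial="t1", response_error=False):
    return ts.CanonicalTrajectory(
        participant=participant,
        trial=trial,
        condition=condition or {"compatibility": "compatible"},
        correct_side=correct_side,
        response_error=response_error,
        t=np.asarray(t, float),
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        flipped=flipped,
    )


@pytest.fixture
def straight_trial():
    """Constant-velocity path from the start centre to the right target
    centre: leaves the start area between t=400 and t=500, enters the
    target between t=800 and t=900 (100 ms sampling)."""
    # Straight line (0,0) -> (600,500); start box |x|<=50 exited once x>50
    # (at 8.3% of the chord), target box entered once x>=530 (88.3%).
    tt = np.arange(0.0, 1001.0, 100.0)
    # dwell 5 samples at the origin, then move linearly along the chord;
    # first sample past the start box at t=500, first inside the target at t=900
    frac = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    x = 600.0 * frac
    y = 500.0 * frac
    return make_canonical(tt, x, y)


@pytest.fixture(scope="session")
def small_experiment():
    """Small synthetic experiment shared by unit/integration tests."""
    params = ts.GeneratorParams(n_participants=8, n_trials=50, seed=11)
    ds = ts.generate_dataset(params)
    proc = ts.process_trials(ds.trials, ds.geometry)
    merged = proc.table.merge(
        ds.truth, on=["participant", "trial", "compatibility", "correct_side"]
    )
    assert len(merged) == len(proc.table)
    return ds, proc, merged


@pytest.fixture(scope="session")
def default_experiment():
    """The default synthetic experiment (40 participants x 200
    trials/condition, seed 1) used by the acceptance suite."""
    params = ts.GeneratorParams()  # defaults, seed 1
    ds = ts.generate_dataset(params)
    proc = ts.process_trials(ds.trials, ds.geometry)
    merged = proc.table.merge(
        ds.truth, on=["participant", "trial", "compatibility", "correct_side"]
    )
    assert len(merged) == len(proc.table)
    return ds, proc, merged
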