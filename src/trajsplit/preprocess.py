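"""Movement truncation, time normalization, and trial-exclusion flags.

The analyzed movement is the part of each trial between leaving the start
area and first reaching the correct target area. Initiation time (IT) is
the time from stimulus onset until the cursor leaves the start area;
movement time (MT) runs from that point until target entry. Both anchors
are defined at the first *sample* outside/inside the region — no
sub-sample boundary interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import DisplayGeometry
from .io import CanonicalTrajectory

__all__ = [
    "Movement",
    "NormalizedTrajectory",
    "UnusableTrialError",
    "truncate",
    "time_normalize",
    "is_downward",
    "flag_outliers",
    "MEASURE_LABELS",
]

log = logging.getLogger(__name__)

#: Column -> short label used in outlier reasons and reports.
MEASURE_LABELS = {"it_ms": "IT", "mt_ms": "MT", "auc_px2": "AUC", "mad_px": "MAD"}


class UnusableTrialError(ValueError):
    """The trial never completes a start-to-target movement."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class Movement:
    """Truncated movement samples (canonical flipped frame) plus timing."""

    it_ms: float
    mt_ms: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class NormalizedTrajectory:
    """Fixed-length time-normalized path with its timing measures.

    ``points[0]`` is the start-exit sample and ``points[-1]`` the
    target-entry sample; intermediate points are linearly interpolated at
    equally spaced times.
    """

    points: np.ndarray  # (n, 2)
    it_ms: float
    mt_ms: float

    @property
    def n(self) -> int:
        return len(self.points)


def _first_exit_index(traj: CanonicalTrajectory, geometry: DisplayGeometry) -> int | None:
    g = geometry.oriented(traj.flipped)
    outside = ~np.asarray(g.start.contains(traj.x, traj.y), dtype=bool)
    if not outside.any():
        return None
    return int(np.argmax(outside))


def truncate(traj: CanonicalTrajectory, geometry: DisplayGeometry) -> Movement:
    """Cut a canonical trajectory down to the start-to-target movement.

    Returns the samples from the first sample outside the start area
    through the first subsequent sample inside the correct target area,
    with ``it_ms`` = exit-sample time and ``mt_ms`` = entry − exit time.
    Re-entries into the start area after the first exit are ignored: the
    anchor is always the *first* exit.

    Raises
    ------
    UnusableTrialError
        If the cursor never leaves the start area, never reaches the
        correct target afterwards, or exit and entry coincide.
    """
    g = geometry.oriented(traj.flipped)
    i_exit = _first_exit_index(traj, geometry)
    if i_exit is None:
        raise UnusableTrialError("never left the start area")
    inside_target = np.asarray(g.target_right.contains(traj.x, traj.y), dtype=bool)
    inside_target[:i_exit] = False
    if not inside_target.any():
        raise UnusableTrialError("never reached the correct target area")
    i_entry = int(np.argmax(inside_target))
    it = float(traj.t[i_exit])
    mt = float(traj.t[i_entry] - traj.t[i_exit])
    if mt <= 0:
        raise UnusableTrialError("target entry coincides with start exit")
    sl = slice(i_exit, i_entry + 1)
    return Movement(it_ms=it, mt_ms=mt, t=traj.t[sl].copy(), x=traj.x[sl].copy(), y=traj.y[sl].copy())


def time_normalize(movement: Movement, n: int = 101) -> NormalizedTrajectory:
    """Resample a movement to ``n`` points at equally spaced times.

    Coordinates are linearly interpolated between the bracketing raw
    samples; the endpoints are reproduced exactly. Applying the operation
    to an already-normalized movement with the same ``n`` is the identity
    up to floating point.
    """
    if movement.n_samples < 2:
        raise ValueError("time normalization needs at least 2 samples")
    if n < 2:
        raise ValueError("n must be >= 2")
    grid = np.linspace(movement.t[0], movement.t[-1], n)
    xs = np.interp(grid, movement.t, movement.x)
    ys = np.interp(grid, movement.t, movement.y)
    return NormalizedTrajectory(points=np.column_stack([xs, ys]), it_ms=movement.it_ms, mt_ms=movement.mt_ms)


def is_downward(traj: CanonicalTrajectory, geometry: DisplayGeometry) -> bool:
    """True iff any post-exit sample falls strictly below the start area.

    "Below" means y smaller than the start area's bottom edge in the
    canonical (y-up) frame; a sample exactly on the edge does not count.
    Trials that never leave the start area return False (they are flagged
    unusable elsewhere).
    """
    g = geometry.oriented(traj.flipped)
    i_exit = _first_exit_index(traj, geometry)
    if i_exit is None:
        return False
    return bool(np.any(traj.y[i_exit:] < g.start.bottom))


def flag_outliers(
    table: pd.DataFrame,
    k: float = 2.5,
    *,
    cell_cols: Sequence[str] = ("participant", "compatibility"),
    measure_cols: Iterable[str] = ("it_ms", "mt_ms", "auc_px2", "mad_px"),
) -> pd.DataFrame:
    """Flag trials deviating more than ``k`` sample SDs from their cell mean.

    A cell is the full crossing of participant and design factors
    (``cell_cols``). Means and SDs (n−1 denominator) are computed once per
    cell and measure — a single pass, no re-computation after removal — and
    a trial is an outlier as soon as *any* of the four measures deviates by
    more than ``k``·SD. Cells with fewer than 3 trials are skipped with a
    warning. Error/downward/unusable trials must be removed beforehand.

    Returns a DataFrame aligned with ``table.index`` holding boolean
    ``outlier`` and a ``;``-joined ``outlier_reasons`` string.
    """
    measure_cols = list(measure_cols)
    outlier = pd.Series(False, index=table.index)
    reasons = pd.Series("", index=table.index, dtype=object)
    for _, grp in table.groupby(list(cell_cols), sort=False, observed=True):
        if len(grp) < 3:
            log.warning(
                "cell %s has %d trial(s) (<3): outlier flagging skipped",
                dict(zip(cell_cols, grp.iloc[0][list(cell_cols)])),
                len(grp),
            )
            continue
        for col in measure_cols:
            v = grp[col].to_numpy(dtype=float)
            sd = v.std(ddof=1)
            if sd == 0:
                continue  # |dev| > 0 never holds
            dev = np.abs(v - v.mean()) > k * sd
            if dev.any():
                idx = grp.index[dev]
                outlier.loc[idx] = True
                label = MEASURE_LABELS.get(col, col)
                for i in idx:
                    cur = reasons.at[i]
                    reasons.at[i] = f"{cur};{label}" if cur else label
    return pd.DataFrame({"outlier": outlier, "outlier_reasons": reasons})
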