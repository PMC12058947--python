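"""Trajectory log I/O and mapping into the canonical analysis frame.

Long-format CSV schema (one row per cursor sample)::

    participant, trial, compatibility, correct_side, response_error,
    t_ms, x_px, y_px [, extra factor columns...]

Rows of one trial are contiguous and share ``(participant, trial)``;
timestamps are milliseconds since onset of the imperative stimulus.
Extra columns are carried through as additional condition factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import DisplayGeometry

__all__ = [
    "RawTrajectory",
    "CanonicalTrajectory",
    "RejectionRecord",
    "TrajectoryError",
    "load_trajectories",
    "write_trajectories",
    "canonicalize",
    "REQUIRED_COLUMNS",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "participant",
    "trial",
    "compatibility",
    "correct_side",
    "response_error",
    "t_ms",
    "x_px",
    "y_px",
]


class TrajectoryError(ValueError):
    """A trajectory violates a precondition of the requested operation."""


@dataclass
class RawTrajectory:
    """Cursor samples of one trial, in the coordinate frame of the log file."""

    participant: str
    trial: str
    condition: dict[str, str]
    correct_side: str  # "left" | "right"
    response_error: bool
    t: np.ndarray  # ms since imperative stimulus onset, strictly increasing
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.correct_side not in ("left", "right"):
            raise TrajectoryError(f"correct_side must be left/right, got {self.correct_side!r}")

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class CanonicalTrajectory(RawTrajectory):
    """Trajectory in the canonical frame: start-centre origin, y up, and
    (after mirroring left-target trials) the correct target on the right."""

    flipped: bool = False


@dataclass(frozen=True)
class RejectionRecord:
    """Machine-readable record of a trial rejected at load time."""

    participant: str
    trial: str
    reason: str


def load_trajectories(
    path: str | Path,
    geometry: DisplayGeometry | None = None,
    *,
    return_rejections: bool = False,
):
    """Read a long-format trajectory CSV into one :class:`RawTrajectory` per trial.

    Trials with non-monotone timestamps or fewer than three samples are
    rejected with a logged warning; pass ``return_rejections=True`` to
    also receive the list of :class:`RejectionRecord`. Coordinates are
    left in the file frame (``geometry`` is accepted for signature
    symmetry with the rest of the pipeline but not needed here).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file missing required columns: {missing}")
    extra_factors = [c for c in df.columns if c not in REQUIRED_COLUMNS]

    trials: list[RawTrajectory] = []
    rejections: list[RejectionRecord] = []
    for (pid, tid), grp in df.groupby(["participant", "trial"], sort=False):
        pid, tid = str(pid), str(tid)
        t = grp["t_ms"].to_numpy(dtype=float)
        if len(t) < 3:
            rejections.append(RejectionRecord(pid, tid, "fewer than 3 samples"))
            log.warning("rejecting trial %s/%s: fewer than 3 samples", pid, tid)
            continue
        if not np.all(np.diff(t) > 0):
            rejections.append(RejectionRecord(pid, tid, "non-monotone timestamps"))
            log.warning("rejecting trial %s/%s: non-monotone timestamps", pid, tid)
            continue
        first = grp.iloc[0]
        condition = {"compatibility": str(first["compatibility"])}
        for c in extra_factors:
            condition[c] = str(first[c])
        trials.append(
            RawTrajectory(
                participant=pid,
                trial=tid,
                condition=condition,
                correct_side=str(first["correct_side"]),
                response_error=bool(first["response_error"]),
                t=t,
                x=grp["x_px"].to_numpy(dtype=float),
                y=grp["y_px"].to_numpy(dtype=float),
            )
        )
    if return_rejections:
        return trials, rejections
    return trials


def write_trajectories(trials: Sequence[RawTrajectory], path: str | Path) -> None:
    """Write trajectories back to the long-format CSV (lossless round trip)."""
    extra = sorted({k for tr in trials for k in tr.condition} - {"compatibility"})
    frames = []
    for tr in trials:
        n = tr.n_samples
        data = {
            "participant": [tr.participant] * n,
            "trial": [tr.trial] * n,
            "compatibility": [tr.condition.get("compatibility", "")] * n,
            "correct_side": [tr.correct_side] * n,
            "response_error": [tr.response_error] * n,
            "t_ms": tr.t,
            "x_px": tr.x,
            "y_px": tr.y,
        }
        for c in extra:
            data[c] = [tr.condition.get(c, "")] * n
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=REQUIRED_COLUMNS + extra
    )
    # %.17g round-trips IEEE doubles exactly
    out.to_csv(path, index=False, float_format="%.17g")


def canonicalize(traj: RawTrajectory, geometry: DisplayGeometry) -> CanonicalTrajectory:
    """Translate into the canonical frame and mirror left-target trials.

    The origin moves to the start-area centre and y increases upward
    (screen-frame logs are y-flipped). Trials whose correct target is on
    the left are mirrored about x = 0, so the correct target ends up at
    positive x for every trial; the ``flipped`` flag records mirroring.

    Raises
    ------
    TrajectoryError
        If the first sample does not lie inside the start area.
    """
    sx, sy = geometry.start.x_center, geometry.start.y_center
    x = traj.x - sx
    if geometry.frame == "screen":
        y = sy - traj.y
    else:
        y = traj.y - sy
    g = geometry.canonical()
    if not bool(g.start.contains(x[0], y[0])):
        raise TrajectoryError(
            f"trial {traj.participant}/{traj.trial}: first sample outside start area"
        )
    flipped = traj.correct_side == "left"
    if flipped:
        x = -x
    return CanonicalTrajectory(
        participant=traj.participant,
        trial=traj.trial,
        condition=dict(traj.condition),
        correct_side=traj.correct_side,
        response_error=traj.response_error,
        t=traj.t.copy(),
        x=x,
        y=y,
        flipped=flipped,
    )
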