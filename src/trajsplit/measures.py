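"""Curvature measures on time-normalized trajectories.

Both measures are taken relative to the *ideal* path: the straight line
through the movement's first and last point. Signs follow the field's
convention for two-choice designs: deviations toward the opposite
(wrong) target count as positive, deviations away from it as negative.
In the canonical flipped frame (correct target to the right) "toward the
wrong target" is the left-hand side of the start→end direction.

* MAD — the signed maximum orthogonal deviation, together with the time
  step at which it occurs.
* AUC — the net signed area between the executed and the ideal path.
  Opposite-side lobes cancel and backtracking along the ideal-line
  direction contributes negatively; this is required for the measure to
  take the small negative means seen in nearly straight movement sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NormalizedTrajectory

__all__ = [
    "TrialMeasures",
    "signed_deviations",
    "compute_mad",
    "compute_auc",
    "compute_measures",
]


@dataclass(frozen=True)
class TrialMeasures:
    """Per-trial kinematic summary."""

    it_ms: float
    mt_ms: float
    auc_px2: float
    mad_px: float
    mad_index: int


def _line_frame(points: np.ndarray):
    """Arc (s) and orthogonal (d) coordinates relative to the ideal line.

    ``s`` is the projection of each point onto the unit start→end vector,
    ``d`` the signed orthogonal offset, positive to the left of that
    direction (i.e. toward the wrong target in the flipped frame).
    """
    start, end = points[0], points[-1]
    chord = end - start
    length = float(np.hypot(*chord))
    if length == 0:
        raise ValueError("coincident endpoints: ideal line undefined")
    u = chord / length
    normal = np.array([-u[1], u[0]])
    rel = points - start
    return rel @ u, rel @ normal, length


def signed_deviations(traj: NormalizedTrajectory) -> np.ndarray:
    """Signed orthogonal distance of every point from the ideal line."""
    _, d, _ = _line_frame(traj.points)
    return d


def compute_mad(traj: NormalizedTrajectory) -> tuple[float, int]:
    """Signed maximum orthogonal deviation and its time-step index.

    Ties in |deviation| resolve to the earliest step, which also makes
    the velocity-profile split deterministic.
    """
    d = signed_deviations(traj)
    idx = int(np.argmax(np.abs(d)))  # argmax returns the earliest maximum
    return float(d[idx]), idx


def compute_auc(traj: NormalizedTrajectory) -> float:
    """Net signed area between the executed and the ideal path (px²).

    Each point is projected onto the ideal line to obtain its arc
    coordinate s; the area is the trapezoid sum Σ (d_i+d_{i+1})/2·Δs_i,
    identical (up to floating-point accumulation) to the shoelace area of
    the closed polygon formed by the path plus the reversed ideal line.
    """
    s, d, _ = _line_frame(traj.points)
    return float(np.trapezoid(d, s))


def compute_measures(traj: NormalizedTrajectory) -> TrialMeasures:
    """IT, MT, signed AUC, and signed MAD for one normalized trajectory."""
    mad, idx = compute_mad(traj)
    return TrialMeasures(
        it_ms=traj.it_ms,
        mt_ms=traj.mt_ms,
        auc_px2=compute_auc(traj),
        mad_px=mad,
        mad_index=idx,
    )
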