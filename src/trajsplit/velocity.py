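"""Velocity profiles split at the point of maximum deviation.

Single-step and multi-step movements differ most clearly in their speed
around the moment of maximum orthogonal deviation (MAD): a smooth
movement is near peak speed there, while a change of mind decelerates
into the turn and re-accelerates out of it. Because the MAD occurs at a
different time in every trial, each trial's speed curve is cut at its
own MAD step and the two segments are re-normalized to a common 0–100%
axis before averaging.

Speeds are computed on the time-normalized path with physical time
restored from the movement time, giving px/ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .preprocess import NormalizedTrajectory

__all__ = [
    "VelocityProfile",
    "EndpointMADError",
    "instantaneous_speed",
    "split_and_renormalize",
    "average_profiles",
]

log = logging.getLogger(__name__)


class EndpointMADError(ValueError):
    """The MAD falls on the first or last step; the split is undefined."""


@dataclass
class VelocityProfile:
    """Pre- and post-MAD speed curves on normalized 0–100% segment time."""

    pre: np.ndarray  # (m,) px/ms
    post: np.ndarray  # (m,) px/ms
    group: str | None = None

    @property
    def m(self) -> int:
        return len(self.pre)


def instantaneous_speed(traj: NormalizedTrajectory) -> np.ndarray:
    """Speed between consecutive normalized points, in px/ms.

    With n points spanning mt_ms, each step lasts mt_ms/(n−1), so
    v_i = ‖p_{i+1} − p_i‖ / (mt_ms/(n−1)) for i = 0..n−2.
    """
    if traj.n < 2:
        raise ValueError("speed needs at least 2 points")
    if traj.mt_ms <= 0:
        raise ValueError("movement time must be positive")
    steps = np.diff(traj.points, axis=0)
    dt = traj.mt_ms / (traj.n - 1)
    return np.hypot(steps[:, 0], steps[:, 1]) / dt


def _resample(segment: np.ndarray, m: int) -> np.ndarray:
    if len(segment) == 1:
        return np.full(m, float(segment[0]))
    frac = np.linspace(0.0, 1.0, len(segment))
    return np.interp(np.linspace(0.0, 1.0, m), frac, segment)


def split_and_renormalize(v: np.ndarray, mad_index: int, m: int = 101) -> VelocityProfile:
    """Split a speed curve at the MAD step and renormalize each part.

    The pre segment covers steps before the MAD point, the post segment
    the steps from the MAD point to target entry; each is linearly
    resampled to ``m`` points over its own 0–100% time fraction so that
    profiles with MADs at different times align.

    Raises
    ------
    EndpointMADError
        If ``mad_index`` is 0 or the last step, leaving one side empty
        (e.g. perfectly straight paths). Such trials are excluded from
        profile averages only.
    """
    v = np.asarray(v, dtype=float)
    n_steps = len(v)
    if not 1 <= mad_index <= n_steps - 1:
        raise EndpointMADError(f"mad_index {mad_index} not interior to 1..{n_steps - 1}")
    return VelocityProfile(pre=_resample(v[:mad_index], m), post=_resample(v[mad_index:], m))


def average_profiles(
    profiles_by_group: Mapping[str, Sequence[VelocityProfile]],
) -> dict[str, tuple[VelocityProfile, int]]:
    """Pointwise mean pre/post curves per group, with the trial count.

    Empty groups are omitted with a warning. Averaging is linear, so
    pooled groups average to the count-weighted mean of group averages.
    """
    out: dict[str, tuple[VelocityProfile, int]] = {}
    for group, profiles in profiles_by_group.items():
        profiles = list(profiles)
        if not profiles:
            log.warning("group %r has no velocity profiles; omitted", group)
            continue
        pre = np.mean([p.pre for p in profiles], axis=0)
        post = np.mean([p.post for p in profiles], axis=0)
        out[group] = (VelocityProfile(pre=pre, post=post, group=group), len(profiles))
    return out
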