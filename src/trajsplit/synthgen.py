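"""Seeded generator of two-choice cursor datasets with known ground truth.

The generator emulates the statistical structure of response-effect
compatibility mouse-tracking experiments: a two-level compatibility
factor varied within participants, per-participant trial blocks, smooth
single-step movements, and a minority of multi-step movements that first
head toward the wrong target — more often under incompatible mappings —
with initiation times slower for incompatible trials.

Kinematics use minimum-jerk timing (smooth bell-shaped speed with the
closed form v(τ) ∝ 30·τ²(1−τ)²), single-step paths bow along a quadratic
Bézier whose control point carries a Gaussian lateral offset, and
multi-step trials consist of two minimum-jerk submovements joined by a
near-stationary dwell at the turn point. By default the single-step path
distribution is *identical* across conditions, so any spatial
compatibility effect enters exclusively through the multi-step trials;
set ``execution_bias_px`` to inject a genuine execution-level curvature
effect instead. All randomness flows through one seeded generator and
the seed is recorded in the output metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import DisplayGeometry, Rect, save_geometry
from .io import RawTrajectory, write_trajectories
from .stepclass import default_cutoff

__all__ = [
    "GeneratorParams",
    "SyntheticDataset",
    "default_geometry",
    "minimum_jerk_progress",
    "generate_single_step",
    "generate_multi_step",
    "generate_dataset",
    "write_dataset",
    "CONDITIONS",
]

log = logging.getLogger(__name__)

CONDITIONS = ("compatible", "incompatible")


def default_geometry() -> DisplayGeometry:
    """Screen-frame layout: 100 px start area at the bottom centre,
    140 px targets 600 px to either side and 500 px above."""
    return DisplayGeometry(
        start=Rect(640.0, 620.0, 100.0, 100.0),
        target_left=Rect(40.0, 120.0, 140.0, 140.0),
        target_right=Rect(1240.0, 120.0, 140.0, 140.0),
        frame="screen",
    ).validate()


@dataclass
class GeneratorParams:
    """Study conditions of the default synthetic experiment.

    The headline parameters — 40 participants × 200 trials/condition,
    multi-step probabilities 9.8% (compatible) vs. 17.5% (incompatible),
    and mean initiation-time dwell 639 vs. 693 ms — define the reference
    dataset; the remaining kinematic parameters are chosen to produce
    realistic 100 Hz cursor logs (see the methods note).
    """

    n_participants: int = 40
    n_trials: int = 200  # per condition per participant
    p_multistep: tuple[float, float] = (0.098, 0.175)  # (compatible, incompatible)
    it_mean_ms: tuple[float, float] = (639.0, 693.0)  # (compatible, incompatible)
    it_sd_ms: float = 110.0
    it_participant_sd_ms: float = 60.0
    mt_mean_ms: float = 440.0
    mt_sd_ms: float = 150.0
    sample_interval_ms: float = 10.0
    path_noise_sd: float = 2.0
    curvature_sd_px: float = 140.0
    execution_bias_px: float = 0.0  # extra mean curvature toward the wrong target, incompatible only
    wrong_excursion_range: tuple[float, float] = (0.13, 0.28)
    turn_dwell_ms: tuple[float, float] = (20.0, 80.0)
    start_jitter_px: float = 15.0
    target_jitter_frac: float = 0.25
    seed: int = 1

    def __post_init__(self) -> None:
        for p in self.p_multistep:
            if not 0.0 <= p <= 1.0:
                raise ValueError("multi-step probabilities must lie in [0, 1]")
        for sd in (self.it_sd_ms, self.it_participant_sd_ms, self.mt_sd_ms, self.path_noise_sd,
                   self.curvature_sd_px):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        lo, hi = self.wrong_excursion_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("wrong_excursion_range must satisfy 0 < lo <= hi <= 1")
        if self.sample_interval_ms <= 0:
            raise ValueError("sample_interval_ms must be positive")

    def per_condition(self, values, condition: str):
        return values[CONDITIONS.index(condition)]


@dataclass
class SyntheticDataset:
    """Generated trials plus geometry and the lossless ground-truth table."""

    trials: list[RawTrajectory]
    geometry: DisplayGeometry
    truth: pd.DataFrame  # participant, trial, compatibility, correct_side, multistep
    params: GeneratorParams


def minimum_jerk_progress(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk path fraction s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ on τ ∈ [0, 1]."""
    tau = np.asarray(tau, dtype=float)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Lognormal draw parametrized by its arithmetic mean and SD."""
    if sd == 0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _bezier(p: np.ndarray, p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    p = p[:, None]
    return (1 - p) ** 2 * p0 + 2 * p * (1 - p) * p1 + p**2 * p2


def _to_file_frame(x: np.ndarray, y: np.ndarray, geometry: DisplayGeometry):
    """Map canonical coordinates back into the geometry's file frame."""
    sx, sy = geometry.start.x_center, geometry.start.y_center
    if geometry.frame == "screen":
        return x + sx, sy - y
    return x + sx, y + sy


def _endpoints(params: GeneratorParams, g: DisplayGeometry, rng: np.random.Generator):
    """Start point in the start area and end point inside the correct
    (right, canonical-flipped) target, both jittered."""
    half = min(params.start_jitter_px, g.start.width / 2.0, g.start.height / 2.0)
    s = rng.uniform(-half, half, size=2)
    tgt = g.target_right
    jx = params.target_jitter_frac * tgt.width / 2.0
    jy = params.target_jitter_frac * tgt.height / 2.0
    e = np.array([tgt.x_center, tgt.y_center]) + rng.uniform([-jx, -jy], [jx, jy])
    return s, e


def _assemble(
    params: GeneratorParams,
    geometry: DisplayGeometry,
    condition: str,
    correct_side: str,
    phases: list[tuple[float, "callable"]],
    rng: np.random.Generator,
    trail_ms: float = 30.0,
) -> RawTrajectory:
    """Sample the piecewise path at the logging rate, add noise, unflip,
    and convert to the geometry's file frame.

    ``phases`` is a list of (duration_ms, pos(t_local: (k,) array) ->
    (k, 2) array) in canonical flipped coordinates; samples after the
    last phase hold its final position for ``trail_ms``.
    """
    dt = params.sample_interval_ms
    total = sum(d for d, _ in phases) + trail_ms
    t = np.arange(0.0, total + dt / 2, dt)
    pos = np.empty((len(t), 2))
    bounds = np.cumsum([0.0] + [d for d, _ in phases])
    for (d, fn), lo, hi in zip(phases, bounds[:-1], bounds[1:]):
        mask = (t >= lo) & (t < hi)
        if mask.any():
            pos[mask] = fn(t[mask] - lo)
    tail = t >= bounds[-1]
    if tail.any():
        pos[tail] = phases[-1][1](np.array([phases[-1][0]]))[0]
    pos = pos + rng.normal(0.0, params.path_noise_sd, size=pos.shape)
    x, y = pos[:, 0], pos[:, 1]
    if correct_side == "left":
        x = -x
    fx, fy = _to_file_frame(x, y, geometry)
    return RawTrajectory(
        participant="",
        trial="",
        condition={"compatibility": condition},
        correct_side=correct_side,
        response_error=False,
        t=t,
        x=fx,
        y=fy,
    )


def generate_single_step(
    params: GeneratorParams,
    condition: str,
    rng: np.random.Generator,
    *,
    geometry: DisplayGeometry | None = None,
    correct_side: str = "right",
    it_offset_ms: float = 0.0,
) -> RawTrajectory:
    """One smooth movement from the start area into the correct target.

    The cursor dwells at the start point for the initiation-time draw,
    then follows a gently curved quadratic Bézier with minimum-jerk
    timing; Gaussian positional noise is added to every sample. The path
    distribution is identical across conditions unless
    ``execution_bias_px`` is nonzero (applied in the incompatible
    condition, toward the wrong target).
    """
    geometry = geometry or default_geometry()
    g = geometry.canonical()
    s, e = _endpoints(params, g, rng)
    it = _lognormal(rng, params.per_condition(params.it_mean_ms, condition) + it_offset_ms,
                    params.it_sd_ms)
    mt = max(_lognormal(rng, params.mt_mean_ms, params.mt_sd_ms), 8 * params.sample_interval_ms)
    bias = params.execution_bias_px if condition == "incompatible" else 0.0
    c = rng.normal(bias, params.curvature_sd_px)
    chord = e - s
    normal = np.array([-chord[1], chord[0]]) / np.hypot(*chord)  # left of travel = wrong side
    ctrl = (s + e) / 2.0 + c * normal

    phases = [
        (it, lambda tl, s=s: np.tile(s, (len(tl), 1))),
        (mt, lambda tl, s=s, e=e, ctrl=ctrl, mt=mt: _bezier(
            minimum_jerk_progress(tl / mt), s, ctrl, e)),
    ]
    return _assemble(params, geometry, condition, correct_side, phases, rng)


def generate_multi_step(
    params: GeneratorParams,
    condition: str,
    rng: np.random.Generator,
    *,
    geometry: DisplayGeometry | None = None,
    correct_side: str = "right",
    it_offset_ms: float = 0.0,
) -> RawTrajectory:
    """One change-of-mind movement: wrong-ward submovement, dwell, correction.

    The first minimum-jerk submovement heads from the start point toward
    the wrong-target centre, covering a Uniform(wrong_excursion_range)
    fraction of the distance and decelerating to a near-stop; after a
    short dwell a second minimum-jerk submovement reaches the correct
    target, so the trial still ends as a correct response.
    """
    geometry = geometry or default_geometry()
    g = geometry.canonical()
    s, e = _endpoints(params, g, rng)
    it = _lognormal(rng, params.per_condition(params.it_mean_ms, condition) + it_offset_ms,
                    params.it_sd_ms)
    mt = max(_lognormal(rng, params.mt_mean_ms, params.mt_sd_ms), 8 * params.sample_interval_ms)
    u = rng.uniform(*params.wrong_excursion_range)
    wrong = np.array([g.target_left.x_center, g.target_left.y_center])
    turn = s + u * (wrong - s)
    dwell = rng.uniform(*params.turn_dwell_ms)
    # Submovement durations do not scale linearly with amplitude: the short
    # wrong-ward movement takes a sizable fraction of a full movement's time,
    # and the correction is executed briskly.
    t1 = max(0.35 * mt, 8 * params.sample_interval_ms)
    t2 = max(0.45 * mt, 8 * params.sample_interval_ms)

    def seg(a, b, dur):
        return lambda tl, a=a, b=b, dur=dur: a + minimum_jerk_progress(tl / dur)[:, None] * (b - a)

    phases = [
        (it, lambda tl, s=s: np.tile(s, (len(tl), 1))),
        (t1, seg(s, turn, t1)),
        (dwell, lambda tl, turn=turn: np.tile(turn, (len(tl), 1))),
        (t2, seg(turn, e, t2)),
    ]
    return _assemble(params, geometry, condition, correct_side, phases, rng)


def generate_dataset(
    params: GeneratorParams | None = None,
    geometry: DisplayGeometry | None = None,
) -> SyntheticDataset:
    """Full synthetic experiment with per-trial ground truth.

    Per participant and condition, a Bernoulli draw with the
    condition-specific multi-step probability selects the trial type;
    initiation-time dwells are lognormal around the condition mean plus a
    participant-level intercept. Trial order interleaves the two
    conditions randomly within each participant block.
    """
    params = params or GeneratorParams()
    geometry = geometry or default_geometry()
    f0 = default_cutoff(geometry).fraction
    if params.wrong_excursion_range[0] <= f0:
        raise ValueError(
            f"wrong_excursion_range floor {params.wrong_excursion_range[0]} must exceed "
            f"the default cutoff fraction {f0:.4f} for multi-step trials to be classifiable"
        )
    rng = np.random.default_rng(params.seed)
    trials: list[RawTrajectory] = []
    truth_rows = []
    for p in range(params.n_participants):
        pid = f"p{p + 1:03d}"
        it_offset = rng.normal(0.0, params.it_participant_sd_ms)
        order = np.repeat([0, 1], params.n_trials)
        rng.shuffle(order)
        for k, ci in enumerate(order):
            condition = CONDITIONS[ci]
            tid = f"t{k + 1:04d}"
            side = "left" if rng.random() < 0.5 else "right"
            multistep = rng.random() < params.per_condition(params.p_multistep, condition)
            gen = generate_multi_step if multistep else generate_single_step
            tr = gen(
                params,
                condition,
                rng,
                geometry=geometry,
                correct_side=side,
                it_offset_ms=it_offset,
            )
            tr.participant = pid
            tr.trial = tid
            trials.append(tr)
            truth_rows.append(
                dict(participant=pid, trial=tid, compatibility=condition,
                     correct_side=side, multistep=multistep)
            )
    return SyntheticDataset(
        trials=trials, geometry=geometry, truth=pd.DataFrame(truth_rows), params=params
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write data.csv, geometry.yaml, truth.csv and params.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": outdir / "data.csv",
        "geometry": outdir / "geometry.yaml",
        "truth": outdir / "truth.csv",
        "params": outdir / "params.json",
    }
    write_trajectories(ds.trials, paths["data"])
    save_geometry(ds.geometry, paths["geometry"])
    ds.truth.to_csv(paths["truth"], index=False)
    paths["params"].write_text(json.dumps(asdict(ds.params), indent=2) + "\n")
    return paths
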