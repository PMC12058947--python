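"""Vertical-cutoff classification of single-step vs. multi-step movements.

A multi-step movement is one that first heads toward the wrong target —
an initial decision error corrected mid-flight. The classifier draws a
vertical line at a fraction ``f`` of the horizontal distance from the
start-area centre to the wrong-target centre (canonical flipped frame,
so the wrong target sits at negative x) and flags every movement whose
truncated raw samples travel strictly beyond it. The default cutoff
touches the start area on its left edge.

Relaxing the cutoff from its default toward the wrong-target centre and
recomputing the paired compatibility effect at each step traces how much
of an aggregate trajectory effect is carried by multi-step trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DisplayGeometry

__all__ = [
    "CutoffSpec",
    "default_cutoff",
    "cutoff_at",
    "is_multistep",
    "classify_dataset",
    "percent_classified",
    "cutoff_sweep",
    "SweepResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutoffSpec:
    """Cutoff as a fraction of the start→wrong-target horizontal distance.

    ``fraction`` = 0 places the line at the start-area centre, 1 at the
    wrong-target centre. ``x_cut`` is the derived abscissa (px, canonical
    flipped frame, hence ≤ 0).
    """

    fraction: float
    x_cut: float


def _wrong_target_distance(geometry: DisplayGeometry) -> float:
    """|x| of the wrong-target centre in the canonical flipped frame."""
    return abs(geometry.canonical().target_left.x_center)


def default_cutoff(geometry: DisplayGeometry) -> CutoffSpec:
    """Cutoff line touching the start area on the left."""
    g = geometry.canonical()
    half_width = g.start.width / 2.0
    dist = _wrong_target_distance(geometry)
    fraction = half_width / dist if dist > 0 else 0.0
    return CutoffSpec(fraction=fraction, x_cut=-half_width)


def cutoff_at(geometry: DisplayGeometry, fraction: float) -> CutoffSpec:
    """Cutoff at an arbitrary fraction of the wrong-target distance."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("cutoff fraction must lie in [0, 1]")
    dist = _wrong_target_distance(geometry)
    return CutoffSpec(fraction=fraction, x_cut=-fraction * dist)


def is_multistep(x: np.ndarray, cutoff: CutoffSpec) -> bool:
    """True iff any truncated raw sample lies strictly beyond the cutoff.

    Evaluated on the truncated raw samples (not the resampled path) so
    brief excursions between resampling knots are not missed; a sample
    exactly on the line does not count.
    """
    return bool(np.any(np.asarray(x) < cutoff.x_cut))


def classify_dataset(
    table: pd.DataFrame,
    cutoff: CutoffSpec,
    *,
    min_x_col: str = "min_x_px",
) -> pd.Series:
    """Multi-step flag for every trial row from its minimum excursion.

    ``table`` must carry, per trial, the minimum x over the truncated raw
    samples; error/downward/outlier trials should already be filtered by
    the caller. Flags are returned (never deleted rows), so with- and
    without-cutoff analyses run from one table.
    """
    return (table[min_x_col] < cutoff.x_cut).rename("multistep")


def percent_classified(
    table: pd.DataFrame,
    multistep: pd.Series,
    *,
    condition_col: str = "compatibility",
) -> pd.DataFrame:
    """%CC per participant × condition: share of trials flagged multi-step.

    Participants lacking trials in a condition get NaN there and are
    reported with a warning; paired comparison across conditions is the
    stats module's job.
    """
    df = table.assign(multistep=multistep.to_numpy())
    pcc = (
        df.groupby(["participant", condition_col], sort=False, observed=True)["multistep"]
        .mean()
        .mul(100.0)
        .unstack(condition_col)
    )
    incomplete = pcc.index[pcc.isna().any(axis=1)]
    for pid in incomplete:
        log.warning("participant %s lacks trials in some condition; excluded from %%CC comparison", pid)
    return pcc


def _sweep_grid(geometry: DisplayGeometry, step: float = 0.025) -> np.ndarray:
    f0 = default_cutoff(geometry).fraction
    grid = np.arange(f0, 1.0 + 1e-12, step)
    if grid[-1] < 1.0 - 1e-12:
        grid = np.append(grid, 1.0)
    return grid


@dataclass
class SweepResult:
    """Effect-size trace over cutoff fractions."""

    frame: pd.DataFrame  # columns: fraction, x_cut, n_participants, n_multistep, t, p, dz, ...
    default_fraction: float
    measure: str


def cutoff_sweep(
    table: pd.DataFrame,
    geometry: DisplayGeometry,
    f_grid: np.ndarray | None = None,
    *,
    measure: str = "auc_px2",
    condition_col: str = "compatibility",
    min_x_col: str = "min_x_px",
) -> SweepResult:
    """Paired compatibility effect in ``measure`` as a function of the cutoff.

    For each fraction f the multi-step trials at that cutoff are excluded,
    per-participant condition means are recomputed, and a paired t-test
    with Cohen's dz is run. Participants lacking trials in a cell at some
    f are dropped at that f (their count is recorded); fewer than two
    complete participants yields NA at that f. The default grid runs from
    the default cutoff fraction to 1 in steps of 0.025.
    """
    from .stats import paired_t  # local import to avoid a module cycle

    if f_grid is None:
        f_grid = _sweep_grid(geometry)
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(np.diff(f_grid) <= 0):
        raise ValueError("cutoff sweep grid must be strictly increasing")

    rows = []
    for f in f_grid:
        cut = cutoff_at(geometry, float(f))
        retained = table[~(table[min_x_col] < cut.x_cut)]
        means = (
            retained.groupby(["participant", condition_col], sort=False, observed=True)[measure]
            .mean()
            .unstack(condition_col)
        )
        pcc = percent_classified(table, classify_dataset(table, cut, min_x_col=min_x_col),
                                 condition_col=condition_col)
        complete = means.dropna()
        row = {
            "fraction": float(f),
            "x_cut": cut.x_cut,
            "n_participants": len(complete),
            "n_dropped_participants": len(means) - len(complete),
            "n_multistep": int((table[min_x_col] < cut.x_cut).sum()),
            "pcc_compatible": float(pcc.get("compatible", pd.Series(dtype=float)).mean()),
            "pcc_incompatible": float(pcc.get("incompatible", pd.Series(dtype=float)).mean()),
        }
        if len(complete) < 2:
            row.update({"t": np.nan, "p": np.nan, "dz": np.nan})
        else:
            res = paired_t(
                complete["compatible"].to_numpy(),
                complete["incompatible"].to_numpy(),
                measure=measure,
            )
            row.update({"t": res.t, "p": res.p, "dz": res.dz})
        rows.append(row)
    return SweepResult(
        frame=pd.DataFrame(rows),
        default_fraction=default_cutoff(geometry).fraction,
        measure=measure,
    )
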