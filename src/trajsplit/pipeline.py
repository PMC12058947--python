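"""Dataset-level orchestration: raw logs -> measures table -> report.

The per-trial operations live in :mod:`trajsplit.preprocess`,
:mod:`trajsplit.measures` and :mod:`trajsplit.velocity`; this module
loops them over a dataset, assembles the per-trial measures table with
all exclusion flags, and drives the full analysis (classification,
report, cutoff sweep, velocity profiles, figures).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .geometry import DisplayGeometry, load_geometry
from .io import RawTrajectory, TrajectoryError, canonicalize, load_trajectories
from .measures import compute_measures
from .preprocess import (
    UnusableTrialError,
    flag_outliers,
    is_downward,
    time_normalize,
    truncate,
)
from .stats import ExperimentReport, build_report
from .stepclass import CutoffSpec, classify_dataset, cutoff_sweep, default_cutoff
from .velocity import EndpointMADError, VelocityProfile, average_profiles, instantaneous_speed, split_and_renormalize

__all__ = ["ProcessedDataset", "process_trials", "velocity_profiles", "RunConfig", "run"]

log = logging.getLogger(__name__)


@dataclass
class ProcessedDataset:
    """Per-trial measures table plus the aligned normalized paths/speeds.

    ``table`` has one row per input trial with identifiers, condition
    factors, all exclusion flags, the four measures, the MAD step index
    and the minimum truncated-sample excursion ``min_x_px``. Rows of
    unusable trials carry NaN measures. ``points`` (n_trials, N, 2) and
    ``speeds`` (n_trials, N−1) are indexed like ``table`` and NaN-filled
    for unusable trials.
    """

    table: pd.DataFrame
    points: np.ndarray
    speeds: np.ndarray
    geometry: DisplayGeometry
    n: int
    condition_factors: list[str]

    @property
    def retained(self) -> pd.Series:
        t = self.table
        return ~t["unusable"] & ~t["response_error"] & ~t["downward"] & ~t["outlier"]


def process_trials(
    trials: Sequence[RawTrajectory],
    geometry: DisplayGeometry,
    *,
    n: int = 101,
    k_outlier: float = 2.5,
) -> ProcessedDataset:
    """Run canonicalization, truncation, normalization and measures.

    Response-error, downward and unusable trials are excluded before the
    outlier pass; the outlier statistics are computed once per
    participant × condition cell, before any multi-step classification.
    """
    rows = []
    points = np.full((len(trials), n, 2), np.nan)
    speeds = np.full((len(trials), n - 1), np.nan)
    factors: list[str] = []
    for tr in trials:
        for key in tr.condition:
            if key not in factors:
                factors.append(key)

    for i, tr in enumerate(trials):
        row = {
            "participant": tr.participant,
            "trial": tr.trial,
            "correct_side": tr.correct_side,
            "response_error": bool(tr.response_error),
            "unusable": False,
            "unusable_reason": "",
            "downward": False,
            "it_ms": np.nan,
            "mt_ms": np.nan,
            "auc_px2": np.nan,
            "mad_px": np.nan,
            "mad_index": -1,
            "min_x_px": np.nan,
        }
        for key in factors:
            row[key] = tr.condition.get(key, "")
        try:
            ct = canonicalize(tr, geometry)
            row["downward"] = is_downward(ct, geometry)
            mv = truncate(ct, geometry)
            nt = time_normalize(mv, n)
            m = compute_measures(nt)
            row.update(
                it_ms=m.it_ms,
                mt_ms=m.mt_ms,
                auc_px2=m.auc_px2,
                mad_px=m.mad_px,
                mad_index=m.mad_index,
                min_x_px=float(mv.x.min()),
            )
            points[i] = nt.points
            speeds[i] = instantaneous_speed(nt)
        except (TrajectoryError, UnusableTrialError, ValueError) as exc:
            reason = getattr(exc, "reason", str(exc))
            row["unusable"] = True
            row["unusable_reason"] = reason
            log.warning("trial %s/%s unusable: %s", tr.participant, tr.trial, reason)
        rows.append(row)

    table = pd.DataFrame(rows)
    table["outlier"] = False
    table["outlier_reasons"] = ""
    usable = ~table["unusable"] & ~table["response_error"] & ~table["downward"]
    if usable.any():
        flags = flag_outliers(
            table[usable], k=k_outlier, cell_cols=["participant", *factors]
        )
        table.loc[usable, "outlier"] = flags["outlier"]
        table.loc[usable, "outlier_reasons"] = flags["outlier_reasons"]
    return ProcessedDataset(
        table=table,
        points=points,
        speeds=speeds,
        geometry=geometry,
        n=n,
        condition_factors=factors,
    )


def velocity_profiles(
    ds: ProcessedDataset,
    groups: pd.Series,
    *,
    m: int = 101,
    mask: pd.Series | None = None,
) -> tuple[dict[str, tuple[VelocityProfile, int]], int]:
    """Group-averaged pre/post-MAD speed profiles.

    ``groups`` labels each row of ``ds.table`` (NaN/None rows are
    ignored); ``mask`` optionally restricts to a subset (default: all
    usable trials). Trials whose MAD index falls on an endpoint are
    skipped and counted in the returned second element.
    """
    if mask is None:
        mask = ~ds.table["unusable"]
    by_group: dict[str, list[VelocityProfile]] = {}
    skipped = 0
    idx = ds.table.index.to_numpy()
    pos_of = {label: k for k, label in enumerate(idx)}
    for label in idx[mask.to_numpy()]:
        g = groups.get(label)
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        k = pos_of[label]
        mad_index = int(ds.table.at[label, "mad_index"])
        try:
            prof = split_and_renormalize(ds.speeds[k], mad_index, m)
        except EndpointMADError:
            skipped += 1
            continue
        by_group.setdefault(str(g), []).append(prof)
    return average_profiles(by_group), skipped


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    data: str
    geometry: str
    out_dir: str = "trajsplit_out"
    cutoff_fraction: float | None = None  # None = default (start-area left edge)
    sweep_step: float = 0.025
    n: int = 101
    m: int = 101
    k_outlier: float = 2.5
    log_level: str = "INFO"
    make_figures: bool = True


def _provenance(config: RunConfig, ds: ProcessedDataset, report: ExperimentReport) -> dict:
    cfg = asdict(config)
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    counts = report.audit.sum().to_dict()
    return {
        "trajsplit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg,
        "config_hash": cfg_hash,
        "n_trials": int(len(ds.table)),
        "exclusion_totals": {k: int(v) for k, v in counts.items()},
    }


def run(config: RunConfig) -> Path:
    """Execute preprocess → measures → classify → velocity → stats.

    Writes the measures table (with flags), the with/without-cutoff
    report (CSV + markdown), the cutoff-sweep and velocity-profile CSVs,
    figures, and a provenance JSON into ``config.out_dir``. Every
    figure's underlying numbers are also emitted as CSV.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geometry = load_geometry(config.geometry)
    trials, rejections = load_trajectories(config.data, geometry, return_rejections=True)
    if rejections:
        pd.DataFrame([asdict(r) for r in rejections]).to_csv(out / "rejections.csv", index=False)

    ds = process_trials(trials, geometry, n=config.n, k_outlier=config.k_outlier)
    cutoff = (
        default_cutoff(geometry)
        if config.cutoff_fraction is None
        else _cutoff(geometry, config.cutoff_fraction)
    )
    table = ds.table.copy()
    table["multistep"] = classify_dataset(table, cutoff).to_numpy()
    table.to_csv(out / "measures.csv", index=False)

    extra = [f for f in ds.condition_factors if f != "compatibility"]
    report = build_report(ds.table, geometry, cutoff, extra_factors=extra)
    report.to_frame().to_csv(out / "report.csv", index=False)
    (out / "report.md").write_text(report.to_markdown() + "\n")
    report.audit.to_csv(out / "audit.csv")

    retained = ds.table[ds.retained]
    sweep = cutoff_sweep(retained, geometry)
    sweep.frame.to_csv(out / "sweep.csv", index=False)

    cls_labels = pd.Series(
        np.where(table["multistep"], "excluded", "retained"), index=table.index
    )
    profiles, skipped = velocity_profiles(ds, cls_labels, m=config.m, mask=ds.retained)
    prof_rows = []
    for group, (prof, count) in profiles.items():
        for segment, curve in (("pre", prof.pre), ("post", prof.post)):
            for pct, v in zip(np.linspace(0, 100, len(curve)), curve):
                prof_rows.append(
                    dict(group=group, segment=segment, percent=pct, mean_speed_px_ms=v, n=count)
                )
    pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)

    mean_rows = _mean_trajectories(ds, table)
    mean_rows.to_csv(out / "mean_trajectories.csv", index=False)

    if config.make_figures:
        from . import plotting

        plotting.plot_mean_trajectories(ds, table).savefig(out / "mean_trajectories.png", dpi=150)
        plotting.plot_sweep(sweep).savefig(out / "sweep.png", dpi=150)
        plotting.plot_velocity_profiles(profiles).savefig(out / "velocity_profiles.png", dpi=150)

    prov = _provenance(config, ds, report)
    prov["n_profile_skipped_endpoint_mad"] = skipped
    (out / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")
    return out


def _cutoff(geometry: DisplayGeometry, fraction: float) -> CutoffSpec:
    from .stepclass import cutoff_at

    return cutoff_at(geometry, fraction)


def _mean_trajectories(ds: ProcessedDataset, table: pd.DataFrame) -> pd.DataFrame:
    """Pointwise average paths by condition, with and without multi-step
    trials: participant averages first, then the grand mean across
    participants."""
    rows = []
    mask_all = ds.retained
    for stage, mask in (
        ("all", mask_all),
        ("single_step", mask_all & ~table["multistep"]),
    ):
        sub = table[mask]
        for cond, grp in sub.groupby("compatibility", sort=False, observed=True):
            per_part = []
            for _, pgrp in grp.groupby("participant", sort=False, observed=True):
                pts = ds.points[pgrp.index.to_numpy()]
                per_part.append(np.nanmean(pts, axis=0))
            grand = np.mean(per_part, axis=0)
            for step, (x, y) in enumerate(grand):
                rows.append(
                    dict(stage=stage, compatibility=cond, step=step, x_px=x, y_px=y,
                         n_participants=len(per_part))
                )
    return pd.DataFrame(rows)
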