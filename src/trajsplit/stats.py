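"""Paired within-subject inference for the two-level compatibility factor.

Everything reduces to the classical paired t-test on per-participant
condition means, reported with the within-subject standardized effect
size Cohen's dz = mean(diff)/SD(diff) (sample SD). Differences are taken
as incompatible − compatible, so positive t/dz means the incompatible
condition is larger. For multifactorial designs the main effect of
compatibility is obtained by collapsing over all other within-subject
factors first; for a two-level factor the repeated-measures F equals t²,
which is reported alongside for comparison with factorial write-ups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import DisplayGeometry
from .stepclass import CutoffSpec, classify_dataset, default_cutoff, percent_classified

__all__ = [
    "PairedResult",
    "ExperimentReport",
    "paired_t",
    "condition_means",
    "main_effect",
    "build_report",
]

log = logging.getLogger(__name__)

MEASURES = (("auc_px2", "AUC"), ("mad_px", "MAD"), ("it_ms", "IT"), ("mt_ms", "MT"))


@dataclass
class PairedResult:
    """Paired t-test summary for one measure."""

    measure: str
    mean_compatible: float
    mean_incompatible: float
    t: float
    df: int
    p: float
    dz: float
    n_participants: int
    f: float | None = None  # t² — RM-ANOVA main-effect F for two levels
    note: str = ""

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.t)


def paired_t(
    compatible: np.ndarray,
    incompatible: np.ndarray,
    *,
    measure: str = "",
) -> PairedResult:
    """Classical paired t-test with Cohen's dz on per-participant means.

    ``t = dz·√n`` with ``dz = mean(d)/SD(d)``, ``d = incompatible −
    compatible`` and the sample SD (n−1). The p-value is two-sided.
    Zero-variance differences make t undefined and are reported as NA
    with a reason.
    """
    compatible = np.asarray(compatible, dtype=float)
    incompatible = np.asarray(incompatible, dtype=float)
    if compatible.shape != incompatible.shape or compatible.ndim != 1:
        raise ValueError("paired_t expects two equal-length 1-d arrays")
    n = len(compatible)
    if n < 2:
        raise ValueError("paired_t needs at least 2 participants")
    diff = incompatible - compatible
    sd = float(diff.std(ddof=1))
    base = dict(
        measure=measure,
        mean_compatible=float(compatible.mean()),
        mean_incompatible=float(incompatible.mean()),
        df=n - 1,
        n_participants=n,
    )
    if sd == 0:
        return PairedResult(
            t=np.nan, p=np.nan, dz=np.nan, note="zero-variance differences", **base
        )
    dz = float(diff.mean() / sd)
    t = dz * np.sqrt(n)
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedResult(t=float(t), p=p, dz=dz, f=float(t) ** 2, **base)


def condition_means(
    table: pd.DataFrame,
    measure: str,
    *,
    condition_col: str = "compatibility",
    extra_factors: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-participant condition means, collapsed over extra factors.

    With extra within-subject factors the collapse first averages within
    each participant × condition × factor cell and then averages the cell
    means (the balanced-design main-effect collapse). If cell sizes are
    unbalanced, the collapse falls back to the trial-weighted mean with a
    warning. Returns a wide frame indexed by participant with one column
    per condition level; participants missing a level carry NaN.
    """
    extra = [f for f in extra_factors if f in table.columns]
    keys = ["participant", condition_col]
    if extra:
        cells = table.groupby(keys + extra, sort=False, observed=True)[measure].agg(["mean", "size"])
        balanced = cells["size"].groupby(level=keys, sort=False, observed=True).nunique().le(1).all()
        if balanced:
            means = cells["mean"].groupby(level=keys, sort=False, observed=True).mean()
        else:
            log.warning("unbalanced cells across %s; using trial-weighted collapse", extra)
            means = table.groupby(keys, sort=False, observed=True)[measure].mean()
    else:
        means = table.groupby(keys, sort=False, observed=True)[measure].mean()
    return means.unstack(condition_col)


def main_effect(
    table: pd.DataFrame,
    measure: str,
    *,
    condition_col: str = "compatibility",
    extra_factors: Sequence[str] = (),
    label: str | None = None,
) -> PairedResult:
    """Main effect of compatibility as a paired t on collapsed means.

    Participants lacking one condition level are dropped (with a warning).
    """
    wide = condition_means(
        table, measure, condition_col=condition_col, extra_factors=extra_factors
    )
    for level in ("compatible", "incompatible"):
        if level not in wide.columns:
            raise ValueError(f"condition level {level!r} absent from data")
    complete = wide.dropna(subset=["compatible", "incompatible"])
    if len(complete) < len(wide):
        log.warning(
            "%d participant(s) lack trials in one condition for %s; dropped",
            len(wide) - len(complete),
            measure,
        )
    if len(complete) < 2:
        raise ValueError(f"fewer than 2 participants with complete cells for {measure}")
    return paired_t(
        complete["compatible"].to_numpy(),
        complete["incompatible"].to_numpy(),
        measure=label or measure,
    )


@dataclass
class ExperimentReport:
    """With/without-cutoff paired results for all measures, plus audit."""

    without_cutoff: dict[str, PairedResult]
    with_cutoff: dict[str, PairedResult]
    pcc: PairedResult | None
    cutoff: CutoffSpec
    audit: pd.DataFrame  # per-participant exclusion counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage, results in (("without_cutoff", self.without_cutoff), ("with_cutoff", self.with_cutoff)):
            for name, r in results.items():
                rows.append(
                    dict(
                        measure=name,
                        stage=stage,
                        mean_compatible=r.mean_compatible,
                        mean_incompatible=r.mean_incompatible,
                        t=r.t,
                        df=r.df,
                        p=r.p,
                        dz=r.dz,
                        F=r.f,
                        n_participants=r.n_participants,
                        note=r.note,
                    )
                )
        if self.pcc is not None:
            r = self.pcc
            rows.append(
                dict(
                    measure="%CC",
                    stage="classification",
                    mean_compatible=r.mean_compatible,
                    mean_incompatible=r.mean_incompatible,
                    t=r.t,
                    df=r.df,
                    p=r.p,
                    dz=r.dz,
                    F=r.f,
                    n_participants=r.n_participants,
                    note=r.note,
                )
            )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        df = self.to_frame()
        cols = ["measure", "stage", "mean_compatible", "mean_incompatible", "t", "df", "p", "dz"]
        lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
        for _, row in df[cols].iterrows():
            cells = []
            for c in cols:
                v = row[c]
                cells.append(f"{v:.3g}" if isinstance(v, (int, float, np.floating)) else str(v))
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)


def build_report(
    table: pd.DataFrame,
    geometry: DisplayGeometry,
    cutoff: CutoffSpec | None = None,
    *,
    extra_factors: Sequence[str] = (),
) -> ExperimentReport:
    """Analyze all four measures twice: all retained trials vs. single-step only.

    ``table`` is the per-trial measures table from the pipeline with the
    flag columns (``response_error``, ``downward``, ``outlier``,
    ``unusable``) and the minimum truncated-sample excursion
    ``min_x_px``. Multi-step trials are flagged (never deleted) at the
    given cutoff (default: the line touching the start area's left edge),
    and the %CC comparison reuses the same paired machinery.
    """
    if len(table) == 0:
        raise ValueError("empty dataset: nothing to report")
    cutoff = cutoff or default_cutoff(geometry)
    retained = table[
        ~table["response_error"]
        & ~table["downward"]
        & ~table["outlier"]
        & ~table["unusable"]
    ]
    if len(retained) == 0:
        raise ValueError("no trials survive error/downward/outlier exclusion")
    multistep = classify_dataset(retained, cutoff)
    singlestep = retained[~multistep.to_numpy()]

    without, with_ = {}, {}
    for col, name in MEASURES:
        without[name] = main_effect(retained, col, extra_factors=extra_factors, label=name)
        with_[name] = main_effect(singlestep, col, extra_factors=extra_factors, label=name)

    pcc_wide = percent_classified(retained, multistep)
    pcc_complete = pcc_wide.dropna()
    pcc: PairedResult | None = None
    if len(pcc_complete) >= 2 and {"compatible", "incompatible"} <= set(pcc_wide.columns):
        pcc = paired_t(
            pcc_complete["compatible"].to_numpy(),
            pcc_complete["incompatible"].to_numpy(),
            measure="%CC",
        )

    # Mutually exclusive exclusion categories (priority order), so that
    # unusable + error + downward + outlier + retained = raw per participant.
    unusable = table["unusable"]
    error = ~unusable & table["response_error"]
    downward = ~unusable & ~error & table["downward"]
    outlier = ~unusable & ~error & ~downward & table["outlier"]
    audit = (
        table.assign(
            n_raw=1,
            n_error=error.astype(int),
            n_downward=downward.astype(int),
            n_unusable=unusable.astype(int),
            n_outlier=outlier.astype(int),
        )
        .groupby("participant", sort=False, observed=True)[
            ["n_raw", "n_error", "n_downward", "n_unusable", "n_outlier"]
        ]
        .sum()
    )
    audit["n_retained"] = (
        retained.groupby("participant", sort=False, observed=True).size().reindex(audit.index, fill_value=0)
    )
    audit["n_multistep"] = (
        retained[multistep.to_numpy()]
        .groupby("participant", sort=False, observed=True)
        .size()
        .reindex(audit.index, fill_value=0)
    )
    return ExperimentReport(
        without_cutoff=without, with_cutoff=with_, pcc=pcc, cutoff=cutoff, audit=audit
    )
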