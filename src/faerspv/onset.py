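"""Time-to-onset analysis for target-drug reports.

Onset is the interval in days from the primary-suspect drug's start date
(START_DT) to the report's event date (EVENT_DT), computed per
(report, PT) pair.  Both dates must be full ``YYYYMMDD`` precision;
partial dates and negative intervals are excluded and counted in an
exclusion log.  Day-0 onsets are valid.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import contingency, signals
from .ingest import CaseReport

logger = logging.getLogger(__name__)

#: Closed integer bins, in days; the last is open-ended.
ONSET_BINS: list[tuple[int, float]] = [
    (0, 30), (31, 60), (61, 90), (91, 180), (181, 360), (361, float("inf")),
]
BIN_LABELS = ["0-30", "31-60", "61-90", "91-180", "181-360", ">360"]


def _report_onset_days(report: CaseReport) -> int | None:
    """Days from the PS drug's start to the event date; None if either date
    is partial/missing or the interval is negative."""
    ps = report.primary_suspect()
    if ps is None:
        return None
    start, event = ps.start_date, report.event_date
    if start is None or event is None:
        return None
    days = (event - start).days
    return days if days >= 0 else None


def compute_onsets(reports: list[CaseReport]) -> tuple[pd.DataFrame, dict[str, int]]:
    """One onset record per (target report, PT).

    Returns a frame with columns ``primary_id, pt, onset_days`` and an
    exclusion log counting reports lost to partial dates or negative
    intervals.
    """
    rows = []
    excluded = {"not_target": 0, "partial_or_missing_date": 0, "negative_interval": 0}
    for r in reports:
        if not r.is_target:
            excluded["not_target"] += 1
            continue
        ps = r.primary_suspect()
        start = ps.start_date if ps is not None else None
        event = r.event_date
        if start is None or event is None:
            excluded["partial_or_missing_date"] += 1
            continue
        days = (event - start).days
        if days < 0:
            excluded["negative_interval"] += 1
            continue
        for pt in sorted(r.events):
            rows.append({"primary_id": r.primary_id, "pt": pt, "onset_days": days})
    logger.info("compute_onsets: %d records, excluded %s", len(rows), excluded)
    return pd.DataFrame(rows, columns=["primary_id", "pt", "onset_days"]), excluded


def bin_onsets(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Counts and proportions over the six fixed onset bins, plus the
    median onset day (computed on raw days, not bin midpoints)."""
    days = np.asarray(records["onset_days"], dtype=float)
    counts = [int(((days >= lo) & (days <= hi)).sum()) for lo, hi in ONSET_BINS]
    total = int(len(days))
    table = pd.DataFrame({
        "interval_days": BIN_LABELS,
        "count": counts,
        "proportion": [c / total if total else np.nan for c in counts],
    })
    median = float(np.median(days)) if total else float("nan")
    return table, median


def cumulative_curves(records: pd.DataFrame, top_k: int = 9) -> pd.DataFrame:
    """Empirical cumulative onset curve for the top-k PTs by record count.

    Long format: columns ``pt, day, cum_prop``; each curve is a
    non-decreasing step function ending at 1.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if records.empty:
        raise ValueError("cumulative_curves requires at least one onset record")
    top = records["pt"].value_counts().index[:top_k]
    rows = []
    for pt in top:
        days = np.sort(records.loc[records["pt"] == pt, "onset_days"].to_numpy())
        uniq, counts = np.unique(days, return_counts=True)
        cum = np.cumsum(counts) / len(days)
        rows.extend({"pt": pt, "day": int(d), "cum_prop": float(p)}
                    for d, p in zip(uniq, cum))
    return pd.DataFrame(rows, columns=["pt", "day", "cum_prop"])


def late_onset_screen(
    reports: list[CaseReport],
    cutoff_days: int = 365,
    min_a: int = 1,
) -> pd.DataFrame:
    """Disproportionality screen restricted to late-onset target reports.

    Target reports with onset >= ``cutoff_days`` are kept; the comparator
    background is unchanged.  Returns the PT metric table with a
    ``late_pass`` column (EBGM05 >= 2 or IC025 >= 0), the screen used to
    ask whether any late-onset safety signal persists.  A cutoff of 0 (or
    less) is a no-op restriction: every target report is kept, including
    those whose onset is not evaluable.
    """
    subset = []
    for r in reports:
        if not r.is_target or cutoff_days <= 0:
            subset.append(r)
            continue
        days = _report_onset_days(r)
        if days is not None and days >= cutoff_days:
            subset.append(r)
    n_late = sum(r.is_target for r in subset)
    if n_late == 0:
        logger.warning("late_onset_screen: no target reports at cutoff %d", cutoff_days)
        return pd.DataFrame(
            columns=["term", "level", "a", "b", "c", "d", "eligible", "corrected",
                     *signals._METRIC_COLS, "late_pass"]
        )
    tables = contingency.build_tables(subset, level="pt", min_a=min_a)
    df = signals.metrics_frame(tables)
    df["late_pass"] = (df["ebgm05"] >= 2.0) | (df["ic025"] >= 0.0)
    return df.sort_values("ebgm05", ascending=False, ignore_index=True)
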