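"""Daily and weekly behavioral metrics, growth performance, welfare scores.

The behavioral output of the pipeline is reported per class per day as
bout count, total bout duration (s) and mean duration per bout (s), and
then averaged per week.  Growth performance is computed at pen level on
an as-fed basis: average daily gain (ADG), average daily feed intake
(ADFI, hay-inclusive for the enriched group) and feed conversion ratio
(FCR = ADFI / ADG).  Lesion and fecal scores are ordinal scales averaged
to the pen, the experimental unit.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bouts import Bout
from .detection_io import BehaviorClass

__all__ = [
    "DailySummary",
    "summarize_daily",
    "summarize_period",
    "weekly_means",
    "compute_adg",
    "compute_fcr",
    "growth_table",
    "pen_mean_score",
    "ear_pig_score",
    "EAR_SCORE_RANGE",
    "TAIL_SCORE_RANGE",
    "FECAL_SCORE_RANGE",
]

#: Ordinal scale ranges: ear lesions 0-3, tail lesions 0-4, fecal 0-3.
EAR_SCORE_RANGE = (0.0, 3.0)
TAIL_SCORE_RANGE = (0.0, 4.0)
FECAL_SCORE_RANGE = (0.0, 3.0)


@dataclass(frozen=True)
class DailySummary:
    """Per-class, per-day bout metrics.

    ``mean_duration_per_bout_s`` is ``None`` on days without bouts (the
    statistic is undefined, not zero).
    """

    date: dt.date
    class_label: BehaviorClass
    bout_count: int
    total_duration_s: int
    mean_duration_per_bout_s: float | None


def summarize_daily(
    bouts: Sequence[Bout], date: dt.date, class_label: BehaviorClass
) -> DailySummary:
    """Aggregate one day's bouts of one class into the daily metrics."""
    for b in bouts:
        if b.date != date or b.class_label is not class_label:
            raise ValueError(
                f"bout {b} does not belong to ({date}, {class_label.value})"
            )
    count = len(bouts)
    total = sum(b.duration_s for b in bouts)
    mean = total / count if count else None
    return DailySummary(date, class_label, count, total, mean)


def summarize_period(
    bouts: Iterable[Bout],
    dates: Sequence[dt.date] | None = None,
    classes: Sequence[BehaviorClass] = tuple(BehaviorClass),
) -> list[DailySummary]:
    """Daily summaries for every (date, class) cell of a period.

    ``dates`` defaults to the dates observed in ``bouts``; cells without
    bouts produce zero-count summaries so that behavior-free days enter
    weekly means explicitly rather than silently dropping out.
    """
    bouts = list(bouts)
    if dates is None:
        dates = sorted({b.date for b in bouts})
    by_cell: dict[tuple[dt.date, BehaviorClass], list[Bout]] = {}
    for b in bouts:
        by_cell.setdefault((b.date, b.class_label), []).append(b)
    return [
        summarize_daily(by_cell.get((d, c), []), d, c)
        for d in dates
        for c in classes
    ]


def weekly_means(
    dailies: Sequence[DailySummary], week: int | None = None
) -> pd.DataFrame:
    """Weekly mean of each daily metric, per class.

    Count/day and duration/day are averaged over all supplied days;
    duration-per-bout is averaged over days with at least one bout
    (it is undefined elsewhere).  Fewer than 7 days per class is
    tolerated with a warning (e.g. camera gaps).

    Returns a frame indexed by class with columns ``bout_count``,
    ``total_duration_s``, ``mean_duration_per_bout_s`` and ``n_days``
    (plus ``week`` when given).
    """
    if not dailies:
        raise ValueError("weekly_means needs at least one daily summary")
    rows = []
    by_class: dict[BehaviorClass, list[DailySummary]] = {}
    for d in dailies:
        by_class.setdefault(d.class_label, []).append(d)
    for cls, days in by_class.items():
        if len(days) < 7:
            warnings.warn(
                f"{cls.value}: only {len(days)} daily summaries in week "
                f"{week if week is not None else '?'}; averaging available days",
                stacklevel=2,
            )
        per_bout = [
            d.mean_duration_per_bout_s for d in days if d.bout_count > 0
        ]
        rows.append(
            {
                "class": cls.value,
                "bout_count": float(np.mean([d.bout_count for d in days])),
                "total_duration_s": float(np.mean([d.total_duration_s for d in days])),
                "mean_duration_per_bout_s": (
                    float(np.mean(per_bout)) if per_bout else np.nan
                ),
                "n_days": len(days),
            }
        )
    frame = pd.DataFrame(rows).set_index("class")
    if week is not None:
        frame.insert(0, "week", week)
    return frame


# ---------------------------------------------------------------------------
# Growth performance

def compute_adg(bw_start_kg: float, bw_end_kg: float, days: int = 7) -> float:
    """Average daily gain, kg/day, over ``days`` (weekly by default)."""
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    if bw_start_kg <= 0 or bw_end_kg <= 0:
        raise ValueError("body weights must be positive")
    return (bw_end_kg - bw_start_kg) / days


def compute_fcr(adfi_kg: float, adg_kg: float) -> float:
    """Feed conversion ratio ADFI/ADG, as-fed basis.

    Undefined (raises) when ADG <= 0: a ratio against zero or negative
    gain is not reported as an infinity.
    """
    if adg_kg <= 0:
        raise ValueError(f"FCR undefined for ADG <= 0 (got {adg_kg})")
    return adfi_kg / adg_kg


def growth_table(records: pd.DataFrame, days_per_week: int = 7) -> pd.DataFrame:
    """Pen x week growth table: ADG, ADFI and FCR from pen-level inputs.

    ``records`` needs columns ``pen, week, bw_start_kg, bw_end_kg,
    feed_intake_kg, hay_intake_kg, n_pigs``; weights are pen means, the
    intakes pen totals for the week.  Hay eaten from the enrichment
    basket counts toward intake with no dry-matter correction.  Rows
    with non-positive ADG get FCR = NaN.
    """
    required = {
        "pen", "week", "bw_start_kg", "bw_end_kg",
        "feed_intake_kg", "hay_intake_kg", "n_pigs",
    }
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    out = []
    for _, row in records.iterrows():
        adg = compute_adg(row["bw_start_kg"], row["bw_end_kg"], days_per_week)
        adfi = (row["feed_intake_kg"] + row["hay_intake_kg"]) / (
            row["n_pigs"] * days_per_week
        )
        try:
            fcr = compute_fcr(adfi, adg)
        except ValueError:
            warnings.warn(
                f"pen {row['pen']} week {row['week']}: ADG {adg:.3f} <= 0, "
                "FCR undefined",
                stacklevel=2,
            )
            fcr = np.nan
        out.append(
            {"pen": row["pen"], "week": row["week"], "adg_kg": adg,
             "adfi_kg": adfi, "fcr": fcr}
        )
    return pd.DataFrame(out, columns=["pen", "week", "adg_kg", "adfi_kg", "fcr"])


# ---------------------------------------------------------------------------
# Welfare scores

def _check_range(score: float, lo: float, hi: float, what: str) -> None:
    if not lo <= score <= hi:
        raise ValueError(f"{what} {score} outside scale [{lo}, {hi}]")


def pen_mean_score(
    per_pig_scores: Sequence[float], scale: tuple[float, float] = EAR_SCORE_RANGE
) -> float:
    """Pen-level mean of per-pig ordinal scores (the experimental unit)."""
    if len(per_pig_scores) == 0:
        raise ValueError("need at least one per-pig score")
    for s in per_pig_scores:
        _check_range(s, *scale, what="score")
    return float(np.mean(per_pig_scores))


def ear_pig_score(left: float, right: float) -> float:
    """Per-pig ear lesion score: mean of the two ears, each on 0-3."""
    _check_range(left, *EAR_SCORE_RANGE, what="left ear score")
    _check_range(right, *EAR_SCORE_RANGE, what="right ear score")
    return (left + right) / 2.0
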