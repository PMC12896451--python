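"""AI-vs-manual agreement on bout-level behavioral metrics.

The automated pipeline is validated against trained-observer coding of
the same recording.  Both sources are reduced to the same bout metrics
(event count, total duration, duration per bout) on paired units —
class x day by default — and compared with Pearson's r, the
single-measure intraclass correlation from a two-way random-effects
model with absolute agreement (McGraw & Wong ICC(A,1), often written
ICC(2,1)), and Cohen's kappa.  Unlike r, the absolute-agreement ICC
penalises systematic offsets between methods.  Kappa is chance-corrected
categorical agreement and is computed here on per-second binary presence
labels derived from the two bout sets; the continuous metrics are
covered by r and ICC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bouts import Bout
from .detection_io import SECONDS_PER_DAY, BehaviorClass

__all__ = [
    "pearson_r",
    "icc_2_1",
    "cohen_kappa",
    "align_bouts",
    "BoutAlignment",
    "agreement_report",
    "METRICS",
]

METRICS = ("event_count", "total_duration", "duration_per_bout")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; errors on constant input rather than
    propagating NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("pearson_r needs two equal-length 1-d sequences, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def icc_2_1(x: Sequence[float], y: Sequence[float]) -> float:
    """Single-measure absolute-agreement ICC, two-way random effects.

    With n paired units rated by k = 2 methods, the two-way ANOVA mean
    squares give

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    where MSR, MSC, MSE are the row (unit), column (method) and residual
    mean squares.  The estimate is clipped to the reporting range
    [-1, 1].  Errors when the data have no variance at all.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("icc_2_1 needs two equal-length 1-d sequences, n >= 2")
    data = np.column_stack([x, y])  # n units x k=2 raters
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("icc_2_1 undefined: zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("icc_2_1 undefined: zero denominator")
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


def cohen_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Cohen's kappa (Po - Pe) / (1 - Pe) with marginal-product Pe.

    When both raters agree perfectly and chance agreement is also 1
    (both sequences constant and identical), kappa is reported as 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("cohen_kappa needs two equal-length 1-d sequences")
    n = len(a)
    cats = np.union1d(a, b)
    po = float(np.mean(a == b))
    pe = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    )
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


@dataclass(frozen=True)
class BoutAlignment:
    """Per-second labels and overlap-matched event pairs for one class/day."""

    labels_manual: np.ndarray  # uint8, per-second presence from manual bouts
    labels_ai: np.ndarray
    pairs: list[tuple[int, int, int]]  # (manual index, ai index, overlap seconds)

    @property
    def second_agreement(self) -> float:
        return float(np.mean(self.labels_manual == self.labels_ai))


def _labels(bouts: Sequence[Bout], window: int) -> np.ndarray:
    lab = np.zeros(window, dtype=np.uint8)
    for b in bouts:
        lab[b.start_s : min(b.end_s, window)] = 1
    return lab


def align_bouts(
    manual: Sequence[Bout],
    ai: Sequence[Bout],
    class_label: BehaviorClass | None = None,
    window: int = SECONDS_PER_DAY,
) -> BoutAlignment:
    """Align two bout lists of one class over one day.

    Produces (a) per-second binary presence labels for each source over
    the analysis window and (b) event pairs by temporal-overlap
    matching: pairs are formed greedily by decreasing overlap, each bout
    used at most once, and a pair requires strictly positive overlap.
    """
    if class_label is not None:
        manual = [b for b in manual if b.class_label is class_label]
        ai = [b for b in ai if b.class_label is class_label]
    candidates = [
        (m.overlap_s(a), mi, ai_i)
        for mi, m in enumerate(manual)
        for ai_i, a in enumerate(ai)
    ]
    candidates = [c for c in candidates if c[0] > 0]
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    m_taken: set[int] = set()
    a_taken: set[int] = set()
    pairs: list[tuple[int, int, int]] = []
    for overlap, mi, ai_i in candidates:
        if mi in m_taken or ai_i in a_taken:
            continue
        m_taken.add(mi)
        a_taken.add(ai_i)
        pairs.append((mi, ai_i, overlap))
    return BoutAlignment(
        labels_manual=_labels(manual, window),
        labels_ai=_labels(ai, window),
        pairs=sorted(pairs),
    )


def _daily_metrics(bouts: Sequence[Bout]) -> tuple[int, int, float | None]:
    count = len(bouts)
    total = sum(b.duration_s for b in bouts)
    return count, total, (total / count if count else None)


def agreement_report(
    manual: Iterable[Bout],
    ai: Iterable[Bout],
    classes: Sequence[BehaviorClass] = tuple(BehaviorClass),
) -> pd.DataFrame:
    """Class x metric agreement table over paired class-day units.

    For each class, the paired unit is the day: r and ICC(A,1) are
    computed on the per-day event counts, total durations, and mean
    durations per bout (the last over days where both sources have at
    least one bout).  Kappa is computed once per class on the pooled
    per-second presence labels of all days and repeated on each metric
    row.  Statistics that are undefined (fewer than 2 paired units, or
    degenerate variance) are reported as NaN with a warning.

    Returns a tidy frame ``class, metric, r, icc, kappa, n_units``.
    """
    manual = list(manual)
    ai = list(ai)
    rows = []
    for cls in classes:
        m_cls = [b for b in manual if b.class_label is cls]
        a_cls = [b for b in ai if b.class_label is cls]
        dates = sorted({b.date for b in m_cls} | {b.date for b in a_cls})
        per_day_m = {d: [b for b in m_cls if b.date == d] for d in dates}
        per_day_a = {d: [b for b in a_cls if b.date == d] for d in dates}
        # pooled per-second kappa across all days of the class
        if dates:
            lab_m = np.concatenate(
                [_labels(per_day_m[d], SECONDS_PER_DAY) for d in dates]
            )
            lab_a = np.concatenate(
                [_labels(per_day_a[d], SECONDS_PER_DAY) for d in dates]
            )
            kappa = cohen_kappa(lab_m, lab_a)
        else:
            kappa = np.nan
        values: dict[str, tuple[list[float], list[float]]] = {
            m: ([], []) for m in METRICS
        }
        for d in dates:
            cm, tm, dm = _daily_metrics(per_day_m[d])
            ca, ta, da = _daily_metrics(per_day_a[d])
            values["event_count"][0].append(cm)
            values["event_count"][1].append(ca)
            values["total_duration"][0].append(tm)
            values["total_duration"][1].append(ta)
            if dm is not None and da is not None:
                values["duration_per_bout"][0].append(dm)
                values["duration_per_bout"][1].append(da)
        for metric in METRICS:
            xs, ys = values[metric]
            r = _safe(pearson_r, xs, ys, cls, metric, "r")
            icc = _safe(icc_2_1, xs, ys, cls, metric, "ICC")
            rows.append(
                {
                    "class": cls.value,
                    "metric": metric,
                    "r": r,
                    "icc": icc,
                    "kappa": kappa,
                    "n_units": len(xs),
                }
            )
    return pd.DataFrame(rows, columns=["class", "metric", "r", "icc", "kappa", "n_units"])


def _safe(fn, xs, ys, cls, metric, name) -> float:
    if len(xs) < 2:
        warnings.warn(
            f"{cls.value}/{metric}: {name} needs >= 2 paired units, "
            f"have {len(xs)}; reported missing",
            stacklevel=3,
        )
        return float("nan")
    try:
        return fn(xs, ys)
    except ValueError as exc:
        warnings.warn(
            f"{cls.value}/{metric}: {name} undefined ({exc}); reported missing",
            stacklevel=3,
        )
        return float("nan")
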