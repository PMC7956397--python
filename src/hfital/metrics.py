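"""Validation of algorithm labels against reference annotations.

The reference is an event table (label, onset, offset) emulating continuous
video observation.  It is segmented onto the same window grid as the
algorithm output (majority label per window), after which every comparison is
window-wise:

* one-vs-rest confusion matrices per activity, plus one for postural
  transitions (computed on the boundary flag arrays);
* sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
  accuracy = (TP+TN)/(TP+FP+TN+FN), all in percent;
* percentage error PE = (reference − algorithm)/reference × 100 on the total
  time per activity (negative PE = overestimation by the algorithm) and on
  the transition counts; APE = |PE|;
* a *total* row pooling the three activities: the total confusion matrix is
  the element-wise sum of the per-activity matrices, and the total error is
  time-weighted, Σ_a |ref_a − algo_a| / Σ_a ref_a × 100 (signed version
  telescopes to exactly 0 on a shared grid).

Cohort aggregation reports median (Q1–Q3) per metric over the subjects for
which the metric is defined; undefined ratios (zero denominators) are
not-available (NaN) rather than imputed.  Acceptability limits:
sensitivity/specificity/accuracy >= 80%, PE within ±10%, APE below 10%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .classify import ActivityLabel, LabelSeries, TransitionSeries, detect_transitions

__all__ = [
    "ACTIVITY_CATEGORIES",
    "CATEGORIES",
    "METRIC_NAMES",
    "CohortSummary",
    "ConfusionCounts",
    "MetricRow",
    "PerformanceReport",
    "QuartileSummary",
    "ReferenceEvents",
    "cohort_summary",
    "confusion",
    "is_acceptable",
    "percentage_error",
    "sens_spec_acc",
    "subject_report",
    "total_error",
    "windowize_reference",
]

ACTIVITY_CATEGORIES = ("sedentary", "standing", "dynamic")
CATEGORIES = ACTIVITY_CATEGORIES + ("total", "transitions")
METRIC_NAMES = ("sensitivity_pct", "specificity_pct", "accuracy_pct", "pe_pct", "ape_pct")

#: target label for the transition confusion matrix
TRANSITION = "transitions"

_TIME_TOL = 1e-9


@dataclass
class ReferenceEvents:
    """Contiguous, non-overlapping reference activity events covering [0, T).

    ``labels`` holds :class:`ActivityLabel` codes; ``onsets``/``offsets`` are
    seconds from recording start, with event k's offset equal to event k+1's
    onset.
    """

    labels: np.ndarray
    onsets: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray([int(ActivityLabel(v)) for v in np.asarray(self.labels)], dtype=np.int8)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        n = self.labels.size
        if not (self.onsets.size == self.offsets.size == n) or n < 1:
            raise ValueError("events require equal-length, non-empty label/onset/offset sequences")
        if np.any(self.offsets <= self.onsets):
            k = int(np.argmax(self.offsets <= self.onsets))
            raise ValueError(f"event {k} has non-positive duration [{self.onsets[k]}, {self.offsets[k]})")
        gaps = self.onsets[1:] - self.offsets[:-1]
        if np.any(np.abs(gaps) > _TIME_TOL):
            k = int(np.argmax(np.abs(gaps) > _TIME_TOL))
            raise ValueError(
                f"events {k} and {k + 1} are not contiguous: offset {self.offsets[k]} vs onset {self.onsets[k + 1]}"
            )

    @classmethod
    def from_segments(cls, segments: Iterable[tuple[ActivityLabel, float]], start_s: float = 0.0) -> "ReferenceEvents":
        """Build events from (label, duration) pairs laid end to end."""
        labels, onsets, offsets = [], [], []
        t = float(start_s)
        for label, dur in segments:
            labels.append(ActivityLabel(label))
            onsets.append(t)
            t += float(dur)
            offsets.append(t)
        return cls(labels=np.array(labels), onsets=np.array(onsets), offsets=np.array(offsets))

    @property
    def n_events(self) -> int:
        return self.labels.size

    @property
    def start_s(self) -> float:
        return float(self.onsets[0])

    @property
    def end_s(self) -> float:
        return float(self.offsets[-1])

    def total_time_s(self, label: ActivityLabel) -> float:
        mask = self.labels == int(label)
        return float(np.sum(self.offsets[mask] - self.onsets[mask]))


def windowize_reference(events: ReferenceEvents, ws_seconds: float, n_windows: int) -> LabelSeries:
    """Majority label of each window on the grid [0, n_windows × ws).

    Each window receives the label occupying the greatest total duration
    within it.  Exact duration ties break toward the later-starting event
    (the label covering the later part of the window).
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    span = n_windows * ws_seconds
    if events.start_s > _TIME_TOL or events.end_s < span - _TIME_TOL:
        raise ValueError(
            f"reference events cover [{events.start_s}, {events.end_s}) but must cover [0, {span})"
        )
    dur = np.zeros((3, n_windows))
    last_cover = np.full((3, n_windows), -np.inf)
    for k in range(events.n_events):
        on, off = events.onsets[k], events.offsets[k]
        lab = int(events.labels[k])
        first = max(int(math.floor(on / ws_seconds + _TIME_TOL)), 0)
        last = min(int(math.ceil(off / ws_seconds - _TIME_TOL)), n_windows)
        if first >= last:
            continue
        idx = np.arange(first, last)
        lo = np.maximum(on, idx * ws_seconds)
        hi = np.minimum(off, (idx + 1) * ws_seconds)
        overlap = np.clip(hi - lo, 0.0, None)
        dur[lab, idx] += overlap
        last_cover[lab, idx] = np.maximum(last_cover[lab, idx], np.where(overlap > _TIME_TOL, hi, -np.inf))
    # majority by duration, ties toward the label covering the later part
    best = np.zeros(n_windows, dtype=np.int8)
    for w in range(n_windows):
        d = dur[:, w]
        top = d.max()
        cands = np.flatnonzero(d >= top - _TIME_TOL)
        best[w] = cands[np.argmax(last_cover[cands, w])] if cands.size > 1 else int(np.argmax(d))
    return LabelSeries(labels=best, ws_seconds=ws_seconds, subject_id="reference")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN counts for one target class (or transitions)."""

    tp: int
    fp: int
    tn: int
    fn: int
    target: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
            target="total",
        )


def _binary_confusion(algo: np.ndarray, ref: np.ndarray, target_name: str) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(np.count_nonzero(algo & ref)),
        fp=int(np.count_nonzero(algo & ~ref)),
        tn=int(np.count_nonzero(~algo & ~ref)),
        fn=int(np.count_nonzero(~algo & ref)),
        target=target_name,
    )


def confusion(algo: LabelSeries, ref: LabelSeries, target: ActivityLabel | str) -> ConfusionCounts:
    """One-vs-rest confusion counts of algorithm vs reference labels.

    ``target`` is an activity label, or ``"transitions"`` to compare the
    boundary flag arrays produced by :func:`detect_transitions`.
    """
    if len(algo) != len(ref):
        raise ValueError(f"label series lengths differ ({len(algo)} vs {len(ref)}): windowing/synchronization bug")
    if isinstance(target, str) and target.lower() == TRANSITION:
        a = detect_transitions(algo).flags.astype(bool)
        r = detect_transitions(ref).flags.astype(bool)
        return _binary_confusion(a, r, TRANSITION)
    target = ActivityLabel(target)
    return _binary_confusion(algo.labels == int(target), ref.labels == int(target), str(target))


def sens_spec_acc(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent.

    A zero denominator makes the corresponding ratio not-available (NaN);
    all-zero counts are an error.
    """
    if c.total == 0:
        raise ValueError("confusion matrix is empty")
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    acc = 100.0 * (c.tp + c.tn) / c.total
    return sens, spec, acc


def percentage_error(ref_quantity: float, algo_quantity: float) -> tuple[float, float]:
    """(PE, APE) in percent: PE = (ref − algo)/ref × 100, APE = |PE|.

    Negative PE means the algorithm overestimates.  A zero reference
    quantity yields (NaN, NaN) — not-available, excluded from aggregation.
    """
    if ref_quantity < 0 or algo_quantity < 0:
        raise ValueError("quantities must be non-negative")
    if ref_quantity == 0:
        return math.nan, math.nan
    pe = 100.0 * (ref_quantity - algo_quantity) / ref_quantity
    return pe, abs(pe)


def total_error(ref_times: Sequence[float], algo_times: Sequence[float]) -> tuple[float, float]:
    """Time-weighted pooled error over all activities.

    total PE = Σ_a (ref_a − algo_a) / Σ_a ref_a × 100 (identically 0 when
    both series live on the same window grid); total APE replaces the inner
    differences by absolute values.
    """
    ref = np.asarray(ref_times, dtype=float)
    algo = np.asarray(algo_times, dtype=float)
    if ref.shape != algo.shape:
        raise ValueError("per-activity time vectors must align")
    total_ref = ref.sum()
    if total_ref <= 0:
        return math.nan, math.nan
    pe = 100.0 * (ref - algo).sum() / total_ref
    ape = 100.0 * np.abs(ref - algo).sum() / total_ref
    return float(pe), float(ape)


@dataclass(frozen=True)
class MetricRow:
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    pe_pct: float
    ape_pct: float

    def get(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class PerformanceReport:
    """All validation metrics of one subject.

    ``rows`` maps each category (sedentary, standing, dynamic, total,
    transitions) to its metrics; times are per-activity totals in seconds on
    the shared window grid; transition counts come from both series.
    """

    subject_id: str
    ws_seconds: float
    rows: dict[str, MetricRow]
    confusions: dict[str, ConfusionCounts]
    reference_time_s: dict[str, float]
    algorithm_time_s: dict[str, float]
    reference_transitions: int
    algorithm_transitions: int


def subject_report(algo: LabelSeries, ref: ReferenceEvents, ws_seconds: float | None = None) -> PerformanceReport:
    """Windowize the reference and compute every metric family for a subject."""
    ws = algo.ws_seconds if ws_seconds is None else ws_seconds
    ref_series = windowize_reference(ref, ws, len(algo))

    confusions: dict[str, ConfusionCounts] = {}
    rows: dict[str, MetricRow] = {}
    ref_time: dict[str, float] = {}
    algo_time: dict[str, float] = {}

    for label in ActivityLabel:
        name = str(label)
        c = confusion(algo, ref_series, label)
        confusions[name] = c
        sens, spec, acc = sens_spec_acc(c)
        rt, at = ref_series.time_s(label), algo.time_s(label)
        ref_time[name], algo_time[name] = rt, at
        pe, ape = percentage_error(rt, at)
        rows[name] = MetricRow(sens, spec, acc, pe, ape)

    total_c = confusions["sedentary"] + confusions["standing"] + confusions["dynamic"]
    confusions["total"] = total_c
    sens, spec, acc = sens_spec_acc(total_c)
    ref_vec = [ref_time[a] for a in ACTIVITY_CATEGORIES]
    algo_vec = [algo_time[a] for a in ACTIVITY_CATEGORIES]
    pe, ape = total_error(ref_vec, algo_vec)
    rows["total"] = MetricRow(sens, spec, acc, pe, ape)

    trans_c = confusion(algo, ref_series, TRANSITION)
    confusions["transitions"] = trans_c
    n_ref_t = detect_transitions(ref_series).count
    n_algo_t = detect_transitions(algo).count
    if trans_c.total > 0:
        sens, spec, acc = sens_spec_acc(trans_c)
    else:  # single-window series: no boundaries to compare
        sens = spec = acc = math.nan
    pe, ape = percentage_error(n_ref_t, n_algo_t)
    rows["transitions"] = MetricRow(sens, spec, acc, pe, ape)

    return PerformanceReport(
        subject_id=algo.subject_id,
        ws_seconds=ws,
        rows=rows,
        confusions=confusions,
        reference_time_s=ref_time,
        algorithm_time_s=algo_time,
        reference_transitions=n_ref_t,
        algorithm_transitions=n_algo_t,
    )


def is_acceptable(metric: str, value: float) -> bool | None:
    """Acceptability limits: sens/spec/acc >= 80%, PE within ±10%, APE < 10%.

    Returns None for not-available values.
    """
    if not np.isfinite(value):
        return None
    if metric in ("sensitivity_pct", "specificity_pct", "accuracy_pct"):
        return value >= 80.0
    if metric == "pe_pct":
        return -10.0 <= value <= 10.0
    if metric == "ape_pct":
        return value < 10.0
    raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class QuartileSummary:
    median: float
    q1: float
    q3: float
    n_defined: int
    acceptable: bool | None


@dataclass
class CohortSummary:
    """Median (Q1–Q3) of every metric across subjects, per category."""

    table: dict[str, dict[str, QuartileSummary]]
    n_subjects: int

    def get(self, category: str, metric: str) -> QuartileSummary:
        return self.table[category][metric]


def cohort_summary(reports: Sequence[PerformanceReport]) -> CohortSummary:
    """Aggregate subject reports to cohort medians and quartiles.

    Quartiles use linear interpolation between order statistics; subjects
    with a not-available metric are excluded from that metric's aggregation.
    The acceptability flag is evaluated on the cohort median.
    """
    if len(reports) == 0:
        raise ValueError("cohort_summary requires at least one report")
    table: dict[str, dict[str, QuartileSummary]] = {}
    for cat in CATEGORIES:
        table[cat] = {}
        for metric in METRIC_NAMES:
            values = np.array([r.rows[cat].get(metric) for r in reports], dtype=float)
            defined = values[np.isfinite(values)]
            if defined.size == 0:
                table[cat][metric] = QuartileSummary(math.nan, math.nan, math.nan, 0, None)
                continue
            q1, med, q3 = np.percentile(defined, [25, 50, 75], method="linear")
            table[cat][metric] = QuartileSummary(float(med), float(q1), float(q3), int(defined.size), is_acceptable(metric, float(med)))
    return CohortSummary(table=table, n_subjects=len(reports))
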