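"""Decision trees turning window features into activity labels.

Two variants share the same thresholds but differ in tree order and in which
axes feed the counts feature:

* **MOXAL** (baseline, tri-axial counts) gates on activity first:
  counts >= PA Th -> dynamic; otherwise orientation >= SO Th -> standing,
  else sedentary.
* **HFITAL** (optimized, anterior-posterior counts) gates on posture first:
  orientation < SO Th -> sedentary; otherwise counts >= PA Th -> dynamic,
  else standing.

The posture-first order means a window with a horizontal thigh is sedentary
no matter how much movement it contains — the behavioural delta that makes
the optimized tree robust to in-bed movement.

Threshold ties are fixed conventions: orientation >= SO Th counts as upright,
counts >= PA Th counts as dynamic.

A postural transition is a sedentary window directly followed by a standing
or dynamic window; transitions are counted on the window grid only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .signal import (
    AccelRecording,
    AlgorithmParams,
    CountsFilter,
    DEFAULT_COUNTS_FILTER,
    FeatureWindow,
    Variant,
    compute_features,
    feature_arrays,
)

__all__ = [
    "ActivityLabel",
    "LabelSeries",
    "TransitionSeries",
    "classify_features",
    "classify_hfital",
    "classify_moxal",
    "detect_transitions",
    "run_pipeline",
]


class ActivityLabel(enum.IntEnum):
    """Closed three-class activity vocabulary."""

    SEDENTARY = 0
    STANDING = 1
    DYNAMIC = 2

    def __str__(self) -> str:  # CSV spelling
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "ActivityLabel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown activity label {name!r}; expected sedentary|standing|dynamic") from None


UPRIGHT = (ActivityLabel.STANDING, ActivityLabel.DYNAMIC)


@dataclass
class LabelSeries:
    """Per-window activity labels aligned to the segmentation grid."""

    labels: np.ndarray
    ws_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.dtype.kind not in "iu":
            arr = np.array([int(ActivityLabel(v)) for v in arr], dtype=np.int8)
        arr = arr.astype(np.int8)
        if arr.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if arr.size and not np.all((arr >= 0) & (arr <= 2)):
            raise ValueError("labels must be drawn from the three-class vocabulary")
        self.labels = arr

    def __len__(self) -> int:
        return self.labels.size

    def __iter__(self) -> Iterator[ActivityLabel]:
        return (ActivityLabel(int(v)) for v in self.labels)

    def __getitem__(self, i: int) -> ActivityLabel:
        return ActivityLabel(int(self.labels[i]))

    def time_s(self, label: ActivityLabel) -> float:
        """Total time (s) the series assigns to one activity."""
        return float(np.count_nonzero(self.labels == int(label)) * self.ws_seconds)


@dataclass
class TransitionSeries:
    """Per-boundary sedentary→upright flags; one flag per window boundary i>=1."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.flags, dtype=np.int8)
        if arr.ndim != 1:
            raise ValueError("flags must be one-dimensional")
        if arr.size and not np.all((arr == 0) | (arr == 1)):
            raise ValueError("flags must be 0/1")
        self.flags = arr

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def __len__(self) -> int:
        return self.flags.size


def _check_features(features: Sequence[FeatureWindow]) -> None:
    if len(features) == 0:
        raise ValueError("cannot classify an empty feature sequence")


def classify_hfital(features: Sequence[FeatureWindow], params: AlgorithmParams, subject_id: str = "") -> LabelSeries:
    """Posture-first tree: sedentary gate, then standing/dynamic by counts.

    Expects features computed in single-axis counts mode.
    """
    _check_features(features)
    orient, counts = feature_arrays(features)
    labels = np.where(
        orient < params.so_th_g,
        int(ActivityLabel.SEDENTARY),
        np.where(counts >= params.pa_th_cps, int(ActivityLabel.DYNAMIC), int(ActivityLabel.STANDING)),
    ).astype(np.int8)
    return LabelSeries(labels=labels, ws_seconds=params.ws_seconds, subject_id=subject_id)


def classify_moxal(features: Sequence[FeatureWindow], params: AlgorithmParams, subject_id: str = "") -> LabelSeries:
    """Activity-first baseline tree: dynamic gate, then standing/sedentary.

    Expects features computed in tri-axial counts mode.
    """
    _check_features(features)
    orient, counts = feature_arrays(features)
    labels = np.where(
        counts >= params.pa_th_cps,
        int(ActivityLabel.DYNAMIC),
        np.where(orient >= params.so_th_g, int(ActivityLabel.STANDING), int(ActivityLabel.SEDENTARY)),
    ).astype(np.int8)
    return LabelSeries(labels=labels, ws_seconds=params.ws_seconds, subject_id=subject_id)


_CLASSIFIERS = {Variant.MOXAL: classify_moxal, Variant.HFITAL: classify_hfital}


def classify_features(features: Sequence[FeatureWindow], params: AlgorithmParams, subject_id: str = "") -> LabelSeries:
    """Dispatch to the tree matching ``params.variant``."""
    return _CLASSIFIERS[params.variant](features, params, subject_id)


def detect_transitions(labels: LabelSeries | Sequence[ActivityLabel]) -> TransitionSeries:
    """Flag every sedentary→standing/dynamic window boundary.

    With fewer than two windows there are no boundaries: empty flags, count 0.
    """
    arr = labels.labels if isinstance(labels, LabelSeries) else LabelSeries(np.asarray([int(v) for v in labels]), ws_seconds=1.0).labels
    if arr.size < 2:
        return TransitionSeries(flags=np.zeros(0, dtype=np.int8))
    flags = ((arr[:-1] == int(ActivityLabel.SEDENTARY)) & (arr[1:] != int(ActivityLabel.SEDENTARY))).astype(np.int8)
    return TransitionSeries(flags=flags)


def run_pipeline(
    recording: AccelRecording,
    params: AlgorithmParams,
    counts_filter: CountsFilter = DEFAULT_COUNTS_FILTER,
) -> tuple[LabelSeries, TransitionSeries]:
    """Segment → features (mode set by variant) → classify → transitions."""
    features = compute_features(recording, params.ws_seconds, params.counts_mode, counts_filter)
    labels = classify_features(features, params, subject_id=recording.subject_id)
    return labels, detect_transitions(labels)
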