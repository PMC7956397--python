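"""Raw-acceleration data model, window segmentation and per-window features.

A thigh-worn tri-axial accelerometer (nominally 25 Hz, ±8 g) yields, per
analysis window, two features:

* **sensor orientation** — the window mean of the raw longitudinal-axis
  acceleration in g.  For a motionless sensor this is the cosine of the
  thigh-to-gravity angle: ~1 g standing, ~0 g with the thigh horizontal.
* **activity counts** — the window-normalized magnitude of the dynamic
  (gravity-removed, band-limited) acceleration, in counts per second (cps).
  One count is 1 g·sample of rectified band-passed signal; a window's
  counts-per-second value is the rectified sum divided by the window
  duration in seconds.

The counts definition is configurable (:class:`CountsFilter`) because the
thresholds that act on it are only meaningful relative to a fixed definition:
default is a 4th-order Butterworth band-pass, 0.25–11 Hz, applied
forward-backward (zero phase) to the whole recording *before* windowing, so
short windows are never dominated by filter transients.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "AXIS_NAMES",
    "AccelRecording",
    "AlgorithmParams",
    "AxisRoles",
    "CountsFilter",
    "CountsMode",
    "FeatureWindow",
    "Variant",
    "activity_counts",
    "compute_features",
    "orientation_feature",
    "rectified_activity",
    "segment_windows",
    "window_sample_count",
    "zero_phase_bandpass",
]

AXIS_NAMES = ("x", "y", "z")
SENSOR_RANGE_G = 8.0


def _parse_axis(spec: str) -> tuple[int, float]:
    """Turn an axis spec such as ``"y"`` or ``"-z"`` into (column, sign)."""
    sign = 1.0
    name = spec.strip().lower()
    if name.startswith(("-", "+")):
        sign = -1.0 if name[0] == "-" else 1.0
        name = name[1:]
    if name not in AXIS_NAMES:
        raise ValueError(f"unknown axis {spec!r}; expected one of {AXIS_NAMES} with optional sign")
    return AXIS_NAMES.index(name), sign


@dataclass(frozen=True)
class AxisRoles:
    """Mapping of device axes onto anatomical roles.

    Each role names a device axis (``"x"``, ``"y"`` or ``"z"``), optionally
    sign-flipped (``"-z"``).  The longitudinal axis must be oriented so that
    quiet standing reads +1 g; mounting-dependent flips are applied here, at
    load time, rather than inside the classifier.
    """

    longitudinal: str = "x"
    anterior_posterior: str = "y"
    medio_lateral: str = "z"

    def __post_init__(self) -> None:
        cols = [_parse_axis(a)[0] for a in (self.longitudinal, self.anterior_posterior, self.medio_lateral)]
        if sorted(cols) != [0, 1, 2]:
            raise ValueError(f"axis roles must be a bijection onto {AXIS_NAMES}, got {self}")

    def column(self, role: str) -> tuple[int, float]:
        return _parse_axis(getattr(self, role))


@dataclass
class AccelRecording:
    """A tri-axial acceleration trace in units of g.

    ``samples`` is an (N, 3) array with columns in device order (x, y, z);
    ``axis_roles`` maps those columns onto anatomical roles.
    """

    samples: np.ndarray
    sample_rate_hz: float = 25.0
    axis_roles: AxisRoles = field(default_factory=AxisRoles)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (N, 3), got shape {self.samples.shape}")
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("acceleration samples must be finite")
        peak = float(np.max(np.abs(self.samples)))
        if peak > SENSOR_RANGE_G:
            raise ValueError(f"|acceleration| exceeds sensor range ±{SENSOR_RANGE_G} g (max {peak:.3f} g)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def axis(self, role: str) -> np.ndarray:
        """Signed 1-D trace for an anatomical role (longitudinal, ...)."""
        col, sign = self.axis_roles.column(role)
        return sign * self.samples[:, col]


class Variant(str, enum.Enum):
    """Decision-tree variant: baseline (MOXAL) or optimized (HFITAL)."""

    MOXAL = "moxal"
    HFITAL = "hfital"


class CountsMode(str, enum.Enum):
    """Which axes feed the activity-counts feature."""

    TRIAXIAL = "triaxial"
    SINGLE_AXIS = "single_axis"


#: Counts mode each variant was defined with: the baseline combines all three
#: axes, the optimized variant uses only the anterior-posterior axis (the most
#: sensitive one for slow, aided gait).
VARIANT_COUNTS_MODE = {Variant.MOXAL: CountsMode.TRIAXIAL, Variant.HFITAL: CountsMode.SINGLE_AXIS}


@dataclass(frozen=True)
class AlgorithmParams:
    """Adjustable parameters of the classification algorithm.

    ws_seconds
        data-segmentation window size (s).
    pa_th_cps
        amount-of-physical-activity threshold separating standing from
        dynamic windows (counts per second).
    so_th_g
        sensor-orientation threshold separating sedentary from upright
        windows (g); 0.8 g ≈ cos 37°.
    """

    ws_seconds: float
    pa_th_cps: float
    so_th_g: float
    variant: Variant

    def __post_init__(self) -> None:
        if self.ws_seconds <= 0:
            raise ValueError("ws_seconds must be positive")
        if self.pa_th_cps <= 0:
            raise ValueError("pa_th_cps must be positive")
        if not 0 < self.so_th_g <= 1:
            raise ValueError("so_th_g must lie in (0, 1]")
        object.__setattr__(self, "variant", Variant(self.variant))

    @classmethod
    def moxal(cls) -> "AlgorithmParams":
        """Baseline settings: WS 2 s, PA Th 7 cps, SO Th 0.8 g, tri-axial."""
        return cls(ws_seconds=2.0, pa_th_cps=7.0, so_th_g=0.8, variant=Variant.MOXAL)

    @classmethod
    def hfital(cls) -> "AlgorithmParams":
        """Optimized settings: WS 4 s, PA Th 4.3 cps, SO Th 0.8 g, single-axis."""
        return cls(ws_seconds=4.0, pa_th_cps=4.3, so_th_g=0.8, variant=Variant.HFITAL)

    @property
    def counts_mode(self) -> CountsMode:
        return VARIANT_COUNTS_MODE[self.variant]


@dataclass(frozen=True)
class CountsFilter:
    """Band-pass used to isolate the dynamic (movement) acceleration."""

    low_hz: float = 0.25
    high_hz: float = 11.0
    order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def coefficients(self, sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
        nyq = sample_rate_hz / 2.0
        if self.high_hz >= nyq:
            raise ValueError(f"high_hz {self.high_hz} must be below the Nyquist frequency {nyq}")
        return butter(self.order, [self.low_hz / nyq, self.high_hz / nyq], btype="bandpass")


DEFAULT_COUNTS_FILTER = CountsFilter()


@dataclass(frozen=True)
class FeatureWindow:
    """One segmentation window's orientation (g) and activity counts (cps)."""

    index: int
    start_s: float
    end_s: float
    orientation_g: float
    counts_cps: float

    def __post_init__(self) -> None:
        if self.counts_cps < 0:
            raise ValueError("counts_cps must be non-negative")
        if not np.isfinite(self.orientation_g):
            raise ValueError("orientation_g must be finite")


def window_sample_count(ws_seconds: float, sample_rate_hz: float) -> int:
    """Samples per window; the WS lattice at 25 Hz lands on integers.

    ``ws_seconds * sample_rate_hz`` must be an integer >= 1 up to float
    rounding drift (grid values such as 7 x 0.4 s x 25 Hz give 69.999...).
    """
    raw = ws_seconds * sample_rate_hz
    n = int(round(raw))
    if n < 1 or abs(raw - n) > 1e-6 * max(1.0, raw):
        raise ValueError(f"window size {ws_seconds} s at {sample_rate_hz} Hz gives {raw} samples; need an integer >= 1")
    return n


def segment_windows(recording: AccelRecording, ws_seconds: float) -> np.ndarray:
    """Non-overlapping, equal-length sample-index ranges anchored at sample 0.

    Returns an (n_windows, 2) array of half-open ``[start, stop)`` index
    pairs.  A trailing partial window is discarded so that algorithm and
    reference label series share an identical grid.
    """
    win = window_sample_count(ws_seconds, recording.sample_rate_hz)
    n = recording.n_samples // win
    if n < 1:
        raise ValueError(
            f"recording of {recording.n_samples} samples is shorter than one "
            f"{ws_seconds} s window ({win} samples minimum)"
        )
    starts = np.arange(n) * win
    return np.stack([starts, starts + win], axis=1)


def zero_phase_bandpass(x: np.ndarray, sample_rate_hz: float, counts_filter: CountsFilter = DEFAULT_COUNTS_FILTER) -> np.ndarray:
    """Forward-backward Butterworth band-pass of a 1-D trace.

    Zero-phase filtering keeps movement energy aligned with its window.  The
    whole recording is filtered once, before windowing, so windows shorter
    than the filter transient remain well defined.
    """
    b, a = counts_filter.coefficients(sample_rate_hz)
    default_pad = 3 * max(len(a), len(b))
    padlen = min(default_pad, x.shape[0] - 1)
    return filtfilt(b, a, x, padlen=padlen)


def rectified_activity(
    recording: AccelRecording,
    mode: CountsMode | str = CountsMode.SINGLE_AXIS,
    counts_filter: CountsFilter = DEFAULT_COUNTS_FILTER,
) -> np.ndarray:
    """Per-sample rectified dynamic acceleration (g), ready for window sums.

    ``single_axis`` rectifies the band-passed anterior-posterior trace;
    ``triaxial`` sums the per-axis rectified contributions of all three axes.
    """
    mode = CountsMode(mode)
    if mode is CountsMode.SINGLE_AXIS:
        return np.abs(zero_phase_bandpass(recording.axis("anterior_posterior"), recording.sample_rate_hz, counts_filter))
    rect = np.zeros(recording.n_samples)
    for role in ("longitudinal", "anterior_posterior", "medio_lateral"):
        rect += np.abs(zero_phase_bandpass(recording.axis(role), recording.sample_rate_hz, counts_filter))
    return rect


def orientation_feature(window: np.ndarray, axis_roles: AxisRoles) -> float:
    """Mean raw longitudinal acceleration (g) over one window's samples.

    For a motionless sensor this equals the cosine of the thigh-to-gravity
    angle; it is compared against the sensor-orientation threshold in g.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3 or window.shape[0] < 1:
        raise ValueError("window must be a non-empty (n, 3) sample block")
    col, sign = axis_roles.column("longitudinal")
    return float(np.mean(sign * window[:, col]))


def activity_counts(
    recording: AccelRecording,
    start: int,
    stop: int,
    mode: CountsMode | str = CountsMode.SINGLE_AXIS,
    counts_filter: CountsFilter = DEFAULT_COUNTS_FILTER,
) -> float:
    """Activity counts (cps) of one window of a recording.

    The whole recording is band-passed first (see :func:`rectified_activity`);
    the window's rectified sum is divided by the window duration.
    """
    if not 0 <= start < stop <= recording.n_samples:
        raise ValueError(f"invalid window [{start}, {stop}) for {recording.n_samples} samples")
    rect = rectified_activity(recording, mode, counts_filter)
    duration_s = (stop - start) / recording.sample_rate_hz
    return float(np.sum(rect[start:stop]) / duration_s)


def compute_features(
    recording: AccelRecording,
    ws_seconds: float,
    mode: CountsMode | str = CountsMode.SINGLE_AXIS,
    counts_filter: CountsFilter = DEFAULT_COUNTS_FILTER,
) -> list[FeatureWindow]:
    """Segment a recording and compute both features for every full window."""
    ranges = segment_windows(recording, ws_seconds)
    win = int(ranges[0, 1] - ranges[0, 0])
    n = ranges.shape[0]
    fs = recording.sample_rate_hz
    longitudinal = recording.axis("longitudinal")[: n * win]
    rect = rectified_activity(recording, mode, counts_filter)[: n * win]
    orient = longitudinal.reshape(n, win).mean(axis=1)
    counts = rect.reshape(n, win).sum(axis=1) / (win / fs)
    return [
        FeatureWindow(
            index=i,
            start_s=ranges[i, 0] / fs,
            end_s=ranges[i, 1] / fs,
            orientation_g=float(orient[i]),
            counts_cps=float(counts[i]),
        )
        for i in range(n)
    ]


def feature_arrays(features: Sequence[FeatureWindow]) -> tuple[np.ndarray, np.ndarray]:
    """(orientation_g, counts_cps) arrays for a feature-window sequence."""
    orient = np.array([f.orientation_g for f in features], dtype=float)
    counts = np.array([f.counts_cps for f in features], dtype=float)
    return orient, counts
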