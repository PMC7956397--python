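"""CSV dialects, report serialization and run configuration.

All artifacts are plain text.  Writers prepend ``#``-prefixed provenance
lines (package version plus the exact parameter set that produced the file);
readers skip comment lines, so round trips are lossless.

Formats
-------
acceleration CSV
    header ``time_s,ax_g,ay_g,az_g``, one row per sample, monotone time at
    the nominal sample rate.  Axis-role mapping and sign flips come from the
    configuration, not the file.
reference CSV
    header ``label,onset_s,offset_s``; contiguous, non-overlapping events
    with labels ``sedentary|standing|dynamic``.
labels CSV
    header ``window_index,start_s,end_s,label``.
transitions CSV
    header ``boundary_index,time_s``, one row per detected transition.
manifest CSV
    header ``subject_id,accel_csv,truth_csv`` with paths relative to the
    manifest location.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ActivityLabel, LabelSeries, TransitionSeries
from .metrics import (
    CATEGORIES,
    METRIC_NAMES,
    CohortSummary,
    PerformanceReport,
    ReferenceEvents,
)
from .signal import AccelRecording, AlgorithmParams, AxisRoles, CountsFilter, Variant

__all__ = [
    "RunConfig",
    "load_config",
    "read_accel_csv",
    "read_labels_csv",
    "read_manifest_csv",
    "read_reference_csv",
    "report_to_dict",
    "summary_to_dict",
    "write_accel_csv",
    "write_labels_csv",
    "write_manifest_csv",
    "write_reference_csv",
    "write_report_json",
    "write_transitions_csv",
]

ACCEL_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]
REFERENCE_COLUMNS = ["label", "onset_s", "offset_s"]


def _stamp_lines(extra: dict[str, Any] | None = None) -> list[str]:
    info: dict[str, Any] = {"generator": f"hfital {__version__}"}
    if extra:
        info.update(extra)
    return [f"# {k}: {v}" for k, v in info.items()]


def _params_stamp(params: AlgorithmParams | None) -> dict[str, Any]:
    if params is None:
        return {}
    return {
        "variant": params.variant.value,
        "ws_seconds": params.ws_seconds,
        "pa_th_cps": params.pa_th_cps,
        "so_th_g": params.so_th_g,
    }


def _write_csv(path: Path | str, frame: pd.DataFrame, stamp: dict[str, Any] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _stamp_lines(stamp):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def _read_csv(path: Path | str, columns: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; expected header {','.join(columns)}")
    return frame


def write_accel_csv(path: Path | str, recording: AccelRecording) -> None:
    t = np.arange(recording.n_samples) / recording.sample_rate_hz
    frame = pd.DataFrame(
        {
            "time_s": t,
            "ax_g": recording.samples[:, 0],
            "ay_g": recording.samples[:, 1],
            "az_g": recording.samples[:, 2],
        }
    )
    _write_csv(path, frame, {"sample_rate_hz": recording.sample_rate_hz, "subject_id": recording.subject_id})


def read_accel_csv(
    path: Path | str,
    expected_sample_rate_hz: float | None = None,
    axis_roles: AxisRoles | None = None,
    subject_id: str = "",
) -> AccelRecording:
    """Read and validate an acceleration CSV.

    The sample rate is inferred from the timestamps; if an expected rate is
    given they must agree within 1%.  NaN, non-monotone time and values
    outside ±8 g are rejected with the offending row number (0-based data
    row, header excluded).
    """
    frame = _read_csv(path, ACCEL_COLUMNS)
    if len(frame) < 1:
        raise ValueError(f"{path}: no samples")
    values = frame[ACCEL_COLUMNS].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        raise ValueError(f"{path}: non-finite value at data row {int(bad[0])}")
    t = values[:, 0]
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"{path}: non-monotone time at data row {row}")
        fs = 1.0 / float(np.median(dt))
    else:
        fs = expected_sample_rate_hz or 25.0
    if expected_sample_rate_hz is not None and abs(fs - expected_sample_rate_hz) > 0.01 * expected_sample_rate_hz:
        raise ValueError(
            f"{path}: inferred sample rate {fs:.3f} Hz differs from configured {expected_sample_rate_hz} Hz by more than 1%"
        )
    accel = values[:, 1:4]
    over = np.flatnonzero(np.abs(accel).max(axis=1) > 8.0)
    if over.size:
        raise ValueError(f"{path}: acceleration outside ±8 g at data row {int(over[0])}")
    return AccelRecording(
        samples=accel,
        sample_rate_hz=fs,
        axis_roles=axis_roles or AxisRoles(),
        subject_id=subject_id or Path(path).stem,
    )


def write_reference_csv(path: Path | str, events: ReferenceEvents) -> None:
    frame = pd.DataFrame(
        {
            "label": [str(ActivityLabel(int(v))) for v in events.labels],
            "onset_s": events.onsets,
            "offset_s": events.offsets,
        }
    )
    _write_csv(path, frame)


def read_reference_csv(path: Path | str) -> ReferenceEvents:
    """Read a reference event table; gap/overlap errors cite the intervals."""
    frame = _read_csv(path, REFERENCE_COLUMNS)
    labels = [ActivityLabel.from_name(str(v)) for v in frame["label"]]
    return ReferenceEvents(
        labels=np.array(labels),
        onsets=frame["onset_s"].to_numpy(dtype=float),
        offsets=frame["offset_s"].to_numpy(dtype=float),
    )


def write_labels_csv(path: Path | str, labels: LabelSeries, params: AlgorithmParams | None = None) -> None:
    ws = labels.ws_seconds
    idx = np.arange(len(labels))
    frame = pd.DataFrame(
        {
            "window_index": idx,
            "start_s": idx * ws,
            "end_s": (idx + 1) * ws,
            "label": [str(v) for v in labels],
        }
    )
    stamp = {"subject_id": labels.subject_id, **_params_stamp(params)}
    _write_csv(path, frame, stamp)


def read_labels_csv(path: Path | str) -> LabelSeries:
    frame = _read_csv(path, ["window_index", "start_s", "end_s", "label"])
    if len(frame) == 0:
        raise ValueError(f"{path}: no windows")
    ws = float(frame["end_s"].iloc[0] - frame["start_s"].iloc[0])
    labels = np.array([int(ActivityLabel.from_name(str(v))) for v in frame["label"]], dtype=np.int8)
    return LabelSeries(labels=labels, ws_seconds=ws, subject_id=Path(path).stem)


def write_transitions_csv(
    path: Path | str, transitions: TransitionSeries, ws_seconds: float, params: AlgorithmParams | None = None
) -> None:
    boundary = np.flatnonzero(transitions.flags == 1) + 1  # flag i covers boundary before window i
    frame = pd.DataFrame({"boundary_index": boundary, "time_s": boundary * ws_seconds})
    _write_csv(path, frame, _params_stamp(params))


def write_manifest_csv(path: Path | str, rows: Iterable[tuple[str, str, str]]) -> None:
    frame = pd.DataFrame(rows, columns=["subject_id", "accel_csv", "truth_csv"])
    _write_csv(path, frame)


def read_manifest_csv(path: Path | str) -> list[tuple[str, Path, Path]]:
    base = Path(path).parent
    frame = _read_csv(path, ["subject_id", "accel_csv", "truth_csv"])
    out = []
    for _, row in frame.iterrows():
        accel = base / str(row["accel_csv"])
        truth = base / str(row["truth_csv"])
        for p in (accel, truth):
            if not p.exists():
                raise FileNotFoundError(f"manifest {path}: referenced file {p} does not exist")
        out.append((str(row["subject_id"]), accel, truth))
    return out


def _clean(x: float) -> float | None:
    return None if isinstance(x, float) and math.isnan(x) else x


def report_to_dict(report: PerformanceReport) -> dict[str, Any]:
    return {
        "subject_id": report.subject_id,
        "ws_seconds": report.ws_seconds,
        "metrics": {
            cat: {m: _clean(report.rows[cat].get(m)) for m in METRIC_NAMES} for cat in CATEGORIES
        },
        "confusions": {
            cat: dataclasses.asdict(report.confusions[cat]) for cat in report.confusions
        },
        "reference_time_s": report.reference_time_s,
        "algorithm_time_s": report.algorithm_time_s,
        "reference_transitions": report.reference_transitions,
        "algorithm_transitions": report.algorithm_transitions,
    }


def summary_to_dict(summary: CohortSummary) -> dict[str, Any]:
    return {
        "n_subjects": summary.n_subjects,
        "metrics": {
            cat: {
                m: {
                    "median": _clean(q.median),
                    "q1": _clean(q.q1),
                    "q3": _clean(q.q3),
                    "n_defined": q.n_defined,
                    "acceptable": q.acceptable,
                }
                for m, q in summary.table[cat].items()
            }
            for cat in CATEGORIES
        },
    }


def write_report_json(
    path: Path | str,
    payload: dict[str, Any],
    params: AlgorithmParams | None = None,
    extra: dict[str, Any] | None = None,
) -> None:
    doc = {"generator": f"hfital {__version__}", "parameters": _params_stamp(params) or None}
    if extra:
        doc.update(extra)
    doc.update(payload)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


@dataclass
class RunConfig:
    """Validated run configuration (YAML key-value file).

    A commented template ships in ``examples/config.yaml``.
    """

    sample_rate_hz: float = 25.0
    axis_roles: AxisRoles = field(default_factory=AxisRoles)
    ws_seconds: float = 4.0
    pa_th_cps: float = 4.3
    so_th_g: float = 0.8
    variant: Variant = Variant.HFITAL
    counts_filter: CountsFilter = field(default_factory=CountsFilter)
    aggregate: str = "median"
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.variant = Variant(self.variant)
        if self.aggregate not in ("median", "mean"):
            raise ValueError("aggregate must be 'median' or 'mean'")
        # validate threshold ranges eagerly, before any computation
        self.params  # noqa: B018

    @property
    def params(self) -> AlgorithmParams:
        return AlgorithmParams(
            ws_seconds=self.ws_seconds, pa_th_cps=self.pa_th_cps, so_th_g=self.so_th_g, variant=self.variant
        )

    @classmethod
    def preset(cls, variant: Variant | str, **overrides: Any) -> "RunConfig":
        params = AlgorithmParams.hfital() if Variant(variant) is Variant.HFITAL else AlgorithmParams.moxal()
        return cls(
            ws_seconds=params.ws_seconds,
            pa_th_cps=params.pa_th_cps,
            so_th_g=params.so_th_g,
            variant=params.variant,
            **overrides,
        )


def load_config(path: Path | str) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    kwargs: dict[str, Any] = {}
    for key in ("sample_rate_hz", "ws_seconds", "pa_th_cps", "so_th_g", "variant", "aggregate", "offset_s"):
        if key in raw:
            kwargs[key] = raw[key]
    if "axis_roles" in raw:
        kwargs["axis_roles"] = AxisRoles(**raw["axis_roles"])
    if "counts_filter" in raw:
        kwargs["counts_filter"] = CountsFilter(**raw["counts_filter"])
    unknown = set(raw) - {
        "sample_rate_hz", "ws_seconds", "pa_th_cps", "so_th_g", "variant",
        "aggregate", "offset_s", "axis_roles", "counts_filter",
    }
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**kwargs)
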