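"""Grid search over window size and activity threshold.

The optimization procedure evaluates the full classification pipeline for
every (WS, PA Th) pair on a lattice — WS from 0.4 to 10 s in steps of 0.4 s
(25 values), PA Th from 2 to 6 cps in steps of 0.025 cps (161 values), 4025
combinations in total — holding the orientation threshold at 0.8 g.  Per grid
point the objective is the cohort aggregate (median by default) of each
subject's total-activity APE; the argmin defines the optimized parameters.

For speed the search factorizes what the pipeline recomputes redundantly:
the band-pass filter does not depend on WS, and window sums do not depend on
PA Th, so each recording is filtered once, windowed once per WS, and the 161
thresholds are swept over the cached per-window features.  The result is
bit-identical to running :func:`hfital.classify.run_pipeline` at every grid
point (asserted in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import ActivityLabel, LabelSeries
from .metrics import ReferenceEvents, total_error, windowize_reference
from .signal import (
    AccelRecording,
    AlgorithmParams,
    CountsFilter,
    DEFAULT_COUNTS_FILTER,
    VARIANT_COUNTS_MODE,
    Variant,
    rectified_activity,
    window_sample_count,
)

__all__ = ["ParameterGrid", "GridResult", "enumerate_grid", "optimize"]


@dataclass(frozen=True)
class ParameterGrid:
    """Lattice of (ws_seconds, pa_th_cps) pairs at a fixed SO Th.

    Values are generated as integer index × step so lattice points are
    reproducible to the last bit across runs.
    """

    ws_values: tuple[float, ...]
    pa_th_values: tuple[float, ...]
    so_th_g: float = 0.8

    @property
    def size(self) -> int:
        return len(self.ws_values) * len(self.pa_th_values)

    def combinations(self) -> list[tuple[float, float]]:
        """All (ws, pa_th) pairs in row-major order (ws outer, pa_th inner)."""
        return [(ws, pa) for ws in self.ws_values for pa in self.pa_th_values]


def enumerate_grid(
    ws_start: float = 0.4,
    ws_stop: float = 10.0,
    ws_step: float = 0.4,
    pa_start: float = 2.0,
    pa_stop: float = 6.0,
    pa_step: float = 0.025,
    so_th_g: float = 0.8,
) -> ParameterGrid:
    """The standard optimization lattice: 25 WS × 161 PA Th = 4025 points."""
    n_ws = int(round((ws_stop - ws_start) / ws_step)) + 1
    n_pa = int(round((pa_stop - pa_start) / pa_step)) + 1
    ws = tuple(ws_start + i * ws_step for i in range(n_ws))
    pa = tuple(pa_start + j * pa_step for j in range(n_pa))
    return ParameterGrid(ws_values=ws, pa_th_values=pa, so_th_g=so_th_g)


@dataclass
class GridResult:
    """Objective surface and argmin of a grid search.

    ``objective`` is (n_ws, n_pa); ``per_subject`` is (n_ws, n_pa,
    n_subjects) with NaN where a subject was too short for that window size.
    """

    grid: ParameterGrid
    variant: Variant
    objective: np.ndarray
    per_subject: np.ndarray
    best_params: AlgorithmParams
    best_objective: float

    def to_frame(self):
        """One row per grid point: ws, pa_th, objective (row-major order)."""
        import pandas as pd

        ws_idx, pa_idx = np.meshgrid(
            np.arange(len(self.grid.ws_values)), np.arange(len(self.grid.pa_th_values)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "ws_seconds": np.asarray(self.grid.ws_values)[ws_idx.ravel()],
                "pa_th_cps": np.asarray(self.grid.pa_th_values)[pa_idx.ravel()],
                "objective_total_ape_pct": self.objective.ravel(),
            }
        )


def _subject_total_ape(
    orient: np.ndarray,
    counts: np.ndarray,
    ref_counts: np.ndarray,
    variant: Variant,
    pa_th: float,
    so_th: float,
) -> float:
    """Total-activity APE of one subject at one grid point (times cancel WS)."""
    if variant is Variant.HFITAL:
        upright = orient >= so_th
        dyn = upright & (counts >= pa_th)
        stand = upright & ~dyn
    else:
        dyn = counts >= pa_th
        stand = ~dyn & (orient >= so_th)
    n_dyn = int(np.count_nonzero(dyn))
    n_stand = int(np.count_nonzero(stand))
    n_sed = orient.size - n_dyn - n_stand
    algo_counts = np.array([n_sed, n_stand, n_dyn], dtype=float)
    _, ape = total_error(ref_counts, algo_counts)
    return ape


def optimize(
    cohort: Sequence[tuple[AccelRecording, ReferenceEvents]],
    variant: Variant | str = Variant.HFITAL,
    grid: ParameterGrid | None = None,
    aggregate: str = "median",
    counts_filter: CountsFilter = DEFAULT_COUNTS_FILTER,
) -> GridResult:
    """Exhaustive grid search minimizing the cohort total-activity APE.

    Parameters
    ----------
    cohort
        (recording, reference events) pairs; every recording should cover at
        least one window at the largest WS — shorter subjects are excluded
        from the affected grid points with a warning.
    variant
        which decision tree / counts mode to optimize.
    grid
        lattice to search; defaults to the standard 4025-point grid.
    aggregate
        ``"median"`` (default, matching median-based reporting) or ``"mean"``.

    Ties in the objective resolve to the first grid point in row-major
    (ws, then pa_th) order.
    """
    if len(cohort) == 0:
        raise ValueError("optimize requires at least one subject")
    variant = Variant(variant)
    if grid is None:
        grid = enumerate_grid()
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    agg = np.nanmedian if aggregate == "median" else np.nanmean
    mode = VARIANT_COUNTS_MODE[variant]

    # Filter each recording once; WS and PA Th sweeps reuse the result.
    rects = [rectified_activity(rec, mode, counts_filter) for rec, _ in cohort]
    longs = [rec.axis("longitudinal") for rec, _ in cohort]

    n_ws, n_pa = len(grid.ws_values), len(grid.pa_th_values)
    per_subject = np.full((n_ws, n_pa, len(cohort)), np.nan)

    for wi, ws in enumerate(grid.ws_values):
        for si, (rec, events) in enumerate(cohort):
            win = window_sample_count(ws, rec.sample_rate_hz)
            n_windows = rec.n_samples // win
            if n_windows < 1:
                warnings.warn(
                    f"subject {rec.subject_id!r} ({rec.duration_s:.1f} s) is shorter than one "
                    f"{ws} s window; excluded at this grid point",
                    stacklevel=2,
                )
                continue
            used = n_windows * win
            orient = longs[si][:used].reshape(n_windows, win).mean(axis=1)
            counts = rects[si][:used].reshape(n_windows, win).sum(axis=1) / (win / rec.sample_rate_hz)
            ref_series = windowize_reference(events, ws, n_windows)
            ref_counts = np.array(
                [np.count_nonzero(ref_series.labels == int(lab)) for lab in ActivityLabel], dtype=float
            )
            for pi, pa in enumerate(grid.pa_th_values):
                per_subject[wi, pi, si] = _subject_total_ape(orient, counts, ref_counts, variant, pa, grid.so_th_g)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices where no subject fits
        objective = agg(per_subject, axis=2)
    flat = np.where(np.isfinite(objective.ravel()), objective.ravel(), np.inf)
    best_flat = int(np.argmin(flat))  # first minimum in row-major order
    bi, bj = divmod(best_flat, n_pa)
    best_params = AlgorithmParams(
        ws_seconds=grid.ws_values[bi],
        pa_th_cps=grid.pa_th_values[bj],
        so_th_g=grid.so_th_g,
        variant=variant,
    )
    return GridResult(
        grid=grid,
        variant=variant,
        objective=objective,
        per_subject=per_subject,
        best_params=best_params,
        best_objective=float(objective[bi, bj]),
    )
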