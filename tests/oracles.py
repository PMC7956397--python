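"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written as straight-line loops over the
mathematical definitions, sharing no code path with the package internals it
cross-checks.
"""

from __future__ import annotations

import numpy as np


# --- zero-phase Butterworth filtering, re-derived from the definition -------


def lfilter_zi_solve(b: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Steady-state initial conditions of the direct-form II transposed
    filter for a unit-step input, from the linear-system definition."""
    b = np.asarray(b, dtype=float) / a[0]
    a = np.asarray(a, dtype=float) / a[0]
    n = max(len(a), len(b))
    a = np.concatenate([a, np.zeros(n - len(a))])
    b = np.concatenate([b, np.zeros(n - len(b))])
    # companion matrix of a, transposed
    comp = np.zeros((n - 1, n - 1))
    comp[0, :] = -a[1:]
    comp[1:, :-1] = np.eye(n - 2)
    iminus = np.eye(n - 1) - comp.T
    rhs = b[1:] - a[1:] * b[0]
    return np.linalg.solve(iminus, rhs)


def lfilter_loop(b: np.ndarray, a: np.ndarray, x: np.ndarray, zi: np.ndarray) -> np.ndarray:
    """Direct-form II transposed difference equation, one sample at a time."""
    b = np.asarray(b, dtype=float) / a[0]
    a = np.asarray(a, dtype=float) / a[0]
    n = max(len(a), len(b))
    a = np.concatenate([a, np.zeros(n - len(a))])
    b = np.concatenate([b, np.zeros(n - len(b))])
    z = np.array(zi, dtype=float)
    y = np.empty_like(x, dtype=float)
    for m in range(len(x)):
        xm = x[m]
        ym = b[0] * xm + z[0]
        for i in range(n - 2):
            z[i] = b[i + 1] * xm + z[i + 1] - a[i + 1] * ym
        z[n - 2] = b[n - 1] * xm - a[n - 1] * ym
        y[m] = ym
    return y


def zero_phase_filter_loop(b: np.ndarray, a: np.ndarray, x: np.ndarray, padlen: int) -> np.ndarray:
    """Forward-backward filtering with odd-extension padding, by hand."""
    x = np.asarray(x, dtype=float)
    front = 2.0 * x[0] - x[padlen:0:-1]
    back = 2.0 * x[-1] - x[-2 : -padlen - 2 : -1]
    ext = np.concatenate([front, x, back])
    zi = lfilter_zi_solve(b, a)
    y = lfilter_loop(b, a, ext, zi * ext[0])
    y = y[::-1]
    y = lfilter_loop(b, a, y, zi * y[0])
    y = y[::-1]
    return y[padlen : len(y) - padlen]


def counts_oracle(ap_trace: np.ndarray, fs: float, start: int, stop: int, b: np.ndarray, a: np.ndarray) -> float:
    """Single-axis activity counts from the hand-rolled filter: rectify the
    zero-phase filtered trace, sum the window, divide by its duration."""
    padlen = min(3 * max(len(a), len(b)), len(ap_trace) - 1)
    filtered = zero_phase_filter_loop(b, a, ap_trace, padlen)
    total = 0.0
    for i in range(start, stop):
        total += abs(filtered[i])
    return total / ((stop - start) / fs)


# --- label-series metrics, by enumeration -----------------------------------


def confusion_loop(algo: list[int], ref: list[int], target: int) -> tuple[int, int, int, int]:
    tp = fp = tn = fn = 0
    for a, r in zip(algo, ref, strict=True):
        if a == target and r == target:
            tp += 1
        elif a == target and r != target:
            fp += 1
        elif a != target and r != target:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def transitions_loop(labels: list[int]) -> list[int]:
    """Adjacent-pair scan: 1 where sedentary (0) precedes standing/dynamic."""
    flags = []
    for prev, cur in zip(labels[:-1], labels[1:]):
        flags.append(1 if prev == 0 and cur != 0 else 0)
    return flags


def total_errors_loop(algo: list[int], ref: list[int], ws: float) -> tuple[float, float]:
    """Time-weighted pooled PE/APE from per-activity window tallies."""
    ref_t = {k: 0.0 for k in (0, 1, 2)}
    algo_t = {k: 0.0 for k in (0, 1, 2)}
    for r in ref:
        ref_t[r] += ws
    for a in algo:
        algo_t[a] += ws
    total = sum(ref_t.values())
    pe = sum(ref_t[k] - algo_t[k] for k in ref_t) / total * 100.0
    ape = sum(abs(ref_t[k] - algo_t[k]) for k in ref_t) / total * 100.0
    return pe, ape


def net_relabel_count(algo: list[int], ref: list[int]) -> int:
    """Minimum number of windows whose label must change to equalize the
    per-activity marginals: sum of positive per-class deficits."""
    deficit = 0
    for k in (0, 1, 2):
        deficit += max(0, sum(1 for r in ref if r == k) - sum(1 for a in algo if a == k))
    return deficit


def windowize_loop(labels, onsets, offsets, ws: float, n_windows: int) -> list[int]:
    """Majority label per window by fine-grained duration accumulation;
    ties toward the label covering the later part of the window."""
    out = []
    for w in range(n_windows):
        lo, hi = w * ws, (w + 1) * ws
        dur = {0: 0.0, 1: 0.0, 2: 0.0}
        last = {0: -1.0, 1: -1.0, 2: -1.0}
        for lab, on, off in zip(labels, onsets, offsets, strict=True):
            o = max(lo, on)
            f = min(hi, off)
            if f - o > 1e-12:
                dur[int(lab)] += f - o
                last[int(lab)] = max(last[int(lab)], f)
        top = max(dur.values())
        cands = [k for k in dur if dur[k] >= top - 1e-9]
        out.append(max(cands, key=lambda k: last[k]))
    return out


def quartiles_sorted(values: list[float]) -> tuple[float, float, float]:
    """Q1/median/Q3 by linear interpolation between order statistics."""
    xs = sorted(values)
    n = len(xs)

    def q(p: float) -> float:
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return q(0.25), q(0.5), q(0.75)
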