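"""Naive, loop-based reference evaluators used to cross-check the package.

These deliberately avoid the vectorized code paths: the spline fit is built
column-by-column from individual B-spline basis elements and solved with a
plain least-squares call; the aberration aggregation, ROC quantities and
threshold scans are explicit Python loops.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import BSpline


def spline_fit_naive(y, n_knots):
    """Least-squares cubic regression spline, built basis-element by element."""
    y = np.asarray(y, dtype=float)
    T = len(y)
    k = n_knots if T >= n_knots + 2 else max(3, T - 2)
    t = np.arange(T, dtype=float)
    knots = np.quantile(t, np.linspace(0.0, 1.0, k))
    full = np.concatenate(([knots[0]] * 3, knots, [knots[-1]] * 3))
    n_basis = len(full) - 4
    B = np.empty((T, n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        B[:, j] = BSpline(full, coef, 3)(t)
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    return B @ coef


def tram_naive(track, scales, params):
    """Explicit-loop evaluation of the aberration score.

    Returns (tau, argmax_time) with the same contract as compute_tram:
    mean-power aggregation over series per time point, max over time,
    smallest index on ties; zero-scale series skipped.
    """
    w = params.time_slice()
    columns = []  # list of (m, mhat, s) per included feature
    for name in params.features:
        s = scales.features[name]
        if s == 0.0:
            continue
        m = np.asarray(track.features[name])[w]
        columns.append((m, spline_fit_naive(m, params.n_knots), s))
    use_xy = params.use_euclidean_xy and scales.s_xy
    if use_xy:
        x = np.asarray(track.x)[w]
        y = np.asarray(track.y)[w]
        xhat = spline_fit_naive(x, params.n_knots)
        yhat = spline_fit_naive(y, params.n_knots)

    T = len(columns[0][0]) if columns else len(x)
    per_time = []
    for t in range(T):
        zs = []
        for m, mhat, s in columns:
            zs.append(abs(m[t] - mhat[t]) / s)
        if use_xy:
            zs.append(
                math.sqrt(
                    ((x[t] - xhat[t]) / scales.s_xy) ** 2
                    + ((y[t] - yhat[t]) / scales.s_xy) ** 2
                )
            )
        acc = 0.0
        for z in zs:
            acc += z**params.p
        per_time.append((acc / len(zs)) ** (1.0 / params.p))
    best_t = 0
    for t in range(1, T):
        if per_time[t] > per_time[best_t]:
            best_t = t
    offset = params.window[0] if params.window is not None else 0
    return per_time[best_t], offset + best_t, per_time


def auc_pairwise(scores, is_fail):
    """AUC as the exhaustive pass/fail pairwise count; ties score 1/2."""
    fails = [s for s, f in zip(scores, is_fail) if f]
    passes = [s for s, f in zip(scores, is_fail) if not f]
    total = 0.0
    for sf in fails:
        for sp in passes:
            if sf > sp:
                total += 1.0
            elif sf == sp:
                total += 0.5
    return total / (len(fails) * len(passes))


def youden_brute(scores, is_fail):
    """Exhaustive scan of every candidate threshold for max J.

    Candidates are midpoints between adjacent distinct scores plus +-inf
    sentinels; ties broken toward the larger threshold.
    """
    uniq = sorted(set(scores))
    candidates = [float("-inf")]
    for a, b in zip(uniq[:-1], uniq[1:]):
        candidates.append((a + b) / 2.0)
    candidates.append(float("inf"))

    n_fail = sum(is_fail)
    n_pass = len(is_fail) - n_fail
    best = None
    for thr in candidates:
        tp = sum(1 for s, f in zip(scores, is_fail) if f and s > thr)
        tn = sum(1 for s, f in zip(scores, is_fail) if not f and s <= thr)
        sens, spec = tp / n_fail, tn / n_pass
        j = sens + spec - 1.0
        if best is None or j >= best[0] - 1e-12:
            best = (j, thr, sens, spec)
    return best  # (J, threshold, sensitivity, specificity)
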