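"""Independent reference implementations used only to check the package.

Everything here is deliberately brute-force / long-hand and shares no code
with ``metapls``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def nipals_pls1(X: np.ndarray, y: np.ndarray, max_iter: int = 500, tol: float = 1e-12):
    """Single-component PLS1 via the classic NIPALS iteration.

    Returns (w, t, p, c) with w unit-norm.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    u = y.copy()
    t_old = None
    for _ in range(max_iter):
        w = X.T @ u / (u @ u)
        w = w / np.linalg.norm(w)
        t = X @ w
        c = y @ t / (t @ t)
        u = y * c / (c * c)
        if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
            break
        t_old = t
    p = X.T @ t / (t @ t)
    return w, t, p, c


def bh_step_up(p_values) -> np.ndarray:
    """Exhaustive Benjamini-Hochberg step-up, written long-hand."""
    p = list(map(float, p_values))
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = indexed[rank_from_top - 1]
        candidate = p[i] * m / rank_from_top
        running_min = min(running_min, candidate)
        adjusted[i] = min(running_min, 1.0)
    return np.asarray(adjusted)


def brute_force_correlation_edges(values: np.ndarray, names, r_threshold, p_threshold):
    """All-pairs double loop with scipy's pearsonr; returns {(a, b): (r, p)}."""
    out = {}
    n_mets = values.shape[1]
    for i in range(n_mets):
        for j in range(i + 1, n_mets):
            xi, xj = values[:, i], values[:, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r, p = stats.pearsonr(xi, xj)
            if abs(r) > r_threshold and p < p_threshold:
                out[(names[i], names[j])] = (r, p)
    return out


def sus_region_oracle(corr_a, corr_b, vip_a, vip_b, vip_cut, axis_deg, diag_deg, floor):
    """Point-by-point angular region test from the stated definitions."""
    if max(vip_a, vip_b) <= vip_cut:
        return None
    if abs(corr_a) < floor and abs(corr_b) < floor:
        return "unclassified"
    theta = math.degrees(math.atan2(corr_b, corr_a))

    def dist_to_line(angle):
        best = 360.0
        for ray in (angle, angle + 180.0):
            d = abs((theta - ray) % 360.0)
            best = min(best, d, 360.0 - d)
        return best

    if dist_to_line(45.0) <= diag_deg:
        return "shared_positive"
    if dist_to_line(-45.0) <= diag_deg:
        return "shared_negative"
    if dist_to_line(0.0) <= axis_deg and abs(corr_a) >= floor:
        return "unique_a"
    if dist_to_line(90.0) <= axis_deg and abs(corr_b) >= floor:
        return "unique_b"
    return "unclassified"
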