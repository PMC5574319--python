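"""Differential-metabolite evidence: S-plots, VIP, BH-adjusted fold changes."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from metapls.opls import OplsModel
from metapls.synthgen import MetaboliteTable

logger = logging.getLogger(__name__)

__all__ = [
    "SPlotPoint",
    "FoldChangeRecord",
    "splot",
    "vip",
    "bh_adjust",
    "fold_change_table",
    "marker_table",
]


@dataclass(frozen=True)
class SPlotPoint:
    """One variable's S-plot coordinates.

    ``cov`` is the covariance of the predictive score with the centered
    variable; ``corr`` the corresponding Pearson correlation.  Reliable
    high-magnitude markers sit far from the origin in the upper-right or
    lower-left quadrant.
    """

    variable: str
    cov: float
    corr: float


@dataclass(frozen=True)
class FoldChangeRecord:
    metabolite: str
    fold_change: float
    raw_p: float
    adjusted_p: float


def splot(model: OplsModel, X_centered: np.ndarray) -> list[SPlotPoint]:
    """S-plot coordinates cov(t_p, x_j) and corr(t_p, x_j) for each variable.

    ``X_centered`` must be column-centered and aligned with the model's
    variables.  Zero-variance variables are omitted with a warning (their
    correlation is undefined).
    """
    X = np.asarray(X_centered, dtype=float)
    t = model.scores_pred
    if X.ndim != 2 or X.shape[0] != len(t):
        raise ValueError("X_centered must have one row per model sample")
    if X.shape[1] != len(model.weights_pred):
        raise ValueError("X_centered must have the model's variables as columns")
    names = model.var_names or tuple(f"var{j + 1}" for j in range(X.shape[1]))

    n = len(t)
    cov = (t @ X) / (n - 1)
    sd_t = t.std(ddof=1)
    sd_x = X.std(axis=0, ddof=1)
    points: list[SPlotPoint] = []
    n_skipped = 0
    for j, name in enumerate(names):
        if sd_x[j] == 0:
            n_skipped += 1
            continue
        points.append(
            SPlotPoint(variable=name, cov=float(cov[j]), corr=float(cov[j] / (sd_t * sd_x[j])))
        )
    if n_skipped:
        logger.warning("splot: omitted %d zero-variance variable(s)", n_skipped)
    return points


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive component.

    Squared weights are scaled by the number of variables so the VIP scores
    have mean square 1; VIP > 1 is the conventional selection cut.  With a
    single predictive component the explained-class-variance weighting
    cancels and VIP reduces to ``sqrt(p) * |w| / ||w||``.
    """
    w = model.weights_pred
    ss_w = float(w @ w)
    if ss_w <= 0 or model.c_pred == 0 or float(model.scores_pred @ model.scores_pred) <= 0:
        raise ValueError("degenerate model: predictive component explains no variance")
    p = len(w)
    return np.sqrt(p * w**2 / ss_w)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def fold_change_table(
    table: MetaboliteTable,
    group_a: str,
    group_ref: str,
    equal_var: bool = False,
) -> list[FoldChangeRecord]:
    """Per-metabolite fold change of ``group_a`` relative to ``group_ref``.

    Fold change is the ratio of group means; raw p-values come from a
    two-sided two-sample t-test (Welch by default, pooled with
    ``equal_var=True``); adjusted p-values are BH step-up over the whole
    table.
    """
    mask_a = table.group_mask(group_a)
    mask_r = table.group_mask(group_ref)
    for name, mask in ((group_a, mask_a), (group_ref, mask_r)):
        if mask.sum() < 2:
            raise ValueError(f"group {name!r} needs at least 2 samples")
    a = table.values[mask_a]
    r = table.values[mask_r]
    mean_r = r.mean(axis=0)
    zero = np.flatnonzero(mean_r == 0)
    if zero.size:
        bad = table.metabolite_names[zero[0]]
        raise ValueError(f"zero reference mean for metabolite {bad!r}")
    fc = a.mean(axis=0) / mean_r
    res = stats.ttest_ind(a, r, axis=0, equal_var=equal_var)
    raw_p = np.clip(np.asarray(res.pvalue, dtype=float), np.finfo(float).tiny, 1.0)
    adj = bh_adjust(raw_p)
    return [
        FoldChangeRecord(metabolite=m, fold_change=float(f), raw_p=float(p), adjusted_p=float(q))
        for m, f, p, q in zip(table.metabolite_names, fc, raw_p, adj)
    ]


def marker_table(
    model: OplsModel,
    X_centered: np.ndarray,
    table: MetaboliteTable,
    group_a: str,
    group_ref: str,
    corr_cut: float = 0.6,
    vip_cut: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combined marker evidence table.

    Columns: metabolite, cov, corr, vip, fold_change, raw_p, adjusted_p,
    selected.  ``selected`` applies the default cut
    ``|corr| >= corr_cut and vip > vip_cut and adjusted_p < alpha``
    (all three thresholds configurable).  The |corr| column doubles as the
    loading-plot color encoding.
    """
    points = {pt.variable: pt for pt in splot(model, X_centered)}
    vips = vip(model)
    names = model.var_names or tuple(f"var{j + 1}" for j in range(len(vips)))
    fc = {rec.metabolite: rec for rec in fold_change_table(table, group_a, group_ref)}

    rows = []
    for j, name in enumerate(names):
        pt = points.get(name)
        rec = fc.get(name)
        if pt is None or rec is None:
            continue
        selected = (
            abs(pt.corr) >= corr_cut and vips[j] > vip_cut and rec.adjusted_p < alpha
        )
        rows.append(
            {
                "metabolite": name,
                "cov": pt.cov,
                "corr": pt.corr,
                "abs_corr": abs(pt.corr),
                "vip": float(vips[j]),
                "fold_change": rec.fold_change,
                "raw_p": rec.raw_p,
                "adjusted_p": rec.adjusted_p,
                "selected": selected,
            }
        )
    return pd.DataFrame(rows)
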