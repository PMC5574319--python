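"""Two-class OPLS-DA: fitting, cross-validation, permutation validation.

The decomposition follows the standard orthogonal-projections scheme:
components of X-variation orthogonal to the class vector are extracted and
deflated one at a time, then a single predictive PLS component is fitted on
the deflated matrix.  With ``n_orthogonal=0`` the fit reduces exactly to
single-component PLS-DA.

Sign convention: the predictive score is flipped, if necessary, so that the
alphabetically second class has positive mean score.  All outputs are stable
under class relabeling up to this convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "OplsModel",
    "CrossValidationResult",
    "PermutationResult",
    "fit_opls_da",
    "cross_validate",
    "permutation_validation",
    "encode_labels",
]


def encode_labels(labels: Sequence[str]) -> tuple[np.ndarray, dict[str, int]]:
    """Encode a two-class label vector as -1/+1 (alphabetical order).

    Raises if there are not exactly two classes or either class is a
    singleton.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    encoding = {classes[0]: -1, classes[1]: 1}
    y = np.asarray([encoding[l] for l in labels], dtype=float)
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    return y, encoding


@dataclass
class OplsModel:
    """Fitted two-class OPLS-DA decomposition.

    Scores/weights/loadings of the predictive component are 1-D arrays;
    orthogonal quantities are stacked with one row per orthogonal component.
    """

    weights_pred: np.ndarray  # (p,), unit norm
    loadings_pred: np.ndarray  # (p,)
    scores_pred: np.ndarray  # (n,)
    c_pred: float  # response loading
    weights_orth: np.ndarray  # (k, p)
    loadings_orth: np.ndarray  # (k, p)
    scores_orth: np.ndarray  # (n, k)
    n_orthogonal: int
    r2x: float
    r2x_pred: float
    r2x_orth: float
    r2y: float
    q2: float | None
    class_encoding: dict[str, int]
    labels: tuple[str, ...]
    y_mean: float
    var_names: tuple[str, ...] | None = None
    column_statistics: dict = field(default_factory=dict)

    @property
    def classes(self) -> tuple[str, str]:
        inv = {v: k for k, v in self.class_encoding.items()}
        return (inv[-1], inv[1])

    def remove_orthogonal(self, X: np.ndarray) -> np.ndarray:
        """Filter class-orthogonal variation out of new (centered) data."""
        Xc = np.asarray(X, dtype=float).copy()
        for k in range(self.n_orthogonal):
            t_o = Xc @ self.weights_orth[k]
            Xc -= np.outer(t_o, self.loadings_orth[k])
        return Xc

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores for new (centered) data."""
        return self.remove_orthogonal(X) @ self.weights_pred

    def predict_response(self, X: np.ndarray) -> np.ndarray:
        """Predicted (uncentered) -1/+1 response for new centered data."""
        return self.transform(X) * self.c_pred + self.y_mean

    def predict_class(self, X: np.ndarray) -> list[str]:
        inv = {v: k for k, v in self.class_encoding.items()}
        return [inv[1] if v >= 0 else inv[-1] for v in self.predict_response(X)]

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "class_encoding": self.class_encoding,
            "n_orthogonal": self.n_orthogonal,
            "r2x": self.r2x,
            "r2x_pred": self.r2x_pred,
            "r2x_orth": self.r2x_orth,
            "r2y": self.r2y,
            "q2": self.q2,
            "y_mean": self.y_mean,
            "weights_pred": self.weights_pred.tolist(),
            "loadings_pred": self.loadings_pred.tolist(),
            "scores_pred": self.scores_pred.tolist(),
            "c_pred": self.c_pred,
            "weights_orth": self.weights_orth.tolist(),
            "loadings_orth": self.loadings_orth.tolist(),
            "scores_orth": self.scores_orth.tolist(),
            "labels": list(self.labels),
            "var_names": list(self.var_names) if self.var_names else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _extract_orthogonal(X: np.ndarray, w: np.ndarray):
    """One orthogonal component of ``X`` with respect to predictive weights ``w``."""
    t = X @ w
    p = X.T @ t / (t @ t)
    w_o = p - (w @ p) * w
    norm = np.linalg.norm(w_o)
    if norm < 1e-12:
        return None
    w_o = w_o / norm
    t_o = X @ w_o
    p_o = X.T @ t_o / (t_o @ t_o)
    return w_o, t_o, p_o


def fit_opls_da(
    X: np.ndarray,
    labels: Sequence[str],
    n_orthogonal: int = 1,
    var_names: Sequence[str] | None = None,
    column_statistics: dict | None = None,
) -> OplsModel:
    """Fit a two-class OPLS-DA model on a column-centered matrix.

    Parameters
    ----------
    X
        Column-centered (optionally scaled) samples x variables matrix.
    labels
        Two-class label vector, one entry per row of ``X``.
    n_orthogonal
        Number of class-orthogonal components to remove before the single
        predictive component; must be below ``rank(X)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    y_enc, encoding = encode_labels(labels)
    if len(y_enc) != X.shape[0]:
        raise ValueError("labels length must match number of rows of X")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be non-negative")
    rank = np.linalg.matrix_rank(X)
    if n_orthogonal >= rank:
        raise ValueError(f"n_orthogonal={n_orthogonal} must be < rank(X)={rank}")

    y_mean = float(y_enc.mean())
    y = y_enc - y_mean
    ss_x_total = float((X**2).sum())
    ss_y_total = float((y**2).sum())

    Xd = X.copy()
    w_orth, t_orth, p_orth = [], [], []
    for _ in range(n_orthogonal):
        w = Xd.T @ y
        w_norm = np.linalg.norm(w)
        if w_norm < 1e-12:
            raise ValueError("class vector carries no X covariance; cannot fit")
        w = w / w_norm
        comp = _extract_orthogonal(Xd, w)
        if comp is None:
            break
        w_o, t_o, p_o = comp
        Xd = Xd - np.outer(t_o, p_o)
        w_orth.append(w_o)
        t_orth.append(t_o)
        p_orth.append(p_o)

    # predictive PLS component on the deflated matrix
    w = Xd.T @ y
    w_norm = np.linalg.norm(w)
    if w_norm < 1e-12:
        raise ValueError("class vector carries no X covariance; cannot fit")
    w = w / w_norm
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = float(y @ t / (t @ t))

    # sign convention: positive mean score for the alphabetically second class
    pos_mask = y_enc > 0
    if t[pos_mask].mean() < 0:
        w, t, p, c = -w, -t, -p, -c

    k = len(w_orth)
    W_o = np.vstack(w_orth) if k else np.zeros((0, X.shape[1]))
    P_o = np.vstack(p_orth) if k else np.zeros((0, X.shape[1]))
    T_o = np.column_stack(t_orth) if k else np.zeros((X.shape[0], 0))

    ss_pred = float((np.outer(t, p) ** 2).sum())
    ss_orth = float(sum((np.outer(t_o, p_o) ** 2).sum() for t_o, p_o in zip(t_orth, p_orth)))
    resid = y - t * c
    r2y = 1.0 - float((resid**2).sum()) / ss_y_total

    return OplsModel(
        weights_pred=w,
        loadings_pred=p,
        scores_pred=t,
        c_pred=c,
        weights_orth=W_o,
        loadings_orth=P_o,
        scores_orth=T_o,
        n_orthogonal=k,
        r2x=(ss_pred + ss_orth) / ss_x_total if ss_x_total > 0 else 0.0,
        r2x_pred=ss_pred / ss_x_total if ss_x_total > 0 else 0.0,
        r2x_orth=ss_orth / ss_x_total if ss_x_total > 0 else 0.0,
        r2y=r2y,
        q2=None,
        class_encoding=encoding,
        labels=tuple(str(l) for l in labels),
        y_mean=y_mean,
        var_names=tuple(var_names) if var_names is not None else None,
        column_statistics=column_statistics or {},
    )


def _q2_cv(
    X: np.ndarray,
    labels: np.ndarray,
    n_orthogonal: int,
    folds: int,
    seed: int,
) -> float:
    """Stratified k-fold Q^2 = 1 - PRESS/TSS for one component count.

    Column centering is re-estimated inside each training fold (no leakage);
    test rows are centered with the training means before prediction.
    """
    y_enc, _ = encode_labels(labels)
    tss = float(((y_enc - y_enc.mean()) ** 2).sum())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    for train_idx, test_idx in skf.split(X, labels):
        train_labels = labels[train_idx]
        if len(set(train_labels.tolist())) < 2:
            raise ValueError("cross-validation fold left a training class empty")
        mu = X[train_idx].mean(axis=0)
        model = fit_opls_da(X[train_idx] - mu, train_labels, n_orthogonal)
        y_hat = model.predict_response(X[test_idx] - mu)
        press += float(((y_enc[test_idx] - y_hat) ** 2).sum())
    return 1.0 - press / tss


@dataclass(frozen=True)
class CrossValidationResult:
    n_orthogonal: int
    q2: float
    q2_per_candidate: tuple[float, ...]
    folds: int


def cross_validate(
    X: np.ndarray,
    labels: Sequence[str],
    folds: int = 7,
    max_orthogonal: int = 3,
    seed: int = 0,
) -> CrossValidationResult:
    """Choose the orthogonal-component count by stratified k-fold Q^2.

    The chosen model is the smallest ``n_orthogonal`` whose Q^2 is within
    0.01 of the maximum over candidates 0..max_orthogonal (parsimony rule).
    Candidates that exceed the rank of a training fold are skipped.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    counts = [int((labels == c).sum()) for c in sorted(set(labels.tolist()))]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > min(counts):
        raise ValueError(
            f"folds={folds} exceeds the smallest class size {min(counts)}; "
            "a fold would leave a training class empty or a test fold unstratified"
        )
    q2s: list[float] = []
    for k in range(max_orthogonal + 1):
        try:
            q2s.append(_q2_cv(X, labels, k, folds, seed))
        except ValueError:
            break
    if not q2s:
        raise ValueError("no candidate component count could be cross-validated")
    best = max(q2s)
    chosen = next(i for i, q in enumerate(q2s) if q >= best - 0.01)
    return CrossValidationResult(
        n_orthogonal=chosen, q2=q2s[chosen], q2_per_candidate=tuple(q2s), folds=folds
    )


@dataclass(frozen=True)
class PermutationResult:
    """Scatter of permuted-model statistics against label correlation."""

    n_permutations: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: tuple[float, ...]
    permuted_q2: tuple[float, ...]
    label_correlations: tuple[float, ...]
    r2y_intercept: float
    q2_intercept: float

    @property
    def q2_empirical_p(self) -> float:
        """Rank-based p of the observed Q^2 among the permuted null set."""
        n_ge = sum(1 for q in self.permuted_q2 if q >= self.observed_q2)
        return (1 + n_ge) / (1 + self.n_permutations)

    def to_table(self):
        import pandas as pd

        rows = [
            {"label_correlation": 1.0, "r2y": self.observed_r2y, "q2": self.observed_q2,
             "kind": "observed"}
        ]
        for r, r2, q2 in zip(self.label_correlations, self.permuted_r2y, self.permuted_q2):
            rows.append({"label_correlation": r, "r2y": r2, "q2": q2, "kind": "permuted"})
        return pd.DataFrame(rows)


def _ols_intercept(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept)


def permutation_validation(
    X: np.ndarray,
    labels: Sequence[str],
    n_permutations: int = 2000,
    folds: int = 7,
    n_orthogonal: int = 1,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation validation of R2Y and Q^2.

    For each permuted label vector (drawn uniformly, never equal to the true
    labeling) the model is refitted and R2Y, Q^2 and the Pearson correlation
    between the permuted and true encoded class vectors are recorded.  Also
    fits the two OLS lines of R2Y and Q^2 on the absolute label correlation
    (observed point at correlation 1 included) and reports their intercepts.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    y_true, _ = encode_labels(labels)
    rng = np.random.default_rng(seed)

    observed = fit_opls_da(X, labels, n_orthogonal)
    observed_q2 = _q2_cv(X, labels, n_orthogonal, folds, seed)

    perm_r2y: list[float] = []
    perm_q2: list[float] = []
    corrs: list[float] = []
    for i in range(n_permutations):
        while True:
            perm = rng.permutation(len(labels))
            perm_labels = labels[perm]
            if not np.array_equal(perm_labels, labels):
                break
        y_perm = y_true[perm]
        r = float(np.corrcoef(y_perm, y_true)[0, 1])
        model = fit_opls_da(X, perm_labels, n_orthogonal)
        q2 = _q2_cv(X, perm_labels, n_orthogonal, folds, seed + i + 1)
        perm_r2y.append(model.r2y)
        perm_q2.append(q2)
        corrs.append(r)

    xs = np.abs(np.asarray(corrs + [1.0]))
    r2y_int = _ols_intercept(xs, np.asarray(perm_r2y + [observed.r2y]))
    q2_int = _ols_intercept(xs, np.asarray(perm_q2 + [observed_q2]))
    return PermutationResult(
        n_permutations=n_permutations,
        observed_r2y=observed.r2y,
        observed_q2=observed_q2,
        permuted_r2y=tuple(perm_r2y),
        permuted_q2=tuple(perm_q2),
        label_correlations=tuple(corrs),
        r2y_intercept=r2y_int,
        q2_intercept=q2_int,
    )
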