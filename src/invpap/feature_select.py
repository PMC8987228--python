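"""SVM-based recursive feature elimination with an RBF kernel.

An RBF-kernel maximum-margin classifier has no primal weight vector, so
features are scored by how much the kernel-space margin objective
``W^2 = sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j)`` changes when the
feature is removed from the kernel, holding the dual coefficients fixed
(the standard nonlinear extension of RFE).  The lowest-scoring fraction
of features is dropped each round; a cross-validated error rate is
recorded at every retained panel size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .abundance import AbundanceMatrix
from .errors import ValidationError

logger = logging.getLogger("invpap")


@dataclass
class FeatureRanking:
    """Best-first feature order with its cross-validated error curve."""

    ordered_proteins: list[str]
    error_curve: dict[int, float]
    chosen_panel_size: int
    cv_folds: int
    seed: int
    group_a: str = ""
    group_b: str = ""

    def as_frame(self) -> pd.DataFrame:
        sizes = sorted(self.error_curve)
        rows = []
        for rank, pid in enumerate(self.ordered_proteins, start=1):
            size = next((s for s in sizes if s >= rank), None)
            rows.append(
                {
                    "protein": pid,
                    "ml_rank": rank,
                    "panel_member": rank <= self.chosen_panel_size,
                    "cv_error_at_size": self.error_curve.get(size, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _standardize(X: np.ndarray, mean: np.ndarray | None = None, scale: np.ndarray | None = None):
    if mean is None:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
    safe = np.where(scale > 0, scale, 1.0)
    return (X - mean) / safe, mean, scale


def _gamma(X: np.ndarray) -> float:
    v = X.var()
    return 1.0 / (X.shape[1] * v) if v > 0 else 1.0


def _rfe_scores(X: np.ndarray, y: np.ndarray, C: float, g: float) -> np.ndarray:
    """|change in W^2| when each feature is removed, dual coefficients fixed."""
    svc = SVC(C=C, kernel="rbf", gamma=g)
    svc.fit(X, y)
    a = svc.dual_coef_[0]  # alpha_i * y_i over support vectors
    S = X[svc.support_]
    K = rbf_kernel(S, gamma=g)
    w2 = a @ K @ a
    # removing feature f multiplies K entries by exp(gamma * (x_if - x_jf)^2)
    diff2 = (S[:, None, :] - S[None, :, :]) ** 2  # (n_sv, n_sv, p)
    Kf = K[:, :, None] * np.exp(g * diff2)
    w2_without = np.einsum("i,ijf,j->f", a, Kf, a)
    return np.abs(w2 - w2_without)


def _cv_error(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int, C: float
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = 0
    for train, test in skf.split(X, y):
        Xtr, mean, scale = _standardize(X[train])
        Xte, _, _ = _standardize(X[test], mean, scale)
        svc = SVC(C=C, kernel="rbf", gamma=_gamma(Xtr))
        svc.fit(Xtr, y[train])
        errors += int((svc.predict(Xte) != y[test]).sum())
    return errors / len(y)


def svm_rfe_rank(
    m: AbundanceMatrix,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    cv_folds: int = 5,
    seed: int = 0,
    drop_fraction: float = 0.1,
    C: float = 1.0,
) -> FeatureRanking:
    """Rank proteins by RBF-kernel recursive elimination between two groups.

    Each round trains the classifier on standardized features, scores each
    remaining feature by the margin-objective change on its removal, and
    drops the lowest-scoring ``drop_fraction`` (at least one).  The
    stratified cross-validated error rate is recorded at every panel size
    visited; features are standardized inside each training fold only.
    """
    if not m.is_complete():
        raise ValidationError("feature selection requires a complete matrix")
    cols_a = [s for s in m.sample_ids if groups.get(s) == group_a]
    cols_b = [s for s in m.sample_ids if groups.get(s) == group_b]
    if not cols_a or not cols_b:
        raise ValidationError("both classes must be non-empty")
    cols = cols_a + cols_b
    X_full = m.data[cols].to_numpy(dtype=float).T  # samples x proteins
    y = np.array([1] * len(cols_a) + [0] * len(cols_b))
    n_min = min(len(cols_a), len(cols_b))
    folds = cv_folds
    if n_min < folds:
        folds = max(2, n_min)
        logger.warning("reducing CV folds to %d (smallest class has %d samples)", folds, n_min)

    proteins = m.protein_ids
    Xs, _, _ = _standardize(X_full)
    # the kernel width is set once on the full standardized feature set and
    # held fixed through the elimination rounds; letting it grow as 1/p
    # overfits the shrinking panels and buries redundant informative features
    g = _gamma(Xs)
    remaining = list(range(len(proteins)))
    eliminated: list[int] = []
    sizes = [len(remaining)]
    while len(remaining) > 1:
        scores = _rfe_scores(Xs[:, remaining], y, C, g)
        n_drop = max(1, int(round(drop_fraction * len(remaining))))
        # exactly tied scores (e.g. duplicated columns) leave together so
        # interchangeable features end up with adjacent ranks
        order_idx = np.argsort(scores, kind="stable")
        cut = scores[order_idx[n_drop - 1]]
        n_drop = int((scores <= cut).sum())
        n_drop = min(n_drop, len(remaining) - 1)
        worst = order_idx[:n_drop]
        eliminated.extend(remaining[i] for i in sorted(worst, key=lambda i: (scores[i], i)))
        keep = set(worst)
        remaining = [f for i, f in enumerate(remaining) if i not in keep]
        sizes.append(len(remaining))
    ordered_idx = remaining + eliminated[::-1]

    error_curve: dict[int, float] = {}
    for s in sizes:
        error_curve[s] = _cv_error(X_full[:, ordered_idx[:s]], y, folds, seed, C)
    best = min(error_curve.values())
    chosen = min(s for s, e in error_curve.items() if e == best)
    return FeatureRanking(
        ordered_proteins=[proteins[i] for i in ordered_idx],
        error_curve=error_curve,
        chosen_panel_size=chosen,
        cv_folds=folds,
        seed=seed,
        group_a=group_a,
        group_b=group_b,
    )


def choose_panel(r: FeatureRanking) -> list[str]:
    """Smallest panel achieving the minimum cross-validated error."""
    if not r.error_curve:
        raise ValidationError("empty error curve")
    best = min(r.error_curve.values())
    k = min(s for s, e in r.error_curve.items() if e == best)
    return r.ordered_proteins[:k]


def shortlist_candidates(
    r: FeatureRanking, ttest: pd.DataFrame, k: int = 5
) -> list[str]:
    """Combine the machine-learning order with the t-test FDR order.

    Panel members are scored by the unweighted sum of their rank in the
    elimination order and their rank by ascending q-value; the ``k``
    best-scoring proteins are returned (ties by q-value then id).
    """
    panel = choose_panel(r)
    if k < 1:
        raise ValidationError("k must be >= 1")
    q = ttest.set_index("protein")["q_value"]
    missing = [p for p in panel if p not in q.index]
    if missing:
        raise ValidationError(f"panel proteins missing from t-test results: {missing}")
    ml_rank = {p: i for i, p in enumerate(panel)}
    by_q = sorted(panel, key=lambda p: (q[p], p))
    q_rank = {p: i for i, p in enumerate(by_q)}
    scored = sorted(panel, key=lambda p: (ml_rank[p] + q_rank[p], q[p], p))
    if k > len(panel):
        logger.warning("shortlist k=%d exceeds panel size %d; returning whole panel", k, len(panel))
        return scored
    return scored[:k]
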