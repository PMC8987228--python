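"""Immunohistochemistry validation statistics.

Per-specimen H-scores from per-cell intensity bins, Mann-Whitney group
comparison, AUROC with a test against the no-discrimination value 0.5,
the Youden-optimal diagnostic cutoff, and Clopper-Pearson exact binomial
confidence intervals for sensitivity and specificity.

The H-score of a specimen is ``1*(% cells 1+) + 2*(% cells 2+) +
3*(% cells 3+)`` with all detected cells (including intensity 0) in the
denominator, ranging from 0 (all negative) to 300 (all strongly
positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

CELL_COLUMNS = ["specimen_id", "diagnosis", "intensity_bin"]
ALLOWED_BINS = (0, 1, 2, 3)


@dataclass
class HScoreResult:
    specimen_id: str
    diagnosis: str
    h_score: float


@dataclass
class RocResult:
    auc: float
    se: float
    p_value: float
    cutoff: float
    sensitivity: float          # percent
    specificity: float          # percent
    sens_ci: tuple[float, float]  # percent
    spec_ci: tuple[float, float]  # percent
    n_positive: int
    n_negative: int


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell detection CSV (specimen_id, diagnosis, intensity_bin)."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    bad = set(df["intensity_bin"].unique()) - set(ALLOWED_BINS)
    if bad:
        raise ValidationError(f"{path}: intensity bins outside {ALLOWED_BINS}: {sorted(bad)}")
    return df[CELL_COLUMNS]


def compute_hscore(bins: Sequence[int]) -> float:
    """H-score of one specimen from its per-cell intensity bins."""
    arr = np.asarray(bins)
    if arr.size == 0:
        raise ValidationError("specimen has no cells")
    if not np.isin(arr, ALLOWED_BINS).all():
        raise ValidationError(f"intensity bins must be in {ALLOWED_BINS}")
    pct = np.array([(arr == b).mean() * 100.0 for b in (1, 2, 3)])
    return float(pct @ np.array([1.0, 2.0, 3.0]))


def hscores_by_specimen(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen H-scores with diagnosis labels from a cell table."""
    if cells.empty:
        raise ValidationError("empty cell table")
    rows = []
    for (spec, diag), grp in cells.groupby(["specimen_id", "diagnosis"], sort=True):
        rows.append(
            {
                "specimen_id": spec,
                "diagnosis": diag,
                "n_cells": len(grp),
                "h_score": compute_hscore(grp["intensity_bin"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)


def mannwhitney_compare(
    scores: Sequence[float], labels: Sequence[str], group_a: str, group_b: str
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two labelled groups.

    Uses the exact distribution when the smaller group has <= 8
    observations and there are no ties, else the tie-corrected normal
    approximation with continuity correction.  Returns (U of ``group_a``,
    two-sided p).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    a = scores[labels == group_a]
    b = scores[labels == group_b]
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(res.pvalue)


def _auc_mann_whitney(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC as the normalized count of (positive > negative) pairs, ties 1/2."""
    pos = scores[positive]
    neg = scores[~positive]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * equal) / (pos.size * neg.size)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _delong_se(scores: np.ndarray, positive: np.ndarray) -> float:
    pos = scores[positive]
    neg = scores[~positive]
    # placement values
    v10 = np.array([( (p > neg).sum() + 0.5 * (p == neg).sum() ) / neg.size for p in pos])
    v01 = np.array([( (pos > n).sum() + 0.5 * (pos == n).sum() ) / pos.size for n in neg])
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    return math.sqrt(max(var, 0.0))


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str,
    se_method: str = "hanley-mcneil",
) -> tuple[float, float, float]:
    """AUROC with a two-sided test against AUC = 0.5.

    The AUC is the Mann-Whitney estimator (ties count 1/2).  The standard
    error follows Hanley & McNeil by default (DeLong available); when the
    observed SE degenerates to zero (perfect separation) the null-variance
    SE is used for the test so the p-value stays defined.
    Returns (auc, se, p_value).
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(labels) == positive_label
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    auc = float(_auc_mann_whitney(scores, positive))
    if se_method == "hanley-mcneil":
        se = _hanley_mcneil_se(auc, n_pos, n_neg)
    elif se_method == "delong":
        se = _delong_se(scores, positive)
    else:
        raise ValidationError(f"unknown se_method {se_method!r}")
    se_test = se if se > 0 else math.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
    z = (auc - 0.5) / se_test
    p = 2 * stats.norm.sf(abs(z))
    return auc, se, float(p)


def youden_cutoff(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str,
    positives_higher: bool = True,
) -> tuple[float, float, float]:
    """Youden-optimal threshold with its sensitivity and specificity (%).

    Candidate thresholds are midpoints between adjacent distinct scores;
    the one maximizing sensitivity + specificity - 1 is chosen, ties going
    to the lower threshold.  With ``positives_higher`` a specimen is
    called positive when its score is >= the threshold (< when False).
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(labels) == positive_label
    if positive.all() or not positive.any():
        raise ValidationError("both classes must be present")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValidationError("constant scores: cutoff undefined")
    thresholds = (distinct[:-1] + distinct[1:]) / 2
    best = (-np.inf, None, None, None)
    for thr in thresholds:
        called_pos = scores >= thr if positives_higher else scores < thr
        sens = (called_pos & positive).sum() / positive.sum()
        spec = (~called_pos & ~positive).sum() / (~positive).sum()
        j = sens + spec - 1
        if j > best[0]:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    return float(thr), float(sens * 100), float(spec * 100)


def exact_binomial_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval, in percent.

    The bounds come from beta-distribution quantiles; the lower bound is 0
    when ``successes`` is 0 and the upper is 100 when ``successes == n``.
    Values are returned unrounded — round only at presentation.
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValidationError(f"invalid counts: {successes} of {n}")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    alpha = 1 - level
    lower = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    upper = 100.0 if successes == n else 100 * stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    return float(100 * lower if successes else 0.0), float(upper)


def ihc_validation_report(
    hscores: pd.DataFrame,
    positive_label: str = "IUP",
    negative_label: str = "PUC_inverted",
    level: float = 0.95,
) -> RocResult:
    """Full validation-cohort analysis from a per-specimen H-score table."""
    scores = hscores["h_score"].to_numpy()
    labels = hscores["diagnosis"].to_numpy()
    auc, se, p = roc_auc(scores, labels, positive_label)
    cutoff, sens, spec = youden_cutoff(scores, labels, positive_label)
    positive = labels == positive_label
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    tp = round(sens / 100 * n_pos)
    tn = round(spec / 100 * n_neg)
    return RocResult(
        auc=auc,
        se=se,
        p_value=p,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        sens_ci=exact_binomial_ci(tp, n_pos, level),
        spec_ci=exact_binomial_ci(tn, n_neg, level),
        n_positive=n_pos,
        n_negative=n_neg,
    )
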