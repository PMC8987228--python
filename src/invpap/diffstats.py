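"""Permutation-based differential expression statistics.

Implements the SAM-style testing scheme used throughout the discovery
stage: a Welch-type two-group statistic (optionally moderated by an
additive fudge factor ``s0`` in the denominator) or a one-way F statistic,
with p-values and false-discovery-rate q-values estimated from label
permutations rather than from parametric null distributions.

Conventions
-----------
* The same set of label permutations is applied to every protein in a
  permutation round (row-wise exchangeability).
* Two-sided permutation p-value with the add-one rule:
  ``p = (1 + #{|perm stat| >= |observed|}) / (1 + B)`` — never zero.
* q-values: for each |statistic| threshold, the median over permutations
  of the number of permuted statistics exceeding the threshold, divided by
  the number of observed calls at that threshold, then made monotone in
  |statistic|.  A protein is significant when ``q < fdr_level``.

Results are returned as a DataFrame with one row per protein and columns
``protein, statistic, log2_fc, p_raw, q_value, significant``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix, check_metadata
from .errors import ValidationError

logger = logging.getLogger("invpap")

RESULT_COLUMNS = ["protein", "statistic", "log2_fc", "p_raw", "q_value", "significant"]

# statistics this close are treated as tied when comparing permuted
# against observed values (guards against float summation-order noise)
_TIE_TOL = 1e-9


@dataclass
class PermutationConfig:
    """Permutation-test settings: permutation count, seed, the variance
    moderation constant ``s0`` and the FDR significance level."""

    n_permutations: int = 1000
    seed: int = 0
    s0: float = 0.0
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValidationError("n_permutations must be >= 100")
        if not 0 < self.fdr_level < 1:
            raise ValidationError("fdr_level must be in (0, 1)")
        if self.s0 < 0:
            raise ValidationError("s0 must be non-negative")


def _welch_stat(X: np.ndarray, nA: int, s0: float) -> np.ndarray:
    """Moderated Welch statistic for proteins x (A columns first, then B)."""
    A, B = X[:, :nA], X[:, nA:]
    nB = B.shape[1]
    mdiff = A.mean(axis=1) - B.mean(axis=1)
    se = np.sqrt(A.var(axis=1, ddof=1) / nA + B.var(axis=1, ddof=1) / nB)
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, mdiff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def _f_stat(X: np.ndarray, sizes: list[int]) -> np.ndarray:
    """One-way F statistic for proteins x samples grouped contiguously."""
    k = len(sizes)
    N = X.shape[1]
    grand = X.mean(axis=1)
    between = np.zeros(X.shape[0])
    within = np.zeros(X.shape[0])
    start = 0
    for n_g in sizes:
        G = X[:, start : start + n_g]
        mg = G.mean(axis=1)
        between += n_g * (mg - grand) ** 2
        within += (n_g - 1) * G.var(axis=1, ddof=1)
        start += n_g
    between /= k - 1
    within /= N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(within > 0, between / np.where(within > 0, within, 1.0), 0.0)
    # zero within-group variance with a real between-group difference is a
    # perfect separation; give it an effectively infinite statistic
    perfect = (within <= 0) & (between > 0)
    F[perfect] = np.inf
    return F


def _sam_qvalues(obs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Permutation FDR over |statistic| thresholds.

    At each threshold the false-positive count is the *mean* over
    permutation rounds of the number of permuted statistics at or above
    the threshold.  (The median variant calls the top observed statistic
    at q = 0 whenever more than half the rounds produce no exceedance,
    which under a global null happens in about half of all datasets —
    an anticonservative failure the mean does not share.)

    ``obs``: observed scores (already non-negative), shape (P,).
    ``perm``: permuted scores, shape (B, P).
    """
    P = obs.shape[0]
    order = np.argsort(-obs, kind="stable")
    # numerical tie tolerance: a permutation reproducing the observed
    # grouping must count as an exceedance even when summation order
    # perturbs the recomputed statistic in the last bits
    thresholds = obs[order] - _TIE_TOL
    sorted_perm = np.sort(perm, axis=1)
    counts = np.empty((perm.shape[0], P), dtype=np.int64)
    for b in range(perm.shape[0]):
        counts[b] = P - np.searchsorted(sorted_perm[b], thresholds, side="left")
    fp_mean = counts.mean(axis=0)
    called = np.arange(1, P + 1, dtype=float)
    q_sorted = np.clip(fp_mean / called, 0.0, 1.0)
    # monotone: q may not decrease as |statistic| decreases
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(P)
    q[order] = q_sorted
    return q


def _permutation_pq(
    X: np.ndarray, stat_fn, cfg: PermutationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared permutation engine.  ``stat_fn(Xcols)`` maps a column-permuted
    matrix to a per-protein statistic; scoring uses |statistic|."""
    obs = stat_fn(X)
    abs_obs = np.abs(obs)
    rng = np.random.default_rng(cfg.seed)
    N = X.shape[1]
    B = cfg.n_permutations
    perm_abs = np.empty((B, X.shape[0]))
    exceed = np.zeros(X.shape[0], dtype=np.int64)
    for b in range(B):
        idx = rng.permutation(N)
        perm_abs[b] = np.abs(stat_fn(X[:, idx]))
        exceed += perm_abs[b] >= abs_obs - _TIE_TOL
    p_raw = (1.0 + exceed) / (1.0 + B)
    q = _sam_qvalues(abs_obs, perm_abs)
    return obs, p_raw, q


def _group_columns(m: AbundanceMatrix, groups: pd.Series, label: str) -> list[str]:
    groups = check_metadata(m, groups)
    cols = [s for s in m.sample_ids if groups[s] == label]
    return cols


def permutation_ttest(
    m: AbundanceMatrix,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    cfg: PermutationConfig,
) -> pd.DataFrame:
    """Two-sided two-group permutation t-test with permutation FDR.

    The statistic is Welch's unequal-variance t with ``cfg.s0`` added to
    the standard-error denominator.  ``log2_fc`` is mean(A) - mean(B) on
    the log2 scale (positive = higher in ``group_a``).
    """
    cols_a = _group_columns(m, groups, group_a)
    cols_b = _group_columns(m, groups, group_b)
    for label, cols in ((group_a, cols_a), (group_b, cols_b)):
        if len(cols) < 2:
            raise ValidationError(f"group {label!r} needs >=2 samples, has {len(cols)}")
    sub = m.data[cols_a + cols_b]
    if sub.isna().any().any():
        raise ValidationError("matrix has missing values on tested columns; impute first")
    X = sub.to_numpy(dtype=float)
    nA = len(cols_a)
    stat, p_raw, q = _permutation_pq(X, lambda Z: _welch_stat(Z, nA, cfg.s0), cfg)
    log2_fc = X[:, :nA].mean(axis=1) - X[:, nA:].mean(axis=1)
    return pd.DataFrame(
        {
            "protein": m.protein_ids,
            "statistic": stat,
            "log2_fc": log2_fc,
            "p_raw": p_raw,
            "q_value": q,
            "significant": q < cfg.fdr_level,
        }
    )


def permutation_anova(
    m: AbundanceMatrix,
    groups: pd.Series,
    cfg: PermutationConfig,
    group_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """One-way permutation F-test across three (or more) groups.

    Group labels are permuted jointly across all samples; p and q are
    computed exactly as in :func:`permutation_ttest` on the F statistic.
    ``log2_fc`` is undefined for a multi-group comparison and reported NaN.
    """
    groups_aligned = check_metadata(m, groups)
    labels = tuple(group_labels) if group_labels else tuple(pd.unique(groups_aligned))
    if len(labels) < 3:
        raise ValidationError(f"ANOVA needs >=3 groups, got {labels}")
    col_blocks = [_group_columns(m, groups, g) for g in labels]
    for g, cols in zip(labels, col_blocks):
        if len(cols) < 2:
            raise ValidationError(f"group {g!r} needs >=2 samples, has {len(cols)}")
    ordered_cols = [c for block in col_blocks for c in block]
    sub = m.data[ordered_cols]
    if sub.isna().any().any():
        raise ValidationError("matrix has missing values on tested columns; impute first")
    X = sub.to_numpy(dtype=float)
    sizes = [len(b) for b in col_blocks]
    stat, p_raw, q = _permutation_pq(X, lambda Z: _f_stat(Z, sizes), cfg)
    return pd.DataFrame(
        {
            "protein": m.protein_ids,
            "statistic": stat,
            "log2_fc": np.nan,
            "p_raw": p_raw,
            "q_value": q,
            "significant": q < cfg.fdr_level,
        }
    )


def fold_change(
    m: AbundanceMatrix, groups: pd.Series, group_a: str, group_b: str
) -> pd.Series:
    """Per-protein log2 fold change mean(A) - mean(B) over present values.

    Requires a log-transformed matrix.  Proteins absent in an entire group
    get NaN (flagged with a warning) — their fold change is undefined.
    """
    if not m.log_transformed:
        raise ValidationError("fold_change expects a log-transformed matrix")
    cols_a = _group_columns(m, groups, group_a)
    cols_b = _group_columns(m, groups, group_b)
    if not cols_a or not cols_b:
        raise ValidationError("both groups must have at least one sample")
    mean_a = m.data[cols_a].mean(axis=1)
    mean_b = m.data[cols_b].mean(axis=1)
    fc = mean_a - mean_b
    fc.name = "log2_fc"
    n_undef = int(fc.isna().sum())
    if n_undef:
        logger.warning(
            "%d proteins absent in a whole group; fold change undefined", n_undef
        )
    return fc
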