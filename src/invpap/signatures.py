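"""Partition ANOVA-significant proteins into 'NU-like' and 'PUC-like'
signature classes of the intermediate (IUP) group.

A protein is *NU-like* when IUP expression is indistinguishable from
normal urothelium but differs from carcinoma (IUP~NU, IUP!=PUC) and
*PUC-like* in the reverse pattern; up/down is the direction of IUP
relative to the dissimilar group.  Similarity is operationalized as the
post-hoc two-group permutation t-test being non-significant at the same
FDR level used for the ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .diffstats import PermutationConfig, permutation_ttest
from .errors import ValidationError

CLASSES = ("NU_like_up", "NU_like_down", "PUC_like_up", "PUC_like_down", "unassigned")

ASSIGNMENT_COLUMNS = [
    "protein",
    "class",
    "mean_IUP",
    "mean_PUC",
    "mean_NU",
    "q_IUP_vs_NU",
    "q_IUP_vs_PUC",
]


def assign_signatures(
    anova: pd.DataFrame,
    m: AbundanceMatrix,
    groups: pd.Series,
    cfg: PermutationConfig,
) -> pd.DataFrame:
    """Label each ANOVA-significant protein with its signature class.

    Post-hoc IUP-vs-NU and IUP-vs-PUC permutation t-tests are run with the
    same permutation machinery and FDR level as the omnibus test.  A
    protein that is significant in exactly one post-hoc comparison gets
    the corresponding class; anything else (including all non-significant
    ANOVA proteins) is ``unassigned``.
    """
    if list(anova["protein"]) != m.protein_ids:
        raise ValidationError("ANOVA results do not match the matrix proteins")
    post_nu = permutation_ttest(m, groups, "IUP", "NU", cfg).set_index("protein")
    post_puc = permutation_ttest(m, groups, "IUP", "PUC", cfg).set_index("protein")

    def group_mean(label: str) -> pd.Series:
        cols = [s for s in m.sample_ids if groups[s] == label]
        return m.data[cols].mean(axis=1)

    mean_iup, mean_puc, mean_nu = group_mean("IUP"), group_mean("PUC"), group_mean("NU")
    sig_anova = anova.set_index("protein")["significant"]
    sig_nu = post_nu["significant"]
    sig_puc = post_puc["significant"]

    classes = []
    for pid in m.protein_ids:
        if not sig_anova[pid]:
            classes.append("unassigned")
            continue
        nu_like = (not sig_nu[pid]) and sig_puc[pid]
        puc_like = sig_nu[pid] and (not sig_puc[pid])
        if nu_like:
            delta = mean_iup[pid] - mean_puc[pid]
            classes.append("NU_like_up" if delta > 0 else "NU_like_down")
        elif puc_like:
            delta = mean_iup[pid] - mean_nu[pid]
            classes.append("PUC_like_up" if delta > 0 else "PUC_like_down")
        else:
            classes.append("unassigned")
    return pd.DataFrame(
        {
            "protein": m.protein_ids,
            "class": classes,
            "mean_IUP": mean_iup.values,
            "mean_PUC": mean_puc.values,
            "mean_NU": mean_nu.values,
            "q_IUP_vs_NU": post_nu["q_value"].values,
            "q_IUP_vs_PUC": post_puc["q_value"].values,
        }
    )


def rank_top_signatures(
    assignments: pd.DataFrame, anova: pd.DataFrame, k: int = 40
) -> dict[str, list[str]]:
    """Return the top-``k`` proteins of each signature class.

    Within a class, proteins are ordered by ascending ANOVA q-value, ties
    broken by descending |F| then lexicographic protein id.  Classes with
    fewer than ``k`` members return all of them.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    stats = anova.set_index("protein")
    ranked: dict[str, list[str]] = {}
    for cls in CLASSES:
        if cls == "unassigned":
            continue
        members = assignments.loc[assignments["class"] == cls, "protein"]
        if members.empty:
            ranked[cls] = []
            continue
        sub = stats.loc[members]
        order = sorted(
            members,
            key=lambda p: (sub.at[p, "q_value"], -abs(sub.at[p, "statistic"]), p),
        )
        ranked[cls] = order[:k]
    return ranked
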