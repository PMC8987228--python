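"""Antibody-staining immunoscore and the proteome/knowledge-base
concordance screen.

Public tissue atlases report, per antibody, the proportion of stained
tumour samples at four intensity levels.  The immunoscore weights these
levels 4 (high), 3 (medium), 2 (low) and 1 (not detected), sums the
weighted proportions and averages over antibodies, giving a value in
[1, 4].  A candidate biomarker is discarded when the atlas calls it
highly expressed in urothelial carcinoma (immunoscore above the cutoff)
while the proteome says the opposite (higher in IUP, i.e. down in PUC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("invpap")

INTENSITY_WEIGHTS = {"high": 4.0, "medium": 3.0, "low": 2.0, "not_detected": 1.0}

PROFILE_COLUMNS = ["protein", "antibody", "tissue", "p_high", "p_medium", "p_low", "p_not_detected"]


@dataclass
class AntibodyStainingProfile:
    """Staining-intensity proportions for one antibody on one protein."""

    protein_id: str
    antibody_id: str
    proportions: Mapping[str, float]  # keys: high, medium, low, not_detected
    tissue: str = "bladder urothelial carcinoma"

    def __post_init__(self) -> None:
        keys = set(self.proportions)
        if keys != set(INTENSITY_WEIGHTS):
            raise ValidationError(f"proportions must cover {sorted(INTENSITY_WEIGHTS)}, got {sorted(keys)}")
        vals = list(self.proportions.values())
        if any(not 0 <= v <= 1 for v in vals):
            raise ValidationError("staining proportions must be in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValidationError(f"staining proportions sum to {sum(vals)}, not 1")


@dataclass
class ImmunoscoreResult:
    protein_id: str
    per_antibody_scores: list[float]
    immunoscore: float


def immunoscore(profiles: Sequence[AntibodyStainingProfile]) -> ImmunoscoreResult:
    """Weighted staining score per antibody, averaged across antibodies."""
    if not profiles:
        raise ValidationError("at least one staining profile required")
    pid = profiles[0].protein_id
    if any(p.protein_id != pid for p in profiles):
        raise ValidationError("profiles mix different proteins")
    scores = [
        sum(INTENSITY_WEIGHTS[level] * p.proportions[level] for level in INTENSITY_WEIGHTS)
        for p in profiles
    ]
    return ImmunoscoreResult(pid, scores, sum(scores) / len(scores))


def read_staining_profiles(path: str | Path) -> dict[str, list[AntibodyStainingProfile]]:
    """Read a profile TSV (columns: protein, antibody, tissue, p_high,
    p_medium, p_low, p_not_detected) into per-protein profile lists."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out: dict[str, list[AntibodyStainingProfile]] = {}
    for row in df.itertuples(index=False):
        prof = AntibodyStainingProfile(
            protein_id=row.protein,
            antibody_id=row.antibody,
            tissue=row.tissue,
            proportions={
                "high": row.p_high,
                "medium": row.p_medium,
                "low": row.p_low,
                "not_detected": row.p_not_detected,
            },
        )
        out.setdefault(row.protein, []).append(prof)
    return out


def concordance_filter(
    candidates: Sequence[str],
    scores: Mapping[str, float],
    fold_changes: Mapping[str, float],
    high_expression_cutoff: float = 2.5,
) -> tuple[list[str], pd.DataFrame]:
    """Drop candidates whose atlas expression contradicts the proteome.

    Exclusion rule: immunoscore >= ``high_expression_cutoff`` (the atlas
    calls the protein highly expressed in carcinoma) AND log2 fold change
    IUP-vs-PUC > 0 (the proteome found it *lower* in carcinoma).  All
    other candidates are retained; candidates without a score or fold
    change are retained as "unscreenable" with a warning.
    """
    retained: list[str] = []
    rows = []
    for pid in candidates:
        score = scores.get(pid)
        fc = fold_changes.get(pid)
        if score is None or fc is None or pd.isna(fc):
            logger.warning("candidate %s lacks immunoscore or fold change; unscreenable", pid)
            verdict = "unscreenable"
            retained.append(pid)
        elif score >= high_expression_cutoff and fc > 0:
            verdict = "excluded_discordant"
        else:
            verdict = "retained_concordant"
            retained.append(pid)
        rows.append(
            {
                "protein": pid,
                "immunoscore": score if score is not None else float("nan"),
                "log2_fc": fc if fc is not None else float("nan"),
                "verdict": verdict,
            }
        )
    return retained, pd.DataFrame(rows)
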