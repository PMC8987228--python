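"""Univariate prognostic screening: Cox proportional hazards on
continuous log2 expression and median-split Kaplan-Meier with a log-rank
test.

Backed by ``lifelines`` (Efron handling of tied event times).  The
hazard ratio is per unit of log2 expression, i.e. per doubling of the
transcript level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import ValidationError

SURVIVAL_COLUMNS = ["patient_id", "time_months", "event"]


@dataclass
class CoxResult:
    gene: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    coef: float
    se: float
    n: int
    n_events: int


@dataclass
class KmLogrankResult:
    gene: str
    cutoff: float
    curves: dict[str, pd.DataFrame]  # "low"/"high" -> timeline + survival prob
    chi_square: float
    p_value: float
    n_low: int
    n_high: int


def _validate_cohort(cohort: pd.DataFrame, gene: str) -> None:
    for col in SURVIVAL_COLUMNS:
        if col not in cohort.columns:
            raise ValidationError(f"survival table missing column {col!r}")
    if gene not in cohort.columns:
        raise ValidationError(f"gene {gene!r} not in survival table")
    if (cohort["time_months"] <= 0).any():
        raise ValidationError("follow-up times must be positive")
    if cohort[gene].isna().any():
        raise ValidationError(f"missing expression values for {gene!r}")
    if len(cohort) < 2:
        raise ValidationError("cohort must have >= 2 patients")
    if int(cohort["event"].sum()) < 1:
        raise ValidationError("cohort has no events")


def cox_univariate(cohort: pd.DataFrame, gene: str) -> CoxResult:
    """Univariate Cox proportional-hazards fit for one gene.

    Maximizes the Efron partial likelihood; returns the hazard ratio per
    log2-expression unit with its 95% Wald confidence interval and
    p-value.
    """
    _validate_cohort(cohort, gene)
    df = cohort[["time_months", "event", gene]].copy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_months", event_col="event")
    s = cph.summary.loc[gene]
    return CoxResult(
        gene=gene,
        hazard_ratio=float(s["exp(coef)"]),
        ci_lower=float(s["exp(coef) lower 95%"]),
        ci_upper=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        coef=float(s["coef"]),
        se=float(s["se(coef)"]),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def km_logrank_median_split(cohort: pd.DataFrame, gene: str) -> KmLogrankResult:
    """Kaplan-Meier curves and log-rank test for a median expression split.

    Patients at or below the median expression form the low group (ties
    to low).  Requires at least two patients on each side of the split.
    """
    _validate_cohort(cohort, gene)
    expr = cohort[gene]
    cutoff = float(expr.median())
    low = cohort[expr <= cutoff]
    high = cohort[expr > cutoff]
    if len(low) < 2 or len(high) < 2:
        raise ValidationError("degenerate median split: <2 patients on one side")
    curves = {}
    for name, grp in (("low", low), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time_months"], grp["event"], label=name)
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time_months": sf.index.to_numpy(), "survival": sf[name].to_numpy()}
        )
    lr = logrank_test(
        low["time_months"], high["time_months"], low["event"], high["event"]
    )
    return KmLogrankResult(
        gene=gene,
        cutoff=cutoff,
        curves=curves,
        chi_square=float(lr.test_statistic),
        p_value=float(lr.p_value),
        n_low=len(low),
        n_high=len(high),
    )


def survival_screen(cohort: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Univariate Cox + median-split log-rank for each gene of interest."""
    rows = []
    for gene in genes:
        cox = cox_univariate(cohort, gene)
        km = km_logrank_median_split(cohort, gene)
        rows.append(
            {
                "gene": gene,
                "hazard_ratio": cox.hazard_ratio,
                "ci_lower": cox.ci_lower,
                "ci_upper": cox.ci_upper,
                "cox_p": cox.p_value,
                "logrank_chi2": km.chi_square,
                "logrank_p": km.p_value,
            }
        )
    return pd.DataFrame(rows)
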