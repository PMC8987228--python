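"""Synthetic cohort generators with recorded ground truth.

Every generator emulates the statistical structure the analysis assumes,
at the study's cohort shapes:

* a 31-sample discovery proteome (9 IUP / 12 PUC / 10 NU) with ~5,000
  proteins, planted signature-class effects and intensity-dependent
  (MNAR) dropout;
* a 41-specimen IHC validation cohort (25 IUP / 16 PUC with inverted
  growth) of per-cell staining-intensity bins;
* a 405-patient survival cohort with exponential event times driven by
  log2 expression;
* antibody staining profiles planted concordant or discordant with the
  proteomic fold change.

All generators are deterministic under their seed and return ground
truth alongside the data, so recovery tests can score the pipeline
against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .abundance import AbundanceMatrix
from .errors import ValidationError
from .hpa import AntibodyStainingProfile

SIGNATURE_CLASSES = ("NU_like_up", "NU_like_down", "PUC_like_up", "PUC_like_down")


@dataclass
class AbundanceSimSpec:
    """Discovery-proteome generator settings.

    Baseline log2 intensities spread with SD ``baseline_sd`` (~2, the
    iBAQ dynamic range); planted proteins are shifted by ``effect_size``
    log2 units in the mean pattern of their class; values below the
    column-wise ``missingness`` quantile drop out (missing not at
    random).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"IUP": 9, "PUC": 12, "NU": 10}
    )
    n_proteins: int = 5000
    planted_counts: dict[str, int] = field(
        default_factory=lambda: {c: 40 for c in SIGNATURE_CLASSES}
    )
    effect_size: float = 2.0
    noise_sd: float = 0.5
    missingness: float = 0.2
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.planted_counts.values()) > self.n_proteins:
            raise ValidationError("planted counts exceed n_proteins")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0 <= self.missingness < 1:
            raise ValidationError("missingness quantile must be in [0, 1)")
        if set(self.planted_counts) - set(SIGNATURE_CLASSES):
            raise ValidationError(f"unknown signature class in {self.planted_counts}")


# mean shift (in effect-size units) per group for each planted class:
# NU-like classes move IUP together with NU away from PUC; PUC-like
# classes move IUP together with PUC away from NU.
_CLASS_PATTERN = {
    "NU_like_up": {"IUP": 1, "NU": 1, "PUC": 0},
    "NU_like_down": {"IUP": -1, "NU": -1, "PUC": 0},
    "PUC_like_up": {"IUP": 1, "PUC": 1, "NU": 0},
    "PUC_like_down": {"IUP": -1, "PUC": -1, "NU": 0},
}


def simulate_abundance(spec: AbundanceSimSpec) -> tuple[AbundanceMatrix, pd.Series, pd.DataFrame]:
    """Generate a raw-scale abundance matrix, group labels and ground truth.

    Returns ``(matrix, groups, truth)`` where ``truth`` has columns
    ``protein`` and ``true_class`` ('background' for unplanted proteins).
    The matrix is on the raw intensity scale (2**log2-value) with MNAR
    missingness, ready for the preprocessing chain.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids, group_of = [], {}
    for g, n in spec.n_per_group.items():
        for i in range(n):
            sid = f"{g}_{i + 1:02d}"
            sample_ids.append(sid)
            group_of[sid] = g
    n_samples = len(sample_ids)
    protein_ids = [f"P{i + 1:05d}" for i in range(spec.n_proteins)]

    classes = np.array(["background"] * spec.n_proteins, dtype=object)
    pos = 0
    for cls in SIGNATURE_CLASSES:
        cnt = spec.planted_counts.get(cls, 0)
        classes[pos : pos + cnt] = cls
        pos += cnt

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_proteins)
    log2 = np.tile(baseline[:, None], (1, n_samples))
    for j, sid in enumerate(sample_ids):
        g = group_of[sid]
        for i in range(spec.n_proteins):
            if classes[i] != "background":
                log2[i, j] += spec.effect_size * _CLASS_PATTERN[classes[i]][g]
    log2 += rng.normal(0.0, spec.noise_sd, size=log2.shape)

    raw = np.power(2.0, log2)
    if spec.missingness > 0:
        for j in range(n_samples):
            cut = np.quantile(raw[:, j], spec.missingness)
            raw[raw[:, j] < cut, j] = np.nan
    data = pd.DataFrame(raw, index=protein_ids, columns=sample_ids)
    groups = pd.Series({s: group_of[s] for s in sample_ids}, name="group")
    truth = pd.DataFrame({"protein": protein_ids, "true_class": classes})
    return AbundanceMatrix(data), groups, truth


@dataclass
class IhcSimSpec:
    """Validation-cohort generator: per-cell staining-intensity bins.

    Each specimen's cells are a single multinomial draw from its
    diagnosis-specific bin-probability vector (bins 0/1+/2+/3+), so the
    expected H-score is exactly ``100 * (p1 + 2*p2 + 3*p3)``.  Setting
    ``dirichlet_concentration`` adds per-specimen Dirichlet jitter around
    the diagnosis vector, emulating between-patient staining
    heterogeneity (off by default).
    """

    n_iup: int = 25
    n_puc: int = 16
    cells_per_specimen: int = 500
    p_bins_iup: tuple[float, float, float, float] = (0.35, 0.30, 0.20, 0.15)
    p_bins_puc: tuple[float, float, float, float] = (0.85, 0.10, 0.04, 0.01)
    dirichlet_concentration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iup < 1 or self.n_puc < 1 or self.cells_per_specimen < 1:
            raise ValidationError("cohort and cell counts must be >= 1")
        for p in (self.p_bins_iup, self.p_bins_puc):
            if len(p) != 4 or any(v < 0 for v in p) or abs(sum(p) - 1) > 1e-9:
                raise ValidationError(f"invalid bin probability vector {p}")


def expected_hscore(p_bins: tuple[float, float, float, float]) -> float:
    """Closed-form expected H-score of a bin-probability vector."""
    return 100.0 * (p_bins[1] + 2 * p_bins[2] + 3 * p_bins[3])


def simulate_ihc(spec: IhcSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a per-cell detection table and per-diagnosis ground truth."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    cohort = [("IUP", i + 1, spec.p_bins_iup) for i in range(spec.n_iup)] + [
        ("PUC_inverted", i + 1, spec.p_bins_puc) for i in range(spec.n_puc)
    ]
    for diag, idx, p in cohort:
        if spec.dirichlet_concentration is not None:
            p = rng.dirichlet(np.asarray(p) * spec.dirichlet_concentration)
        counts = rng.multinomial(spec.cells_per_specimen, p)
        bins = np.repeat([0, 1, 2, 3], counts)
        sid = f"{diag}_{idx:02d}"
        rows.append(
            pd.DataFrame(
                {"specimen_id": sid, "diagnosis": diag, "intensity_bin": bins}
            )
        )
    cells = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {
            "diagnosis": ["IUP", "PUC_inverted"],
            "expected_h_score": [
                expected_hscore(spec.p_bins_iup),
                expected_hscore(spec.p_bins_puc),
            ],
        }
    )
    return cells, truth


@dataclass
class SurvivalSimSpec:
    """Survival-cohort generator settings.

    Expression is standard normal per gene; event times are exponential
    with hazard ``baseline_hazard * exp(beta * expression)``; censoring
    times are uniform on (0, c_max) with c_max calibrated so the realized
    censoring fraction approximates ``censoring_rate``.  The default
    baseline hazard gives a ~30-month median survival.
    """

    n_patients: int = 405
    log_hr: dict[str, float] = field(default_factory=lambda: {"GENE_A": 0.25})
    baseline_hazard: float = float(np.log(2) / 30.0)
    censoring_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValidationError("n_patients must be >= 10")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")


def simulate_survival(spec: SurvivalSimSpec) -> pd.DataFrame:
    """Generate a survival table: patient_id, time_months, event, one
    column of log2 expression per gene.

    With several genes the hazards multiply: the individual hazard is
    ``baseline * exp(sum_g beta_g x_g)`` with independent expression
    across genes.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.log_hr)
    X = rng.standard_normal((spec.n_patients, len(genes)))
    betas = np.array([spec.log_hr[g] for g in genes])
    rate = spec.baseline_hazard * np.exp(X @ betas)
    T = rng.exponential(1.0 / rate)

    if spec.censoring_rate > 0:
        # P(C < T) for C ~ U(0, c) is E[min(T, c)] / c; calibrate c on the
        # realized event-time sample
        def censored_frac(c: float) -> float:
            return float(np.minimum(T, c).mean() / c) - spec.censoring_rate

        lo, hi = 1e-6, float(T.max() * 100)
        c_max = optimize.brentq(censored_frac, lo, hi)
        C = rng.uniform(0.0, c_max, size=spec.n_patients)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(spec.n_patients, dtype=int)

    out = pd.DataFrame(
        {
            "patient_id": [f"PT{i + 1:04d}" for i in range(spec.n_patients)],
            "time_months": np.maximum(time, 1e-6),
            "event": event,
        }
    )
    for g, col in zip(genes, X.T):
        out[g] = col
    return out


def simulate_hpa_profiles(
    proteins: list[str],
    regimes: dict[str, str],
    seed: int = 0,
) -> tuple[dict[str, list[AntibodyStainingProfile]], pd.DataFrame, dict[str, float]]:
    """Generate staining profiles planted concordant or discordant.

    ``regimes`` maps protein -> {'concordant', 'discordant'}.  Discordant
    proteins get a high-intensity-dominated profile (immunoscore >= 2.5)
    paired with a planted positive IUP-vs-PUC log2 fold change — exactly
    the pattern the concordance screen excludes.  Concordant proteins get
    a weak-staining profile with the same positive fold change, so they
    survive the screen.  Returns (profiles, truth, fold_changes).
    """
    rng = np.random.default_rng(seed)
    profiles: dict[str, list[AntibodyStainingProfile]] = {}
    fold_changes: dict[str, float] = {}
    rows = []
    for pid in proteins:
        regime = regimes.get(pid, "concordant")
        if regime not in ("concordant", "discordant"):
            raise ValidationError(f"unknown regime {regime!r} for {pid}")
        if regime == "discordant":
            base = np.array([0.60, 0.25, 0.10, 0.05])  # high, medium, low, nd
        else:
            base = np.array([0.05, 0.10, 0.25, 0.60])
        jitter = rng.dirichlet(base * 100)
        profiles[pid] = [
            AntibodyStainingProfile(
                protein_id=pid,
                antibody_id=f"AB_{pid}",
                proportions={
                    "high": jitter[0],
                    "medium": jitter[1],
                    "low": jitter[2],
                    "not_detected": jitter[3],
                },
            )
        ]
        fold_changes[pid] = float(rng.uniform(0.5, 2.0))
        rows.append({"protein": pid, "regime": regime})
    return profiles, pd.DataFrame(rows), fold_changes


def profiles_to_frame(profiles: dict[str, list[AntibodyStainingProfile]]) -> pd.DataFrame:
    """Flatten staining profiles to the on-disk TSV layout."""
    rows = []
    for pid, plist in profiles.items():
        for p in plist:
            rows.append(
                {
                    "protein": pid,
                    "antibody": p.antibody_id,
                    "tissue": p.tissue,
                    "p_high": p.proportions["high"],
                    "p_medium": p.proportions["medium"],
                    "p_low": p.proportions["low"],
                    "p_not_detected": p.proportions["not_detected"],
                }
            )
    return pd.DataFrame(rows)
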