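"""End-to-end orchestration of the biomarker-discovery workflow.

Stages: preprocess -> differential expression (ANOVA + pairwise t-test)
-> signature partition -> SVM-RFE feature selection -> FDR/rank
shortlist -> staining-atlas concordance screen -> optional IHC
validation statistics -> optional survival screen.  Each stage writes a
self-describing TSV into the output directory; a run log records seeds,
configuration hash and package versions, and ``report.txt`` summarizes
the final candidates with their audit trail.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import (
    AbundanceMatrix,
    PreprocessConfig,
    check_metadata,
    filter_by_presence,
    impute_missing,
    log_and_normalize,
    pca_embed,
    read_abundance_table,
    read_metadata,
    write_abundance_table,
)
from .diffstats import PermutationConfig, fold_change, permutation_anova, permutation_ttest
from .errors import StageError, ValidationError
from .feature_select import choose_panel, shortlist_candidates, svm_rfe_rank
from .hpa import concordance_filter, immunoscore, read_staining_profiles
from .ihc import hscores_by_specimen, ihc_validation_report, read_cell_table
from .signatures import assign_signatures, rank_top_signatures
from .survival import survival_screen

logger = logging.getLogger("invpap")


@dataclass
class RunConfig:
    """Paths and settings for one pipeline run."""

    abundance_path: str
    metadata_path: str
    out_dir: str
    hpa_profiles_path: str | None = None
    ihc_cells_path: str | None = None
    survival_path: str | None = None
    survival_genes: list[str] = field(default_factory=list)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    cv_folds: int = 5
    hpa_cutoff: float = 2.5
    shortlist_k: int = 5
    top_signatures_k: int = 40
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        perm = PermutationConfig(**raw.pop("permutation", {}))
        return cls(preprocess=pre, permutation=perm, **raw)

    def validate_paths(self) -> None:
        required = {"abundance": self.abundance_path, "metadata": self.metadata_path}
        optional = {
            "hpa_profiles": self.hpa_profiles_path,
            "ihc_cells": self.ihc_cells_path,
            "survival": self.survival_path,
        }
        for name, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(p).is_file():
                raise ValidationError(f"{name} input does not exist: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# invpap {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full discovery workflow; returns the result bundle.

    Any stage failure raises :class:`StageError` naming the stage;
    outputs of completed stages remain on disk.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    bundle: dict = {"config_hash": cfg_hash}

    stage = "preprocess"
    try:
        m_raw = read_abundance_table(cfg.abundance_path)
        groups = check_metadata(m_raw, read_metadata(cfg.metadata_path))
        m = filter_by_presence(m_raw, cfg.preprocess)
        m = log_and_normalize(m, cfg.preprocess)
        m = impute_missing(m, cfg.preprocess)
        coords, evr = pca_embed(m)
        write_abundance_table(m, out / "preprocessed.tsv")
        pca_df = coords.reset_index(names="sample_id")
        pca_df["group"] = [groups[s] for s in coords.index]
        _write(pca_df, out / "pca.tsv", cfg_hash)
        bundle.update(matrix=m, groups=groups, pca=coords, pca_evr=evr)

        stage = "diffexp"
        anova = permutation_anova(m, groups, cfg.permutation, ("IUP", "PUC", "NU"))
        ttest = permutation_ttest(m, groups, "IUP", "PUC", cfg.permutation)
        _write(anova, out / "anova.tsv", cfg_hash)
        _write(ttest, out / "ttest_IUP_vs_PUC.tsv", cfg_hash)
        bundle.update(anova=anova, ttest=ttest)

        stage = "signatures"
        assignments = assign_signatures(anova, m, groups, cfg.permutation)
        top = rank_top_signatures(assignments, anova, cfg.top_signatures_k)
        _write(assignments, out / "signatures.tsv", cfg_hash)
        bundle.update(signatures=assignments, top_signatures=top)

        stage = "feature_selection"
        ranking = svm_rfe_rank(m, groups, "IUP", "PUC", cfg.cv_folds, cfg.seed)
        panel = choose_panel(ranking)
        shortlist = shortlist_candidates(ranking, ttest, cfg.shortlist_k)
        _write(ranking.as_frame(), out / "feature_ranking.tsv", cfg_hash)
        bundle.update(ranking=ranking, panel=panel, shortlist=shortlist)

        stage = "hpa_screen"
        final_candidates = shortlist
        if cfg.hpa_profiles_path:
            profiles = read_staining_profiles(cfg.hpa_profiles_path)
            scores = {
                pid: immunoscore(plist).immunoscore for pid, plist in profiles.items()
            }
            fc = fold_change(m, groups, "IUP", "PUC")
            final_candidates, verdicts = concordance_filter(
                shortlist, scores, fc.to_dict(), cfg.hpa_cutoff
            )
            _write(verdicts, out / "hpa_screen.tsv", cfg_hash)
            bundle["hpa_verdicts"] = verdicts
        bundle["final_candidates"] = final_candidates

        if cfg.ihc_cells_path:
            stage = "ihc_validation"
            cells = read_cell_table(cfg.ihc_cells_path)
            hs = hscores_by_specimen(cells)
            roc = ihc_validation_report(hs)
            _write(hs, out / "hscores.tsv", cfg_hash)
            bundle.update(hscores=hs, roc=roc)

        if cfg.survival_path and cfg.survival_genes:
            stage = "survival"
            cohort = pd.read_csv(cfg.survival_path, sep="\t")
            surv = survival_screen(cohort, cfg.survival_genes)
            _write(surv, out / "survival_screen.tsv", cfg_hash)
            bundle["survival"] = surv
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    _write_report(bundle, cfg, out)
    _write_run_log(cfg, out, cfg_hash)
    return bundle


def _write_report(bundle: dict, cfg: RunConfig, out: Path) -> None:
    lines = ["Biomarker discovery run summary", "=" * 34, ""]
    anova = bundle["anova"]
    lines.append(f"Proteins tested: {len(anova)}")
    lines.append(f"ANOVA-significant (q < {cfg.permutation.fdr_level}): {int(anova['significant'].sum())}")
    sig = bundle["signatures"]
    for cls in ("NU_like_up", "NU_like_down", "PUC_like_up", "PUC_like_down"):
        lines.append(f"  {cls}: {int((sig['class'] == cls).sum())}")
    r = bundle["ranking"]
    err = r.error_curve[r.chosen_panel_size]
    lines.append(f"SVM-RFE panel: {r.chosen_panel_size} proteins, CV error {err:.3f}")
    lines.append(f"Shortlist (FDR + ML rank): {', '.join(bundle['shortlist'])}")
    lines.append(f"Final candidates after concordance screen: {', '.join(bundle['final_candidates'])}")
    if "roc" in bundle:
        roc = bundle["roc"]
        lines.append(
            f"IHC validation: AUROC {roc.auc:.3f} (p={roc.p_value:.2e}), "
            f"cutoff {roc.cutoff:.1f}, sens {roc.sensitivity:.0f}% "
            f"({roc.sens_ci[0]:.1f}-{roc.sens_ci[1]:.1f}), "
            f"spec {roc.specificity:.0f}% ({roc.spec_ci[0]:.1f}-{roc.spec_ci[1]:.1f})"
        )
    if "survival" in bundle:
        for row in bundle["survival"].itertuples(index=False):
            lines.append(
                f"Cox {row.gene}: HR {row.hazard_ratio:.3f} "
                f"({row.ci_lower:.3f}-{row.ci_upper:.3f}), p={row.cox_p:.4f}"
            )
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def _write_run_log(cfg: RunConfig, out: Path, cfg_hash: str) -> None:
    import numpy
    import scipy
    import sklearn

    log = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "preprocess_seed": cfg.preprocess.seed,
        "permutation_seed": cfg.permutation.seed,
        "config": asdict(cfg),
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
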