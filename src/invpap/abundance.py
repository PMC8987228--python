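"""Label-free protein abundance matrices: I/O, presence filtering,
log transformation, per-sample normalization, downshifted-normal
imputation and PCA embedding.

The central container is :class:`AbundanceMatrix`, a thin wrapper around a
proteins x samples :class:`pandas.DataFrame` in which ``NaN`` marks a
missing (not detected / not quantified) value.  Intensities are iBAQ-style
arbitrary units on the raw scale; after :func:`log_and_normalize` the
matrix holds log2 values and may be negative.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ParseError, ValidationError

logger = logging.getLogger("invpap")

GROUPS = ("IUP", "PUC", "NU")

DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan"})


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity table with missing values.

    Parameters
    ----------
    data
        DataFrame indexed by protein id with one column per sample;
        ``NaN`` encodes a missing value.
    log_transformed
        Whether values are on the log2 scale.  Raw-scale matrices must be
        non-negative; log-scale matrices may contain negative values.
    """

    data: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if not np.isfinite(vals[present]).all():
            raise ValidationError("non-finite intensity present")
        if not self.log_transformed and present.any() and (vals[present] < 0).any():
            raise ValidationError("negative intensity in a raw-scale matrix")

    @property
    def protein_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def presence_counts(self) -> pd.Series:
        """Number of present (non-missing) values per protein."""
        return self.data.notna().sum(axis=1)

    def is_complete(self) -> bool:
        return not self.data.isna().any().any()


@dataclass
class PreprocessConfig:
    """Settings for the preprocessing chain.

    ``min_presence_fraction`` follows the study design: a protein is kept
    when it is quantified in at least 20% of all samples.  Imputation uses
    the downshifted-normal convention of label-free proteomics (per-sample
    normal draws centred ``impute_downshift`` column SDs below the column
    mean, with width ``impute_width`` column SDs).
    """

    min_presence_fraction: float = 0.20
    log_base: int = 2
    normalization: str = "median-center"  # or "none"
    imputation: str = "downshifted-normal"  # or "none"
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_presence_fraction <= 1:
            raise ValidationError("min_presence_fraction must be in (0, 1]")
        if self.impute_width <= 0:
            raise ValidationError("impute_width must be > 0")
        if self.normalization not in ("median-center", "none"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.imputation not in ("downshifted-normal", "none"):
            raise ValidationError(f"unknown imputation {self.imputation!r}")


def read_abundance_table(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    log_transformed: bool = False,
) -> AbundanceMatrix:
    """Read a tab-delimited protein x sample intensity table.

    The first column holds protein ids, the header row holds sample ids.
    Cells matching ``missing_tokens`` become missing values.  Ragged or
    non-numeric rows raise :class:`ParseError` naming the line; duplicated
    protein ids raise :class:`ValidationError`.  Pass
    ``log_transformed=True`` when re-reading an already log2-scale table
    (negative values are then allowed).
    """
    tokens = set(missing_tokens)
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ParseError(f"{path}: line 1: header must list at least one sample")
        sample_ids = header[1:]
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            ids.append(row[0])
            parsed: list[float] = []
            for cell in row[1:]:
                if cell.strip() in tokens:
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric cell {cell!r}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = pd.DataFrame(rows, index=ids, columns=sample_ids, dtype=float)
    return AbundanceMatrix(data, log_transformed=log_transformed)


def read_metadata(path: str | Path) -> pd.Series:
    """Read sample metadata (columns ``sample_id``, ``group``) into a
    Series mapping sample id -> group label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated sample_id")
    return pd.Series(df["group"].values, index=df["sample_id"].values, name="group")


def check_metadata(m: AbundanceMatrix, groups: pd.Series) -> pd.Series:
    """Validate that every sample in ``m`` has exactly one group label."""
    missing = [s for s in m.sample_ids if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    return groups.loc[m.sample_ids]


def write_abundance_table(m: AbundanceMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.index.name = "protein"
    out.to_csv(path, sep="\t", na_rep="NA")


def filter_by_presence(m: AbundanceMatrix, cfg: PreprocessConfig) -> AbundanceMatrix:
    """Keep proteins present in at least ``min_presence_fraction`` of samples.

    The comparison is inclusive on the exact fraction (2 of 10 passes a
    0.20 threshold); protein order is preserved and the operation is
    idempotent.
    """
    if m.n_proteins == 0 or m.n_samples == 0:
        raise ValidationError("cannot presence-filter an empty matrix")
    frac = m.presence_counts() / m.n_samples
    keep = frac >= cfg.min_presence_fraction
    return replace(m, data=m.data.loc[keep])


def log_and_normalize(m: AbundanceMatrix, cfg: PreprocessConfig) -> AbundanceMatrix:
    """Log2-transform and (optionally) median-center each sample column.

    Median centering subtracts the per-column median of present values so
    that every sample's median becomes 0, removing loading differences.
    The missingness pattern is unchanged.
    """
    if m.log_transformed:
        raise ValidationError("matrix already log transformed")
    vals = m.values
    present = ~np.isnan(vals)
    if (vals[present] <= 0).any():
        raise ValidationError("non-positive intensity cannot be log transformed")
    logged = np.where(present, np.log(np.where(present, vals, 1.0)) / np.log(cfg.log_base), np.nan)
    if cfg.normalization == "median-center":
        for j in range(logged.shape[1]):
            col = logged[:, j]
            pres = ~np.isnan(col)
            if not pres.any():
                logger.warning("sample %s has no present values; left unchanged", m.sample_ids[j])
                continue
            logged[:, j] = col - np.median(col[pres])
    data = pd.DataFrame(logged, index=m.data.index, columns=m.data.columns)
    return AbundanceMatrix(data, log_transformed=True)


def impute_missing(m: AbundanceMatrix, cfg: PreprocessConfig) -> AbundanceMatrix:
    """Replace missing values by draws from a downshifted normal.

    Per sample column, draws come from
    ``Normal(mean - impute_downshift * sd, impute_width * sd)`` where mean
    and sd are computed over the column's present values — emulating the
    left-censored (detection-limit) nature of label-free missingness.
    Columns with fewer than two present values fall back to the global
    mean/SD with a warning.  Deterministic under ``cfg.seed``.
    """
    if not m.log_transformed:
        raise ValidationError("impute_missing expects a log-transformed matrix")
    if cfg.imputation == "none" or m.is_complete():
        return m
    rng = np.random.default_rng(cfg.seed)
    vals = m.values.copy()
    present = ~np.isnan(vals)
    global_mean = float(np.nanmean(vals))
    global_sd = float(np.nanstd(vals, ddof=1))
    for j in range(vals.shape[1]):
        col = vals[:, j]
        pres = present[:, j]
        n_missing = int((~pres).sum())
        if n_missing == 0:
            continue
        if pres.sum() >= 2:
            mu = float(col[pres].mean())
            sd = float(col[pres].std(ddof=1))
        else:
            logger.warning(
                "sample %s has <2 present values; imputing from global statistics",
                m.sample_ids[j],
            )
            mu, sd = global_mean, global_sd
        draws = rng.normal(
            mu - cfg.impute_downshift * sd, cfg.impute_width * sd, size=n_missing
        )
        col[~pres] = draws
    data = pd.DataFrame(vals, index=m.data.index, columns=m.data.columns)
    return AbundanceMatrix(data, log_transformed=True)


def pca_embed(m: AbundanceMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto principal components of the protein space.

    Returns per-sample coordinates (rows = samples, columns ``PC1..PCk``)
    and the explained-variance fractions, which are non-increasing and sum
    to at most 1.  Requires a complete (imputed) matrix.
    """
    if not m.is_complete():
        raise ValidationError("PCA requires a complete matrix; impute first")
    if m.n_samples < 2:
        raise ValidationError("PCA requires at least two samples")
    n_components = min(n_components, m.n_samples - 1, m.n_proteins)
    X = m.values.T  # samples x proteins
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=m.sample_ids, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )
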