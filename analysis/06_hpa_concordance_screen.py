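"""Knowledge-base concordance screen of the shortlisted candidates.

Computes the antibody-staining immunoscore (weights 4/3/2/1 for
high/medium/low/not-detected staining, averaged over antibodies) for
each shortlisted protein and excludes candidates the public atlas calls
highly expressed in urothelial carcinoma while the proteome found them
higher in IUP (i.e. down in carcinoma).
"""

from pathlib import Path

import pandas as pd

from invpap import (
    concordance_filter,
    fold_change,
    immunoscore,
    read_abundance_table,
    read_metadata,
)
from invpap.hpa import read_staining_profiles

OUT = Path("results")


def main() -> None:
    shortlist = pd.read_csv(OUT / "shortlist.tsv", sep="\t")["protein"].tolist()
    profiles = read_staining_profiles(OUT / "data" / "hpa_profiles.tsv")
    scores = {pid: immunoscore(plist).immunoscore for pid, plist in profiles.items()}

    m = read_abundance_table(OUT / "preprocessed.tsv", log_transformed=True)
    groups = read_metadata(OUT / "data" / "metadata.tsv")
    fc = fold_change(m, groups, "IUP", "PUC")

    retained, verdicts = concordance_filter(shortlist, scores, fc.to_dict())
    verdicts.to_csv(OUT / "hpa_screen.tsv", sep="\t", index=False)
    for row in verdicts.itertuples(index=False):
        print(f"{row.protein}: immunoscore {row.immunoscore:.2f}, "
              f"log2 FC {row.log2_fc:+.2f} -> {row.verdict}")
    print(f"final candidates: {', '.join(retained) if retained else '(none)'}")
    pd.DataFrame({"protein": retained}).to_csv(
        OUT / "final_candidates.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
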