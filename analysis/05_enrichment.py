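#!/usr/bin/env python
"""Hypergeometric enrichment of age-related CpGs in annotation sets.

Takes the top-500 positively and negatively age-correlated CpGs from each
EWAS source (meta, laevis, tropicalis) and tests their overlap with the
PRC2 and PRC1 annotation sets against the cohort background.  The planted
expectation, mirroring the biology, is strong PRC2 enrichment of the
positive lists only.  Reads results/ewas/, writes results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from frogclock.enrichment import enrichment_report
from frogclock.io import read_annotation_sets

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sets = read_annotation_sets(
        ROOT / "cohort" / "annotation_sets.tsv",
        ROOT / "cohort" / "annotation_background.tsv",
    )
    tables = {
        name: pd.read_csv(ROOT / "ewas" / f"ewas_{name}.tsv", sep="\t")
        for name in ("meta", "laevis", "tropicalis")
    }
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    table = enrichment_report(tables, sets, k=500)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    for _, row in table.iterrows():
        print(
            f"{row['source']:>10} {row['direction']} vs {row['set_name']:>4}: "
            f"overlap {row['k_overlap']:>3}/{row['n_selected']} "
            f"OR={row['odds_ratio']:.2f}  p={row['p']:.2e}"
        )


if __name__ == "__main__":
    main()
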