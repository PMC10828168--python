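#!/usr/bin/env python
"""EWAS of age per frog species, plus Stouffer meta-analysis.

Correlates each CpG's methylation with chronological age within X. laevis
and X. tropicalis separately (tissue ignored — the low-n design choice),
combines the two screens with the equal-weight Stouffer method, reports
the counts of genome-wide (p < 1e-7) and suggestive (p < 1e-5) hits, and
checks them against the planted ground truth.  Writes results/ewas/.
"""

import json
from pathlib import Path

import pandas as pd

from frogclock.ewas import correlation_screen, stouffer_combine, threshold_report
from frogclock.io import assemble_cohort, read_beta_matrix, read_sample_sheet

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = assemble_cohort(
        read_beta_matrix(ROOT / "cohort" / "beta.tsv"),
        read_sample_sheet(ROOT / "cohort" / "samples.tsv"),
    )
    frogs = cohort.select_samples(cohort.cohorts == "frog")
    truth = pd.read_csv(ROOT / "cohort" / "truth_cpgs.tsv", sep="\t")
    planted = set(truth.loc[truth["direction"] != 0, "cpg_id"])

    out = ROOT / "ewas"
    out.mkdir(parents=True, exist_ok=True)
    tables = {}
    for sp in ("laevis", "tropicalis"):
        sub = frogs.select_samples(frogs.species == sp)
        tables[sp] = correlation_screen(sub)
        tables[sp].to_csv(out / f"ewas_{sp}.tsv", sep="\t", index=False)
    meta = stouffer_combine([tables["laevis"], tables["tropicalis"]])
    meta.to_csv(out / "ewas_meta.tsv", sep="\t", index=False)

    report = threshold_report(meta)
    (out / "thresholds.json").write_text(json.dumps(report, indent=2) + "\n")
    for level in ("genomewide", "suggestive"):
        rep = report[level]
        hits = set(rep["positive_ids"]) | set(rep["negative_ids"])
        frac = len(hits & planted) / len(hits) if hits else float("nan")
        print(
            f"{level} (p < {rep['cutoff']:.0e}): {rep['n_total']} CpGs "
            f"({rep['n_positive']}+ / {rep['n_negative']}-), "
            f"{frac:.0%} planted"
        )


if __name__ == "__main__":
    main()
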