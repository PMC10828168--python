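#!/usr/bin/env python
"""Hierarchical clustering QC of the frog samples.

Computes 1 - Pearson correlation distances between samples, builds the
average-linkage (UPGMA) dendrogram, and reports how the branch structure
relates to species — in the study the two outermost branches separate
X. laevis from X. tropicalis.  Reads results/cohort/, writes results/qc/.
"""

from pathlib import Path

from frogclock.cluster import average_linkage, correlation_dissimilarity, cut_height, to_newick
from frogclock.io import assemble_cohort, read_beta_matrix, read_sample_sheet

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = assemble_cohort(
        read_beta_matrix(ROOT / "cohort" / "beta.tsv"),
        read_sample_sheet(ROOT / "cohort" / "samples.tsv"),
    )
    frogs = cohort.select_samples(cohort.cohorts == "frog")
    dend = average_linkage(correlation_dissimilarity(frogs))
    two_branch = cut_height(dend, dend.heights[-1] - 1e-9)

    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    two_branch.rename_axis("sample_id").reset_index().to_csv(
        out / "branches.tsv", sep="\t", index=False
    )
    (out / "dendrogram.nwk").write_text(to_newick(dend) + "\n")

    species = dict(zip([s.sample_id for s in frogs.samples], frogs.species))
    purity = {}
    for branch in sorted(two_branch.unique()):
        members = two_branch[two_branch == branch].index
        sp = [species[m] for m in members]
        top = max(set(sp), key=sp.count)
        purity[branch] = (top, sp.count(top) / len(sp))
    print(f"{len(dend.heights)} merges, final height {dend.heights[-1]:.4f}")
    for branch, (sp, frac) in purity.items():
        print(f"branch {branch}: dominated by {sp} ({frac:.0%})")


if __name__ == "__main__":
    main()
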