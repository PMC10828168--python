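"""Epigenome-wide association study of age.

Each per-species screen correlates chronological age with individual CpG
methylation levels: Pearson r, the exact t statistic ``r*sqrt(n-2)/sqrt(1-r^2)``
with its two-sided Student-t p-value, and the signed standard-normal
equivalent ``z = sign(r) * Phi^{-1}(1 - p/2)``.  Species-level results are
combined with Stouffer's equal-weight method, ``z_meta = sum(z_i)/sqrt(k)``,
which is standard normal under the null of no age correlation in any study.

Tissue is ignored within a species by default (the study's low-n choice); a
per-tissue screen combined across tissues by the same Stouffer rule is
available for the stratified variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylationCohort, ValidationError

__all__ = [
    "correlation_screen",
    "correlation_screen_by_tissue",
    "stouffer_combine",
    "threshold_report",
    "compare_z",
]

P_FLOOR = 1e-300  # keeps z finite when |r| is numerically 1

GENOMEWIDE_P = 1e-7
SUGGESTIVE_P = 1e-5


def _screen_arrays(values: np.ndarray, ages: np.ndarray):
    """Vectorised per-row Pearson screen of a CpG-by-sample matrix against
    age; NaN betas are excluded row-wise (pairwise-complete)."""
    n_cpg = values.shape[0]
    r = np.full(n_cpg, np.nan)
    n_used = np.zeros(n_cpg, dtype=int)
    mask = ~np.isnan(values)
    for i in range(n_cpg):
        m = mask[i]
        n = int(m.sum())
        n_used[i] = n
        if n < 4:
            continue
        x = values[i, m]
        a = ages[m]
        sx = x.std()
        sa = a.std()
        if sx == 0 or sa == 0:
            continue
        r[i] = np.clip(((x - x.mean()) * (a - a.mean())).mean() / (sx * sa),
                       -1.0, 1.0)
    return r, n_used


def correlation_screen(cohort: MethylationCohort,
                       universe=None) -> pd.DataFrame:
    """Per-CpG Pearson correlation of beta with chronological age.

    Parameters
    ----------
    cohort
        Samples of one species (or whatever grouping the caller intends).
    universe
        Optional CpG id set restricting the screen (e.g. the genome-mapped
        subset); cohort order is preserved.

    Returns
    -------
    DataFrame with columns cpg_id, n, r, z, p, direction.  CpGs with
    undefined correlation (zero variance, or too few samples) appear with
    NaN r and are excluded from downstream ranking.
    """
    if cohort.n_samples < 4:
        raise ValidationError("EWAS needs at least 4 samples")
    if universe is not None:
        keep = [c for c in cohort.beta.cpg_ids if c in set(universe)]
        if not keep:
            raise ValidationError("universe does not intersect cohort CpGs")
        cohort = cohort.select_cpgs(keep)
    r, n_used = _screen_arrays(cohort.beta.values, cohort.ages)

    with np.errstate(divide="ignore", invalid="ignore"):
        df_t = n_used - 2
        t = r * np.sqrt(df_t) / np.sqrt(1.0 - r**2)
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df_t, 1))
    p = np.where(np.isfinite(t), p, 0.0)        # |r| == 1 exactly
    p = np.clip(p, P_FLOOR, 1.0)
    z = np.sign(r) * stats.norm.isf(p / 2.0)
    z = np.where(np.isnan(r), np.nan, z)
    p = np.where(np.isnan(r), np.nan, p)

    return pd.DataFrame(
        {
            "cpg_id": cohort.beta.cpg_ids,
            "n": n_used,
            "r": r,
            "z": z,
            "p": p,
            "direction": np.where(np.isnan(r), "", np.where(r >= 0, "+", "-")),
        }
    )


def correlation_screen_by_tissue(cohort: MethylationCohort, universe=None,
                                 min_n: int = 4) -> pd.DataFrame:
    """Stratified variant: screen each tissue separately (tissues with fewer
    than *min_n* samples are skipped) and Stouffer-combine across tissues."""
    tables = []
    for tissue in sorted(set(cohort.tissues)):
        sub = cohort.select_samples(cohort.tissues == tissue)
        if sub.n_samples < min_n:
            continue
        tables.append(correlation_screen(sub, universe=universe))
    if not tables:
        raise ValidationError("no tissue stratum has enough samples")
    if len(tables) == 1:
        t = tables[0].rename(columns={"z": "z_meta", "p": "p_meta"})
        t["k"] = 1
        return t[["cpg_id", "z_meta", "p_meta", "k"]]
    return stouffer_combine(tables)


def stouffer_combine(tables) -> pd.DataFrame:
    """Equal-weight Stouffer combination over the CpG intersection.

    ``z_meta = sum(z_i) / sqrt(k)``; rows with undefined r in any input are
    dropped.  Symmetric under table exchange.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 EWAS tables to combine")
    frames = []
    for i, t in enumerate(tables):
        f = t.loc[~t["r"].isna(), ["cpg_id", "z"]].set_index("cpg_id")
        frames.append(f.rename(columns={"z": f"z{i}"}))
    joined = frames[0]
    for f in frames[1:]:
        joined = joined.join(f, how="inner")
    if joined.empty:
        raise ValidationError("EWAS tables share no CpGs with defined r")
    k = len(tables)
    z_meta = joined.sum(axis=1).to_numpy() / np.sqrt(k)
    p_meta = np.clip(2.0 * stats.norm.sf(np.abs(z_meta)), P_FLOOR, 1.0)
    # preserve first table's CpG order over the intersection
    order = [c for c in tables[0]["cpg_id"] if c in joined.index]
    out = pd.DataFrame(
        {"cpg_id": joined.index, "z_meta": z_meta, "p_meta": p_meta, "k": k}
    ).set_index("cpg_id").loc[order].reset_index()
    return out


def _zp_columns(rows: pd.DataFrame):
    if "z_meta" in rows.columns:
        return "z_meta", "p_meta"
    return "z", "p"


def threshold_report(rows: pd.DataFrame, genomewide: float = GENOMEWIDE_P,
                     suggestive: float = SUGGESTIVE_P) -> dict:
    """Counts and id lists of CpGs passing the genome-wide and suggestive
    p-value cutoffs, split by direction of association."""
    if not (0 < genomewide <= suggestive < 1):
        raise ValueError("need 0 < genomewide <= suggestive < 1")
    zcol, pcol = _zp_columns(rows)
    ok = rows.loc[~rows[zcol].isna()]
    report = {}
    for label, cutoff in (("genomewide", genomewide), ("suggestive", suggestive)):
        passing = ok.loc[ok[pcol] < cutoff]
        pos = passing.loc[passing[zcol] > 0, "cpg_id"].tolist()
        neg = passing.loc[passing[zcol] < 0, "cpg_id"].tolist()
        report[label] = {
            "cutoff": cutoff,
            "n_total": len(passing),
            "n_positive": len(pos),
            "n_negative": len(neg),
            "positive_ids": pos,
            "negative_ids": neg,
        }
    return report


def compare_z(a: pd.Series, b: pd.Series):
    """Pearson correlation between two z vectors over their shared CpGs.

    Mirrors the cross-study comparison of age-EWAS Z statistics (e.g. frog
    meta-analysis vs an external eutherian EWAS).  Returns (r, two-sided p).
    """
    a = pd.Series(a).dropna()
    b = pd.Series(b).dropna()
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValidationError("need >= 3 shared CpGs to compare z vectors")
    x = a.loc[common].to_numpy(float)
    y = b.loc[common].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("constant z vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
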