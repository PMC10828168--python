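"""Hypergeometric overlap of age-related CpGs with annotation sets.

The top-k CpGs gaining (or losing) methylation with age are intersected with
named annotation sets (PRC1/PRC2 targets, chromatin states, ...) over a
restricted background — the CpG universe actually analysed, not the whole
array — so enrichment is not confounded by platform design.  For each set
the one-sided upper-tail hypergeometric p-value tests over-representation;
the sample odds ratio of the 2x2 overlap table (Haldane-Anscombe 0.5
correction when any cell is empty) conveys direction, with OR < 1 read as
depletion (the complementary lower-tail p is also emitted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationSets, ValidationError

__all__ = ["select_top_k", "hypergeom_enrich", "enrichment_report"]

TOP_K = 500


def select_top_k(rows: pd.DataFrame, k: int, direction: str) -> list:
    """The k CpGs most associated with age in the given direction.

    Rows are ranked by z (descending for '+', ascending for '-'); only rows
    whose z has the requested sign are eligible.  Ties break by
    lexicographic CpG id.  Returns ids in rank order (fewer than k if the
    table runs out).
    """
    if direction not in ("+", "-"):
        raise ValueError("direction must be '+' or '-'")
    if k < 1:
        raise ValueError("k must be >= 1")
    zcol = "z_meta" if "z_meta" in rows.columns else "z"
    ok = rows.loc[~rows[zcol].isna(), ["cpg_id", zcol]]
    if direction == "+":
        ok = ok.loc[ok[zcol] > 0]
        ranked = ok.sort_values([zcol, "cpg_id"], ascending=[False, True])
    else:
        ok = ok.loc[ok[zcol] < 0]
        ranked = ok.sort_values([zcol, "cpg_id"], ascending=[True, True])
    if ranked.empty:
        raise ValidationError(f"no rows with direction {direction!r}")
    return ranked["cpg_id"].head(k).tolist()


def _odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Sample OR of the 2x2 table [[a, b], [c, d]] with 0.5 correction
    applied to every cell when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def hypergeom_enrich(selected, sets: AnnotationSets) -> pd.DataFrame:
    """Overlap of a selected CpG list with every named set.

    For each set of size K in a background of size N, with n selected CpGs
    of which k overlap the set, the enrichment p-value is
    P(X >= k), X ~ Hypergeometric(N, K, n).  Columns: set_name, k_overlap,
    K_set, n_selected, N_background, odds_ratio, p, p_lower.
    """
    selected = set(selected)
    extra = selected - sets.background
    if extra:
        raise ValidationError(
            f"selected CpGs outside the background: {sorted(extra)[:5]}"
        )
    N = len(sets.background)
    n = len(selected)
    rows = []
    for name in sorted(sets.named_sets):
        members = sets.named_sets[name]
        K = len(members)
        k = len(selected & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_lower = float(stats.hypergeom.cdf(k, N, K, n))
        odds = _odds_ratio(k, K - k, n - k, N - K - n + k)
        rows.append(
            {
                "set_name": name,
                "k_overlap": k,
                "K_set": K,
                "n_selected": n,
                "N_background": N,
                "odds_ratio": odds,
                "p": min(max(p, np.nextafter(0, 1)), 1.0),
                "p_lower": min(p_lower, 1.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["set_name", "k_overlap", "K_set", "n_selected",
                 "N_background", "odds_ratio", "p", "p_lower"],
    )


def enrichment_report(ewas_tables: dict, sets: AnnotationSets,
                      k: int = TOP_K) -> pd.DataFrame:
    """Enrichment of top-k positive and negative CpG lists from each EWAS
    source (e.g. meta, laevis, tropicalis) against every annotation set.

    The ``signed_log10_p`` display column is -log10(p) carrying the sign of
    (OR > 1): positive for over-, negative for under-representation.
    """
    frames = []
    for source, table in ewas_tables.items():
        for direction in ("+", "-"):
            chosen = select_top_k(table, k, direction)
            enr = hypergeom_enrich(chosen, sets)
            enr.insert(0, "source", source)
            enr.insert(1, "direction", direction)
            frames.append(enr)
    if not frames:
        return pd.DataFrame(
            columns=["source", "direction", "set_name", "k_overlap", "K_set",
                     "n_selected", "N_background", "odds_ratio", "p",
                     "p_lower", "signed_log10_p"]
        )
    out = pd.concat(frames, ignore_index=True)
    if out.empty:
        out["signed_log10_p"] = pd.Series(dtype=float)
        return out
    sign = np.where(out["odds_ratio"] > 1, 1.0, -1.0)
    out["signed_log10_p"] = -np.log10(out["p"]) * sign
    return out
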