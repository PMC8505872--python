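"""GO-term over-representation analysis.

One-sided hypergeometric test of each term's annotation count in a study
set against the population, with rare terms removed before testing and
Benjamini-Hochberg FDR control across the remaining terms.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = ["hypergeom_upper_tail", "enrich", "term_map_from_annotation"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K annotated, n drawn).

    ``k`` study genes annotated with the term, out of ``n`` study genes,
    against ``K`` annotated genes in a population of ``N``.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def term_map_from_annotation(annotation: pd.DataFrame, column: str = "go_terms") -> dict:
    """Term -> set-of-genes map from a per-gene annotation table.

    ``annotation[column]`` holds semicolon-delimited term identifiers (empty
    string for unannotated genes).
    """
    terms: dict[str, set] = {}
    for gene, cell in annotation[column].items():
        if not isinstance(cell, str) or not cell:
            continue
        for term in cell.split(";"):
            term = term.strip()
            if term:
                terms.setdefault(term, set()).add(gene)
    return terms


def enrich(
    study_set,
    population,
    term_map: dict,
    min_term_size: int = 5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-represented terms in ``study_set`` relative to ``population``.

    Terms annotating fewer than ``min_term_size`` population genes are
    dropped *before* testing, so the BH correction runs over the filtered
    term list only.  Returns one row per tested term with the hypergeometric
    counts (k, n, K, N), the upper-tail p, BH q and the enriched flag
    (q < fdr_threshold).
    """
    study = set(study_set)
    pop = set(population)
    stray = study - pop
    if stray:
        raise ValueError(f"study genes absent from population: {sorted(stray)[:3]}")
    N, n = len(pop), len(study)

    rows = []
    for term, genes in sorted(term_map.items()):
        annotated = genes & pop
        K = len(annotated)
        if K < min_term_size:
            continue
        k = len(annotated & study)
        rows.append(
            {
                "term": term,
                "study_hits": k,
                "study_size": n,
                "population_hits": K,
                "population_size": N,
                "pvalue": hypergeom_upper_tail(k, K, n, N),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["term", "study_hits", "study_size", "population_hits", "population_size", "pvalue"],
    )
    if len(result):
        result["qvalue"] = bh_adjust(result["pvalue"].to_numpy())
        result["enriched"] = result["qvalue"] < fdr_threshold
        result = result.sort_values("pvalue", kind="stable").reset_index(drop=True)
    else:
        result["qvalue"] = []
        result["enriched"] = []
    return result
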