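"""Pathway enrichment and GO-term meta-enrichment.

Pathway enrichment is the standard hypergeometric over-representation
test of a gene list against a GOBP-like collection: the universe is
fixed first, every set is intersected with it, and a pathway is called
significant only at FDR q < 0.05 *and* with at least two input genes in
the pathway.

Term meta-enrichment summarises a collection of significant pathways at
the level of their annotated GO-style terms (a REVIGO-like reduction):
per term, a 2x2 table of [annotated vs not] x [significant vs not]
pathways is tested with two-sided Fisher, BH-adjusted across terms, and
a term is flagged *enriched* only when q < 0.05 and the odds ratio
exceeds 1 (depletions are reported but never flagged).
"""

from __future__ import annotations

import pandas as pd

from .containers import GeneSetCollection
from .integrate import OverlapResult, list_overlap
from .stats import (
    ContingencyTable2x2,
    HypergeomQuery,
    bh_adjust,
    fisher_exact_two_sided,
    hypergeometric_tail,
)

PATHWAY_COLUMNS = ("pathway", "overlap_k", "set_size", "pvalue", "qvalue", "significant", "member_genes")
TERM_COLUMNS = ("term", "odds_ratio", "pvalue", "qvalue", "pct_of_pathways", "enriched")


def pathway_enrichment(
    gene_list,
    collection: GeneSetCollection,
    universe,
    q_threshold: float = 0.05,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Returns one row per pathway with a non-empty universe
    intersection, sorted by p-value. ``significant`` requires
    q < ``q_threshold`` and ``overlap_k >= min_overlap``.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    genes = frozenset(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    if not genes <= uni:
        raise ValueError("gene list must be a subset of the universe")

    restricted = collection.restricted_to(uni)
    N, n = len(uni), len(genes)
    rows = []
    for name in restricted:
        members = restricted[name]
        K = len(members)
        overlap = members & genes
        k = len(overlap)
        p = hypergeometric_tail(HypergeomQuery(N=N, K=K, n=n, k=k))
        rows.append(
            dict(
                pathway=name,
                overlap_k=k,
                set_size=K,
                pvalue=p,
                member_genes=",".join(sorted(overlap)),
            )
        )
    out = pd.DataFrame(rows, columns=["pathway", "overlap_k", "set_size", "pvalue", "member_genes"])
    if len(out):
        out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["qvalue"] = pd.Series(dtype=float)
    out["significant"] = (out["qvalue"] < q_threshold) & (out["overlap_k"] >= min_overlap)
    return out[list(PATHWAY_COLUMNS)].sort_values(
        ["pvalue", "pathway"], kind="stable", ignore_index=True
    )


def go_term_meta_enrichment(
    significant_pathways,
    all_pathways,
    annotation: dict,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """REVIGO-style term enrichment over a set of significant pathways.

    ``annotation`` maps pathway name -> set of term ids and must cover
    ``all_pathways``; terms annotating no pathway are skipped. Returns
    one row per term with the Fisher odds ratio, p/q, the share of
    significant pathways carrying the term, and the enriched flag
    (q < 0.05 and OR > 1).
    """
    all_set = set(all_pathways)
    sig_set = set(significant_pathways)
    if not sig_set <= all_set:
        raise ValueError("significant pathways must be a subset of all pathways")
    missing = [p for p in all_set if p not in annotation]
    if missing:
        raise ValueError(f"annotation missing for pathways: {sorted(missing)[:5]}")
    if not sig_set:
        return pd.DataFrame(columns=list(TERM_COLUMNS))

    terms: set[str] = set()
    for p in all_set:
        terms |= set(annotation[p])
    rows = []
    n_sig = len(sig_set)
    for term in sorted(terms):
        carriers = {p for p in all_set if term in annotation[p]}
        a = len(carriers & sig_set)  # annotated & significant
        b = len(carriers) - a
        c = n_sig - a
        d = len(all_set) - len(carriers) - c
        orat, p = fisher_exact_two_sided(ContingencyTable2x2(a=a, b=b, c=c, d=d))
        rows.append(
            dict(term=term, odds_ratio=orat, pvalue=p, pct_of_pathways=100.0 * a / n_sig)
        )
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["enriched"] = (out["qvalue"] < q_threshold) & (out["odds_ratio"] > 1)
    return out[list(TERM_COLUMNS)].sort_values(
        ["pvalue", "term"], kind="stable", ignore_index=True
    )


def pathway_list_overlap(sig_a, sig_b, all_pathways) -> OverlapResult:
    """Hypergeometric overlap of two significant-pathway lists over the
    tested-pathway universe."""
    return list_overlap(sig_a, sig_b, all_pathways)
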