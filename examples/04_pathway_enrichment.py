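"""Pathway enrichment of network targets and GO-term meta-enrichment.

Network target genes are tested against a GOBP-like collection
(hypergeometric, FDR < 0.05, >= 2 overlapping genes); the significant
pathways are then summarized at the level of their GO-style term
annotations with a two-sided Fisher test and an odds-ratio > 1 filter.
"""

import mirweave as mw

study = mw.simulate_study(mw.SimulationConfig(seed=1))
gene_de = mw.classify_de_genes(mw.fit_de(study.gene_counts, study.metadata))
mirna = mw.screen_de_mirnas(mw.fit_de(study.mirna_counts, study.metadata))
net = mw.enrich_mirna_targets(mirna, gene_de, study.compendium, "canonical_up_down")

measured = set(gene_de["feature_id"])
table = mw.pathway_enrichment(sorted(net.target_genes), study.gobp, measured)
sig = table[table["significant"]]
print(f"significant pathways: {len(sig)} of {len(table)} tested")
print(sig.head(8)[["pathway", "overlap_k", "set_size", "qvalue"]].to_string(index=False))

terms = mw.go_term_meta_enrichment(list(sig["pathway"]), list(study.gobp.sets),
                                   study.term_annotation)
enriched = terms[terms["enriched"]]
print(f"\nenriched GO-style terms: {len(enriched)} of {len(terms)} tested")
print(enriched[["term", "odds_ratio", "qvalue", "pct_of_pathways"]]
      .round(4).to_string(index=False))
print("\nThe planted target-heavy pathways preferentially carry the first few")
print("term ids, so those terms surface with odds ratio > 1 at FDR < 0.05.")
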