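"""Call differentially expressed genes and screen miRNA candidates.

Genes: NB GLM with Sex/Age/PMI/pH/RIN adjustment, called at
|fold change| > 1.5 and FDR q < 0.05. miRNAs: screened at unadjusted
p < 0.05 with direction by the sign of the fold change.
"""

import mirweave as mw

study = mw.simulate_study(mw.SimulationConfig(seed=1))

gene_de = mw.classify_de_genes(mw.fit_de(study.gene_counts, study.metadata))
mirna = mw.screen_de_mirnas(mw.fit_de(study.mirna_counts, study.metadata))

n_up = (gene_de["direction"] == "up").sum()
n_down = (gene_de["direction"] == "down").sum()
print(f"DE genes: {n_down} down, {n_up} up of {len(gene_de)} tested")

targets = gene_de[gene_de["feature_id"].isin(study.truth.all_target_genes)]
print(f"planted targets called down: {(targets['direction'] == 'down').sum()} / {len(targets)}")
print(f"median estimated log2FC on targets: {targets['log2fc'].median():+.2f} (planted -1)")

cand = mirna[mirna["direction"] != "ns"]
print(f"\nmiRNA candidates at raw p<0.05: {len(cand)} "
      f"({(cand['direction'] == 'up').sum()} up)")
print(cand[["feature_id", "log2fc", "pvalue", "direction"]].to_string(index=False))

demo = mw.demographics_compare(study.metadata)
lo, hi = demo["age_ci"]
print(f"\ncohort demographics: {demo['male_pct_control']}% vs {demo['male_pct_case']}% male "
      f"(Fisher p={demo['sex_fisher_p']:.3f}); age gap 95% CI [{lo:.1f}, {hi:.1f}] years")
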