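"""Summed z-score signature correlation over a 425-sample corpus.

Each gene set's score per corpus sample is the sum of its members'
z-scored log2CPM; co-regulated sets (sharing a planted latent factor)
show high score-score Pearson correlation, independent sets do not.
"""

import mirweave as mw

config = mw.SimulationConfig(seed=1)
truth = mw.make_ground_truth(config)
corpus = mw.simulate_reference_corpus(config, truth)
print(f"reference corpus: {corpus}")

modules = sorted(set(truth.planted_module_labels.values()))
module_sets = mw.GeneSetCollection({
    m: frozenset(g for g, label in truth.planted_module_labels.items() if label == m)
    for m in modules
})
hallmark = mw.GeneSetCollection({n: truth.pathway_membership[n] for n in truth.hallmark_names})

scores_m = mw.score_signatures(corpus, module_sets)
scores_h = mw.score_signatures(corpus, hallmark)
table = mw.correlate_scores(scores_m, scores_h).set_index(["set_a", "set_b"])

print("\nmodule vs co-regulated Hallmark-like set (shared latent factor):")
for i, m in enumerate(modules):
    partner = truth.hallmark_names[i]
    r = table.loc[(m, partner), "r"]
    print(f"  {m} ~ {partner}: r = {r:+.3f}")

stranger = truth.hallmark_names[20]
r0 = table.loc[(modules[0], stranger), "r"]
print(f"\nindependent pair {modules[0]} ~ {stranger}: r = {r0:+.3f}")
print("Shared-factor pairs approach r = 1; independent pairs sit near 0,")
print("within sampling noise for a 425-sample corpus.")
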