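"""Choose the topic count automatically and annotate topics with gene sets.

The scan fits one model per candidate count and scores each by topic
specificity (how unevenly a topic spreads over cells) and purity (how few
topics dominate each cell); the combination score picks the winner. Topics
are then annotated by hypergeometric over-representation of their top-10%
genes against a user gene-set collection.
"""

import numpy as np

import topicscreen as ts

cfg = ts.SimConfig(seed=3, n_perturbations=3, n_cells_per_perturbation=40,
                   n_control_cells=100, library_size=500.0)
dataset, truth = ts.simulate_screen(cfg)

scan = ts.select_topic_number(dataset.counts.astype(int), [2, 3, 4, 5],
                              seed=3, n_iter=150, burn_in=75,
                              gene_ids=dataset.gene_ids)
print("topic-number scan (planted count is 3; larger CS is better):")
print(scan.as_frame().round(3).to_string(index=False))
print(f"selected: {scan.best} topics")

# annotate against the planted programs: each set = a topic's top genes
model = scan.models[scan.best]
sets = {}
for t in range(truth.phi_true.shape[0]):
    top = np.argsort(truth.phi_true[t])[::-1][:15]
    sets[f"program_{t}"] = [dataset.gene_ids[g] for g in top]
ann = ts.annotate_topics(model, ts.GeneSetCollection(sets=sets),
                         top_fraction=0.10, n_terms=3)
print("\ntop enriched set per fitted topic (q = BH-adjusted hypergeometric):")
best = ann.enrichment.groupby("topic").head(1)
print(best[["topic", "term", "overlap", "q"]].to_string(index=False))
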