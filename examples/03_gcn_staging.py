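"""Transductive GCN staging on one population graph, end to end.

Trains the two-layer GCN on the full MCI-versus-CN graph (test nodes
present but unlabelled), then reports test-set metrics in the benchmark's
ACC/PRE/REC/F1/MCC layout, alongside a linear-SVM baseline that sees the
same feature vectors without the graph.
"""
import numpy as np

import popgraph_stager as pg

# a noisy-embedding regime: high-rank residual noise so the feature vectors
# alone are weak evidence, while the CDR-SB edges remain clean
config = pg.CohortConfig(class_counts={"CN": 80, "MCI": 80, "AD": 0},
                         feature_dim=128, class_separation=1.0,
                         residual_sd=2.0, seed=4)
cohort = pg.generate_cohort(config)
features = pg.generate_features(cohort, config)
sub = cohort.subset(("CN", "MCI"))
labels = cohort.labels(("CN", "MCI"))

spec = pg.EdgeSpec("combined", [pg.EdgeFeature("CDR_SB", "quantitative", 1.0)])
graph = pg.build_graph(features, sub, spec)

gcn_config = pg.GCNConfig(n_classes=2, learning_rate=3e-3, seed=0)
model, history = pg.train_transductive(graph, labels, gcn_config)
pred, _ = pg.predict(model, graph)

test = graph.masks["test"]
cm = pg.confusion(labels[test], pred[test], [0, 1])
cm.positive_class = 1  # MCI, the more-impaired class
report = pg.binary_metrics(cm)
print(f"GCN on {spec.label} graph ({len(history)} epochs):")
print("  " + "  ".join(f"{k} {v:.1f}" for k, v in report.as_row().items()))

svm_report, _ = pg.vector_baseline(features.values, labels, sub.masks())
print("linear SVM on the same vectors (no graph):")
print("  " + "  ".join(f"{k} {v:.1f}" for k, v in svm_report.as_row().items()))

# The GCN sees both the feature vectors and the phenotype-agreement edges;
# when the embeddings are noisy but the edge covariate is informative, the
# graph route beats the vector-only SVM.  With clean, linearly separable
# embeddings the SVM can match or exceed it — the graph pays off exactly
# when the edges carry complementary information.
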