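"""Train the 3-D DenseNet on toy phantoms and extract node features.

Uses a reduced architecture on 16^3 phantom volumes with class-proportional
'atrophy' in fixed ellipsoidal regions, then pulls the first-FC-layer
embedding that would feed the population graph.  The default configuration
(not trained here) reproduces the full architecture: 64^3 input, three
dense blocks of three units, growth 12, bottleneck 48, compression 0.5 and
a 512/256 FC head.
"""
import numpy as np

import popgraph_stager as pg
from popgraph_stager.densenet import build_extractor

# the full architecture, just to show its shape table
full = build_extractor(pg.DenseNetConfig())
print("default architecture (first rows of the shape table):")
for layer in full.layers[:6]:
    print(f"  {layer['name']:<14} channels {layer['channels']:>3} "
          f"spatial {layer['spatial']}")
print(f"  ... embedding width {full.embedding_dim}, "
      f"{full.n_params:,} parameters\n")

config = pg.CohortConfig(class_counts={"CN": 12, "MCI": 0, "AD": 12}, seed=6)
cohort = pg.generate_cohort(config)
volumes = pg.generate_volumes(cohort, shape=(16, 16, 16),
                              atrophy_amplitude=0.8, seed=6)

cnn = pg.DenseNetConfig(input_shape=(16, 16, 16), n_blocks=2,
                        units_per_block=2, growth_rate=4,
                        bottleneck_channels=8, init_channels=8,
                        fc_sizes=(32, 16), learning_rate=1e-3, batch_size=8,
                        max_epochs=25, patience=25, seed=6)
labels = cohort.labels(("CN", "AD"))
model, history = pg.train_extractor(volumes, labels, cohort.split, cnn)
features = pg.extract_features(model, volumes)

train_idx = [i for i, sid in enumerate(volumes.ids)
             if cohort.split[sid] == "train"]
logits, _ = model.forward(volumes.data[train_idx], training=False)
acc = np.mean(logits.data.argmax(1) == labels[train_idx])
print(f"reduced CNN: {len(history)} epochs, training accuracy {acc:.2f}")
print(f"embedding matrix: {features.values.shape}, "
      f"nonnegative: {bool(np.all(features.values >= 0))}")
# these rows are exactly what build_graph consumes as node features
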