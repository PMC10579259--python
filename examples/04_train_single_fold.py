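"""Train one supervised conv autoencoder on a single fold's data.

A small 1-s dataset keeps this quick.  The per-epoch trace shows the
joint objective at work: classification cross-entropy (CL),
reconstruction MSE (RC_L) and the weighted total TL = 0.5*CL + 1.0*RC_L
all fall as the model learns both to reconstruct and to classify.
"""

import numpy as np

from seizurecae import (SynthConfig, TrainConfig, assemble,
                        generate_segments, prepare_dataset, train_fold)

collection = generate_segments(
    SynthConfig(segment_seconds=1, n_segments_per_class=40, seed=0))
dataset = prepare_dataset(collection.values[collection.labels == 1],
                          collection.values[collection.labels == 0], seed=0)

train_mask = dataset.fold_ids != 0  # hold fold 0 out
config = TrainConfig(variant="dcae_bilstm", segment_seconds=1, epochs=5,
                     learning_rate=1e-3, seed=0)
model = assemble(config.variant, config.segment_seconds, seed=0)
history = train_fold(model, dataset.values[train_mask],
                     dataset.labels[train_mask], config,
                     shuffle_rng=np.random.default_rng(0))

print("epoch    CL      RC_L    TL      train acc")
for e in range(len(history)):
    print(f"{e + 1:3d}   {history.cl[e]:.4f}  {history.rc[e]:.4f}  "
          f"{history.tl[e]:.4f}   {history.acc[e]:.3f}")
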