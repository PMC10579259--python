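"""Tenfold stratified cross-validation of one model variant.

Runs the full protocol at desk scale (1-s segments, small sample) and
prints per-fold accuracies plus the mean +/- std summary in the layout
used for reporting: sensitivity, specificity, accuracy, precision and
F-score, all as percentages over the held-out folds.
"""

from seizurecae import (SynthConfig, TrainConfig, cross_validate,
                        generate_segments, prepare_dataset)
from seizurecae.experiment import format_mean_std

collection = generate_segments(
    SynthConfig(segment_seconds=1, n_segments_per_class=50, seed=1))
dataset = prepare_dataset(collection.values[collection.labels == 1],
                          collection.values[collection.labels == 0], seed=1)

config = TrainConfig(variant="dcae_bilstm", segment_seconds=1, epochs=5,
                     learning_rate=1e-3, seed=1)
result = cross_validate(dataset, config)

print("per-fold accuracy (%):",
      [round(m.acc, 1) for m in result.fold_metrics])
mean, std = result.mean, result.std
for label, m, s in [("Se", mean.se, std.se), ("Sp", mean.sp, std.sp),
                    ("Acc", mean.acc, std.acc), ("Pr", mean.pr, std.pr),
                    ("F score", mean.f1, std.f1)]:
    print(f"{label:8s} {format_mean_std(m, s)} %")
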