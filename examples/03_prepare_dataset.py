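"""Build a balanced, normalized, fold-assigned dataset from a recording.

Cuts non-overlapping 2-s ictal and interictal segments from an
annotated synthetic recording, balances the classes, standardizes each
channel, scales the whole dataset into [0, 1], appends the depth axis
and assigns stratified tenfold cross-validation folds.
"""

import numpy as np

from seizurecae import (SynthConfig, extract_segments, generate_recording,
                        prepare_dataset)

config = SynthConfig(seed=3)
recording = generate_recording(config, duration_s=1200, n_seizures=4,
                               max_seizure_s=45)

ictal = extract_segments(recording.values, recording.seizure_intervals, 2,
                         "ictal")
# a 60-s exclusion buffer keeps interictal windows away from seizures
interictal = extract_segments(recording.values, recording.seizure_intervals,
                              2, "interictal", exclusion_buffer_s=60.0)
print(f"extracted {len(ictal)} ictal and {len(interictal)} interictal "
      f"segments of shape {ictal.shape[1]} x {ictal.shape[2]}")

dataset = prepare_dataset(ictal, interictal, seed=0)
inter_n, ictal_n = dataset.class_counts()
print(f"balanced dataset: {ictal_n} ictal + {inter_n} interictal, "
      f"values in [{dataset.values.min():.2f}, {dataset.values.max():.2f}], "
      f"shape {dataset.values.shape}")
fold_sizes = [int((dataset.fold_ids == f).sum()) for f in range(10)]
print(f"fold sizes: {fold_sizes}")
print(f"channel stats recorded for inversion: mean[0]="
      f"{dataset.channel_stats.mean[0]:.4f}, "
      f"std[0]={dataset.channel_stats.std[0]:.4f}, "
      f"scale bounds={np.round(dataset.scale_bounds, 3)}")
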