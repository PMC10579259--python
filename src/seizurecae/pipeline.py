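"""From annotated recordings to a balanced, normalized, fold-assigned dataset.

The preparation order is fixed and mirrors the modelling protocol:

1. cut non-overlapping segments (ictal inside seizure intervals,
   interictal outside a buffered neighbourhood of every seizure);
2. balance the classes by seeded down-sampling of the interictal pool;
3. z-score every channel using statistics of the merged dataset;
4. min-max scale the whole dataset globally to [0, 1];
5. append the singleton depth axis;
6. assign stratified tenfold cross-validation folds.

Normalization statistics are computed on the entire merged dataset
before the fold split.  This follows the modelled protocol exactly and
implies a mild train/test leakage of first- and second-moment
information; a per-fold-statistics mode is available via the
``stats`` argument of :func:`zscore_per_channel` for leakage-free
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SegmentTensor",
    "ChannelStats",
    "LabeledDataset",
    "BalanceError",
    "extract_segments",
    "balance_classes",
    "zscore_per_channel",
    "minmax_scale",
    "add_depth_axis",
    "assign_folds",
    "prepare_dataset",
    "inverse_transform",
    "save_dataset",
    "load_dataset",
]

#: Default half-width, in seconds, of the exclusion zone around each
#: seizure from which no interictal segment is drawn (30 min, matching
#: the conventional preictal-window horizon).
DEFAULT_EXCLUSION_BUFFER_S = 1800.0


class BalanceError(ValueError):
    """Raised when the interictal pool is smaller than the ictal pool."""


@dataclass(frozen=True)
class SegmentTensor:
    """One EEG segment: (time x channel [x depth]) values plus a label."""

    values: np.ndarray
    label: int


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and population standard deviation."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")

    @property
    def safe_std(self) -> np.ndarray:
        """Std with zeros replaced by 1 so division is always defined."""
        return np.where(self.std > 0, self.std, 1.0)


@dataclass(frozen=True)
class LabeledDataset:
    """Stacked segments with labels, folds, and normalization state.

    ``values`` has shape (n, I, J) before depth-axis insertion and
    (n, I, J, 1) after; ``labels`` is a binary vector (1 = ictal).
    """

    values: np.ndarray
    labels: np.ndarray
    sampling_rate_hz: float
    segment_seconds: int
    fold_ids: np.ndarray | None = None
    channel_stats: ChannelStats | None = None
    scale_bounds: tuple[float, float] | None = None
    manifest: pd.DataFrame | None = None

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def segments(self) -> list[SegmentTensor]:
        return [SegmentTensor(v, int(l))
                for v, l in zip(self.values, self.labels)]

    def class_counts(self) -> tuple[int, int]:
        """(interictal, ictal) counts."""
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

def _complement(intervals, duration_s: float):
    """Complement of a union of sorted half-open intervals in [0, dur)."""
    free = []
    cursor = 0.0
    for start, end in intervals:
        start, end = max(0.0, start), min(duration_s, end)
        if start > cursor:
            free.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < duration_s:
        free.append((cursor, duration_s))
    return free


def _merge(intervals):
    merged: list[list[float]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def extract_segments(recording: np.ndarray, intervals, segment_seconds: int,
                     state: str, sampling_rate_hz: float = 256.0,
                     exclusion_buffer_s: float = DEFAULT_EXCLUSION_BUFFER_S,
                     ) -> np.ndarray:
    """Cut non-overlapping segments from qualifying regions.

    Parameters
    ----------
    recording
        (channels x samples) grid.
    intervals
        Seizure intervals, half-open [start_s, end_s), sorted, disjoint.
    state
        ``"ictal"`` cuts inside the given intervals; ``"interictal"``
        cuts outside a ``exclusion_buffer_s``-buffered neighbourhood of
        every interval.

    Segments are cut left-aligned and contiguous inside each region;
    trailing partial windows are discarded.  Returns an array of shape
    (n_segments, I, J) with I = rate x window and J = channel count; a
    region shorter than one window simply yields no segments.
    """
    if state not in ("ictal", "interictal"):
        raise ValueError(f"state must be 'ictal' or 'interictal', got {state!r}")
    fs = sampling_rate_hz
    n_ch, n_samp = recording.shape
    duration_s = n_samp / fs
    if state == "ictal":
        regions = [(s, e) for s, e in intervals]
    else:
        buffered = _merge(
            (s - exclusion_buffer_s, e + exclusion_buffer_s)
            for s, e in intervals
        )
        regions = _complement(buffered, duration_s)

    seg_len = int(round(fs * segment_seconds))
    out = []
    for start, end in regions:
        i0 = int(round(start * fs))
        i1 = min(int(round(end * fs)), n_samp)
        n_fit = (i1 - i0) // seg_len
        for k in range(n_fit):
            a = i0 + k * seg_len
            out.append(recording[:, a:a + seg_len].T)
    if not out:
        return np.empty((0, seg_len, n_ch))
    return np.stack(out)


# ---------------------------------------------------------------------------
# Balancing, normalization, folds
# ---------------------------------------------------------------------------

def balance_classes(ictal_segments: np.ndarray,
                    interictal_segments: np.ndarray, seed: int,
                    sampling_rate_hz: float = 256.0,
                    segment_seconds: int | None = None) -> LabeledDataset:
    """Down-sample the interictal pool to the ictal count (seeded).

    Raises :class:`BalanceError` when there are fewer interictal than
    ictal segments; extract more interictal data in that case.
    """
    n_ictal = ictal_segments.shape[0]
    n_inter = interictal_segments.shape[0]
    if n_inter < n_ictal:
        raise BalanceError(
            f"only {n_inter} interictal segments for {n_ictal} ictal ones; "
            "extract more interictal data before balancing"
        )
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n_inter, size=n_ictal, replace=False))
    values = np.concatenate([ictal_segments, interictal_segments[keep]])
    labels = np.concatenate([np.ones(n_ictal, dtype=np.int8),
                             np.zeros(n_ictal, dtype=np.int8)])
    if segment_seconds is None:
        segment_seconds = int(round(
            ictal_segments.shape[1] / sampling_rate_hz))
    return LabeledDataset(values=values, labels=labels,
                          sampling_rate_hz=sampling_rate_hz,
                          segment_seconds=segment_seconds)


def compute_channel_stats(values: np.ndarray) -> ChannelStats:
    """Mean/population-std per channel over the merged dataset."""
    mean = values.mean(axis=(0, 1))
    std = values.std(axis=(0, 1))  # population (divide by n) convention
    return ChannelStats(mean=mean, std=std)


def zscore_per_channel(dataset: LabeledDataset,
                       stats: ChannelStats | None = None) -> LabeledDataset:
    """Standardize every channel to zero mean, unit std (merged stats).

    Channels with zero variance are centered and left at zero (the
    division guard replaces a zero std by 1), never a division fault.
    """
    if stats is None:
        stats = compute_channel_stats(dataset.values)
    values = (dataset.values - stats.mean) / stats.safe_std
    return replace(dataset, values=values, channel_stats=stats)


def minmax_scale(dataset: LabeledDataset) -> LabeledDataset:
    """Scale the whole dataset globally (not per channel) into [0, 1].

    A constant dataset maps to all zeros.  The bounds are recorded on
    the dataset so the transform is invertible.
    """
    lo = float(dataset.values.min())
    hi = float(dataset.values.max())
    if hi - lo < 1e-300:
        values = np.zeros_like(dataset.values)
    else:
        values = (dataset.values - lo) / (hi - lo)
    return replace(dataset, values=values, scale_bounds=(lo, hi))


def add_depth_axis(dataset: LabeledDataset) -> LabeledDataset:
    """Append the singleton depth axis: (n, I, J) -> (n, I, J, 1)."""
    if dataset.values.ndim == 4:
        return dataset
    return replace(dataset, values=dataset.values[..., None])


def assign_folds(dataset: LabeledDataset, k: int = 10,
                 seed: int = 0) -> LabeledDataset:
    """Assign stratified k-fold ids with a seeded shuffle.

    Fold sizes differ by at most one segment and each fold's class
    counts match the dataset proportions within one segment per class.
    Remainder segments of the two classes are placed at opposite ends of
    the fold range so overall fold sizes stay within one of each other.
    """
    labels = dataset.labels
    fold_ids = np.full(len(dataset), -1, dtype=np.int64)
    rng = np.random.default_rng(seed)
    for cls_rank, cls in enumerate(np.unique(labels)):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has only {len(idx)} segments for {k} folds"
            )
        rng.shuffle(idx)
        base, rem = divmod(len(idx), k)
        counts = np.full(k, base, dtype=int)
        if rem:
            extras = (np.arange(rem) if cls_rank % 2 == 0
                      else k - 1 - np.arange(rem))
            counts[extras] += 1
        fold_of = np.repeat(np.arange(k), counts)
        fold_ids[idx] = fold_of
    return replace(dataset, fold_ids=fold_ids)


def prepare_dataset(ictal_segments: np.ndarray,
                    interictal_segments: np.ndarray,
                    seed: int = 0, k: int = 10,
                    sampling_rate_hz: float = 256.0,
                    segment_seconds: int | None = None) -> LabeledDataset:
    """Run the full preparation chain in the fixed protocol order."""
    ds = balance_classes(ictal_segments, interictal_segments, seed=seed,
                         sampling_rate_hz=sampling_rate_hz,
                         segment_seconds=segment_seconds)
    ds = zscore_per_channel(ds)
    ds = minmax_scale(ds)
    ds = add_depth_axis(ds)
    ds = assign_folds(ds, k=k, seed=seed)
    return ds


def inverse_transform(values: np.ndarray, stats: ChannelStats,
                      scale_bounds: tuple[float, float]) -> np.ndarray:
    """Map normalized values back to original signal units."""
    lo, hi = scale_bounds
    v = np.asarray(values)
    if v.ndim == 4:
        v = v[..., 0]
    v = v * (hi - lo) + lo
    return v * stats.safe_std + stats.mean


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_dataset(dataset: LabeledDataset, path: str | Path) -> Path:
    """Serialize to a portable ``.npz`` archive (+``.csv`` manifest)."""
    path = Path(path)
    payload = {
        "values": dataset.values,
        "labels": dataset.labels,
        "sampling_rate_hz": dataset.sampling_rate_hz,
        "segment_seconds": dataset.segment_seconds,
    }
    if dataset.fold_ids is not None:
        payload["fold_ids"] = dataset.fold_ids
    if dataset.channel_stats is not None:
        payload["channel_mean"] = dataset.channel_stats.mean
        payload["channel_std"] = dataset.channel_stats.std
    if dataset.scale_bounds is not None:
        payload["scale_bounds"] = np.asarray(dataset.scale_bounds)
    np.savez_compressed(path, **payload)
    if dataset.manifest is not None:
        dataset.manifest.to_csv(path.with_suffix(".csv"), index=False)
    return path


def load_dataset(path: str | Path) -> LabeledDataset:
    path = Path(path)
    with np.load(path) as z:
        stats = None
        if "channel_mean" in z:
            stats = ChannelStats(mean=z["channel_mean"], std=z["channel_std"])
        bounds = tuple(z["scale_bounds"]) if "scale_bounds" in z else None
        manifest_path = path.with_suffix(".csv")
        manifest = (pd.read_csv(manifest_path)
                    if manifest_path.exists() else None)
        return LabeledDataset(
            values=z["values"], labels=z["labels"],
            sampling_rate_hz=float(z["sampling_rate_hz"]),
            segment_seconds=int(z["segment_seconds"]),
            fold_ids=z["fold_ids"] if "fold_ids" in z else None,
            channel_stats=stats, scale_bounds=bounds, manifest=manifest,
        )
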