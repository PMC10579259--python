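"""Ingestion of scalp EEG recordings in EDF form with seizure annotations.

The module reads EDF files (via :mod:`mne`) plus seizure-interval
annotations into the same in-memory recording representation that the
synthetic generator emits, so the rest of the pipeline is agnostic to
the data source.  Channel identity is enforced through an explicit
manifest rather than trusting file order: public scalp-EEG corpora are
known to change channel names and electrode placements between files.

Annotation inputs are plain sidecar files with one ``start_s end_s``
pair per line; a convenience parser for CHB-MIT-style ``*-summary.txt``
files is also provided.  All intervals are half-open ``[start, end)``
in seconds; sample indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RecordingManifest",
    "ChannelNotFoundError",
    "SamplingRateMismatchError",
    "read_recording",
    "read_annotations",
    "filter_seizures",
    "parse_chb_summary",
]


class ChannelNotFoundError(KeyError):
    """A manifest channel is absent from the EDF file."""


class SamplingRateMismatchError(ValueError):
    """The EDF sampling rate differs from the manifest's."""


@dataclass(frozen=True)
class RecordingManifest:
    """What to read and how to interpret it.

    ``channel_names`` fixes both the selection and the order of channels
    in the returned grid; ``seizure_intervals`` are half-open
    ``[start_s, end_s)`` pairs.
    """

    record_id: str
    edf_path: Path
    channel_names: tuple[str, ...]
    seizure_intervals: tuple[tuple[float, float], ...] = ()
    sampling_rate_hz: float = 256.0


def read_recording(manifest: RecordingManifest) -> np.ndarray:
    """Read an EDF file into a (channels x samples) grid.

    Channels are returned in manifest order.  Raises
    :class:`ChannelNotFoundError` naming the first missing channel and
    :class:`SamplingRateMismatchError` on a rate disagreement.
    """
    import mne

    raw = mne.io.read_raw_edf(str(manifest.edf_path), preload=True,
                              verbose="error")
    available = raw.ch_names
    for name in manifest.channel_names:
        if name not in available:
            raise ChannelNotFoundError(
                f"channel {name!r} not found in {manifest.edf_path} "
                f"(file has {available})"
            )
    sfreq = float(raw.info["sfreq"])
    if abs(sfreq - manifest.sampling_rate_hz) > 1e-6:
        raise SamplingRateMismatchError(
            f"{manifest.edf_path}: file sampling rate {sfreq} Hz, "
            f"manifest expects {manifest.sampling_rate_hz} Hz"
        )
    picks = [available.index(name) for name in manifest.channel_names]
    data = raw.get_data(picks=picks)
    # mne rescales channels with a recognized physical dimension to SI
    # units (volts for uV-dimensioned EEG); undo that so the grid is in
    # the file's native physical units.
    units = getattr(raw, "_orig_units", None) or {}
    factors = np.ones(len(picks))
    for i, name in enumerate(manifest.channel_names):
        if units.get(name, "").lower() in ("uv", "µv"):
            factors[i] = 1e6
    return data * factors[:, None]


def read_annotations(path: str | Path) -> tuple[tuple[float, float], ...]:
    """Read a plain-text sidecar of ``start_s end_s`` lines."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        start_s, end_s = line.split()[:2]
        intervals.append((float(start_s), float(end_s)))
    return tuple(intervals)


def filter_seizures(intervals, min_duration_s: float = 10.0):
    """Drop seizures shorter than ``min_duration_s``, preserving order.

    Mirrors the corpus-curation rule that seizures lasting less than
    10 s are not considered.  Endpoints are never edited and the list
    never grows.
    """
    return tuple(
        (start, end) for start, end in intervals
        if end - start >= min_duration_s
    )


def parse_chb_summary(text: str) -> dict[str, tuple[tuple[float, float], ...]]:
    """Parse a CHB-MIT-style summary text into per-file seizure intervals.

    Understands the ``File Name: ...`` / ``Seizure [N ]Start Time: S
    seconds`` / ``Seizure [N ]End Time: E seconds`` layout.  Returns a
    mapping from EDF file name to a tuple of (start_s, end_s) pairs.
    """
    result: dict[str, list[tuple[float, float]]] = {}
    current: str | None = None
    pending_start: float | None = None
    for raw_line in text.splitlines():
        line = raw_line.strip()
        low = line.lower()
        if low.startswith("file name:"):
            current = line.split(":", 1)[1].strip()
            result.setdefault(current, [])
            pending_start = None
        elif "seizure" in low and "start time" in low and current:
            pending_start = float(line.split(":", 1)[1].split()[0])
        elif "seizure" in low and "end time" in low and current:
            end = float(line.split(":", 1)[1].split()[0])
            if pending_start is None:
                raise ValueError(f"seizure end without start near: {line!r}")
            result[current].append((pending_start, end))
            pending_start = None
    return {k: tuple(v) for k, v in result.items()}
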