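"""Seedable generator of labelled multichannel EEG-like signals.

Two-class structure mirroring scalp-EEG seizure data: the *interictal*
(between-seizure) state is modelled as zero-mean broadband noise, the
*ictal* (seizure) state as the same background plus a higher-amplitude
rhythmic sinusoidal burst.  The burst amplitude is
``(ictal_amplitude_gain - 1) * background_noise_sd`` so that a gain of 1
degenerates exactly to the interictal generative law, and the two classes
are separable by amplitude / band power for any gain > 1.

The generator is deliberately minimal: it does not attempt spike-wave
morphology, artifacts or montage effects.  Its purpose is to give every
downstream stage (segmentation, normalization, model training) a fully
deterministic, downloadable-data-free test path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SynthConfig",
    "SynthRecording",
    "SegmentCollection",
    "generate_segments",
    "generate_recording",
    "write_edf",
    "write_annotations",
    "DEFAULT_CHANNEL_NAMES",
]

#: Bipolar 10-20 montage channel names as used by CHB-MIT-style scalp EEG.
DEFAULT_CHANNEL_NAMES = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9",
    "FT9-FT10", "FT10-T8", "T8-P8-2",
)

VALID_SEGMENT_SECONDS = (1, 2, 4)

#: Minimum annotated seizure duration, in seconds, that the downstream
#: pipeline keeps; generated seizures always satisfy it.
MIN_SEIZURE_SECONDS = 10.0


class ConfigurationError(ValueError):
    """Raised when a :class:`SynthConfig` violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the two-class synthetic EEG generator.

    Parameters
    ----------
    sampling_rate_hz
        Samples per second per channel (scalp EEG convention: 256 Hz).
    n_channels
        Number of recording channels (23 for the bipolar montage emulated).
    segment_seconds
        Segment window length; one of {1, 2, 4}.
    n_segments_per_class
        Segments generated for each of the two classes.
    ictal_burst_freq_hz
        Frequency of the rhythmic seizure burst (default 4 Hz, the
        theta/delta boundary typical of ictal rhythms).
    ictal_amplitude_gain
        Amplitude ratio of ictal activity to background; must exceed 1
        for the classes to be separable in expectation.
    background_noise_sd
        Standard deviation of the background noise, in arbitrary units.
    pink_background
        If true, colour the background as 1/f ("pink") noise instead of
        white Gaussian noise.
    seed
        Seed for the internal random generator; identical seeds give
        bit-identical output.
    """

    sampling_rate_hz: float = 256.0
    n_channels: int = 23
    segment_seconds: int = 2
    n_segments_per_class: int = 100
    ictal_burst_freq_hz: float = 4.0
    ictal_amplitude_gain: float = 3.0
    background_noise_sd: float = 1.0
    pink_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be positive")
        if self.n_channels <= 0:
            raise ConfigurationError("n_channels must be positive")
        if self.segment_seconds not in VALID_SEGMENT_SECONDS:
            raise ConfigurationError(
                f"segment_seconds must be one of {VALID_SEGMENT_SECONDS}, "
                f"got {self.segment_seconds}"
            )
        rows = self.sampling_rate_hz * self.segment_seconds
        if abs(rows - round(rows)) > 1e-9:
            raise ConfigurationError(
                "sampling_rate_hz x segment_seconds must be an integer "
                f"(got {rows})"
            )
        if self.n_segments_per_class <= 0:
            raise ConfigurationError("n_segments_per_class must be positive")
        if self.ictal_burst_freq_hz <= 0:
            raise ConfigurationError("ictal_burst_freq_hz must be positive")
        if self.ictal_amplitude_gain < 1:
            raise ConfigurationError("ictal_amplitude_gain must be >= 1")
        if self.background_noise_sd <= 0:
            raise ConfigurationError("background_noise_sd must be positive")

    @property
    def segment_samples(self) -> int:
        """Rows per segment: sampling rate times window length."""
        return int(round(self.sampling_rate_hz * self.segment_seconds))

    @property
    def burst_amplitude(self) -> float:
        """Sinusoid amplitude added inside ictal activity."""
        return (self.ictal_amplitude_gain - 1.0) * self.background_noise_sd


@dataclass(frozen=True)
class SynthRecording:
    """A continuous multichannel recording with seizure annotations.

    ``values`` is a (channels x samples) grid in arbitrary amplitude
    units; ``seizure_intervals`` are half-open ``[start_s, end_s)`` pairs,
    sorted and non-overlapping, all inside the recording duration.
    """

    values: np.ndarray
    sampling_rate_hz: float
    seizure_intervals: tuple[tuple[float, float], ...]
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        dur = self.duration_s
        prev_end = 0.0
        for start, end in self.seizure_intervals:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"interval ({start}, {end}) outside recording of {dur} s"
                )
            if start < prev_end:
                raise ValueError("seizure intervals overlap or are unsorted")
            prev_end = end

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.values.shape[1] / self.sampling_rate_hz


@dataclass(frozen=True)
class SegmentCollection:
    """Pre-cut labelled segments: ``values`` is (n, time, channels)."""

    values: np.ndarray
    labels: np.ndarray  # 1 = ictal, 0 = interictal
    sampling_rate_hz: float

    def __len__(self) -> int:
        return self.values.shape[0]


def _background(rng: np.random.Generator, n_channels: int, n_samples: int,
                sd: float, pink: bool) -> np.ndarray:
    """Zero-mean background noise, white by default, optionally 1/f."""
    white = rng.standard_normal((n_channels, n_samples))
    if not pink:
        return sd * white
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    weights = np.ones_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    coloured = np.fft.irfft(spec * weights, n=n_samples, axis=1)
    coloured /= coloured.std(axis=1, keepdims=True)
    return sd * coloured


def _burst(rng: np.random.Generator, config: SynthConfig,
           n_samples: int, t0: float = 0.0) -> np.ndarray:
    """Rhythmic sinusoidal burst, random phase per channel."""
    t = t0 + np.arange(n_samples) / config.sampling_rate_hz
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(config.n_channels, 1))
    return config.burst_amplitude * np.sin(
        2.0 * np.pi * config.ictal_burst_freq_hz * t[None, :] + phases
    )


def generate_segments(config: SynthConfig) -> SegmentCollection:
    """Generate a balanced two-class collection of pre-cut segments.

    Returns ``n_segments_per_class`` ictal followed by the same number of
    interictal segments, each of shape (segment_samples x n_channels).
    Interictal segments are pure background noise; ictal segments add the
    rhythmic burst.  Identical configs (including seed) give bit-identical
    arrays.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_segments_per_class
    rows = config.segment_samples
    values = np.empty((2 * n, rows, config.n_channels))
    labels = np.concatenate([np.ones(n, dtype=np.int8),
                             np.zeros(n, dtype=np.int8)])
    for i in range(n):  # ictal
        seg = _background(rng, config.n_channels, rows,
                          config.background_noise_sd, config.pink_background)
        seg += _burst(rng, config, rows)
        values[i] = seg.T
    for i in range(n):  # interictal
        seg = _background(rng, config.n_channels, rows,
                          config.background_noise_sd, config.pink_background)
        values[n + i] = seg.T
    return SegmentCollection(values=values, labels=labels,
                             sampling_rate_hz=config.sampling_rate_hz)


def generate_recording(config: SynthConfig, duration_s: float,
                       n_seizures: int,
                       max_seizure_s: float = 60.0) -> SynthRecording:
    """Generate a continuous recording with annotated seizure intervals.

    Each seizure lasts at least :data:`MIN_SEIZURE_SECONDS` (uniformly
    drawn up to ``max_seizure_s``); intervals are disjoint with random
    gaps.  Raises ``ValueError`` when ``duration_s`` cannot host the
    requested seizures.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if n_seizures < 0:
        raise ValueError("n_seizures must be non-negative")
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(duration_s * config.sampling_rate_hz))

    durations = rng.uniform(MIN_SEIZURE_SECONDS,
                            max(max_seizure_s, MIN_SEIZURE_SECONDS),
                            size=n_seizures)
    free = duration_s - durations.sum()
    if n_seizures and free < 0:
        raise ValueError(
            f"cannot place {n_seizures} seizures of total "
            f"{durations.sum():.1f} s in a {duration_s:.1f} s recording"
        )
    intervals: list[tuple[float, float]] = []
    if n_seizures:
        gaps = rng.random(n_seizures + 1)
        gaps = gaps / gaps.sum() * free
        cursor = 0.0
        for g, d in zip(gaps[:-1], durations):
            start = cursor + g
            intervals.append((start, start + d))
            cursor = start + d

    values = _background(rng, config.n_channels, n_samples,
                         config.background_noise_sd, config.pink_background)
    for start, end in intervals:
        i0 = int(round(start * config.sampling_rate_hz))
        i1 = int(round(end * config.sampling_rate_hz))
        values[:, i0:i1] += _burst(rng, config, i1 - i0, t0=start)

    return SynthRecording(
        values=values,
        sampling_rate_hz=config.sampling_rate_hz,
        seizure_intervals=tuple(intervals),
        channel_names=tuple(DEFAULT_CHANNEL_NAMES[: config.n_channels])
        if config.n_channels <= len(DEFAULT_CHANNEL_NAMES)
        else tuple(f"CH{i + 1:02d}" for i in range(config.n_channels)),
    )


# ---------------------------------------------------------------------------
# EDF output
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: SynthRecording, path: str | Path,
              channel_names: tuple[str, ...] | None = None,
              physical_dim: str = "uV") -> Path:
    """Write a recording as a plain EDF file (16-bit, 1-second records).

    The amplitude range of each channel is mapped onto the full signed
    16-bit digital range, so the round-trip error is bounded by the EDF
    quantization step (physical range / 65535).  Recordings whose
    duration is not a whole number of seconds are zero-padded to the next
    second.
    """
    path = Path(path)
    values = np.asarray(recording.values, dtype=np.float64)
    n_ch, n_samp = values.shape
    fs = recording.sampling_rate_hz
    spr = int(round(fs))  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    names = channel_names or recording.channel_names or tuple(
        f"CH{i + 1:02d}" for i in range(n_ch)
    )
    if len(names) != n_ch:
        raise ValueError("channel_names length mismatch")

    n_records = -(-n_samp // spr)  # ceil
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = values

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (n_ch + 1)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(n_ch), 4),
    ])
    fmt8 = lambda x: f"{x:.8g}"[:8]
    signal_header = b"".join([
        b"".join(_edf_field(n, 16) for n in names),
        b"".join(_edf_field("", 80) for _ in names),
        b"".join(_edf_field(physical_dim, 8) for _ in names),
        b"".join(_edf_field(fmt8(v), 8) for v in pmin),
        b"".join(_edf_field(fmt8(v), 8) for v in pmax),
        b"".join(_edf_field(str(dmin), 8) for _ in names),
        b"".join(_edf_field(str(dmax), 8) for _ in names),
        b"".join(_edf_field("", 80) for _ in names),
        b"".join(_edf_field(str(spr), 8) for _ in names),
        b"".join(_edf_field("", 32) for _ in names),
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
    return path


def write_annotations(intervals, path: str | Path) -> Path:
    """Write seizure intervals as a sidecar: one ``start_s end_s`` per line."""
    path = Path(path)
    with open(path, "w") as fh:
        for start, end in intervals:
            fh.write(f"{start:.6f} {end:.6f}\n")
    return path
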