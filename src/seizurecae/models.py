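"""The four seizure-detection architectures.

Two families share an identical encoder stack — four stages of
convolution (3x2 kernel, ReLU), batch normalization and ceil-mode max
pooling with filter counts 32/64/32/64 and pool windows
(2,2)/(2,2)/(2,2)/(2,3) — so a ``256 s x 23 x 1`` segment maps to a
``(16 s) x 1 x 64`` latent grid (s = segment seconds):

* supervised convolutional autoencoders (``dcae_*``) add a decoder of
  four conv + nearest-neighbour upsample stages (filters 64/32/32/1,
  factors (2,3)/(2,2)/(2,2)/(2,2), final sigmoid) that reconstructs the
  input; the channel axis comes back as 24 and is cropped to 23;
* plain convolutional classifiers (``dcnn_*``) keep only the encoder.

Either family feeds its latent code to one of two heads: an MLP
(flatten, dense 50 ReLU, dense 32 ReLU, dense 1 sigmoid) or a Bi-LSTM
(the latent time axis as the sequence, 50 units per direction,
time-averaged, dense 1 sigmoid).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from seizurecae.nn.layers import (
    BatchNorm, Conv2D, CropTo, Dense, Flatten, Layer, MaxPool2D, ReLU,
    Sigmoid, SqueezeAxis, Upsample2D,
)
from seizurecae.nn.recurrent import BiLSTM

__all__ = ["ModelSpec", "SeizureModel", "assemble", "latent_shape",
           "VARIANTS", "save_model", "load_model"]

VARIANTS = ("dcae_mlp", "dcae_bilstm", "dcnn_mlp", "dcnn_bilstm")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one architecture variant."""

    variant: str = "dcae_bilstm"
    segment_seconds: int = 4
    n_channels: int = 23
    sampling_rate_hz: float = 256.0
    encoder_filters: tuple[int, ...] = (32, 64, 32, 64)
    decoder_filters: tuple[int, ...] = (64, 32, 32, 1)
    kernel: tuple[int, int] = (3, 2)
    pool_plan: tuple[tuple[int, int], ...] = ((2, 2), (2, 2), (2, 2), (2, 3))
    upsample_plan: tuple[tuple[int, int], ...] = ((2, 3), (2, 2), (2, 2),
                                                 (2, 2))
    mlp_hidden: tuple[int, ...] = (50, 32)
    lstm_units: int = 50
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.variant.lower() not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        object.__setattr__(self, "variant", self.variant.lower())
        if self.segment_seconds not in (1, 2, 4):
            raise ValueError("segment_seconds must be 1, 2 or 4")
        if len(self.encoder_filters) != len(self.pool_plan):
            raise ValueError("encoder needs one pool window per conv stage")
        if len(self.encoder_filters) != 4:
            raise ValueError("encoder must have exactly four stages")
        if self.has_decoder:
            if len(self.decoder_filters) != len(self.upsample_plan):
                raise ValueError(
                    "decoder needs one upsample factor per conv stage")
            if self.decoder_filters[-1] != 1:
                raise ValueError("final decoder conv must have one filter")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def has_decoder(self) -> bool:
        return self.variant.startswith("dcae")

    @property
    def head(self) -> str:
        return self.variant.split("_", 1)[1]

    @property
    def input_shape(self) -> tuple[int, int, int]:
        rows = int(round(self.sampling_rate_hz * self.segment_seconds))
        return (rows, self.n_channels, 1)


def latent_shape(spec: ModelSpec) -> tuple[int, int, int]:
    """Latent grid (time, channel, features) after the encoder."""
    h, w, _ = spec.input_shape
    for ph, pw in spec.pool_plan:
        h = math.ceil(h / ph)
        w = math.ceil(w / pw)
    return (h, w, spec.encoder_filters[-1])


def _build_encoder(spec: ModelSpec, rng: np.random.Generator) -> list[Layer]:
    layers: list[Layer] = []
    in_ch = 1
    for filters, window in zip(spec.encoder_filters, spec.pool_plan):
        layers += [
            Conv2D(in_ch, filters, kernel=spec.kernel, rng=rng),
            ReLU(inplace=True),
            BatchNorm(filters),
            MaxPool2D(window),
        ]
        in_ch = filters
    return layers


def _build_decoder(spec: ModelSpec, rng: np.random.Generator) -> list[Layer]:
    layers: list[Layer] = []
    in_ch = spec.encoder_filters[-1]
    n_stages = len(spec.decoder_filters)
    for i, (filters, factor) in enumerate(
            zip(spec.decoder_filters, spec.upsample_plan)):
        layers.append(Conv2D(in_ch, filters, kernel=spec.kernel, rng=rng))
        layers.append(Sigmoid() if i == n_stages - 1 else ReLU(inplace=True))
        layers.append(Upsample2D(factor))
        in_ch = filters
    rows, channels, _ = spec.input_shape
    layers.append(CropTo(rows, channels))
    return layers


def _build_head(spec: ModelSpec, rng: np.random.Generator) -> list[Layer]:
    lat_h, lat_w, lat_f = latent_shape(spec)
    if spec.head == "mlp":
        layers: list[Layer] = [Flatten()]
        in_features = lat_h * lat_w * lat_f
        for width in spec.mlp_hidden:
            layers += [Dense(in_features, width, rng=rng), ReLU()]
            in_features = width
        layers += [Dense(in_features, 1, rng=rng), Sigmoid()]
        return layers
    # Bi-LSTM head: latent time axis is the sequence, (lat_w x lat_f)
    # flattens to the per-step feature vector
    return [
        SqueezeAxis(2),
        BiLSTM(lat_w * lat_f, spec.lstm_units, rng=rng,
               dropout=spec.dropout),
        Dense(2 * spec.lstm_units, 1, rng=rng),
        Sigmoid(),
    ]


def _run(layers: list[Layer], x: np.ndarray, train: bool) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, train=train)
    return x


def _run_back(layers: list[Layer], d: np.ndarray) -> np.ndarray:
    for layer in reversed(layers):
        d = layer.backward(d)
    return d


class SeizureModel:
    """An assembled variant: encoder, optional decoder, classifier head.

    ``forward`` returns ``(probabilities, reconstruction)`` where the
    reconstruction is ``None`` for the encoder-only variants;
    ``backward`` consumes the matching loss gradients and accumulates
    parameter gradients in every layer.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        # independent streams so the encoder (and head) initialization is
        # bit-identical between the dcae and dcnn variant of a seed
        enc_ss, dec_ss, head_ss = np.random.SeedSequence(seed).spawn(3)
        self.encoder = _build_encoder(spec, np.random.default_rng(enc_ss))
        self.decoder = (_build_decoder(spec, np.random.default_rng(dec_ss))
                        if spec.has_decoder else None)
        self.head = _build_head(spec, np.random.default_rng(head_ss))

    # -- execution ----------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True
                ) -> tuple[np.ndarray, np.ndarray | None]:
        expected = self.spec.input_shape
        if tuple(x.shape[1:]) != expected:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec {expected}")
        latent = _run(self.encoder, x, train)
        probs = _run(self.head, latent, train)[:, 0]
        recon = (_run(self.decoder, latent, train)
                 if self.decoder is not None else None)
        return probs, recon

    def backward(self, dprobs: np.ndarray,
                 drecon: np.ndarray | None = None) -> None:
        dlatent = _run_back(self.head, dprobs[:, None])
        if self.decoder is not None:
            if drecon is None:
                raise ValueError("dcae variants need a reconstruction "
                                 "gradient")
            dlatent = dlatent + _run_back(self.decoder, drecon)
        _run_back(self.encoder, dlatent)

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Latent grid for inspection (inference mode)."""
        return _run(self.encoder, x, train=False)

    # -- bookkeeping --------------------------------------------------

    def layers(self) -> list[Layer]:
        stacks = [self.encoder, self.head]
        if self.decoder is not None:
            stacks.insert(1, self.decoder)
        out: list[Layer] = []
        for stack in stacks:
            for layer in stack:
                if isinstance(layer, BiLSTM):
                    out.extend(layer.sublayers)
                else:
                    out.append(layer)
        return out

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_parameters for layer in self.layers())

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        return latent_shape(self.spec)


def assemble(variant: str, segment_seconds: int, seed: int = 0,
             **overrides) -> SeizureModel:
    """Build one of the four variants for a given segment length."""
    spec = ModelSpec(variant=variant, segment_seconds=segment_seconds,
                     **overrides)
    return SeizureModel(spec, seed=seed)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: SeizureModel, path: str | Path) -> Path:
    """Serialize spec + parameters (+ batch-norm state) to ``.npz``."""
    path = Path(path)
    payload: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers()):
        for name, p in layer.params.items():
            payload[f"layer{i:03d}/{name}"] = p
        if isinstance(layer, BatchNorm):
            payload[f"layer{i:03d}/running_mean"] = layer.running_mean
            payload[f"layer{i:03d}/running_var"] = layer.running_var
    meta = json.dumps({"spec": asdict(model.spec), "seed": model.seed})
    payload["meta"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    np.savez(path, **payload)
    return path


def load_model(path: str | Path) -> SeizureModel:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        spec_kw = meta["spec"]
        for key in ("encoder_filters", "decoder_filters", "kernel",
                    "mlp_hidden"):
            spec_kw[key] = tuple(spec_kw[key])
        spec_kw["pool_plan"] = tuple(map(tuple, spec_kw["pool_plan"]))
        spec_kw["upsample_plan"] = tuple(map(tuple, spec_kw["upsample_plan"]))
        model = SeizureModel(ModelSpec(**spec_kw), seed=meta["seed"])
        for i, layer in enumerate(model.layers()):
            for name in layer.params:
                layer.params[name] = z[f"layer{i:03d}/{name}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = z[f"layer{i:03d}/running_mean"]
                layer.running_var = z[f"layer{i:03d}/running_var"]
                layer.n_updates = 1  # stats are meaningful, not placeholders
    return model
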