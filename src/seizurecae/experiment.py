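"""Training loop, stratified tenfold cross-validation, and reporting.

The supervised-autoencoder variants minimize the weighted total loss
(classification cross-entropy at weight 0.5 plus reconstruction MSE at
weight 1.0); the encoder-only variants minimize the cross-entropy
alone.  Evaluation runs stratified tenfold cross-validation: a fresh
model per fold, metrics from the held-out fold only, and mean +/- std
aggregation over the ten folds.  Every source of randomness (model
initialization, batch shuffling) derives from the single master seed,
so a repeated run is bit-identical.

Training is carried out in float32; the last partial batch of an epoch
is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from seizurecae.losses import (
    LossWeights, classification_loss, classification_loss_grad,
    reconstruction_loss, reconstruction_loss_grad, total_loss,
)
from seizurecae.metrics import (MetricsRecord, compute_metrics,
                                threshold_predictions)
from seizurecae.models import SeizureModel, assemble
from seizurecae.nn.layers import BatchNorm
from seizurecae.nn.optim import make_optimizer
from seizurecae.pipeline import LabeledDataset

__all__ = [
    "TrainConfig", "FoldHistory", "CVResult", "TrainingDivergedError",
    "train_fold", "predict", "cross_validate", "run_grid",
    "plot_histories", "format_mean_std",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss turns non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol; the defaults reproduce the modelled one
    (Adam, learning rate 1e-4, batch size 32)."""

    variant: str = "dcae_bilstm"
    segment_seconds: int = 4
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


@dataclass
class FoldHistory:
    """Per-epoch loss/accuracy traces for one fold's training run."""

    cl: list[float] = field(default_factory=list)
    rc: list[float] = field(default_factory=list)
    tl: list[float] = field(default_factory=list)
    acc: list[float] = field(default_factory=list)
    test_cl: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tl)


@dataclass(frozen=True)
class CVResult:
    """Per-fold metrics with their mean and standard deviation."""

    fold_metrics: tuple[MetricsRecord, ...]
    histories: tuple[FoldHistory, ...]
    config: TrainConfig

    def _stack(self) -> np.ndarray:
        return np.array([[m.se, m.sp, m.acc, m.pr, m.f1]
                         for m in self.fold_metrics])

    @property
    def mean(self) -> MetricsRecord:
        se, sp, acc, pr, f1 = self._stack().mean(axis=0)
        return MetricsRecord(acc=acc, se=se, sp=sp, pr=pr, f1=f1)

    @property
    def std(self) -> MetricsRecord:
        se, sp, acc, pr, f1 = self._stack().std(axis=0)
        return MetricsRecord(acc=acc, se=se, sp=sp, pr=pr, f1=f1)


def _cast_model(model: SeizureModel, dtype) -> None:
    for layer in model.layers():
        for name in layer.params:
            layer.params[name] = layer.params[name].astype(dtype)
        if isinstance(layer, BatchNorm):
            layer.running_mean = layer.running_mean.astype(dtype)
            layer.running_var = layer.running_var.astype(dtype)


def _refresh_parameters(warm: SeizureModel, fresh: SeizureModel) -> None:
    """Move a freshly initialized model's parameters into a warm one.

    Keeps the warm model's workspace buffers (whose first-touch cost is
    substantial) while restoring a bit-exact fresh initialization,
    including batch-norm running statistics and dropout streams.
    """
    warm_layers, fresh_layers = warm.layers(), fresh.layers()
    assert len(warm_layers) == len(fresh_layers)
    for wl, fl in zip(warm_layers, fresh_layers):
        assert type(wl) is type(fl)
        wl.params = fl.params
        wl.grads = {}
        if isinstance(wl, BatchNorm):
            wl.running_mean = fl.running_mean
            wl.running_var = fl.running_var
            wl.n_updates = fl.n_updates
    for wstack, fstack in ((warm.head, fresh.head),):
        for wl, fl in zip(wstack, fstack):
            if hasattr(wl, "_drop_rng"):
                wl._drop_rng = fl._drop_rng
    warm.seed = fresh.seed


def train_fold(model: SeizureModel, values: np.ndarray, labels: np.ndarray,
               config: TrainConfig,
               shuffle_rng: np.random.Generator | None = None,
               test_values: np.ndarray | None = None,
               test_labels: np.ndarray | None = None) -> FoldHistory:
    """Train one model on one fold's training split.

    Records per-epoch means of the classification loss, reconstruction
    loss, total loss and training accuracy (and, when a test split is
    supplied, test loss/accuracy per epoch).  All randomness comes from
    ``shuffle_rng``; with a fixed generator state the run is
    bit-identical.
    """
    if shuffle_rng is None:
        shuffle_rng = np.random.default_rng(config.seed)
    _cast_model(model, np.float32)
    x = np.ascontiguousarray(values, dtype=np.float32)
    y = np.asarray(labels).astype(np.float32)
    n = x.shape[0]
    opt = make_optimizer(config.optimizer, config.learning_rate)
    weights = config.loss_weights
    has_decoder = model.spec.has_decoder
    history = FoldHistory()
    layers = model.layers()

    for _epoch in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        sums = {"cl": 0.0, "rc": 0.0, "correct": 0.0}
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            probs, recon = model.forward(xb, train=True)
            cl = classification_loss(probs, yb)
            dcl = classification_loss_grad(probs, yb)
            if has_decoder:
                rc = reconstruction_loss(xb, recon)
                drc = (weights.weight_rlc
                       * reconstruction_loss_grad(xb, recon))
                model.backward(weights.weight_cl * dcl, drc)
            else:
                rc = 0.0
                model.backward(dcl)
            if not np.isfinite(cl) or not np.isfinite(rc):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {_epoch}: CL={cl}, RC={rc}")
            opt.step(layers)
            m = len(idx)
            sums["cl"] += cl * m
            sums["rc"] += rc * m
            sums["correct"] += float(np.sum((probs >= 0.5) == (yb >= 0.5)))
        history.cl.append(sums["cl"] / n)
        history.rc.append(sums["rc"] / n)
        history.tl.append(total_loss(sums["cl"] / n, sums["rc"] / n, weights))
        history.acc.append(sums["correct"] / n)
        if test_values is not None:
            probs = predict(model, test_values)
            history.test_cl.append(classification_loss(probs, test_labels))
            history.test_acc.append(
                float(np.mean((probs >= 0.5) == (test_labels >= 0.5))))
    return history


def predict(model: SeizureModel, values: np.ndarray,
            batch_size: int = 32) -> np.ndarray:
    """Class probabilities in inference mode (running batch-norm stats)."""
    x = np.ascontiguousarray(values, dtype=np.float32)
    out = []
    for start in range(0, x.shape[0], batch_size):
        probs, _ = model.forward(x[start:start + batch_size], train=False)
        out.append(probs)
    return np.concatenate(out)


def cross_validate(dataset: LabeledDataset, config: TrainConfig,
                   record_test_curves: bool = False) -> CVResult:
    """Stratified tenfold cross-validation of one variant/length.

    A fresh model is built per fold; the held-out fold never reaches the
    optimizer and supplies the fold's metrics.
    """
    if dataset.fold_ids is None:
        raise ValueError("dataset has no fold assignment; run assign_folds")
    fold_ids = dataset.fold_ids
    k = int(fold_ids.max()) + 1
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * k)
    metrics: list[MetricsRecord] = []
    histories: list[FoldHistory] = []
    warm_model: SeizureModel | None = None
    for f in range(k):
        test_mask = fold_ids == f
        train_mask = ~test_mask
        for name, mask in (("test", test_mask), ("train", train_mask)):
            present = np.unique(dataset.labels[mask])
            if len(present) < 2:
                raise ValueError(f"fold {f}: {name} split lacks a class")
        fresh = assemble(config.variant, config.segment_seconds,
                         seed=int(seeds[f]), dropout=config.dropout,
                         n_channels=dataset.values.shape[2],
                         sampling_rate_hz=dataset.sampling_rate_hz)
        if warm_model is None:
            model = warm_model = fresh
        else:
            # keep warm workspace buffers; take the fresh initialization
            _refresh_parameters(warm_model, fresh)
            model = warm_model
        shuffle_rng = np.random.default_rng(int(seeds[k + f]))
        test_kw = {}
        if record_test_curves:
            test_kw = {"test_values": dataset.values[test_mask],
                       "test_labels": dataset.labels[test_mask]}
        history = train_fold(model, dataset.values[train_mask],
                             dataset.labels[train_mask], config,
                             shuffle_rng=shuffle_rng, **test_kw)
        probs = predict(model, dataset.values[test_mask])
        _, counts = threshold_predictions(probs, dataset.labels[test_mask])
        assert counts.total == int(test_mask.sum())
        metrics.append(compute_metrics(counts))
        histories.append(history)
    return CVResult(fold_metrics=tuple(metrics), histories=tuple(histories),
                    config=config)


def format_mean_std(mean: float, std: float) -> str:
    return f"{mean:.2f} ± {std:.2f}"


def run_grid(datasets: dict[int, LabeledDataset], config: TrainConfig,
             variants=("dcae_mlp", "dcae_bilstm", "dcnn_mlp", "dcnn_bilstm"),
             ) -> tuple[pd.DataFrame, dict[tuple[int, str], CVResult]]:
    """Cross-validate every variant at every provided segment length.

    Returns the results table (one row per variant x length, cells as
    ``mean +/- std`` percentages) and the raw per-cell CV results.  A
    missing segment length yields a warning, not an error.
    """
    rows = []
    results: dict[tuple[int, str], CVResult] = {}
    for seconds in (1, 2, 4):
        if seconds not in datasets:
            warnings.warn(f"no dataset for {seconds}-s segments; skipping",
                          RuntimeWarning)
            continue
        for variant in variants:
            cfg = replace(config, variant=variant, segment_seconds=seconds)
            res = cross_validate(datasets[seconds], cfg)
            results[(seconds, variant)] = res
            mean, std = res.mean, res.std
            rows.append({
                "Segment length": f"{seconds} s",
                "Method": variant,
                "Se (%)": format_mean_std(mean.se, std.se),
                "Sp (%)": format_mean_std(mean.sp, std.sp),
                "Acc (%)": format_mean_std(mean.acc, std.acc),
                "Pr (%)": format_mean_std(mean.pr, std.pr),
                "F score (%)": format_mean_std(mean.f1, std.f1),
            })
    return pd.DataFrame(rows), results


def plot_histories(result: CVResult, outdir: str | Path,
                   folds=None) -> list[Path]:
    """Write per-fold accuracy and loss curves as PNG files."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    folds = range(len(result.histories)) if folds is None else folds
    for f in folds:
        history = result.histories[f]
        if len(history) == 0:
            warnings.warn(f"fold {f} has an empty history; skipping",
                          RuntimeWarning)
            continue
        epochs = np.arange(1, len(history) + 1)
        fig, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(10, 4))
        ax_acc.plot(epochs, history.acc, label="train")
        if history.test_acc:
            ax_acc.plot(epochs, history.test_acc, label="test")
        ax_acc.set_xlabel("epoch")
        ax_acc.set_ylabel("accuracy")
        ax_acc.legend()
        ax_loss.plot(epochs, history.cl, label="classification")
        if any(history.rc):
            ax_loss.plot(epochs, history.rc, label="reconstruction")
        ax_loss.plot(epochs, history.tl, label="total")
        if history.test_cl:
            ax_loss.plot(epochs, history.test_cl, label="test CL")
        ax_loss.set_xlabel("epoch")
        ax_loss.set_ylabel("loss")
        ax_loss.legend()
        fig.suptitle(f"{result.config.variant}, "
                     f"{result.config.segment_seconds}-s segments, fold {f}")
        fig.tight_layout()
        path = outdir / f"fold{f:02d}_curves.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths
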