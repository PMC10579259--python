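"""Training loop and cross-validation driver on desk-size problems.

These tests run 1-s segments with a handful of examples so that a full
tenfold pass stays in seconds; the large-scale end-to-end behaviour is
exercised by the acceptance tests.
"""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from seizurecae.experiment import (CVResult, FoldHistory, TrainConfig,
                                   TrainingDivergedError, cross_validate,
                                   plot_histories, predict, run_grid,
                                   train_fold)
from seizurecae.losses import LossWeights
from seizurecae.metrics import MetricsRecord
from seizurecae.models import assemble
from seizurecae.pipeline import prepare_dataset
from seizurecae.synth import SynthConfig, generate_segments


def tiny_dataset(per_class=15, seconds=1, seed=0):
    cfg = SynthConfig(segment_seconds=seconds, n_segments_per_class=per_class,
                      seed=seed)
    col = generate_segments(cfg)
    return prepare_dataset(col.values[col.labels == 1],
                           col.values[col.labels == 0], seed=seed)


def tiny_config(**kw):
    base = dict(variant="dcae_bilstm", segment_seconds=1, epochs=2,
                learning_rate=1e-3, seed=3)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def dataset():
    return tiny_dataset()


class TestTrainFold:
    def test_history_lengths_equal_epochs(self, dataset):
        cfg = tiny_config(epochs=3)
        model = assemble(cfg.variant, 1, seed=0)
        hist = train_fold(model, dataset.values, dataset.labels, cfg)
        assert len(hist) == 3
        assert len(hist.cl) == len(hist.rc) == len(hist.acc) == 3

    def test_seeded_training_is_reproducible(self, dataset):
        cfg = tiny_config()
        hists = []
        for _ in range(2):
            model = assemble(cfg.variant, 1, seed=11)
            rng = np.random.default_rng(5)
            hists.append(train_fold(model, dataset.values, dataset.labels,
                                    cfg, shuffle_rng=rng))
        assert hists[0].tl == hists[1].tl
        assert hists[0].acc == hists[1].acc

    def test_loss_decreases_on_separable_data(self, dataset):
        cfg = tiny_config(epochs=5)
        model = assemble(cfg.variant, 1, seed=2)
        hist = train_fold(model, dataset.values, dataset.labels, cfg,
                          shuffle_rng=np.random.default_rng(1))
        assert hist.tl[4] < hist.tl[0]

    def test_zero_reconstruction_weight_reduces_to_dcnn(self, dataset):
        """A supervised autoencoder trained with weight_rlc = 0 follows
        the encoder-only classifier's loss trajectory (shared seed, zero
        gradient through the decoder).  The remaining objectives differ
        only by the constant factor weight_cl, which Adam absorbs up to
        its epsilon, so the histories agree to ~1e-4 rather than
        bit-exactly."""
        weights = LossWeights(weight_cl=0.5, weight_rlc=0.0)
        histories = {}
        for variant in ("dcae_bilstm", "dcnn_bilstm"):
            cfg = tiny_config(variant=variant, loss_weights=weights,
                              epochs=2)
            model = assemble(variant, 1, seed=21)
            hist = train_fold(model, dataset.values, dataset.labels, cfg,
                              shuffle_rng=np.random.default_rng(8))
            histories[variant] = hist
        np.testing.assert_allclose(histories["dcae_bilstm"].cl,
                                   histories["dcnn_bilstm"].cl, atol=1e-4)

    def test_nan_input_aborts_with_diagnostic(self, dataset):
        cfg = tiny_config()
        model = assemble(cfg.variant, 1, seed=0)
        bad = dataset.values.copy()
        bad[0] = np.nan
        with pytest.raises(TrainingDivergedError):
            train_fold(model, bad, dataset.labels, cfg)


@pytest.fixture(scope="module")
def cv_result(dataset):
    return cross_validate(dataset, tiny_config(epochs=2))


class TestCrossValidate:
    def test_each_segment_tested_exactly_once(self, dataset, cv_result):
        counts = np.zeros(len(dataset))
        for f in range(10):
            counts[dataset.fold_ids == f] += 1
        assert (counts == 1).all()
        assert len(cv_result.fold_metrics) == 10

    def test_mean_is_arithmetic_mean_of_folds(self, cv_result):
        accs = [m.acc for m in cv_result.fold_metrics]
        assert cv_result.mean.acc == pytest.approx(np.mean(accs), abs=1e-12)
        assert cv_result.std.acc == pytest.approx(np.std(accs), abs=1e-12)

    def test_repeat_run_bit_identical(self, dataset, cv_result):
        again = cross_validate(dataset, tiny_config(epochs=2))
        for a, b in zip(cv_result.fold_metrics, again.fold_metrics):
            assert a == b
        for ha, hb in zip(cv_result.histories, again.histories):
            assert ha.tl == hb.tl

    def test_missing_fold_assignment_rejected(self, dataset):
        stripped = replace(dataset, fold_ids=None)
        with pytest.raises(ValueError):
            cross_validate(stripped, tiny_config())


class TestPredict:
    def test_probabilities_in_unit_interval(self, dataset):
        model = assemble("dcnn_mlp", 1, seed=0)
        probs = predict(model, dataset.values[:7])
        assert probs.shape == (7,)
        assert np.all((probs > 0) & (probs < 1))


def _stub_cv_result(config):
    metrics = tuple(MetricsRecord(acc=95.0 + f / 10, se=94.0, sp=96.0,
                                  pr=95.5, f1=94.7) for f in range(10))
    return CVResult(fold_metrics=metrics, histories=tuple(FoldHistory()
                                                          for _ in range(10)),
                    config=config)


class TestRunGrid:
    def test_full_grid_has_twelve_formatted_rows(self, monkeypatch):
        import seizurecae.experiment as exp

        monkeypatch.setattr(exp, "cross_validate",
                            lambda ds, cfg: _stub_cv_result(cfg))
        datasets = {1: "d1", 2: "d2", 4: "d4"}
        table, results = run_grid(datasets, tiny_config())
        assert len(table) == 12
        assert len(results) == 12
        cell = table.iloc[0]["Acc (%)"]
        assert cell == "95.45 ± 0.29"  # mean ± std at two decimals

    def test_partial_grid_warns_and_proceeds(self, dataset):
        cfg = tiny_config(epochs=1)
        with pytest.warns(RuntimeWarning, match="skipping"):
            table, results = run_grid({1: dataset}, cfg,
                                      variants=("dcnn_mlp",))
        assert len(table) == 1
        assert table.iloc[0]["Segment length"] == "1 s"

    def test_grid_rerun_reproducible(self, monkeypatch):
        import seizurecae.experiment as exp

        monkeypatch.setattr(exp, "cross_validate",
                            lambda ds, cfg: _stub_cv_result(cfg))
        datasets = {1: "d1", 2: "d2", 4: "d4"}
        t1, _ = run_grid(datasets, tiny_config())
        t2, _ = run_grid(datasets, tiny_config())
        pd.testing.assert_frame_equal(t1, t2)


class TestPlots:
    def test_one_figure_per_fold(self, tmp_path):
        hist = FoldHistory(cl=[0.7, 0.6], rc=[0.1, 0.08], tl=[0.45, 0.38],
                           acc=[0.6, 0.8])
        res = CVResult(fold_metrics=(), histories=(hist, hist),
                       config=tiny_config())
        paths = plot_histories(res, tmp_path)
        assert len(paths) == 2
        assert all(p.exists() for p in paths)

    def test_empty_history_warns_and_skips(self, tmp_path):
        res = CVResult(fold_metrics=(), histories=(FoldHistory(),),
                       config=tiny_config())
        with pytest.warns(RuntimeWarning, match="empty"):
            paths = plot_histories(res, tmp_path)
        assert paths == []


class TestTrainConfig:
    def test_defaults_follow_protocol(self):
        cfg = TrainConfig()
        assert cfg.optimizer == "adam"
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.batch_size == 32
        assert cfg.loss_weights == LossWeights(0.5, 1.0)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
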