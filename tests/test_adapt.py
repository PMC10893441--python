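"""Model wiring, stage-wise training contracts, determinism."""

import numpy as np
import pytest

from nirshift.adapt import (
    METHODS,
    AdaptationResults,
    DomainAdaptationModel,
    TransferLossSpec,
    make_model,
)
from nirshift.nn import TrainingConfig
from nirshift.spectra import SpectraSet, random_split

FAST = dict(iters_warmup=30, iters_adapt=10, iters_joint=20,
            private_width=8, shared_width=4, batch_size=8)


def _model(ds, method, **over):
    cfg = TrainingConfig(**{**FAST, **over})
    return DomainAdaptationModel(ds.source, ds.target, method=method, config=cfg)


class TestWiring:
    def test_cdan_has_discriminator_and_histogram_slot(self, tiny_paired):
        m = _model(tiny_paired, "cdan")
        assert m.discriminator is not None
        assert m.histogram is None  # built at fit time from source labels
        m.fit(stages="A")
        assert m.histogram is not None

    def test_dan_has_no_auxiliaries(self, tiny_paired):
        m = _model(tiny_paired, "dan")
        assert m._aux_params() == []

    def test_mdd_has_auxiliary_head(self, tiny_paired):
        m = _model(tiny_paired, "mdd")
        assert m.aux_head is not None

    def test_etd_has_attention_and_potential(self, tiny_paired):
        m = _model(tiny_paired, "etd")
        assert m.loss_spec.ot.attention is not None
        assert m.loss_spec.ot.potential is not None

    def test_unknown_method_rejected(self, tiny_paired):
        with pytest.raises(ValueError, match="unknown method"):
            TransferLossSpec("pls")

    def test_unlabeled_source_rejected(self, tiny_paired):
        with pytest.raises(ValueError, match="labeled"):
            DomainAdaptationModel(tiny_paired.source.without_labels(),
                                  tiny_paired.target, method="dan")

    def test_make_model_checks_shapes(self, tiny_paired):
        with pytest.raises(ValueError, match="shapes"):
            make_model("dan", (99, 24), source=tiny_paired.source,
                       target=tiny_paired.target)


class TestTraining:
    @pytest.mark.parametrize("method", METHODS)
    def test_every_method_trains_and_predicts(self, tiny_paired, method):
        res = _model(tiny_paired, method).fit()
        assert isinstance(res, AdaptationResults)
        pred = res.predict(tiny_paired.target, "target")
        assert pred.shape == (tiny_paired.target.n_samples,)
        assert np.all(np.isfinite(pred))
        log = res.training_log
        assert set(log.stage) == {"A", "B", "C"}
        assert len(log) == FAST["iters_warmup"] + FAST["iters_adapt"] + FAST["iters_joint"]

    def test_same_seed_bit_identical(self, tiny_paired):
        r1 = _model(tiny_paired, "dan", seed=5).fit()
        r2 = _model(tiny_paired, "dan", seed=5).fit()
        assert r1.training_log.equals(r2.training_log)
        assert np.array_equal(r1.predict(tiny_paired.target, "target"),
                              r2.predict(tiny_paired.target, "target"))
        for part in ("private_source", "private_target", "shared", "head"):
            assert np.array_equal(getattr(r1.model.backbone, part).W.data,
                                  getattr(r2.model.backbone, part).W.data)

    def test_lambda_zero_reproduces_task_only_baseline(self, tiny_paired):
        r0 = _model(tiny_paired, "dan", transfer_loss_weight=0.0, seed=3).fit()
        r1 = _model(tiny_paired, "dan", transfer_loss_weight=0.0, seed=3).fit()
        assert np.array_equal(r0.predict(tiny_paired.target, "target"),
                              r1.predict(tiny_paired.target, "target"))
        assert np.all(r0.training_log.query("stage == 'C'").transfer_loss == 0.0)

    def test_frozen_source_layer_unchanged_in_stage_b(self, tiny_paired):
        m = _model(tiny_paired, "dan", seed=2)
        m.fit(stages="A")
        before = m.backbone.private_source.W.data.copy()
        m.fit(stages="B")  # fit asserts the freezing contract internally
        assert np.array_equal(before, m.backbone.private_source.W.data)

    def test_predict_before_fit_raises(self, tiny_paired):
        m = _model(tiny_paired, "dan")
        with pytest.raises(RuntimeError, match="not fitted"):
            m.predict(tiny_paired.target, "target")

    def test_predictions_inside_label_band(self, tiny_paired):
        res = _model(tiny_paired, "glot").fit()
        pred = res.predict(tiny_paired.target, "target")
        sc = res.model.backbone.label_scaler
        lo = sc.unscale(np.array([0.0]))[0]
        hi = sc.unscale(np.array([1.0]))[0]
        assert np.all((pred > lo) & (pred < hi))

    def test_eval_predictions_are_repeatable(self, tiny_paired):
        res = _model(tiny_paired, "mdd").fit()
        a = res.predict(tiny_paired.target, "target")
        b = res.predict(tiny_paired.target, "target")
        assert np.array_equal(a, b)

    def test_summary_mentions_method_and_sizes(self, tiny_paired):
        res = _model(tiny_paired, "etd").fit()
        s = res.summary()
        assert "etd" in s and "24" in s and "30" in s


class TestOptimizationSanity:
    def test_warmup_loss_decreases_on_averaged_windows(self, tiny_paired):
        cfg = TrainingConfig(iters_warmup=400, iters_adapt=0, iters_joint=0,
                             private_width=16, shared_width=8, dropout_rate=0.0)
        m = DomainAdaptationModel(tiny_paired.source, tiny_paired.target,
                                  method="dan", config=cfg)
        log = m.fit(stages="A").training_log
        first = log.task_loss.iloc[:50].mean()
        last = log.task_loss.iloc[-50:].mean()
        assert last < first

    def test_noise_free_source_fit_is_tight(self):
        """Self-consistency: with no instrument shift and ample iterations the
        source-domain test RMSE is well under 10% of the label spread."""
        from nirshift.simulate import InstrumentProfile, default_library, generate_paired

        lib = default_library()
        lib.label_noise_sd = 0.0
        prof = InstrumentProfile(n_channels=64, noise_sd=0.0)
        ds = generate_paired(150, 10, lib, prof, prof, seed=21)
        sp = random_split(ds.source, 0.7, 1)
        cfg = TrainingConfig(iters_warmup=2500, iters_adapt=0, iters_joint=0,
                             dropout_rate=0.0, weight_decay=0.0, seed=2)
        m = DomainAdaptationModel(sp.train, ds.target, method="dan", config=cfg)
        res = m.fit(stages="A")
        pred = res.predict(sp.test, "source")
        rmse = np.sqrt(np.mean((pred - sp.test.labels) ** 2))
        assert rmse < 0.10 * ds.source.labels.std()
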