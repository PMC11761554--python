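"""Neural fitter: normalization, physics loss, training and prediction."""

import numpy as np
import pytest

from relaxfit.fitter import (
    NetworkSpec,
    TrainConfig,
    load_fitter,
    normalize_signal,
    physics_loss,
    predict,
    save_fitter,
    train,
)
from relaxfit.models import default_bounds, evaluate
from relaxfit.synthetic import NoiseSpec, ParamPrior, make_dataset

SMALL_NET = NetworkSpec(num_blocks=2, width=32, dropout_rate=0.1)


@pytest.fixture(scope="module")
def me_fitter_and_data():
    ds = make_dataset("me", 4000, seed=21)
    fitter = train(ds, NetworkSpec(num_blocks=2, width=64, dropout_rate=0.1),
                   TrainConfig(epochs=30, seed=5))
    return fitter, ds


class TestNormalization:
    def test_unit_first_sample_is_identity(self):
        s = np.array([1.0, 0.8, 0.5])
        out, scale = normalize_signal(s)
        np.testing.assert_array_equal(out, s)
        assert scale == 1.0

    def test_scale_equivariance(self):
        s = np.array([2.0, 1.0, 0.5])
        out1, sc1 = normalize_signal(s)
        out5, sc5 = normalize_signal(5 * s)
        np.testing.assert_allclose(out1, out5)
        assert sc5 == pytest.approx(5 * sc1)

    def test_me_amplitude_cancels(self, schedule):
        s1 = evaluate("me", np.array([1.0, 50.0]), schedule)
        s3 = evaluate("me", np.array([3.0, 50.0]), schedule)
        np.testing.assert_allclose(normalize_signal(s3)[0], normalize_signal(s1)[0], rtol=1e-14)

    def test_nonpositive_first_sample_rejected(self):
        with pytest.raises(ValueError):
            normalize_signal(np.array([-1.0, 0.5]))


class TestPhysicsLoss:
    def test_zero_at_perfect_prediction(self, schedule):
        theta = np.array([[1.0, 0.4, 2.0, 40.0]])
        s = evaluate("be", theta, schedule)
        assert physics_loss(s, theta, theta, "be", schedule) == 0.0

    def test_hand_computed_parameter_term(self, schedule):
        """Normalized errors (0.1, 0.2) with gamma_s=0 give gamma_theta*0.05."""
        b = default_bounds("me")
        truth = np.array([[1.0, 100.0]])
        pred = truth + np.array([[0.1 * b.range[0], 0.2 * b.range[1]]])
        s = evaluate("me", truth, schedule)
        loss = physics_loss(s, truth, pred, "me", schedule, gamma_s=0.0, gamma_theta=1.0)
        assert loss == pytest.approx(0.05, rel=1e-9)

    def test_signal_term_linear_in_weight(self, schedule):
        truth = np.array([[1.0, 50.0]])
        pred = np.array([[1.0, 60.0]])
        s = evaluate("me", truth, schedule)
        l1 = physics_loss(s, truth, pred, "me", schedule, gamma_s=1.0, gamma_theta=0.0)
        l2 = physics_loss(s, truth, pred, "me", schedule, gamma_s=2.0, gamma_theta=0.0)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_negative_weights_rejected(self, schedule):
        theta = np.array([[1.0, 50.0]])
        s = evaluate("me", theta, schedule)
        with pytest.raises(ValueError):
            physics_loss(s, theta, theta, "me", schedule, gamma_s=-1.0)


class TestTraining:
    def test_point_mass_task_is_learned(self):
        """A single noise-free target is driven to a tiny validation loss."""
        prior = ParamPrior("me", {"T_me": (60.0, 60.0)})
        ds = make_dataset("me", 600, prior=prior, noise=NoiseSpec("none", 0.0, 1), seed=2)
        fitter = train(ds, NetworkSpec(num_blocks=2, width=32, dropout_rate=0.0),
                       TrainConfig(epochs=60, seed=3))
        val = fitter.history["val_loss"]
        assert min(val) < 1e-3 * val[0]

    def test_zero_epochs_returns_untrained_network(self):
        ds = make_dataset("me", 100, seed=1)
        fitter = train(ds, SMALL_NET, TrainConfig(epochs=0, seed=0))
        assert fitter.history["train_loss"] == []
        assert predict(fitter, ds.signals).shape == (100, 2)

    def test_training_descends(self, me_fitter_and_data):
        fitter, _ = me_fitter_and_data
        tl = fitter.history["train_loss"]
        assert np.mean(tl[-3:]) <= tl[0]

    def test_history_has_one_entry_per_epoch(self, me_fitter_and_data):
        fitter, _ = me_fitter_and_data
        assert len(fitter.history["train_loss"]) == len(fitter.history["val_loss"]) == 30

    def test_empty_split_rejected(self):
        ds = make_dataset("me", 100, seed=1)
        ds.split[:] = "train"
        with pytest.raises(ValueError):
            train(ds, SMALL_NET, TrainConfig(epochs=1))


class TestPrediction:
    def test_deterministic_in_eval_mode(self, me_fitter_and_data):
        fitter, ds = me_fitter_and_data
        a = predict(fitter, ds.signals[:50])
        b = predict(fitter, ds.signals[:50])
        np.testing.assert_array_equal(a, b)

    def test_outputs_always_within_bounds(self, me_fitter_and_data):
        fitter, _ = me_fitter_and_data
        rng = np.random.default_rng(0)
        junk = rng.standard_normal((10_000, 6))  # pure noise, signs mixed
        theta = predict(fitter, junk)
        b = fitter.bounds
        assert np.all(theta[:, 1:] >= b.lo[1:]) and np.all(theta[:, 1:] <= b.hi[1:])
        assert np.all(theta[:, 0] > 0)

    def test_amplitude_equivariance(self, me_fitter_and_data):
        fitter, ds = me_fitter_and_data
        base = predict(fitter, ds.signals[:20])
        scaled = predict(fitter, 3.7 * ds.signals[:20])
        np.testing.assert_allclose(scaled[:, 1:], base[:, 1:], rtol=1e-10)
        np.testing.assert_allclose(scaled[:, 0], 3.7 * base[:, 0], rtol=1e-10)

    def test_noiseless_easier_than_noisy(self, me_fitter_and_data):
        from relaxfit.metrics import EvaluationSet, mnad

        fitter, ds = me_fitter_and_data
        te = ds.subset("test")
        noisy = mnad(EvaluationSet("me", te.params, predict(fitter, te.signals)))
        clean = mnad(EvaluationSet("me", te.params, predict(fitter, te.clean_signals)))
        assert clean < noisy

    def test_length_mismatch_rejected(self, me_fitter_and_data):
        fitter, _ = me_fitter_and_data
        with pytest.raises(ValueError):
            predict(fitter, np.ones((5, 4)))


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, me_fitter_and_data, tmp_path):
        fitter, ds = me_fitter_and_data
        path = save_fitter(fitter, tmp_path / "fitter")
        back = load_fitter(path)
        np.testing.assert_array_equal(
            predict(back, ds.signals[:20]), predict(fitter, ds.signals[:20])
        )
        assert back.spec == fitter.spec
        assert back.schedule.times == fitter.schedule.times
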