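"""Autoencoder: shape contracts, training protocol, determinism, gradients."""

import numpy as np
import pytest

from eegrecon import (
    AeConfig,
    EegDataset,
    SyntheticConfig,
    build_autoencoder,
    generate_dataset,
    train_autoencoder,
)
from eegrecon.autoencoder import ConvAutoencoder, _Conv1d, _ConvTranspose1d

SMALL = AeConfig(length=512, epochs=5, batch_size=8, seed=0)


@pytest.fixture(scope="module")
def small_data():
    return generate_dataset(SyntheticConfig(n_per_class=10, length=512, seed=2))


class TestBuild:
    def test_output_length_matches_input(self):
        model = build_autoencoder(SMALL)
        x = np.random.default_rng(0).uniform(size=(3, 512))
        assert model.forward(x).shape == (3, 512)

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            AeConfig(length=4097)

    def test_same_seed_identical_initial_weights(self):
        a, b = build_autoencoder(SMALL), build_autoencoder(SMALL)
        for la, lb in zip(a.layers, b.layers):
            for (_, pa), (_, pb) in zip(la.params, lb.params):
                np.testing.assert_array_equal(pa, pb)

    def test_different_seed_different_weights(self):
        a = build_autoencoder(SMALL)
        b = build_autoencoder(AeConfig(length=512, seed=1))
        assert not np.array_equal(a.layers[0].w, b.layers[0].w)

    @pytest.mark.parametrize("lr, epochs", [(0.0, 5), (1e-3, 0)])
    def test_bad_optimizer_settings(self, lr, epochs):
        with pytest.raises(ValueError):
            AeConfig(learning_rate=lr, epochs=epochs)


class TestGradients:
    """Backward passes match central finite differences on tiny layers."""

    @pytest.mark.parametrize("layer_cls", [_Conv1d, _ConvTranspose1d])
    def test_input_gradient(self, layer_cls, rng):
        lay = layer_cls(2, 3, 7, 2, np.random.default_rng(0))
        x = rng.normal(size=(2, 2, 16)).astype(np.float32)
        gy = rng.normal(size=lay.forward(x).shape).astype(np.float32)
        lay.forward(x, train=True)
        gx = lay.backward(gy)
        eps = 1e-3
        num = np.zeros_like(x)
        for idx in np.ndindex(x.shape):
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num[idx] = ((lay.forward(xp) - lay.forward(xm)) * gy).sum() / (2 * eps)
        np.testing.assert_allclose(gx, num, atol=5e-3)

    @pytest.mark.parametrize("layer_cls", [_Conv1d, _ConvTranspose1d])
    def test_weight_gradient(self, layer_cls, rng):
        lay = layer_cls(2, 2, 7, 2, np.random.default_rng(1))
        x = rng.normal(size=(1, 2, 16)).astype(np.float32)
        gy = rng.normal(size=lay.forward(x).shape).astype(np.float32)
        lay.forward(x, train=True)
        lay.backward(gy)
        eps = 1e-3
        w0 = lay.w.copy()
        for idx in [(0, 0), (1, 5), (0, 9)]:
            lay.w = w0.copy()
            lay.w[idx] += eps
            up = (lay.forward(x) * gy).sum()
            lay.w = w0.copy()
            lay.w[idx] -= eps
            down = (lay.forward(x) * gy).sum()
            lay.w = w0
            assert lay.gw[idx] == pytest.approx((up - down) / (2 * eps), abs=5e-3)


class TestTraining:
    def test_loss_decreases(self, small_data):
        inter = small_data.subset("interictal")
        model = build_autoencoder(AeConfig(length=512, epochs=30, batch_size=8, seed=0))
        train_autoencoder(model, inter)
        assert len(model.loss_history) == 30
        assert model.loss_history[-1] < model.loss_history[0]

    def test_mixed_labels_rejected(self, small_data):
        model = build_autoencoder(SMALL)
        with pytest.raises(ValueError, match="single label"):
            train_autoencoder(model, small_data)

    def test_empty_and_singleton_rejected(self, small_data):
        model = build_autoencoder(SMALL)
        with pytest.raises(ValueError):
            train_autoencoder(model, EegDataset([]))
        with pytest.raises(ValueError, match="at least 2"):
            train_autoencoder(model, EegDataset(small_data.records[:1]))

    def test_single_epoch_history(self, small_data):
        cfg = AeConfig(length=512, epochs=1, batch_size=8, seed=0)
        model = train_autoencoder(build_autoencoder(cfg), small_data.subset("ictal"))
        assert len(model.loss_history) == 1

    def test_training_deterministic(self, small_data):
        inter = small_data.subset("interictal")
        runs = []
        for _ in range(2):
            m = train_autoencoder(build_autoencoder(SMALL), inter)
            runs.append((m.layers[0].w.copy(), list(m.loss_history)))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]


class TestReconstruct:
    def test_untrained_model_gives_valid_output(self, small_data):
        model = build_autoencoder(SMALL)
        xhat = model.reconstruct(small_data.records[0])
        assert xhat.shape == (512,)
        assert np.isfinite(xhat).all()

    def test_length_mismatch_rejected(self, small_data):
        model = build_autoencoder(AeConfig(length=1024))
        with pytest.raises(ValueError, match="length"):
            model.reconstruct(small_data.records[0])

    def test_inference_deterministic(self, small_data):
        model = build_autoencoder(SMALL)
        a = model.reconstruct(small_data.records[0])
        b = model.reconstruct(small_data.records[0])
        np.testing.assert_array_equal(a, b)


class TestCheckpoint:
    def test_round_trip_bit_identical(self, tmp_path, small_data):
        model = train_autoencoder(build_autoencoder(SMALL), small_data.subset("interictal"))
        path = tmp_path / "ae.npz"
        model.save(path)
        loaded = ConvAutoencoder.load(path)
        assert loaded.config == model.config
        assert loaded.loss_history == model.loss_history
        rec = small_data.records[0]
        np.testing.assert_array_equal(loaded.reconstruct(rec), model.reconstruct(rec))

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, __tag__=np.array("other"), x=np.zeros(3))
        with pytest.raises(ValueError, match="checkpoint"):
            ConvAutoencoder.load(path)


class TestSpecificity:
    """The one-class claim: off-class signals reconstruct worse (200-epoch AE)."""

    def test_heldout_interictal_reconstructs_below_ictal_tenth_percentile(
        self, heldout_features
    ):
        df = heldout_features.df
        inter = df[df.label == "interictal"].mse
        ictal = df[df.label == "ictal"].mse
        assert inter.median() < np.percentile(ictal, 10)

    def test_training_loss_converges(self, trained_ae):
        h = trained_ae.loss_history
        assert np.mean(h[-5:]) < np.mean(h[:5])
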