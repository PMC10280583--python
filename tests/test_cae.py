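"""Autoencoder architecture, training contract, and hyperparameter search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.exceptions import NotFittedError

from nircae.cae import (
    CAEConfig,
    ConvolutionalAutoencoder,
    DivergenceError,
    random_search,
)

TABLE_COUNTS = {
    "conv1": 96, "conv2": 2592, "dense1": 358464, "bottleneck": 2080,
    "expand": 184800, "convT1": 3104, "convT2": 1552, "convT3": 49,
}


def _small_cae(**overrides):
    """Fast config for a 64-channel input."""
    kw = dict(input_length=64, encoder_filters=(4, 8), dense_hidden=16,
              latent_dim=4, max_epochs=8, seed=0)
    kw.update(overrides)
    return ConvolutionalAutoencoder(**kw)


class TestArchitecture:
    def test_default_parameter_counts(self):
        table = ConvolutionalAutoencoder().parameter_table()
        counts = dict(zip(table["layer"], table["n_parameters"]))
        for layer, expected in TABLE_COUNTS.items():
            assert counts[layer] == expected, layer
        zero_layers = table[table["n_parameters"] == 0]["type"]
        assert set(zero_layers) == {"MaxPool1D", "Flatten", "Reshape",
                                    "Upsample1D"}

    def test_default_shape_chain(self):
        model = ConvolutionalAutoencoder()
        assert model.encoder_output_lengths() == [700, 350, 350, 175,
                                                  5600, 64, 32]
        table = model.parameter_table()
        assert tuple(table.iloc[-1]["output_shape"]) == (700, 1)

    def test_latent_dim_changes_only_bottleneck(self):
        base = ConvolutionalAutoencoder().parameter_table()
        small = ConvolutionalAutoencoder(latent_dim=2).parameter_table()
        enc_base = base[base.part == "encoder"]
        enc_small = small[small.part == "encoder"]
        # all shapes equal except the bottleneck width
        for (_, a), (_, b) in zip(enc_base.iterrows(), enc_small.iterrows()):
            if a["layer"] == "bottleneck":
                assert b["output_shape"] == (2,)
            else:
                assert a["output_shape"] == b["output_shape"]

    @pytest.mark.parametrize("bad", [
        dict(input_length=702),        # not divisible by pool^2
        dict(latent_dim=0),
        dict(max_epochs=0),
        dict(encoder_kernel=4),
        dict(val_fraction=1.5),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            ConvolutionalAutoencoder(**bad).fit(np.ones((10, 700)))

    def test_config_roundtrip(self):
        cfg = CAEConfig(latent_dim=8, encoder_kernel=7)
        assert CAEConfig.from_dict(cfg.to_dict()) == cfg


class TestTraining:
    def test_deterministic_given_seed(self, small_dataset):
        X = small_dataset.absorbance
        a = _small_cae(seed=3).fit(X)
        b = _small_cae(seed=3).fit(X)
        for la, lb in zip(a.encoder_layers_ + a.decoder_layers_,
                          b.encoder_layers_ + b.decoder_layers_):
            for pa, pb in zip(la.params, lb.params):
                np.testing.assert_array_equal(pa, pb)
        pd.testing.assert_frame_equal(a.training_log_, b.training_log_)

    def test_loss_decreases_over_training(self, small_dataset):
        """Epoch-5 training loss below epoch-1 loss on >= 2 of 3 seeds."""
        X = small_dataset.absorbance
        improved = 0
        for seed in (0, 1, 2):
            log = _small_cae(seed=seed).fit(X).training_log_
            if len(log) >= 5 and log.train_loss.iloc[4] < log.train_loss.iloc[0]:
                improved += 1
        assert improved >= 2

    def test_identical_spectra_learned_by_bias(self):
        """A dataset of one repeated spectrum is reconstructible to
        near-zero loss within the epoch budget."""
        x = 0.5 + 0.3 * np.sin(np.linspace(0, 6, 64))
        X = np.tile(x, (20, 1))
        model = _small_cae(max_epochs=20).fit(X)
        assert model.training_log_.train_loss.iloc[-1] < 1e-4

    def test_wrong_channel_count_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="channels"):
            _small_cae(input_length=32).fit(small_dataset.absorbance)

    @pytest.mark.filterwarnings("ignore:overflow", "ignore:invalid value")
    def test_divergence_raises_with_epoch(self, small_dataset):
        with pytest.raises(DivergenceError, match="epoch"):
            _small_cae(learning_rate=1e200).fit(small_dataset.absorbance)

    def test_training_log_contract(self, small_dataset):
        m = _small_cae().fit(small_dataset.absorbance)
        log = m.training_log_
        assert list(log.columns) == ["epoch", "train_loss", "val_loss"]
        assert len(log) <= m.max_epochs
        assert m.stopped_early_ == (len(log) < m.max_epochs)
        assert np.isfinite(log.to_numpy()).all()


@pytest.fixture(scope="module")
def trained(small_dataset):
    return _small_cae().fit(small_dataset.absorbance)


class TestEncodeDecode:
    def test_latent_matrix_shape(self, trained, small_dataset):
        H = trained.transform(small_dataset.absorbance[:20])
        assert H.shape == (20, 4)

    def test_latents_strictly_inside_unit_interval(self, trained,
                                                   small_dataset):
        H = trained.transform(small_dataset.absorbance)
        assert np.all(np.abs(H) < 1.0)

    def test_identical_rows_encode_identically(self, trained, small_dataset):
        x = small_dataset.absorbance[:1]
        H = trained.transform(np.vstack([x, x]))
        np.testing.assert_array_equal(H[0], H[1])

    def test_reconstruction_preserves_shape(self, trained, small_dataset):
        X = small_dataset.absorbance[:7]
        assert trained.reconstruct(X).shape == X.shape

    def test_untrained_model_raises(self, small_dataset):
        with pytest.raises(NotFittedError):
            _small_cae().transform(small_dataset.absorbance)
        with pytest.raises(NotFittedError):
            _small_cae().inverse_transform(np.zeros((2, 4)))

    def test_persistence_roundtrip(self, trained, small_dataset, tmp_path):
        trained.save(tmp_path / "model")
        back = ConvolutionalAutoencoder.load(tmp_path / "model")
        X = small_dataset.absorbance[:5]
        np.testing.assert_allclose(back.transform(X), trained.transform(X),
                                   atol=1e-12)
        np.testing.assert_allclose(back.reconstruct(X),
                                   trained.reconstruct(X), atol=1e-12)


class TestRandomSearch:
    SMALL_BASE = CAEConfig(input_length=64, encoder_filters=(4, 8),
                           dense_hidden=16, latent_dim=4, max_epochs=5)

    def test_single_configuration_returned(self, small_dataset):
        space = {"latent_dim": [4]}
        best, log = random_search(small_dataset.absorbance, space,
                                  n_trials=1, seed=0,
                                  base_config=self.SMALL_BASE)
        assert best.latent_dim == 4
        assert len(log) == 1

    def test_trial_log_length(self, small_dataset):
        space = {"latent_dim": [2, 4], "batch_size": [8, 16]}
        _, log = random_search(small_dataset.absorbance, space, n_trials=3,
                               seed=0, base_config=self.SMALL_BASE)
        assert len(log) == 3

    def test_exhausted_space_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            random_search(small_dataset.absorbance, {"latent_dim": [2, 4]},
                          n_trials=3, seed=0, base_config=self.SMALL_BASE)

    def test_empty_space_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="non-empty"):
            random_search(small_dataset.absorbance, {"latent_dim": []},
                          n_trials=1, seed=0)

    def test_wide_bottleneck_wins_on_structured_data(self, small_dataset):
        """Latent width {2, 32}: the 32-unit bottleneck reconstructs the
        multi-factor spectra better on a majority of seeds."""
        wins = 0
        for seed in (0, 1, 2):
            best, _ = random_search(
                small_dataset.absorbance, {"latent_dim": [2, 32]},
                n_trials=2, seed=seed, base_config=self.SMALL_BASE)
            wins += best.latent_dim == 32
        assert wins >= 2
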