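"""Recurrent VAE: loss closed forms, gradients, training behavior, checkpoints."""

import dataclasses

import numpy as np
import pytest

from latentnets import (
    LabeledDataset,
    TimeSeriesRecord,
    VAEConfig,
    encode,
    kl_term,
    load_checkpoint,
    reconstruct,
    reparameterize,
    save_checkpoint,
    train,
    vae_loss,
)
from latentnets.vae import (
    LatentGaussianSet,
    TrainedVAE,
    TrainingDiverged,
    _backward,
    _forward,
    _init_params,
)

from conftest import two_class_config
from latentnets import generate_dataset


def make_latent(mu, sd):
    mu, sd = np.atleast_1d(np.asarray(mu, float)), np.atleast_1d(np.asarray(sd, float))
    return LatentGaussianSet(means=mu, stds=sd)


def untrained_model(M=8, H=16, seed=0, **kw):
    cfg = VAEConfig(latent_dim=M, hidden_units=H, seed=seed, **kw)
    params = _init_params(cfg, np.random.default_rng(seed))
    return TrainedVAE(params=params, config=cfg)


class TestKlTerm:
    def test_standard_normal_gives_zero(self):
        assert kl_term(make_latent([0, 0, 0], [1, 1, 1])) == pytest.approx(0.0)

    def test_unit_mean_unit_std(self):
        # 1/2 (mu^2 + sigma^2 - 1 - log sigma^2) = 1/2 (1 + 1 - 1 - 0)
        assert kl_term(make_latent([1.0], [1.0])) == pytest.approx(0.5)

    def test_std_e_closed_form(self):
        expected = 0.5 * (np.e**2 - 1 - 2)
        assert kl_term(make_latent([0.0], [np.e])) == pytest.approx(expected)
        assert expected == pytest.approx(2.1945, abs=1e-4)

    def test_literal_scale_one(self):
        assert kl_term(make_latent([1.0], [1.0]), kl_scale=1.0) == pytest.approx(1.0)

    def test_nonnegative_on_random_latents(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            lat = make_latent(rng.normal(size=5), rng.uniform(0.05, 5.0, size=5))
            assert kl_term(lat) >= 0.0

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            make_latent([0.0], [0.0])


class TestReparameterize:
    def test_zero_eps_returns_mean(self):
        lat = make_latent([1.0, -2.0], [0.5, 3.0])

        class ZeroRng:
            def standard_normal(self, n):
                return np.zeros(n)

        np.testing.assert_array_equal(reparameterize(lat, ZeroRng()), lat.means)

    def test_unit_eps_returns_mean_plus_std(self):
        lat = make_latent([1.0, -2.0], [0.5, 3.0])

        class OneRng:
            def standard_normal(self, n):
                return np.ones(n)

        np.testing.assert_array_equal(
            reparameterize(lat, OneRng()), lat.means + lat.stds
        )

    def test_sample_mean_clt_bound(self):
        lat = make_latent([1.0, -2.0, 0.3], [0.5, 3.0, 1.0])
        rng = np.random.default_rng(1)
        n = 20_000
        draws = np.array([reparameterize(lat, rng) for _ in range(n)])
        bound = 4 * lat.stds / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - lat.means) < bound)


class TestEncode:
    def test_shapes_and_finiteness_untrained(self):
        model = untrained_model(M=6)
        rec = TimeSeriesRecord(values=np.sin(np.linspace(0, 5, 40)), label=0)
        lat = encode(rec, model)
        assert lat.M == 6
        assert np.all(np.isfinite(lat.means)) and np.all(np.isfinite(lat.stds))

    def test_deterministic(self):
        model = untrained_model()
        rec = TimeSeriesRecord(values=np.linspace(-1, 1, 30), label=0)
        a, b = encode(rec, model), encode(rec, model)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.stds, b.stds)

    def test_stds_strictly_positive_on_random_series(self):
        model = untrained_model(M=4, H=8)
        rng = np.random.default_rng(2)
        for _ in range(100):
            rec = rng.normal(size=rng.integers(5, 60))
            assert np.all(encode(rec, model).stds > 0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            encode(np.array([1.0]), untrained_model())


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic BPTT gradients agree with central differences."""
        cfg = VAEConfig(
            latent_dim=3, hidden_units=5, n_recurrent_layers=2,
            batch_size=2, mc_samples=2, seed=1,
        )
        rng = np.random.default_rng(0)
        params = _init_params(cfg, rng)
        params["dec_x0"] = np.array([0.3])  # exercise the input-token gradient
        X = rng.normal(size=(2, 7))
        lengths = np.array([7, 5])
        mask = np.zeros((2, 7))
        mask[0, :7] = 1
        mask[1, :5] = 1
        eps_list = [rng.standard_normal((2, 3)) for _ in range(2)]

        ctx = _forward(params, cfg, X, mask, lengths, eps_list)
        grads = _backward(params, cfg, ctx)
        h = 1e-6
        pick = np.random.default_rng(3)
        for key, p in params.items():
            flat_idx = pick.choice(p.size, size=min(4, p.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + h
                lp = _forward(params, cfg, X, mask, lengths, eps_list)["loss"].total
                p[idx] = orig - h
                lm = _forward(params, cfg, X, mask, lengths, eps_list)["loss"].total
                p[idx] = orig
                num = (lp - lm) / (2 * h)
                ana = grads[key][idx]
                assert ana == pytest.approx(num, rel=1e-3, abs=1e-7), key


class TestVaeLoss:
    def test_kl_nonnegative_over_random_batches(self, small_dataset):
        model = untrained_model(M=4, H=8)
        rng = np.random.default_rng(4)
        for _ in range(20):
            batch = [small_dataset.records[i] for i in rng.choice(50, size=5)]
            assert vae_loss(batch, model, rng).kl >= 0.0

    def test_total_is_reconstruction_plus_kl(self, small_dataset):
        model = untrained_model(M=4, H=8)
        loss = vae_loss(small_dataset.records[:6], model, np.random.default_rng(5))
        assert loss.total == pytest.approx(loss.reconstruction + loss.kl)

    def test_mc_samples_agree_within_monte_carlo_error(self, small_dataset):
        model = untrained_model(M=4, H=8)
        batch = list(small_dataset.records[:8])
        r1 = [vae_loss(batch, model, np.random.default_rng(1000 + i),).reconstruction
              for i in range(100)]
        model4 = TrainedVAE(
            params=model.params,
            config=dataclasses.replace(model.config, mc_samples=4),
        )
        r4 = [vae_loss(batch, model4, np.random.default_rng(2000 + i)).reconstruction
              for i in range(100)]
        se = np.std(r1) / np.sqrt(len(r1)) + np.std(r4) / np.sqrt(len(r4))
        assert abs(np.mean(r1) - np.mean(r4)) < 5 * se + 1e-9

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            vae_loss([], untrained_model(), np.random.default_rng(0))


class TestTraining:
    def test_loss_improves(self, small_model):
        hist = small_model.history
        assert np.all(np.isfinite([h.total for h in hist]))
        assert hist[-1].total < hist[0].total

    def test_seeded_reproducibility(self, small_dataset, small_vae_config):
        cfg = dataclasses.replace(small_vae_config, max_epochs=5)
        h1 = [h.total for h in train(small_dataset, cfg).history]
        h2 = [h.total for h in train(small_dataset, cfg).history]
        assert h1 == h2

    def test_labels_never_used(self, small_dataset, small_vae_config):
        cfg = dataclasses.replace(small_vae_config, max_epochs=5)
        rng = np.random.default_rng(6)
        permuted = LabeledDataset(
            records=tuple(
                TimeSeriesRecord(values=r.values, label=int(l), id=r.id)
                for r, l in zip(
                    small_dataset.records,
                    rng.permutation(small_dataset.labels),
                )
            )
        )
        h1 = [h.total for h in train(small_dataset, cfg).history]
        h2 = [h.total for h in train(permuted, cfg).history]
        assert h1 == h2

    def test_constant_series_fit(self):
        recs = tuple(
            TimeSeriesRecord(values=np.full(20, 2.5), label=0, id=f"s{i}")
            for i in range(8)
        )
        ds = LabeledDataset(records=recs)
        cfg = VAEConfig(
            latent_dim=2, hidden_units=8, batch_size=8, learning_rate=5e-3,
            max_epochs=200, patience=200, seed=0,
        )
        model = train(ds, cfg)
        assert model.history[-1].reconstruction < 0.1
        out = reconstruct(recs[0], model)
        assert np.max(np.abs(out - recs[0].values)) < 0.1

    def test_non_finite_loss_raises(self):
        # un-normalized astronomically scaled inputs overflow the squared error
        recs = tuple(
            TimeSeriesRecord(values=np.full(20, 1e200), label=0, id=f"s{i}")
            for i in range(4)
        )
        cfg = VAEConfig(
            latent_dim=2, hidden_units=4, batch_size=4, max_epochs=5,
            normalize_input=False, seed=0,
        )
        with pytest.raises(TrainingDiverged, match="non-finite"):
            with np.errstate(over="ignore"):
                train(LabeledDataset(records=recs), cfg)

    def test_variable_length_batches(self):
        rng = np.random.default_rng(7)
        recs = tuple(
            TimeSeriesRecord(
                values=rng.normal(size=rng.integers(10, 40)), label=0, id=f"s{i}"
            )
            for i in range(12)
        )
        ds = LabeledDataset(records=recs)
        cfg = VAEConfig(
            latent_dim=3, hidden_units=8, batch_size=6, max_epochs=3, seed=0
        )
        model = train(ds, cfg)
        assert np.all(np.isfinite([h.total for h in model.history]))
        assert encode(recs[0], model).M == 3


class TestReconstruct:
    def test_output_length_matches_input(self):
        model = untrained_model()
        out = reconstruct(np.zeros(140) + np.linspace(0, 1, 140), model)
        assert out.shape == (140,)
        assert np.all(np.isfinite(out))

    def test_sampled_reconstruction_differs_from_mean_decode(self, small_model):
        rec = np.sin(np.linspace(0, 6, 50))
        mean_out = reconstruct(rec, small_model)
        samp_out = reconstruct(rec, small_model, np.random.default_rng(8))
        assert mean_out.shape == samp_out.shape == (50,)
        assert not np.array_equal(mean_out, samp_out)


class TestCheckpoint:
    def test_roundtrip_restores_encode_bit_exactly(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(small_model, path)
        back = load_checkpoint(path)
        assert back.config == small_model.config
        rec = np.cos(np.linspace(0, 3, 77))
        a, b = encode(rec, small_model), encode(rec, back)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.stds, b.stds)

    def test_history_preserved(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(small_model, path)
        back = load_checkpoint(path)
        assert [h.total for h in back.history] == [
            h.total for h in small_model.history
        ]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"latent_dim": 1},
            {"hidden_units": 0},
            {"learning_rate": 0.0},
            {"kl_scale": -0.1},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            VAEConfig(**kw)
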