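"""Tests for the conditional GAN: losses, JSD, backprop, training behavior."""

import numpy as np
import pandas as pd
import pytest

from ephysgan import datasets as D
from ephysgan import gan as G


class TestAdversarialLosses:
    def test_indifferent_discriminator(self):
        p = np.full(32, 0.5)
        d_loss, g_loss = G.adversarial_losses(p, p)
        assert d_loss == pytest.approx(2 * np.log(2), abs=1e-12)
        assert g_loss == pytest.approx(0.0, abs=1e-12)

    def test_perfect_discriminator_limit(self):
        d_loss, _ = G.adversarial_losses(np.ones(8), np.zeros(8))
        # probabilities are clipped at 1e-7 before the logs
        assert d_loss < 1e-6

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        pr = rng.uniform(0.01, 0.99, 100)
        pf = rng.uniform(0.01, 0.99, 100)
        d_loss, g_loss = G.adversarial_losses(pr, pf)
        d_hand = -sum(np.log(p) for p in pr) / 100 \
                 - sum(np.log(1 - p) for p in pf) / 100
        g_hand = sum(np.log(1 - p) for p in pf) / 100 \
                 - sum(np.log(p) for p in pf) / 100
        assert d_loss == pytest.approx(d_hand, abs=1e-6)
        assert g_loss == pytest.approx(g_hand, abs=1e-6)


class TestJSD:
    def test_identical_sample_sets_give_zero(self):
        x = np.random.default_rng(1).normal(0, 1, (500, 3))
        assert G.jsd(x, x.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports_give_one(self):
        a = np.zeros((200, 2))
        b = np.ones((200, 2)) * 10
        assert G.jsd(a, b) == pytest.approx(1.0, abs=1e-6)

    def test_three_bin_hand_calculation(self):
        p = np.array([0.5, 0.3, 0.2])
        q = np.array([0.2, 0.3, 0.5])
        m = (p + q) / 2
        expected = 0.5 * np.sum(p * np.log2(p / m)) + \
            0.5 * np.sum(q * np.log2(q / m))
        assert G.jsd_discrete(p, q) == pytest.approx(expected, abs=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(0, 1, (100, 2))
            b = rng.normal(rng.uniform(-3, 3), 1, (100, 2))
            assert 0.0 <= G.jsd(a, b) <= 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            G.jsd(np.empty((0, 2)), np.ones((5, 2)))


class TestBackprop:
    def test_mlp_gradients_match_finite_differences(self):
        """End-to-end gradient check of the manual backprop through a small
        discriminator-style network with the real-batch loss term."""
        rng = np.random.default_rng(3)
        net = G._MLP([4, 8, 8, 1], rng)
        x = rng.normal(0, 1, (6, 4))

        def loss():
            s = net.forward(x)[:, 0]
            p = G._sigmoid(s)
            return -np.mean(np.log(p))

        cache = []
        s = net.forward(x, cache)[:, 0]
        p = G._sigmoid(s)
        g = (-(1 - p) / len(s))[:, None]
        dW, db, _ = net.backward(cache, g)

        eps = 1e-6
        for li, idx in [(0, (0, 0)), (0, (1, 3)), (2, (0, 0)), (2, (5, 0))]:
                orig = net.W[li][idx]
                net.W[li][idx] = orig + eps
                up = loss()
                net.W[li][idx] = orig - eps
                dn = loss()
                net.W[li][idx] = orig
                fd = (up - dn) / (2 * eps)
                assert dW[li][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_generator_gradient_through_discriminator(self):
        """Gradient of the non-saturating generator loss w.r.t. a generator
        weight, checked against finite differences through both networks."""
        rng = np.random.default_rng(4)
        gen = G._MLP([3, 6, 2], rng)
        disc = G._MLP([2, 6, 1], rng)
        zin = rng.normal(0, 1, (5, 3))

        def g_loss():
            xg = gen.forward(zin)
            s = disc.forward(xg)[:, 0]
            p = np.clip(G._sigmoid(s), 1e-7, 1 - 1e-7)
            return np.mean(np.log(1 - p) - np.log(p))

        cache_g, cache_d = [], []
        xg = gen.forward(zin, cache_g)
        s = disc.forward(xg, cache_d)[:, 0]
        g_out = np.full((len(s), 1), -1.0 / len(s))
        _, _, g_in = disc.backward(cache_d, g_out)
        dWg, _, _ = gen.backward(cache_g, g_in)

        eps = 1e-6
        for idx in [(0, 0), (2, 1)]:
            orig = gen.W[0][idx]
            gen.W[0][idx] = orig + eps
            up = g_loss()
            gen.W[0][idx] = orig - eps
            dn = g_loss()
            gen.W[0][idx] = orig
            fd = (up - dn) / (2 * eps)
            assert dWg[0][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


def _identity_dataset(n=2000, seed=0):
    """Parameters deterministically recoverable from the features:
    y = (2x1 - 1, x2^3) is invertible on the unit square."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, 2))
    Y = np.column_stack([2 * X[:, 0] - 1, X[:, 1] ** 3])
    return D.TrainingDataset(
        params=pd.DataFrame(X, columns=["a", "b"]),
        features=pd.DataFrame(Y, columns=["f1", "f2"]),
        bounds=D.Box(("a", "b"), np.zeros(2), np.ones(2)),
        discarded=0, seed=seed)


@pytest.fixture(scope="module")
def trained_identity():
    ds = _identity_dataset()
    cfg = G.GANConfig.desk(epochs=100, minibatch=128, holdout=300,
                           latent_dim=2, gen_layers=(48, 48),
                           disc_layers=(48, 48), seed=1)
    return ds, G.train(ds, cfg)


@pytest.fixture(scope="module")
def trained_tiny():
    ds = _identity_dataset(300, seed=8)
    cfg = G.GANConfig.smoke(latent_dim=2, seed=2)
    return ds, G.train(ds, cfg)


@pytest.fixture(scope="module")
def tiny_ensemble():
    ds = _identity_dataset(300, seed=21)
    members = [G.train(ds, G.GANConfig.smoke(latent_dim=2, seed=s))
               for s in (0, 1)]
    return ds, G.GeneratorEnsemble(members)


class TestTraining:
    def test_same_seed_reproduces_loss_curves(self):
        ds = _identity_dataset(400, seed=5)
        cfg = dict(epochs=3, minibatch=64, holdout=80, latent_dim=2,
                   gen_layers=(16,), disc_layers=(16,), seed=9)
        a = G.train(ds, G.GANConfig.smoke(**cfg))
        b = G.train(ds, G.GANConfig.smoke(**cfg))
        pd.testing.assert_frame_equal(a.log, b.log)
        np.testing.assert_array_equal(a.jsd_trace, b.jsd_trace)

    def test_selected_checkpoint_minimizes_jsd(self, trained_identity):
        _, tg = trained_identity
        js = tg.jsd_trace
        assert js[tg.selected] == js.min()
        assert js[tg.selected] <= js[-1]

    def test_jsd_improves_during_training(self, trained_identity):
        _, tg = trained_identity
        # the 2-D selection score improves despite its small-sample floor
        js = tg.jsd_trace
        assert js.min() < js[0] / 1.5
        # the marginal joint JSD improves strongly
        assert tg.marginal_jsd.min() < tg.marginal_jsd[0] / 3

    def test_identifiable_problem_concentrates_conditionals(
            self, trained_identity):
        """When parameters are a deterministic function of the features, the
        conditional samples should be much narrower than the prior."""
        ds, tg = trained_identity
        P = ds.params.to_numpy()
        idx = [i for i in range(len(P)) if 0.2 < P[i, 1] < 0.8][:20]
        sds = []
        for i in idx:
            X = G.sample(tg, ds.features.iloc[i].to_numpy(), 200, seed=11)
            sds.append(X.std(axis=0))
        prior_sd = 1.0 / np.sqrt(12)   # U(0,1)
        assert np.mean(sds) < 0.35 * prior_sd

    def test_conditional_mean_tracks_truth(self, trained_identity):
        """Conditional sample means follow the true inverse away from the
        cube-root singularity at b = 0 where the inverse is ill-conditioned."""
        ds, tg = trained_identity
        P = ds.params.to_numpy()
        idx = [i for i in range(len(P)) if 0.2 < P[i, 1] < 0.8][:15]
        errs = []
        for i in idx:
            c = ds.features.iloc[i].to_numpy()
            X = G.sample(tg, c, 200, seed=12)
            errs.append(np.abs(X.mean(axis=0) - P[i]).max())
        assert np.mean(errs) < 0.12
        assert np.max(errs) < 0.25

    def test_losses_logged_every_iteration(self, trained_identity):
        _, tg = trained_identity
        assert {"iteration", "epoch", "d_loss", "g_loss"} <= set(tg.log.columns)
        assert np.isfinite(tg.log[["d_loss", "g_loss"]].to_numpy()).all()


class TestSample:
    def test_shape_bounds_and_reproducibility(self, trained_tiny):
        ds, tg = trained_tiny
        c = ds.features.iloc[0].to_numpy()
        X1 = G.sample(tg, c, 100, seed=3)
        X2 = G.sample(tg, c, 100, seed=3)
        assert X1.shape == (100, 2)
        np.testing.assert_array_equal(X1, X2)
        assert X1.min() >= 0.0 and X1.max() <= 1.0

    def test_condition_dimension_mismatch_raises(self, trained_tiny):
        _, tg = trained_tiny
        with pytest.raises(ValueError):
            G.sample(tg, np.zeros(5), 10)

    def test_matrix_conditions_stack_in_order(self, trained_tiny):
        ds, tg = trained_tiny
        C2 = ds.features.iloc[:3].to_numpy()
        X = G.sample(tg, C2, 4, seed=6)
        assert X.shape == (12, 2)


class TestEnsemble:
    def test_sample_shape_reproducibility_and_bounds(self, tiny_ensemble):
        ds, ens = tiny_ensemble
        c = ds.features.iloc[:4].to_numpy()
        X1 = G.sample(ens, c, 5, seed=9)
        X2 = G.sample(ens, c, 5, seed=9)
        assert X1.shape == (20, 2)
        np.testing.assert_array_equal(X1, X2)
        assert X1.min() >= 0.0 and X1.max() <= 1.0

    def test_draws_mix_members(self, tiny_ensemble):
        ds, ens = tiny_ensemble
        c = ds.features.iloc[0].to_numpy()
        pooled = G.sample(ens, c, 400, seed=10)
        singles = [G.sample(m, c, 400, seed=10) for m in ens.members]
        # the pooled mean lies between the member means
        lo = np.minimum(singles[0].mean(0), singles[1].mean(0))
        hi = np.maximum(singles[0].mean(0), singles[1].mean(0))
        assert np.all(pooled.mean(0) >= lo - 0.05)
        assert np.all(pooled.mean(0) <= hi + 0.05)

    def test_save_load_round_trip(self, tiny_ensemble, tmp_path):
        ds, ens = tiny_ensemble
        out = str(tmp_path / "ens")
        ens.save(out)
        back = G.GeneratorEnsemble.load(out)
        assert len(back.members) == 2
        c = ds.features.iloc[:3].to_numpy()
        np.testing.assert_allclose(G.sample(ens, c, 4, seed=2),
                                   G.sample(back, c, 4, seed=2))

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            G.GeneratorEnsemble(members=[])


class TestQuantileTransform:
    def test_normal_scores_are_monotone_and_standardized(self):
        ds = _identity_dataset(2000, seed=30)
        cfg = G.GANConfig.smoke(latent_dim=2, feature_transform="quantile",
                                epochs=1, seed=0)
        X, Y, norm = G._normalize(ds, cfg)
        raw = ds.features.to_numpy()
        # monotone per column and approximately standard normal
        for j in range(Y.shape[1]):
            order = np.argsort(raw[:, j])
            assert np.all(np.diff(Y[order, j]) >= -1e-12)
        assert abs(Y.mean()) < 0.05
        assert abs(Y.std() - 1.0) < 0.1

    def test_unknown_transform_rejected(self):
        ds = _identity_dataset(100, seed=31)
        with pytest.raises(ValueError):
            G.train(ds, G.GANConfig.smoke(latent_dim=2, epochs=1,
                                          feature_transform="rank"))


class TestPersistence:
    def test_save_load_round_trip_preserves_samples(self, tmp_path):
        ds = _identity_dataset(300, seed=13)
        tg = G.train(ds, G.GANConfig.smoke(latent_dim=2, seed=4))
        out = str(tmp_path / "model")
        tg.save(out)
        back = G.TrainedGenerator.load(out)
        c = ds.features.iloc[:5].to_numpy()
        np.testing.assert_allclose(G.sample(tg, c, 7, seed=5),
                                   G.sample(back, c, 7, seed=5))
        assert back.param_names == tg.param_names
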