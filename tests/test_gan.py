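"""Conditional WGAN training, sampling, MMD distance and the quality gate.

Heavy GAN training happens once in the session-scoped ``toy_gan`` fixture;
everything else uses tiny budgets.
"""

import dataclasses

import numpy as np
import pytest

from eegaug.gan import (
    CWGANConfig,
    ConditionalWGAN,
    augment_trainset,
    mmd2,
    quality_gate,
)


def _tiny_model(X, y, steps=5, seed=0):
    cfg = CWGANConfig(
        latent_dim=8, gen_hidden=(16,), critic_hidden=(16,),
        steps=steps, seed=seed,
    )
    return ConditionalWGAN(cfg).fit(X, y)


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(0)
    n = 200
    y = rng.integers(0, 2, n)
    X = np.tanh(np.array([[-0.5], [0.5]])[y] + 0.3 * rng.standard_normal((n, 3)))
    return X, y


class TestConfig:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"latent_dim": 0},
            {"learning_rate": 0.0},
            {"gp_lambda": -1.0},
            {"steps": 0},
        ],
    )
    def test_invalid_rejected(self, overrides):
        with pytest.raises(ValueError):
            dataclasses.replace(CWGANConfig(), **overrides).validate()

    def test_epochs_alias_converts_to_steps(self):
        cfg = dataclasses.replace(CWGANConfig(), steps=None, epochs=3)
        assert cfg.resolve_steps(100) == 3 * int(np.ceil(100 / 32))


class TestTraining:
    def test_loss_history_length(self, small_problem):
        X, y = small_problem
        model = _tiny_model(X, y, steps=7)
        assert len(model.loss_history_) == 7
        assert set(model.loss_history_.columns) == {
            "step", "critic_loss", "gen_loss", "score_gap"
        }

    def test_seed_determinism(self, small_problem):
        X, y = small_problem
        a = _tiny_model(X, y, steps=5, seed=3)
        b = _tiny_model(X, y, steps=5, seed=3)
        assert a.loss_history_.equals(b.loss_history_)
        fa, _ = a.sample(4, 1, rng=np.random.default_rng(0))
        fb, _ = b.sample(4, 1, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(fa, fb)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            ConditionalWGAN(CWGANConfig(batch_size=32)).fit(
                rng.standard_normal((10, 3)), rng.integers(0, 2, 10)
            )


class TestSampling:
    def test_output_contract(self, small_problem):
        X, y = small_problem
        model = _tiny_model(X, y)
        fake, labels = model.sample(7, 1, rng=np.random.default_rng(1))
        assert fake.shape == (7, X.shape[1])
        assert np.all((fake >= -1) & (fake <= 1))   # tanh-bounded output
        assert np.all(labels == 1)

    def test_untrained_and_bad_n(self, small_problem):
        X, y = small_problem
        with pytest.raises(RuntimeError):
            ConditionalWGAN().sample(3, 0)
        model = _tiny_model(X, y)
        with pytest.raises(ValueError):
            model.sample(0, 1)


class TestMMD:
    def test_identical_sets_near_zero(self):
        X = np.random.default_rng(2).standard_normal((100, 5))
        assert mmd2(X, X.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_grows_with_shift(self):
        X = np.random.default_rng(3).standard_normal((150, 5))
        d1 = mmd2(X, X + 0.5)
        d2 = mmd2(X, X + 2.0)
        assert 0 < d1 < d2


class TestQualityGate:
    def test_self_comparison_passes(self):
        X = np.random.default_rng(4).standard_normal((120, 6))
        report = quality_gate(X, X.copy(), seed=0)
        assert report.distance == pytest.approx(0.0, abs=1e-12)
        assert report.passed

    def test_large_shift_fails(self):
        X = np.random.default_rng(5).standard_normal((120, 6))
        shifted = X + 10.0 * X.std(axis=0)
        report = quality_gate(X, shifted, seed=0)
        assert not report.passed

    def test_threshold_row_order_invariant(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((80, 4))
        fake = rng.standard_normal((80, 4))
        a = quality_gate(X, fake, seed=3)
        b = quality_gate(X[rng.permutation(80)], fake, seed=3)
        assert a.threshold == b.threshold

    def test_pca_projections_shapes(self):
        X = np.random.default_rng(7).standard_normal((50, 6))
        F = np.random.default_rng(8).standard_normal((30, 6))
        report = quality_gate(X, F, seed=0)
        assert report.pca_real.shape == (50, 2)
        assert report.pca_fake.shape == (30, 2)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            quality_gate(np.zeros((1, 3)), np.zeros((5, 3)))


class TestAugment:
    def test_zero_fake_is_identity(self, small_problem):
        X, y = small_problem
        model = _tiny_model(X, y)
        import pandas as pd

        feats = pd.DataFrame(X)
        out, labels, report = augment_trainset(feats, y, model, 0)
        assert out.equals(feats)
        np.testing.assert_array_equal(labels, y)
        assert report.passed

    def test_constant_generator_gated_out(self, small_problem):
        """A generator collapsed to a constant has large MMD to dispersed
        real data, so the gate must reject it and leave rows unchanged."""
        X, y = small_problem
        model = _tiny_model(X, y)
        for W in model.generator_.W:
            W[:] = 0.0
        import pandas as pd

        feats = pd.DataFrame(X)
        out, labels, report = augment_trainset(feats, y, model, 100, seed=1)
        assert not report.passed
        assert len(out) == len(feats)

    def test_label_proportion_and_conservation(self, small_problem):
        X, y = small_problem
        model = _tiny_model(X, y)
        import pandas as pd

        out, labels, report = augment_trainset(
            pd.DataFrame(X), y, model, 100, gate=False, seed=2
        )
        assert len(out) == len(X) + 100
        added = labels[len(X):]
        assert abs(added.mean() - y.mean()) < 0.02


class TestToyConvergence:
    """Checks on the session-scoped toy two-Gaussian CWGAN (500 steps)."""

    def test_fake_closer_than_noise(self, toy_gauss, toy_gan):
        X, y = toy_gauss
        rng = np.random.default_rng(3)
        parts = [toy_gan.sample(int(np.sum(y == c)), c, rng=rng)[0] for c in (0, 1)]
        fake = np.vstack(parts)
        noise = rng.uniform(-1, 1, size=X.shape)
        assert mmd2(X, fake) < mmd2(X, noise)

    def test_critic_gap_shrinks(self, toy_gan):
        gap = toy_gan.loss_history_.score_gap.to_numpy()
        q = len(gap) // 4
        assert np.abs(gap[-q:]).mean() < np.abs(gap[:q]).mean()

    def test_generated_data_passes_gate(self, toy_gauss, toy_gan):
        X, y = toy_gauss
        rng = np.random.default_rng(4)
        parts = [toy_gan.sample(int(np.sum(y == c)), c, rng=rng)[0] for c in (0, 1)]
        report = quality_gate(X, np.vstack(parts), seed=1)
        assert report.passed
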