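"""Masked autoregressive flow: exact density algebra, autoregressive
masking, invertibility, training behaviour and score calibration."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from wristgait._autodiff import Tensor
from wristgait.detectors.maf import (LOG2PI, MADELayer, MAFDetector, MAFModel,
                                     MAFTrainConfig, score_to_probability)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestMADELayer:
    def test_fresh_layer_is_identity(self, rng):
        lay = MADELayer(dim=5, rng=rng)
        x = rng.normal(size=(4, 5))
        u, logdet = lay.transform(Tensor(x))
        np.testing.assert_allclose(u.data, x, atol=1e-12)
        np.testing.assert_allclose(logdet.data, 0.0, atol=1e-12)

    def test_single_dimension_closed_form(self):
        lay = MADELayer(dim=1)
        lay.set_affine(np.array([1.0]), np.array([np.log(2.0)]))
        u, logdet = lay.transform(Tensor(np.array([[3.0]])))
        assert u.data[0, 0] == pytest.approx(1.0)
        assert logdet.data[0] == pytest.approx(-np.log(2.0))

    def test_autoregressive_masking(self, rng):
        """Perturbing x_j must leave u_i unchanged for all i with rank < j."""
        lay = MADELayer(dim=4, rng=rng)
        for p in lay.params():
            p.data += 0.3 * rng.normal(size=p.data.shape)
        x = rng.normal(size=(1, 4))
        u0, _ = lay.transform(Tensor(x))
        for j in range(4):
            xp = x.copy()
            xp[0, j] += 1e-4
            up, _ = lay.transform(Tensor(xp))
            changed = np.abs(up.data - u0.data)[0] > 1e-12
            ranks = lay.order
            assert not changed[ranks < ranks[j]].any()

    def test_inverse_roundtrip(self, rng):
        lay = MADELayer(dim=4, rng=rng)
        for p in lay.params():
            p.data += 0.2 * rng.normal(size=p.data.shape)
        x = rng.normal(size=(6, 4))
        u, _ = lay.transform(Tensor(x))
        np.testing.assert_allclose(lay.inverse(u.data), x, atol=1e-6)


class TestMAFModel:
    def test_identity_log_density_at_origin(self):
        for d in (1, 3, 8):
            m = MAFModel(dim=d)
            assert m.log_density(np.zeros((1, d)))[0] == pytest.approx(
                -(d / 2) * LOG2PI)

    def test_single_affine_layer_matches_gaussian(self):
        mu, s = 1.3, 2.0
        m = MAFModel(dim=1, n_layers=1)
        m.layers[0].set_affine(np.array([mu]), np.array([np.log(s)]))
        x = np.linspace(-5, 7, 41)[:, None]
        np.testing.assert_allclose(
            m.log_density(x), sp_stats.norm(mu, s).logpdf(x[:, 0]), atol=1e-8)

    def test_stacked_invertibility(self, rng):
        m = MAFModel(dim=4, n_layers=5, seed=3)
        for p in m.params():
            p.data += 0.1 * rng.normal(size=p.data.shape)
        x = rng.normal(size=(10, 4))
        u, _ = m.transform(Tensor(x))
        np.testing.assert_allclose(m.inverse(u.data), x, atol=1e-6)

    def test_logdet_matches_finite_difference_jacobian(self, rng):
        for d in (2, 4):
            m = MAFModel(dim=d, n_layers=3, seed=d)
            for p in m.params():
                p.data += 0.2 * rng.normal(size=p.data.shape)
            x = rng.normal(size=(1, d))
            u0, logdet = m.transform(Tensor(x))
            J = np.zeros((d, d))
            for j in range(d):
                xp = x.copy()
                xp[0, j] += 1e-6
                up, _ = m.transform(Tensor(xp))
                J[:, j] = (up.data - u0.data)[0] / 1e-6
            assert logdet.data[0] == pytest.approx(
                np.log(abs(np.linalg.det(J))), abs=1e-4)

    def test_density_integrates_to_one_1d(self, rng):
        data = rng.normal(0.5, 1.5, size=(400, 1))
        res = MAFDetector(data, MAFTrainConfig(epochs=15, l2=1e-4, seed=0)).fit()
        grid = np.linspace(-8, 9, 2001)[:, None]
        p = np.exp(res.model.log_density(grid))
        assert np.trapezoid(p, grid[:, 0]) == pytest.approx(1.0, abs=0.05)


class TestTraining:
    def test_seeded_training_reproducible(self, rng):
        data = rng.normal(size=(300, 3))
        cfg = MAFTrainConfig(epochs=5, seed=9)
        r1 = MAFDetector(data, cfg).fit()
        r2 = MAFDetector(data, cfg).fit()
        assert r1.history["train_nll"] == r2.history["train_nll"]

    def test_beats_single_gaussian_on_mixture(self, rng):
        data = np.concatenate([rng.normal([-2, 0], 0.5, size=(300, 2)),
                               rng.normal([2, 1], 0.5, size=(300, 2))])
        rng.shuffle(data)
        held = np.concatenate([rng.normal([-2, 0], 0.5, size=(200, 2)),
                               rng.normal([2, 1], 0.5, size=(200, 2))])
        res = MAFDetector(data, MAFTrainConfig(epochs=40, l2=1e-4,
                                               batch_size=128, seed=0)).fit()
        maf_ll = res.model.log_density(held).mean()
        gauss = sp_stats.multivariate_normal(data.mean(0), np.cov(data.T))
        assert maf_ll > gauss.logpdf(held).mean()

    def test_self_consistent_on_base_distribution(self, rng):
        """Standard-normal data carry no structure beyond the identity
        initialization, so training barely moves the loss."""
        data = rng.normal(size=(500, 4))
        res = MAFDetector(data, MAFTrainConfig(epochs=10, seed=1)).fit()
        first, best = res.history["train_nll"][0], min(res.history["train_nll"])
        assert first - best < 0.25

    def test_anomaly_score_is_negative_log_density(self, rng):
        data = rng.normal(size=(200, 2))
        res = MAFDetector(data, MAFTrainConfig(epochs=3, seed=2)).fit()
        x = rng.normal(size=(20, 2))
        np.testing.assert_allclose(res.anomaly_score(x),
                                   -res.model.log_density(x), atol=1e-12)

    def test_mode_scores_below_tail_scores(self, rng):
        data = rng.normal(5.0, 1.0, size=(400, 2))
        res = MAFDetector(data, MAFTrainConfig(epochs=20, seed=3)).fit()
        centre = res.anomaly_score(np.array([[5.0, 5.0]]))
        tail = res.anomaly_score(np.array([[15.0, -5.0]]))
        assert centre[0] < tail[0]


class TestScoreCalibration:
    def test_boundary_and_median(self):
        cal = np.arange(1.0, 102.0)  # median = 51
        assert score_to_probability(np.array([0.0]), cal)[0] == 1.0
        assert score_to_probability(np.array([51.0]), cal)[0] == pytest.approx(
            0.5, abs=0.005)

    def test_monotone_non_increasing_gait_trained(self, rng):
        cal = rng.normal(size=200)
        s = np.sort(rng.normal(size=300))
        p = score_to_probability(s, cal, "gait")
        assert np.all(np.diff(p) <= 1e-12)

    def test_non_gait_direction_is_complement(self, rng):
        cal = rng.normal(size=100)
        s = rng.normal(size=50)
        np.testing.assert_allclose(
            score_to_probability(s, cal, "gait")
            + score_to_probability(s, cal, "non_gait"), 1.0, atol=1e-12)

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            score_to_probability(np.array([1.0]), np.array([]))
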