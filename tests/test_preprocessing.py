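"""Signal conditioning: norm, activity gate, windowing, normalization, PCA
and subject-disjoint folds."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wristgait.io import AccelRecording
from wristgait.preprocessing import (activity_gate, apply_norm, apply_pca,
                                     bandpower_features, euclidean_norm,
                                     fit_norm_stats, fit_pca, inverse_norm,
                                     label_windows, make_folds,
                                     segment_windows)


class TestEuclideanNorm:
    @pytest.mark.parametrize("xyz,expected", [
        ((0.0, 0.0, 0.0), 0.0),
        ((3.0, 4.0, 0.0), 5.0),
        ((1.0, 1.0, 1.0), np.sqrt(3.0)),
    ])
    def test_closed_forms(self, xyz, expected):
        assert euclidean_norm(np.array([xyz]))[0] == pytest.approx(expected)

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            euclidean_norm(np.zeros((5, 2)))


def _gate_oracle(norm, fs, window_s=3.0, thr=0.1):
    block = int(round(window_s * fs))
    keep = np.ones(len(norm), dtype=bool)
    for s in range(0, len(norm), block):
        seg = norm[s : s + block]
        if len(seg) < 2 or seg.std() < thr:
            keep[s : s + block] = False
    return keep


class TestActivityGate:
    def test_constant_signal_all_removed(self):
        assert not activity_gate(np.full(300, 9.81), 25.0).any()

    def test_unit_sine_all_kept(self):
        t = np.arange(750) / 25.0
        assert activity_gate(9.81 + np.sin(2 * np.pi * t), 25.0).all()

    def test_piecewise_signal_matches_block_oracle(self, rng):
        t = np.arange(500) / 25.0
        norm = np.concatenate([np.full(250, 9.81),
                               9.81 + np.sin(2 * np.pi * 1.5 * t[:250])])
        norm += rng.normal(0, 0.01, 500)
        np.testing.assert_array_equal(activity_gate(norm, 25.0),
                                      _gate_oracle(norm, 25.0))


class TestSegmentWindows:
    def _rec(self, n, fs=25.0):
        acc = np.arange(n * 3, dtype=float).reshape(n, 3)
        return AccelRecording(acc=acc, fs=fs)

    def test_window_count_example(self):
        ws = segment_windows(self._rec(300), window_s=6.0, overlap=0.5)
        assert ws.window_len == 150 and ws.hop == 75 and ws.n_windows == 3

    def test_dc_removal_zeroes_constant_window(self):
        rec = AccelRecording(acc=np.full((200, 3), 5.0), fs=25.0)
        ws = segment_windows(rec, 6.0, 0.5, remove_dc=True)
        assert np.abs(ws.windows).max() < 1e-12

    def test_zero_overlap_tiles(self):
        ws = segment_windows(self._rec(450), 6.0, overlap=0.0)
        assert np.array_equal(ws.starts, [0, 150, 300])

    def test_too_short_recording(self):
        with pytest.raises(ValueError):
            segment_windows(self._rec(100), 6.0)

    @given(st.integers(150, 2000), st.sampled_from([0.0, 0.25, 0.5, 0.75]))
    def test_window_count_formula(self, n, overlap):
        ws = segment_windows(self._rec(n), 6.0, overlap, remove_dc=False)
        L, hop = ws.window_len, ws.hop
        assert ws.n_windows == (n - L) // hop + 1
        assert ws.starts[-1] + L <= n  # fully inside the recording
        if ws.n_windows > 1:
            assert np.all(np.diff(ws.starts) == hop)


class TestLabelWindows:
    def test_majority_rule(self):
        rec = AccelRecording(acc=np.zeros((300, 3)), fs=25.0)
        ws = segment_windows(rec, 6.0, 0.5, remove_dc=False)
        mask = np.zeros(300, dtype=int)
        mask[:80] = 1  # first window: 80/150 gait
        labelled = label_windows(ws, mask)
        assert labelled.labels[0] == 1
        mask[:] = 0
        mask[:70] = 1  # 70/150: not a strict majority
        assert label_windows(ws, mask).labels[0] == 0

    def test_full_and_empty_windows(self):
        rec = AccelRecording(acc=np.zeros((300, 3)), fs=25.0)
        ws = segment_windows(rec, 6.0, 0.5, remove_dc=False)
        mask = np.zeros(300, dtype=int)
        mask[:150] = 1
        lab = label_windows(ws, mask).labels
        assert lab[0] == 1 and lab[-1] == 0

    def test_missing_mask(self):
        rec = AccelRecording(acc=np.zeros((300, 3)), fs=25.0)
        ws = segment_windows(rec, 6.0)
        with pytest.raises(ValueError):
            label_windows(ws, None)


class TestNormalization:
    def test_train_mean_zero_sd_one(self, rng):
        x = rng.normal(3.0, 2.5, size=(500, 8))
        stats = fit_norm_stats(x)
        z = apply_norm(x, stats)
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0) - 1).max() < 1e-9

    def test_test_transform_elementwise(self, rng):
        x = rng.normal(size=(100, 4))
        stats = fit_norm_stats(x)
        y = rng.normal(size=(10, 4))
        np.testing.assert_allclose(apply_norm(y, stats),
                                   (y - x.mean(0)) / x.std(0), atol=1e-12)

    def test_constant_feature_dropped_with_warning(self, rng):
        x = rng.normal(size=(50, 3))
        x[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            stats = fit_norm_stats(x)
        assert apply_norm(x, stats).shape == (50, 2)

    def test_inverse_identity(self, rng):
        x = rng.normal(size=(60, 5))
        stats = fit_norm_stats(x)
        np.testing.assert_allclose(inverse_norm(apply_norm(x, stats), stats),
                                   x, atol=1e-9)


class TestPCA:
    def test_exact_low_rank_recovery(self, rng):
        basis = rng.normal(size=(2, 6))
        x = rng.normal(size=(200, 2)) @ basis + 5.0
        proj = fit_pca(x, 2)
        z = apply_pca(x, proj)
        recon = z @ proj.components + proj.mean
        assert np.abs(recon - x).max() < 1e-9

    def test_explained_variance_non_increasing(self, rng):
        proj = fit_pca(rng.normal(size=(100, 5)), 5)
        assert np.all(np.diff(proj.explained_variance) <= 1e-12)

    def test_projected_covariance_matches_eigenvalues(self, rng):
        x = rng.normal(size=(400, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        proj = fit_pca(x, 4)
        z = apply_pca(x, proj)
        cov = np.cov(z.T)
        np.testing.assert_allclose(np.diag(cov), proj.explained_variance,
                                   rtol=1e-8)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-9

    def test_excess_components_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(10, 3)), 4)


class TestBandpowerFeatures:
    def test_total_power_is_parseval_consistent(self, rng):
        w = rng.normal(size=(5, 3, 150))
        w -= w.mean(axis=2, keepdims=True)
        f = bandpower_features(w, 25.0, n_bands=12)
        # sum of band powers (before log) equals total rfft power
        tot = np.exp(f).sum(axis=1)
        ref = (np.abs(np.fft.rfft(w, axis=2)) ** 2).sum(axis=(1, 2))
        np.testing.assert_allclose(tot, ref, rtol=1e-6)

    def test_shift_invariance_for_periodic_windows(self):
        t = np.arange(150) / 25.0
        w1 = np.stack([np.sin(2 * np.pi * 1.5 * t)] * 3)[None]
        w2 = np.stack([np.sin(2 * np.pi * 1.5 * t + 1.1)] * 3)[None]
        f1 = bandpower_features(w1, 25.0)
        f2 = bandpower_features(w2, 25.0)
        assert np.abs(f1 - f2).max() < 0.2


class TestFolds:
    def test_balanced_disjoint_partition(self):
        subj = [f"s{i}" for i in range(10)]
        split = make_folds(subj, k=5, seed=0)
        sizes = [sum(1 for v in split.assignment.values() if v == f)
                 for f in range(5)]
        assert sizes == [2] * 5
        assert set(split.assignment) == set(subj)

    def test_seed_reproducibility(self):
        subj = [f"s{i}" for i in range(7)]
        a = make_folds(subj, k=3, seed=4).assignment
        b = make_folds(subj, k=3, seed=4).assignment
        assert a == b

    def test_union_and_intersections(self):
        subj = [f"s{i}" for i in range(9)]
        split = make_folds(subj, k=4, seed=1)
        folds = [set(s for s, f in split.assignment.items() if f == i)
                 for i in range(4)]
        assert set().union(*folds) == set(subj)
        for i in range(4):
            for j in range(i + 1, 4):
                assert not folds[i] & folds[j]

    def test_gait_percentage_balancing(self):
        subj = [f"s{i}" for i in range(10)]
        pct = {s: float(i) for i, s in enumerate(subj)}
        split = make_folds(subj, k=5, seed=0, gait_pct=pct)
        vals = list(split.fold_gait_pct.values())
        assert max(vals) - min(vals) <= 5.0  # greedy keeps folds close

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=3)
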