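"""Gait quantity (daily minutes, wear-day rule) and quality (spectral and
regularity) measures."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from wristgait.io import AccelRecording
from wristgait.measures import (GaitQualityRecord, aggregate_quality,
                                bout_quality, daily_walking_minutes,
                                pearson_r, quality_agreement,
                                quality_from_recording)

FS = 25.0
G = 9.80665


def sine_bout(freq, amp, duration_s, fs=FS, noise=0.0, rng=None):
    """Tri-axial bout whose norm is gravity + a pure sine along one axis."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    acc = np.zeros((n, 3))
    acc[:, 2] = G + amp * np.sin(2 * np.pi * freq * t)
    if noise and rng is not None:
        acc += rng.normal(0, noise, (n, 3))
    return acc


class TestDailyWalkingMinutes:
    def _rec(self, hours_per_day, days=1, fs=1.0):
        n = int(sum(hours_per_day[:days]) * 3600 * fs)
        rec = AccelRecording(acc=np.zeros((n, 3)), fs=fs,
                             t0=datetime(2021, 3, 1, 0, 0))
        return rec

    def test_thirty_minutes_on_nine_hour_day(self):
        fs = 1.0
        rec = self._rec([9], fs=fs)
        pred = np.zeros(rec.n_samples, dtype=int)
        pred[: int(30 * 60 * fs)] = 1
        out = daily_walking_minutes(rec, pred)
        assert len(out) == 1
        assert out[0].walking_minutes_predicted == pytest.approx(30.0)

    def test_seven_hour_day_excluded(self):
        rec = self._rec([7])
        out = daily_walking_minutes(rec, np.ones(rec.n_samples, dtype=int))
        assert out == []

    def test_minutes_match_sample_count(self, rng):
        fs = 2.0
        n = int(10 * 3600 * fs)
        rec = AccelRecording(acc=np.zeros((n, 3)), fs=fs,
                             t0=datetime(2021, 3, 1))
        pred = (rng.random(n) < 0.1).astype(int)
        out = daily_walking_minutes(rec, pred)
        assert out[0].walking_minutes_predicted == pytest.approx(
            pred.sum() / fs / 60.0)

    def test_reference_minutes_from_mask(self):
        fs = 1.0
        n = int(9 * 3600 * fs)
        mask = np.zeros(n, dtype=int)
        mask[: 600] = 1
        rec = AccelRecording(acc=np.zeros((n, 3)), fs=fs, mask=mask,
                             t0=datetime(2021, 3, 1))
        out = daily_walking_minutes(rec, mask)
        assert out[0].walking_minutes_reference == pytest.approx(10.0)


class TestPearson:
    def test_identity_and_affine(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_fixed_table_matches_formula(self):
        x = np.array([1.0, 2, 4, 4, 5, 7, 8, 8, 9, 12])
        y = np.array([2.1, 3.0, 3.9, 5.2, 5.0, 7.5, 7.7, 9.0, 8.6, 12.2])
        r, _ = pearson_r(x, y)
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        assert r == pytest.approx(cov / (x.std() * y.std()), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestBoutQuality:
    def test_pure_sine_closed_forms(self):
        amp, freq = 2.0, 1.25  # exact integer cycles over 20 s at 25 Hz
        q = bout_quality(sine_bout(freq, amp, 20.0), FS)
        assert q.rms == pytest.approx(amp / np.sqrt(2), abs=1e-6)
        assert abs(q.dominant_frequency - freq) <= 0.25 + 1e-9  # one Welch bin
        assert q.stride_regularity > 0.95

    def test_white_noise_low_regularity(self, rng):
        vals = []
        for i in range(5):
            acc = rng.normal(0, 1.0, (750, 3))
            acc[:, 2] += G
            vals.append(bout_quality(acc, FS).stride_regularity)
        assert np.abs(vals).max() < 0.2

    def test_two_interleaved_sines_dominant_is_stronger(self):
        n = int(30 * FS)
        t = np.arange(n) / FS
        acc = np.zeros((n, 3))
        acc[:, 2] = (G + 1.05 * np.sin(2 * np.pi * 1.0 * t)
                     + 1.0 * np.sin(2 * np.pi * 1.4 * t))
        q = bout_quality(acc, FS)
        assert q.dominant_frequency == pytest.approx(1.0, abs=0.25)

    def test_short_bout_rejected(self):
        with pytest.raises(ValueError):
            bout_quality(sine_bout(1.2, 1.0, 8.0), FS)

    def test_quality_bout_filter(self):
        """Bouts are rebuilt from the mask: >= 6 s detection rule, then only
        > 10 s bouts yield quality records."""
        n = int(60 * FS)
        t = np.arange(n) / FS
        acc = np.zeros((n, 3))
        acc[:, 2] = G + 2.0 * np.sin(2 * np.pi * 1.2 * t)
        rec = AccelRecording(acc=acc, fs=FS)
        pred = np.zeros(n, dtype=int)
        pred[0 : int(8 * FS)] = 1          # 8 s: detected but too short
        pred[int(20 * FS) : int(35 * FS)] = 1  # 15 s: qualifies
        pred[int(50 * FS) : int(54 * FS)] = 1  # 4 s: dropped by 6 s rule
        recs = quality_from_recording(rec, pred)
        assert len(recs) == 1
        assert recs[0].bout_duration_s == pytest.approx(15.0)


class TestAggregation:
    def _record(self, sid, date, **kw):
        base = dict(bout_id=0, bout_duration_s=12.0, dominant_frequency=1.0,
                    amplitude_dominant=0.5, rms=1.0, stride_regularity=0.5,
                    subject_id=sid, date=date)
        base.update(kw)
        return GaitQualityRecord(**base)

    def test_single_bout_passthrough(self):
        out = aggregate_quality([self._record("a", "d1", rms=2.5)])
        assert out["group"].loc["rms", "mean"] == pytest.approx(2.5)

    def test_median_of_odd_count(self):
        recs = [self._record("a", "d1", rms=v) for v in (1.0, 5.0, 2.0)]
        out = aggregate_quality(recs)
        assert out["daily"]["rms"].iloc[0] == pytest.approx(2.0)

    def test_matches_brute_force_groupby(self, rng):
        recs = []
        for s in ("a", "b"):
            for d in ("d1", "d2"):
                for _ in range(3):
                    recs.append(self._record(s, d, rms=float(rng.random())))
        out = aggregate_quality(recs)
        df = pd.DataFrame([vars(r) for r in recs])
        daily = df.groupby(["subject_id", "date"])["rms"].median()
        subject = daily.groupby("subject_id").median()
        assert out["group"].loc["rms", "mean"] == pytest.approx(subject.mean())
        assert out["group"].loc["rms", "sd"] == pytest.approx(
            subject.std(ddof=1))


class TestAgreement:
    @pytest.fixture
    def rng(self):
        # local generator: draws must not depend on test execution order
        return np.random.default_rng(99)

    def _daily(self, rng, n=50, copy=None):
        df = pd.DataFrame({
            "subject_id": ["s"] * n,
            "date": list(range(n)),
            "dominant_frequency": rng.random(n),
            "amplitude_dominant": rng.random(n),
            "rms": rng.random(n),
            "stride_regularity": rng.random(n),
        })
        return df

    def test_identical_values_r_one(self, rng):
        a = self._daily(rng)
        out = quality_agreement(a, a.copy())
        assert np.allclose(out["r"], 1.0)
        assert out["significant_bonferroni"].all()

    def test_independent_noise_not_significant(self, rng):
        a = self._daily(rng, n=100)
        b = self._daily(rng, n=100)
        b[["dominant_frequency", "amplitude_dominant", "rms",
           "stride_regularity"]] = rng.random((100, 4))
        out = quality_agreement(a, b)
        assert (np.abs(out["r"]) < 0.3).all()
        assert not out["significant_bonferroni"].any()

    def test_bonferroni_threshold_definition(self, rng):
        a = self._daily(rng)
        out = quality_agreement(a, a.copy(), alpha=0.05)
        # 4 measures tested: each compared against 0.05 / 4
        assert (out["p"] < 0.05 / 4).equals(out["significant_bonferroni"])

    def test_too_few_days(self, rng):
        a = self._daily(rng, n=2)
        with pytest.raises(ValueError):
            quality_agreement(a, a.copy())
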