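"""Seeded generator of labelled, multiday wrist-like accelerometer recordings.

The generator emulates the structure of daily-living wrist recordings that
the detectors rely on: rare quasi-periodic gait bouts inside long stretches
of low activity, sporadic aperiodic hand-activity bursts, constant gravity
along a fixed (random) sensor orientation, and cohort-level degradation of
gait amplitude and regularity.

Gait model
----------
Each bout is a sum of a fundamental at ``step_freq_hz`` plus two harmonics,
with cycle-level phase and amplitude jitter scaled by ``regularity`` (0 =
perfectly periodic), projected onto the three axes through a random fixed
orientation unit vector. Bout durations are log-normal with the configured
mean/SD, truncated at 6 s. Non-gait is gravity plus sensor noise with
Poisson-arriving band-limited activity bursts; the ``pd`` profile adds a
low-amplitude 4-6 Hz tremor component.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .io import G_TO_MS2, AccelRecording

__all__ = ["SimConfig", "simulate_recording", "simulate_cohort", "COHORT_PROFILES"]

#: Per-cohort default overrides: healthy young adults walk with larger,
#: more regular wrist acceleration; older adults and people with
#: parkinsonism show reduced amplitude and regularity, and the pd profile
#: adds a 4-6 Hz tremor band.
COHORT_PROFILES: dict[str, dict] = {
    "hya": {"gait_amp": 3.8, "regularity": 0.05, "tremor_amp": 0.0},
    "oa": {"gait_amp": 1.9, "regularity": 0.15, "tremor_amp": 0.0},
    "pd": {"gait_amp": 1.6, "regularity": 0.20, "tremor_amp": 0.3},
}


@dataclass
class SimConfig:
    """Configuration of one simulated recording (defaults: hya profile)."""

    fs: float = 25.0
    duration_s: float = 3600.0
    gait_fraction: float = 0.10
    bout_duration_mean_s: float = 19.5
    bout_duration_sd_s: float = 4.1
    min_bout_s: float = 6.0
    step_freq_hz: float = 1.5
    harmonic_weights: tuple[float, float] = (0.4, 0.2)
    gait_amp: float = 3.8
    regularity: float = 0.05
    nongait_burst_rate: float = 40.0  # bursts per hour
    nongait_burst_amp: float = 1.5
    nongait_burst_mean_s: float = 10.0
    noise_sd: float = 0.05
    tremor_amp: float = 0.0
    tremor_freq_hz: float = 5.0
    cohort_profile: str = "hya"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gait_fraction < 1:
            raise ValueError("gait_fraction must be in [0, 1)")
        if not 0.5 <= self.step_freq_hz <= 3.0:
            raise ValueError("step_freq_hz must lie in the 0.5-3 Hz locomotor band")
        for name in ("gait_amp", "nongait_burst_amp", "noise_sd", "tremor_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cohort_profile not in COHORT_PROFILES:
            raise ValueError(f"unknown cohort_profile {self.cohort_profile!r}")
        if self.gait_fraction > 0 and self.bout_duration_mean_s > self.duration_s:
            raise ValueError("mean bout duration exceeds recording duration")

    @classmethod
    def for_profile(cls, profile: str, **overrides) -> "SimConfig":
        base = dict(COHORT_PROFILES[profile], cohort_profile=profile)
        base.update(overrides)
        return cls(**base)


def _derive_seed(master: int, *tags) -> int:
    """Deterministic child seed below 2^31 from a master seed and tags."""
    h = hashlib.sha256(("|".join(map(str, (master, *tags)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _place_bouts(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Draw non-overlapping bout intervals until the target gait time is met."""
    n = int(round(cfg.duration_s * cfg.fs))
    target = cfg.gait_fraction * n
    if target <= 0:
        return []
    # log-normal parameterized from the desired mean/SD, truncated at min_bout_s
    m, s = cfg.bout_duration_mean_s, max(cfg.bout_duration_sd_s, 1e-6)
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    durations: list[int] = []
    total = 0.0
    while total < target:
        d = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if d < cfg.min_bout_s:
            continue
        d_n = int(round(d * cfg.fs))
        if total + d_n > n:  # never exceed the recording
            d_n = int(n - total)
            if d_n < cfg.min_bout_s * cfg.fs:
                break
        durations.append(d_n)
        total += d_n
    # spread bouts over the recording: partition free time into random gaps
    free = n - sum(durations)
    k = len(durations)
    if k == 0:
        return []
    w = rng.dirichlet(np.ones(k + 1))
    gaps = np.floor(w * free).astype(int)
    bouts = []
    pos = int(gaps[0])
    order = rng.permutation(k)
    for i, j in enumerate(order):
        d_n = durations[j]
        bouts.append((pos, pos + d_n))
        pos += d_n + int(gaps[i + 1])
    return bouts


def _gait_waveform(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic scalar gait signal of n samples."""
    t = np.arange(n) / cfg.fs
    # cycle-level phase jitter: random walk over cycles, interpolated to samples
    n_cycles = max(int(np.ceil(t[-1] * cfg.step_freq_hz)) + 2, 2)
    cycle_t = np.arange(n_cycles) / cfg.step_freq_hz
    phase_jit = np.cumsum(rng.normal(0.0, cfg.regularity, n_cycles))
    amp_jit = 1.0 + cfg.regularity * rng.normal(0.0, 1.0, n_cycles)
    phi = 2 * np.pi * cfg.step_freq_hz * t + np.interp(t, cycle_t, phase_jit)
    amp = cfg.gait_amp * np.clip(np.interp(t, cycle_t, amp_jit), 0.1, None)
    x = np.sin(phi)
    for h, w in enumerate(cfg.harmonic_weights, start=2):
        x = x + w * np.sin(h * phi + rng.uniform(0, 2 * np.pi))
    # taper edges so bouts ramp in/out over ~0.5 s
    ramp = min(int(0.5 * cfg.fs), max(n // 4, 1))
    env = np.ones(n)
    env[:ramp] = np.linspace(0, 1, ramp)
    env[-ramp:] = np.linspace(1, 0, ramp)
    return amp * env * x


def _bursts(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Aperiodic hand-activity bursts: band-limited noise envelopes."""
    out = np.zeros(n)
    hours = n / cfg.fs / 3600.0
    n_bursts = rng.poisson(cfg.nongait_burst_rate * hours)
    for _ in range(n_bursts):
        dur = int(max(cfg.fs, rng.exponential(cfg.nongait_burst_mean_s) * cfg.fs))
        start = rng.integers(0, max(n - dur, 1))
        seg = rng.normal(0.0, 1.0, dur)
        # smooth to concentrate power below ~5 Hz (hand movement scale)
        k = max(int(cfg.fs / 10), 1)
        seg = np.convolve(seg, np.ones(k) / k, mode="same")
        seg *= cfg.nongait_burst_amp / max(seg.std(), 1e-12)
        out[start : start + dur] += seg
    return out


def simulate_recording(
    cfg: SimConfig,
    subject_id: str = "S0",
    t0: Optional[datetime] = None,
    seed: Optional[int] = None,
) -> AccelRecording:
    """Generate one labelled recording. Fixed seed => bit-identical output."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = int(round(cfg.duration_s * cfg.fs))
    acc = rng.normal(0.0, cfg.noise_sd, (n, 3))
    # constant gravity along a random fixed orientation
    g_dir = rng.normal(size=3)
    g_dir /= np.linalg.norm(g_dir)
    acc += G_TO_MS2 * g_dir

    mask = np.zeros(n, dtype=np.int8)
    # arm swing rotates the sensor through the gravity field, so the gait
    # component is never orthogonal to gravity: draw a direction with a
    # guaranteed alignment |cos| in [0.4, 0.9]
    perp = rng.normal(size=3)
    perp -= (perp @ g_dir) * g_dir
    perp /= np.linalg.norm(perp)
    c = rng.uniform(0.4, 0.9) * rng.choice([-1.0, 1.0])
    gait_dir = c * g_dir + np.sqrt(1 - c**2) * perp
    for s, e in _place_bouts(cfg, rng):
        wav = _gait_waveform(e - s, cfg, rng)
        acc[s:e] += wav[:, None] * gait_dir
        mask[s:e] = 1

    burst = _bursts(n, cfg, rng)
    burst_dir = rng.normal(size=3)
    burst_dir /= np.linalg.norm(burst_dir)
    nz = mask == 0  # bursts model non-gait hand activity
    acc[nz] += burst[nz, None] * burst_dir

    if cfg.tremor_amp > 0:
        t = np.arange(n) / cfg.fs
        trem = cfg.tremor_amp * np.sin(
            2 * np.pi * (cfg.tremor_freq_hz + 0.5 * rng.standard_normal()) * t
        )
        trem_dir = rng.normal(size=3)
        trem_dir /= np.linalg.norm(trem_dir)
        acc += trem[:, None] * trem_dir

    kwargs = {} if t0 is None else {"t0": t0}
    return AccelRecording(
        acc=acc, fs=cfg.fs, subject_id=subject_id, wear_site="wrist",
        mask=mask, **kwargs,
    )


def simulate_cohort(
    n_subjects: int, cfg: SimConfig, days: int = 1
) -> list[AccelRecording]:
    """Generate ``n_subjects * days`` recordings (one per subject-day).

    Per-subject seeds derive deterministically from the master seed, so any
    subject's recordings can be regenerated independently of order.
    Per-subject jitter of step frequency and amplitude creates inter-subject
    variability.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    recs = []
    for i in range(n_subjects):
        sid = f"sub{i:02d}"
        srng = np.random.default_rng(_derive_seed(cfg.seed, "subject", i))
        step = float(np.clip(cfg.step_freq_hz + srng.normal(0, 0.15), 0.5, 3.0))
        amp = float(cfg.gait_amp * np.exp(srng.normal(0, 0.1)))
        sub_cfg = replace(cfg, step_freq_hz=step, gait_amp=amp)
        for d in range(days):
            recs.append(
                simulate_recording(
                    sub_cfg,
                    subject_id=sid,
                    t0=datetime(2000, 1, 1) + timedelta(days=d),
                    seed=_derive_seed(cfg.seed, "subject", i, "day", d),
                )
            )
    return recs
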