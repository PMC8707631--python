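"""Seeded generator of paired sEMG/force trials.

The sEMG model is amplitude-modulated, band-limited Gaussian noise: a
slowly varying activation envelope multiplies a zero-mean, unit-RMS
carrier restricted to the EMG band, with an optional 50 Hz mains line
added on top.  The envelope RMS rises from ``A_rest`` (0.2 mV) at rest
to ``A_mvc`` (0.6 mV) at maximal effort; the triceps channel is a
low-gain co-contraction copy of the biceps activation.  Force follows a
mild power law of activation with additive Gaussian noise, clamped at
zero.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .records import CHANNELS, EMGRecording

PATTERNS = ("trapezoid", "ramp", "hold")


@dataclass
class SynthConfig:
    """Knobs of the synthetic trial generator (all config-exposed)."""

    fs: float = 1000.0
    duration_s: float = 10.0
    A_rest: float = 0.2          # envelope RMS at rest, mV
    A_mvc: float = 0.6           # envelope RMS at maximal effort, mV
    cocontraction: float = 0.15  # triceps activation gain relative to biceps
    F_max: float = 30.0          # force at full activation, N
    force_noise_sd: float = 0.5  # additive force noise, N
    mains_amp: float = 0.05      # 50 Hz interference amplitude, mV
    emg_band: tuple[float, float] = (20.0, 450.0)
    nonlinearity_p: float = 1.2  # force = F_max * a**p
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.A_mvc > self.A_rest > 0):
            raise ValueError("need A_mvc > A_rest > 0")
        if not (0.0 <= self.cocontraction <= 1.0):
            raise ValueError("cocontraction must lie in [0, 1]")
        if self.F_max <= 0:
            raise ValueError("F_max must be positive")
        low, high = self.emg_band
        if not (0 < low < high):
            raise ValueError(f"invalid emg_band {self.emg_band}")
        if self.fs <= 2 * high:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for emg_band upper edge {high} Hz"
            )


@dataclass
class ActivationProfile:
    """Unitless activation trajectory on a uniform time grid."""

    time: np.ndarray      # seconds
    a: np.ndarray         # activation in [0, 1]
    pattern: str

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.time.shape != self.a.shape:
            raise ValueError("time and activation grids differ in length")
        if self.a.size and (self.a.min() < 0 or self.a.max() > 1):
            raise ValueError("activation must lie in [0, 1]")


def activation_profile(config: SynthConfig, pattern: str = "trapezoid") -> ActivationProfile:
    """Build an effort trajectory from rest to maximal output and back.

    ``trapezoid`` rises linearly over the first 40% of the trial, holds
    at 1.0 for 20%, and falls linearly over the last 40%.  ``ramp`` is a
    linear 0 -> 1 rise across the whole trial; ``hold`` sits at 1.0.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown activation pattern {pattern!r}; choose from {PATTERNS}")
    if config.duration_s < 1:
        raise ValueError("duration_s must be at least 1 s")
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    T = config.duration_s
    if pattern == "trapezoid":
        rise, hold = 0.4 * T, 0.2 * T
        a = np.where(
            t < rise,
            t / rise,
            np.where(t < rise + hold, 1.0, (T - t) / rise),
        )
    elif pattern == "ramp":
        a = t / T
    else:  # hold
        a = np.ones_like(t)
    return ActivationProfile(time=t, a=np.clip(a, 0.0, 1.0), pattern=pattern)


def _bandlimited_unit_noise(n: int, fs: float, band: tuple[float, float],
                            rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian noise band-limited to ``band`` and rescaled to unit RMS."""
    low, high = band
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    w = sps.sosfilt(sos, rng.standard_normal(n))
    w -= w.mean()
    rms = np.sqrt(np.mean(w**2))
    if rms == 0:
        raise RuntimeError("degenerate carrier noise")
    return w / rms


def synth_emg(profile: ActivationProfile, channel: str, config: SynthConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Generate one sEMG channel (mV) for the given activation profile.

    The signal is ``envelope(t) * w(t) + mains`` where ``envelope`` maps
    channel activation affinely from ``A_rest`` to ``A_mvc``, ``w`` is the
    unit-RMS band-limited carrier, and ``mains`` is a 50 Hz sine.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; choose from {CHANNELS}")
    a_ch = profile.a if channel == "biceps" else config.cocontraction * profile.a
    envelope = config.A_rest + (config.A_mvc - config.A_rest) * a_ch
    w = _bandlimited_unit_noise(profile.a.size, config.fs, config.emg_band, rng)
    mains = config.mains_amp * np.sin(2 * np.pi * 50.0 * profile.time)
    return envelope * w + mains


def synth_force(profile: ActivationProfile, config: SynthConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Ground-truth force label: power law of activation plus noise, clamped at 0."""
    clean = config.F_max * profile.a ** config.nonlinearity_p
    noise = config.force_noise_sd * rng.standard_normal(profile.a.size)
    return np.maximum(clean + noise, 0.0)


def make_trial(config: SynthConfig, seed: int, pattern: str = "trapezoid",
               meta: dict | None = None) -> EMGRecording:
    """Generate a single paired two-channel sEMG + force recording."""
    rng = np.random.default_rng(seed)
    profile = activation_profile(config, pattern)
    channels = {ch: synth_emg(profile, ch, config, rng) for ch in CHANNELS}
    force = synth_force(profile, config, rng)
    info = {"seed": seed, "pattern": pattern}
    info.update(meta or {})
    return EMGRecording(fs=config.fs, channels=channels, force=force, meta=info)


def make_dataset(n_trials: int = 5, config: SynthConfig | None = None,
                 pattern: str = "trapezoid") -> list[EMGRecording]:
    """Generate ``n_trials`` recordings with per-trial seeds derived from the master seed.

    Trial ``k`` uses seed ``config.seed + k`` so any single trial can be
    regenerated in isolation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    config = config or SynthConfig()
    return [
        make_trial(config, seed=config.seed + k, pattern=pattern, meta={"trial": k})
        for k in range(n_trials)
    ]


def save_dataset(recordings: list[EMGRecording], out_dir, config: SynthConfig | None = None,
                 prefix: str = "trial") -> list[Path]:
    """Write one CSV per trial plus a JSON sidecar echoing the generator config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, rec in enumerate(recordings):
        p = out_dir / f"{prefix}_{k:02d}.csv"
        rec.to_csv(p)
        paths.append(p)
    if config is not None:
        sidecar = out_dir / f"{prefix}_config.json"
        sidecar.write_text(json.dumps(asdict(config), indent=2, sort_keys=True) + "\n")
    return paths


def load_dataset(data_dir, prefix: str = "trial") -> list[EMGRecording]:
    data_dir = Path(data_dir)
    paths = sorted(data_dir.glob(f"{prefix}_[0-9]*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trial CSVs matching {prefix}_NN.csv under {data_dir}")
    return [EMGRecording.from_csv(p, meta={"path": str(p), "trial": k})
            for k, p in enumerate(paths)]
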