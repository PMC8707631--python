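"""sEMG conditioning chain.

Stages, in order: DC offset removal, 50 Hz notch, 4th-order Butterworth
band-pass (10-500 Hz nominal), full-wave rectification, and MVC
normalization.  Filtering is causal by default to honor real-time
semantics; a zero-phase mode is available for offline analysis.

The nominal 500 Hz upper edge equals the Nyquist frequency at the 1000 Hz
sampling rate and is unrealizable in a digital design, so the high edge is
clamped to ``0.99 * fs / 2`` (495 Hz at 1000 Hz) when necessary; the
clamping is reported through the :mod:`logging` machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import EMGRecording

logger = logging.getLogger(__name__)

NYQUIST_CLAMP = 0.99  # fraction of Nyquist the band-pass high edge is clamped to


@dataclass
class FilterSpec:
    notch_hz: float = 50.0
    notch_q: float = 30.0
    bp_order: int = 4
    bp_low: float = 10.0
    bp_high: float = 500.0
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.bp_order % 2 != 0 or self.bp_order < 2:
            raise ValueError("bp_order must be a positive even integer")
        if not (0 < self.bp_low < self.bp_high):
            raise ValueError("need 0 < bp_low < bp_high")

    def effective_high(self, fs: float) -> float:
        """Band-pass high edge after clamping below Nyquist."""
        nyq = fs / 2.0
        if self.bp_high >= nyq:
            clamped = NYQUIST_CLAMP * nyq
            logger.info(
                "band-pass high edge %.1f Hz >= Nyquist %.1f Hz; clamped to %.1f Hz",
                self.bp_high, nyq, clamped,
            )
            return clamped
        return self.bp_high


@dataclass
class ProcessedEMG:
    """Outputs of the conditioning chain for one recording.

    ``filtered`` is the band-limited signed signal, ``rectified`` its
    absolute value, ``scaled`` the MVC-scaled signed signal fed to feature
    extraction, and ``normalized`` the rectified envelope mapped to [0, 1].
    """

    fs: float
    filtered: dict[str, np.ndarray]
    rectified: dict[str, np.ndarray]
    scaled: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    mvc: dict[str, float]
    force: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def remove_dc(signal: np.ndarray) -> np.ndarray:
    """Subtract the series mean (DC offset)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise ValueError("need at least 2 samples to remove a DC offset")
    return signal - signal.mean()


def notch_50hz(signal: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Second-order IIR notch at the mains frequency (50 Hz, Q = 30 default)."""
    spec = spec or FilterSpec()
    if fs <= 2 * spec.notch_hz:
        raise ValueError(f"fs={fs} too low for a {spec.notch_hz} Hz notch")
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    if spec.zero_phase:
        return sps.filtfilt(b, a, signal)
    return sps.lfilter(b, a, signal)


def _bandpass_sos(fs: float, spec: FilterSpec) -> np.ndarray:
    high = spec.effective_high(fs)
    if not (0 < spec.bp_low < high < fs / 2):
        raise ValueError(
            f"band edges ({spec.bp_low}, {high}) invalid for fs={fs}"
        )
    # scipy's N is the per-section prototype order; a band-pass doubles it,
    # so N = bp_order/2 yields the stated overall transfer-function order.
    return sps.butter(spec.bp_order // 2, [spec.bp_low, high],
                      btype="bandpass", fs=fs, output="sos")


def butterworth_bandpass(signal: np.ndarray, fs: float,
                         spec: FilterSpec | None = None) -> np.ndarray:
    """Butterworth band-pass of the stated overall order (default 4th, 10-495 Hz)."""
    spec = spec or FilterSpec()
    sos = _bandpass_sos(fs, spec)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, signal)
    return sps.sosfilt(sos, signal)


def bandpass_response(fs: float, freqs, spec: FilterSpec | None = None) -> np.ndarray:
    """Magnitude response of the band-pass design at ``freqs`` (Hz)."""
    spec = spec or FilterSpec()
    _, h = sps.sosfreqz(_bandpass_sos(fs, spec), worN=np.atleast_1d(freqs), fs=fs)
    return np.abs(h)


def notch_response(fs: float, freqs, spec: FilterSpec | None = None) -> np.ndarray:
    """Magnitude response of the notch design at ``freqs`` (Hz)."""
    spec = spec or FilterSpec()
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    _, h = sps.freqz(b, a, worN=np.atleast_1d(freqs), fs=fs)
    return np.abs(h)


def full_wave_rectify(signal: np.ndarray) -> np.ndarray:
    """Elementwise absolute value."""
    return np.abs(np.asarray(signal, dtype=float))


def filter_chain(signal: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """DC removal -> notch -> band-pass, in that order."""
    spec = spec or FilterSpec()
    return butterworth_bandpass(notch_50hz(remove_dc(signal), fs, spec), fs, spec)


def moving_average(signal: np.ndarray, fs: float, win_s: float = 0.2) -> np.ndarray:
    """Causal boxcar smoother; output sample i averages the last ``win_s`` seconds."""
    k = max(int(round(win_s * fs)), 1)
    kernel = np.ones(k) / k
    return np.convolve(np.asarray(signal, dtype=float), kernel, mode="full")[: len(signal)]


def compute_mvc(recording: EMGRecording, channel: str,
                spec: FilterSpec | None = None, prefiltered: bool = False) -> float:
    """MVC reference: peak of the smoothed rectified envelope of one channel.

    The channel is run through the filter chain (unless ``prefiltered``),
    rectified, smoothed with a 0.2 s moving average, and the maximum taken.
    """
    if channel not in recording.channels:
        raise KeyError(f"channel {channel!r} not in recording")
    x = recording.channels[channel]
    if not np.any(x):
        raise ValueError(f"channel {channel!r} is all zeros; MVC undefined")
    if not prefiltered:
        x = filter_chain(x, recording.fs, spec)
    envelope = moving_average(full_wave_rectify(x), recording.fs, 0.2)
    mvc = float(envelope.max())
    if mvc <= 0:
        raise ValueError(f"MVC for channel {channel!r} is non-positive")
    return mvc


def mvc_normalize(signal: np.ndarray, mvc: float, clip: bool = True) -> np.ndarray:
    """Scale by the MVC reference; clamp to [0, 1] unless ``clip`` is False."""
    if mvc <= 0:
        raise ValueError(f"mvc must be positive, got {mvc}")
    scaled = np.asarray(signal, dtype=float) / mvc
    return np.clip(scaled, 0.0, 1.0) if clip else scaled


def preprocess_chain(recording: EMGRecording, spec: FilterSpec | None = None,
                     mvc_map: dict[str, float] | None = None) -> ProcessedEMG:
    """Run the full conditioning chain over every channel of a recording.

    When ``mvc_map`` is omitted the MVC reference is computed from the
    recording itself (it must then contain a maximal-effort segment).
    """
    spec = spec or FilterSpec()
    if mvc_map is None:
        mvc_map = {ch: compute_mvc(recording, ch, spec) for ch in recording.channels}
    missing = set(recording.channels) - set(mvc_map)
    if missing:
        raise KeyError(f"no MVC reference for channels {sorted(missing)}")
    filtered, rectified, scaled, normalized = {}, {}, {}, {}
    for ch, raw in recording.channels.items():
        f = filter_chain(raw, recording.fs, spec)
        filtered[ch] = f
        rectified[ch] = full_wave_rectify(f)
        scaled[ch] = mvc_normalize(f, mvc_map[ch], clip=False)
        normalized[ch] = mvc_normalize(rectified[ch], mvc_map[ch], clip=True)
    return ProcessedEMG(
        fs=recording.fs,
        filtered=filtered,
        rectified=rectified,
        scaled=scaled,
        normalized=normalized,
        mvc={ch: float(m) for ch, m in mvc_map.items()},
        force=recording.force,
        meta=dict(recording.meta),
    )
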