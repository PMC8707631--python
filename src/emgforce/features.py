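"""Sliding-window time-domain feature extraction.

Four features per channel and window: mean absolute value (MAV), root
mean square (RMS), difference absolute standard deviation value (DASDV),
and waveform length (WL).  With two channels the per-window input vector
has eight entries, in the frozen ordering ``biceps[MAV, RMS, DASDV, WL]``
then ``triceps[MAV, RMS, DASDV, WL]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ProcessedEMG

FEATURE_NAMES = ("mav", "rms", "dasdv", "wl")
CHANNEL_ORDER = ("biceps", "triceps")
#: Column ordering of the 8-dimensional input vector.
FEATURE_COLUMNS = tuple(f"{ch[0]}_{f}" for ch in CHANNEL_ORDER for f in FEATURE_NAMES)


@dataclass
class WindowSpec:
    win_s: float = 0.2
    step_s: float = 0.1
    alignment: str = "window-end"

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.win_s):
            raise ValueError("need 0 < step_s <= win_s")

    def sizes(self, fs: float) -> tuple[int, int]:
        win = int(round(self.win_s * fs))
        step = int(round(self.step_s * fs))
        if win < 2:
            raise ValueError(f"window of {win} samples is too short")
        if step < 1:
            raise ValueError("step shorter than one sample")
        return win, step


@dataclass
class FeatureSeries:
    """Per-window feature matrix with aligned force labels.

    ``t`` holds window-end timestamps (causal convention), ``X`` the
    (n_windows, 8) feature matrix in :data:`FEATURE_COLUMNS` order and
    ``y`` the per-window force label (window mean, N).
    """

    t: np.ndarray
    X: np.ndarray
    y: np.ndarray
    meta: dict | None = None

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.X) == len(self.y)):
            raise ValueError("t, X and y must agree in window count")

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_COLUMNS))
        df.insert(0, "t_s", self.t)
        df["force_n"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def sliding_windows(signal: np.ndarray, fs: float, spec: WindowSpec | None = None) -> np.ndarray:
    """Stack overlapping windows of ``win_s`` seconds advancing by ``step_s``.

    Returns an (n_windows, win_samples) view-backed array; a trailing
    partial window is discarded.
    """
    spec = spec or WindowSpec()
    signal = np.asarray(signal, dtype=float)
    win, step = spec.sizes(fs)
    if signal.size < win:
        raise ValueError(f"signal of {signal.size} samples is shorter than one "
                         f"{win}-sample window")
    view = np.lib.stride_tricks.sliding_window_view(signal, win)
    return view[::step]


def window_end_times(n_samples: int, fs: float, spec: WindowSpec | None = None) -> np.ndarray:
    spec = spec or WindowSpec()
    win, step = spec.sizes(fs)
    n_win = (n_samples - win) // step + 1
    ends = win + step * np.arange(n_win)
    return ends / fs


def mav(window: np.ndarray) -> float:
    """Mean absolute value: (1/n) * sum |x_i|."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(window)))


def rms(window: np.ndarray) -> float:
    """Root mean square: sqrt((1/n) * sum x_i^2)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(window**2)))


def dasdv(window: np.ndarray) -> float:
    """Difference absolute standard deviation: sqrt((1/(n-1)) * sum (x_{i+1}-x_i)^2)."""
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("DASDV needs at least 2 samples")
    d = np.diff(window)
    return float(np.sqrt(np.sum(d**2) / (window.size - 1)))


def wl(window: np.ndarray) -> float:
    """Waveform length: sum |x_{i+1} - x_i|."""
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("WL needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(window))))


def _features_of_windows(wins: np.ndarray) -> np.ndarray:
    """Vectorized (n_windows, 4) feature block for one channel."""
    n = wins.shape[1]
    d = np.diff(wins, axis=1)
    return np.column_stack([
        np.mean(np.abs(wins), axis=1),
        np.sqrt(np.mean(wins**2, axis=1)),
        np.sqrt(np.sum(d**2, axis=1) / (n - 1)),
        np.sum(np.abs(d), axis=1),
    ])


def feature_matrix(processed: ProcessedEMG, force: np.ndarray | None = None,
                   spec: WindowSpec | None = None, source: str = "scaled") -> FeatureSeries:
    """Assemble the 8-dimensional per-window input matrix with force labels.

    ``source`` selects the per-channel series features are computed on:
    ``"scaled"`` (MVC-scaled band-passed signal, default) or
    ``"normalized"`` (rectified envelope in [0, 1]).
    """
    spec = spec or WindowSpec()
    if source not in ("scaled", "normalized"):
        raise ValueError(f"unknown feature source {source!r}")
    series = getattr(processed, source)
    missing = [ch for ch in CHANNEL_ORDER if ch not in series]
    if missing:
        raise KeyError(f"processed recording is missing channels {missing}")
    if force is None:
        force = processed.force
    if force is None:
        raise ValueError("no force series available for labels")
    force = np.asarray(force, dtype=float)
    n = len(series[CHANNEL_ORDER[0]])
    if force.size != n:
        raise ValueError("force series is not synchronized with the sEMG channels")

    blocks = [_features_of_windows(sliding_windows(series[ch], processed.fs, spec))
              for ch in CHANNEL_ORDER]
    X = np.hstack(blocks)
    y = sliding_windows(force, processed.fs, spec).mean(axis=1)
    t = window_end_times(n, processed.fs, spec)
    return FeatureSeries(t=t, X=X, y=y, meta=dict(processed.meta))


def load_feature_csv(path) -> FeatureSeries:
    df = pd.read_csv(path)
    return FeatureSeries(
        t=df["t_s"].to_numpy(),
        X=df[list(FEATURE_COLUMNS)].to_numpy(),
        y=df["force_n"].to_numpy(),
    )
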