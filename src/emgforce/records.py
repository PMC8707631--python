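"""Core record types and columnar trial I/O.

A trial is a pair of synchronized series: two sEMG channels (biceps,
triceps; millivolts) and a fingertip force (newtons), all sampled on a
common uniform grid. Trials are stored as plain CSV with the columns
``time_s, biceps_mv, triceps_mv, force_n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS: tuple[str, str] = ("biceps", "triceps")

_CSV_COLUMNS = ["time_s", "biceps_mv", "triceps_mv", "force_n"]


@dataclass
class EMGRecording:
    """Raw multi-channel sEMG plus synchronized force.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    channels : dict of str -> ndarray
        Named sEMG series in mV; all series must share one length.
    force : ndarray
        Measured force in N, synchronized with the sEMG series.
    meta : dict
        Free-form trial metadata (subject, trial index, phase, seed).
    """

    fs: float
    channels: dict[str, np.ndarray]
    force: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("recording needs at least one sEMG channel")
        self.force = np.asarray(self.force, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        n = self.force.shape[0]
        for name, sig in self.channels.items():
            if sig.shape[0] != n:
                raise ValueError(
                    f"channel {name!r} has {sig.shape[0]} samples but force has {n}"
                )

    @property
    def n_samples(self) -> int:
        return self.force.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds (starts at 0)."""
        return np.arange(self.n_samples) / self.fs

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.t}
        for name in CHANNELS:
            if name not in self.channels:
                raise KeyError(f"recording is missing channel {name!r}")
            data[f"{name}_mv"] = self.channels[name]
        data["force_n"] = self.force
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path, fs: float | None = None, meta: dict | None = None) -> "EMGRecording":
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial CSV {path} is missing columns {missing}")
        if fs is None:
            dt = np.median(np.diff(df["time_s"].to_numpy()))
            if dt <= 0:
                raise ValueError("time_s column is not increasing; cannot infer fs")
            fs = 1.0 / dt
        return cls(
            fs=float(fs),
            channels={name: df[f"{name}_mv"].to_numpy() for name in CHANNELS},
            force=df["force_n"].to_numpy(),
            meta=dict(meta or {}),
        )
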