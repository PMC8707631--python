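"""Estimation and assist metrics: RMSE, squared correlation, per-trial summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TrialMetrics:
    trial_id: str
    rmse: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {"trial_id": self.trial_id, "rmse": self.rmse, "r2": self.r2, "n": self.n}


def rmse(est: np.ndarray, act: np.ndarray) -> float:
    """Root-mean-square error between estimated and actual series (N)."""
    est = np.asarray(est, dtype=float)
    act = np.asarray(act, dtype=float)
    if est.shape != act.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {act.shape}")
    if est.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean((est - act) ** 2)))


def r_squared(est: np.ndarray, act: np.ndarray) -> float:
    """Squared sample Pearson correlation between the two series.

    Reported both as a fraction and, times 100, as a percentage.
    """
    est = np.asarray(est, dtype=float)
    act = np.asarray(act, dtype=float)
    if est.shape != act.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {act.shape}")
    if est.size < 2:
        raise ValueError("need at least 2 samples")
    if np.std(est) == 0 or np.std(act) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    r = np.corrcoef(est, act)[0, 1]
    return float(r * r)


def bilateral_mae(f_health: np.ndarray, f_affected: np.ndarray) -> float:
    """Mean absolute bilateral force error |F_health - F_affected| (N)."""
    f_health = np.asarray(f_health, dtype=float)
    f_affected = np.asarray(f_affected, dtype=float)
    if f_health.shape != f_affected.shape:
        raise ValueError(f"length mismatch: {f_health.shape} vs {f_affected.shape}")
    if f_health.size == 0:
        raise ValueError("empty series")
    return float(np.mean(np.abs(f_health - f_affected)))


def summarize_trials(trials: list[tuple[np.ndarray, np.ndarray]],
                     ids: list[str] | None = None) -> dict:
    """Per-trial RMSE/R^2 plus mean/min/max aggregates over a trial list."""
    if not trials:
        raise ValueError("need at least one trial")
    ids = ids or [f"trial_{k:02d}" for k in range(len(trials))]
    per_trial = [
        TrialMetrics(trial_id=i, rmse=rmse(est, act), r2=r_squared(est, act), n=len(act))
        for i, (est, act) in zip(ids, trials)
    ]
    r2s = np.array([m.r2 for m in per_trial])
    rmses = np.array([m.rmse for m in per_trial])
    return {
        "trials": [m.to_dict() for m in per_trial],
        "r2": {"mean": float(r2s.mean()), "min": float(r2s.min()), "max": float(r2s.max())},
        "rmse": {"mean": float(rmses.mean()), "min": float(rmses.min()),
                 "max": float(rmses.max())},
    }
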