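"""Backpropagation force estimator (8-3-1 feedforward network).

The topology rule sets the hidden width to ``ceil(log2(n_inputs))`` (3
for the 8-dimensional multi-feature input).  Hidden units apply the
symmetric sigmoid ``2 / (1 + exp(-2 z)) - 1`` (algebraically tanh) to
``z = w_in . x - t``; the output neuron is linear, ``w_out . h + b_out``,
trained on min-max normalized features and targets.  Predictions are
anti-normalized back to newtons.

Training is full-batch gradient descent with momentum on the mean squared
error, with early stopping on a validation split; the weights of the best
validation epoch are returned.  All randomness flows from the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FEATURE_COLUMNS, FeatureSeries, WindowSpec, feature_matrix
from .preprocess import FilterSpec, preprocess_chain
from .records import EMGRecording

ACTIVATION = "tansig"


def hidden_size(n_input: int) -> int:
    """Hidden-layer width from the topology rule ceil(log2(n_input))."""
    if n_input < 2:
        raise ValueError("need at least 2 inputs")
    return math.ceil(math.log2(n_input))


def normalize_targets(force: np.ndarray, force_norm: tuple[float, float]) -> np.ndarray:
    """Affine map sending ``min -> 0`` and ``max -> 1``."""
    lo, hi = force_norm
    if hi <= lo:
        raise ValueError(f"degenerate target range ({lo}, {hi})")
    return (np.asarray(force, dtype=float) - lo) / (hi - lo)


def denormalize_targets(y: np.ndarray, force_norm: tuple[float, float]) -> np.ndarray:
    """Inverse of :func:`normalize_targets` (anti-normalization)."""
    lo, hi = force_norm
    if hi <= lo:
        raise ValueError(f"degenerate target range ({lo}, {hi})")
    return np.asarray(y, dtype=float) * (hi - lo) + lo


def _tansig(z: np.ndarray) -> np.ndarray:
    # symmetric sigmoid 2/(1+e^(-2z)) - 1; written in the expanded form
    return 2.0 / (1.0 + np.exp(-2.0 * z)) - 1.0


@dataclass
class TrainConfig:
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    lr: float = 0.05
    momentum: float = 0.9
    max_epochs: int = 2000
    patience: int = 200
    seed: int = 0
    tol: float = 1e-10

    def __post_init__(self) -> None:
        tr, va, te = self.split
        if tr <= 0 or va <= 0 or te < 0:
            raise ValueError("train and validation fractions must be positive")
        if abs(tr + va + te - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class BPNNModel:
    """Weights, thresholds and normalization constants of the estimator."""

    w_in: np.ndarray                  # (n_hidden, n_input)
    t: np.ndarray                     # (n_hidden,) hidden thresholds
    w_out: np.ndarray                 # (n_hidden,)
    b_out: float                      # output threshold
    feat_min: np.ndarray              # (n_input,)
    feat_max: np.ndarray              # (n_input,)
    force_norm: tuple[float, float]   # (min, max) in N
    feature_order: tuple[str, ...] = FEATURE_COLUMNS
    activation: str = ACTIVATION
    seed: int | None = None

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.feat_min = np.asarray(self.feat_min, dtype=float)
        self.feat_max = np.asarray(self.feat_max, dtype=float)
        n_hidden, n_input = self.w_in.shape
        if self.t.shape != (n_hidden,) or self.w_out.shape != (n_hidden,):
            raise ValueError("threshold/output-weight shapes inconsistent with w_in")
        if self.feat_min.shape != (n_input,) or self.feat_max.shape != (n_input,):
            raise ValueError("feature-normalization shapes inconsistent with w_in")
        if self.force_norm[1] <= self.force_norm[0]:
            raise ValueError("force_norm max must exceed min")

    @property
    def n_input(self) -> int:
        return self.w_in.shape[1]

    def normalize_features(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.feat_max > self.feat_min, self.feat_max - self.feat_min, 1.0)
        return (np.asarray(X, dtype=float) - self.feat_min) / span

    def _forward_normalized(self, Xn: np.ndarray) -> np.ndarray:
        h = _tansig(Xn @ self.w_in.T - self.t)
        return h @ self.w_out + self.b_out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Estimate force (N) for raw (un-normalized) feature rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_input:
            raise ValueError(f"expected {self.n_input} features, got {X.shape[1]}")
        return denormalize_targets(self._forward_normalized(self.normalize_features(X)),
                                   self.force_norm)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "activation": self.activation,
            "b_out": float(self.b_out),
            "feat_max": self.feat_max.tolist(),
            "feat_min": self.feat_min.tolist(),
            "feature_order": list(self.feature_order),
            "force_norm": [float(v) for v in self.force_norm],
            "seed": self.seed,
            "t": self.t.tolist(),
            "w_in": self.w_in.tolist(),
            "w_out": self.w_out.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "BPNNModel":
        try:
            return cls(
                w_in=np.array(d["w_in"], dtype=float),
                t=np.array(d["t"], dtype=float),
                w_out=np.array(d["w_out"], dtype=float),
                b_out=float(d["b_out"]),
                feat_min=np.array(d["feat_min"], dtype=float),
                feat_max=np.array(d["feat_max"], dtype=float),
                force_norm=(float(d["force_norm"][0]), float(d["force_norm"][1])),
                feature_order=tuple(d.get("feature_order", FEATURE_COLUMNS)),
                activation=d.get("activation", ACTIVATION),
                seed=d.get("seed"),
            )
        except (KeyError, TypeError, IndexError, ValueError) as exc:
            raise ValueError(f"corrupt model file: {exc}") from exc

    @classmethod
    def load(cls, path) -> "BPNNModel":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt model file {path}: {exc}") from exc
        return cls.from_dict(d)


def forward(model: BPNNModel, x: np.ndarray) -> float:
    """Single-vector force estimate (N); ``x`` is a raw 8-feature vector."""
    return float(model.predict(np.asarray(x, dtype=float).reshape(1, -1))[0])


def split_indices(n: int, split: tuple[float, float, float],
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled train/validation/test index partition of ``range(n)``."""
    perm = rng.permutation(n)
    n_tr = int(round(split[0] * n))
    n_va = int(round(split[1] * n))
    return perm[:n_tr], perm[n_tr:n_tr + n_va], perm[n_tr + n_va:]


@dataclass
class TrainReport:
    train_mse: float
    val_mse: float
    best_epoch: int
    epochs_run: int
    n_train: int
    n_val: int
    n_test: int
    trial_test_r2: list[float] = field(default_factory=list)
    trial_test_rmse: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_epoch": self.best_epoch,
            "epochs_run": self.epochs_run,
            "n_test": self.n_test,
            "n_train": self.n_train,
            "n_val": self.n_val,
            "train_mse": self.train_mse,
            "trial_test_r2": self.trial_test_r2,
            "trial_test_rmse": self.trial_test_rmse,
            "val_mse": self.val_mse,
        }


def _gradient_descent(Xtr: np.ndarray, ytr: np.ndarray, Xva: np.ndarray, yva: np.ndarray,
                      n_hidden: int, cfg: TrainConfig, rng: np.random.Generator):
    """Full-batch backprop with momentum and best-validation-epoch snapshot."""
    n_in = Xtr.shape[1]
    w_in = rng.uniform(-0.5, 0.5, size=(n_hidden, n_in))
    t = rng.uniform(-0.5, 0.5, size=n_hidden)
    w_out = rng.uniform(-0.5, 0.5, size=n_hidden)
    b_out = rng.uniform(-0.5, 0.5)
    vel = [np.zeros_like(w_in), np.zeros_like(t), np.zeros_like(w_out), 0.0]

    def val_mse() -> float:
        h = _tansig(Xva @ w_in.T - t)
        return float(np.mean((h @ w_out + b_out - yva) ** 2))

    best = (val_mse(), w_in.copy(), t.copy(), w_out.copy(), b_out, 0)
    last_train = np.inf
    n = len(ytr)
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        h = _tansig(Xtr @ w_in.T - t)
        yhat = h @ w_out + b_out
        err = yhat - ytr
        train_mse = float(np.mean(err**2))

        g_y = 2.0 * err / n
        g_wout = h.T @ g_y
        g_bout = float(g_y.sum())
        g_z = np.outer(g_y, w_out) * (1.0 - h**2)
        g_win = g_z.T @ Xtr
        g_t = -g_z.sum(axis=0)

        vel[0] = cfg.momentum * vel[0] - cfg.lr * g_win
        vel[1] = cfg.momentum * vel[1] - cfg.lr * g_t
        vel[2] = cfg.momentum * vel[2] - cfg.lr * g_wout
        vel[3] = cfg.momentum * vel[3] - cfg.lr * g_bout
        w_in += vel[0]
        t += vel[1]
        w_out += vel[2]
        b_out += vel[3]

        vm = val_mse()
        if vm < best[0]:
            best = (vm, w_in.copy(), t.copy(), w_out.copy(), b_out, epoch)
        elif epoch - best[5] >= cfg.patience:
            break
        if abs(last_train - train_mse) < cfg.tol:
            break
        last_train = train_mse
    return best, train_mse, epoch


def fit_trials(trials: list[FeatureSeries], cfg: TrainConfig | None = None,
               n_restarts: int = 3) -> tuple[BPNNModel, TrainReport]:
    """Train on a set of feature series with per-trial train/val/test splits.

    Each trial's windows are partitioned independently so every trial
    retains held-out test windows; the best of ``n_restarts`` seeded weight
    initializations (by validation MSE) is kept.
    """
    from .evaluation import r_squared, rmse as _rmse  # local import avoids a cycle

    cfg = cfg or TrainConfig()
    if not trials:
        raise ValueError("no trials given")
    rng = np.random.default_rng(cfg.seed)
    tr_parts, va_parts, te_parts = [], [], []
    for fs in trials:
        itr, iva, ite = split_indices(len(fs), cfg.split, rng)
        tr_parts.append((fs.X[itr], fs.y[itr]))
        va_parts.append((fs.X[iva], fs.y[iva]))
        te_parts.append((fs.X[ite], fs.y[ite]))
    Xtr = np.vstack([p[0] for p in tr_parts])
    ytr = np.concatenate([p[1] for p in tr_parts])
    Xva = np.vstack([p[0] for p in va_parts])
    yva = np.concatenate([p[1] for p in va_parts])
    if len(ytr) < 50:
        raise ValueError(f"need at least 50 training windows, got {len(ytr)}")
    if np.ptp(ytr) <= 0:
        raise ValueError("degenerate targets: zero range")

    feat_min, feat_max = Xtr.min(axis=0), Xtr.max(axis=0)
    force_norm = (float(ytr.min()), float(ytr.max()))
    span = np.where(feat_max > feat_min, feat_max - feat_min, 1.0)
    Xtr_n = (Xtr - feat_min) / span
    Xva_n = (Xva - feat_min) / span
    ytr_n = normalize_targets(ytr, force_norm)
    yva_n = normalize_targets(yva, force_norm)

    n_hidden = hidden_size(Xtr.shape[1])
    best_run = None
    for _ in range(max(n_restarts, 1)):
        best, train_mse, epochs = _gradient_descent(
            Xtr_n, ytr_n, Xva_n, yva_n, n_hidden, cfg, rng)
        if best_run is None or best[0] < best_run[0][0]:
            best_run = (best, train_mse, epochs)
    (val_best, w_in, t, w_out, b_out, best_epoch), train_mse, epochs = best_run

    model = BPNNModel(
        w_in=w_in, t=t, w_out=w_out, b_out=b_out,
        feat_min=feat_min, feat_max=feat_max, force_norm=force_norm,
        seed=cfg.seed,
    )
    trial_r2, trial_rmse = [], []
    for Xte, yte in te_parts:
        if len(yte) >= 2:
            est = model.predict(Xte)
            trial_r2.append(r_squared(est, yte))
            trial_rmse.append(_rmse(est, yte))
    report = TrainReport(
        train_mse=train_mse, val_mse=val_best, best_epoch=best_epoch,
        epochs_run=epochs, n_train=len(ytr), n_val=len(yva),
        n_test=sum(len(p[1]) for p in te_parts),
        trial_test_r2=trial_r2, trial_test_rmse=trial_rmse,
    )
    return model, report


def train(features: FeatureSeries, cfg: TrainConfig | None = None) -> BPNNModel:
    """Train on a single feature series (windows split train/val/test)."""
    model, _ = fit_trials([features], cfg)
    return model


@dataclass
class ValidationReport:
    r2: float
    rmse: float
    threshold: float
    accepted: bool
    n_windows: int

    def to_dict(self) -> dict:
        return {
            "accepted": bool(self.accepted),
            "n_windows": self.n_windows,
            "r2": self.r2,
            "rmse": self.rmse,
            "threshold": self.threshold,
        }


def validate_online(model: BPNNModel, recording: EMGRecording,
                    threshold: float = 0.90,
                    filter_spec: FilterSpec | None = None,
                    window_spec: WindowSpec | None = None,
                    mvc_map: dict[str, float] | None = None) -> ValidationReport:
    """Stream a fresh trial through the pipeline and gate on trial R^2.

    The recording is preprocessed, features are extracted window by
    window, the model predicts force, and the trial-level squared
    correlation and RMSE against the measured force decide acceptance.
    """
    from .evaluation import r_squared, rmse as _rmse

    processed = preprocess_chain(recording, filter_spec, mvc_map)
    feats = feature_matrix(processed, spec=window_spec)
    est = model.predict(feats.X)
    if np.std(est) == 0 or np.std(feats.y) == 0:
        r2 = 0.0
    else:
        r2 = r_squared(est, feats.y)
    report = ValidationReport(
        r2=r2, rmse=_rmse(est, feats.y), threshold=threshold,
        accepted=bool(r2 >= threshold), n_windows=len(feats),
    )
    return report
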