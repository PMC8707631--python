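"""Three-phase protocol orchestration.

Offline learning (train the estimator on recorded/synthetic trials),
online validation (gate the trained model on a fresh trial), and the
real-time assist phase (closed-loop force tracking with a simultaneous
participation-assessment overlay from the affected side's sEMG).

Each phase persists its artifact and refuses to run without its
predecessor's unless explicitly overridden.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .bpnn import BPNNModel, TrainReport, ValidationReport, fit_trials, validate_online
from .config import RunConfig
from .control import AssistSimResult, simulate_assist
from .evaluation import r_squared, rmse
from .features import feature_matrix
from .preprocess import moving_average, preprocess_chain
from .records import EMGRecording
from .synth import load_dataset, make_dataset, make_trial, save_dataset

logger = logging.getLogger(__name__)

#: Seed offsets so each phase draws fresh, reproducible trials from one master seed.
VALIDATION_SEED_OFFSET = 1000
ASSIST_SEED_OFFSET = 2000


def _log_run_header(cfg: RunConfig) -> None:
    logger.info("seeds: synth=%d train=%d", cfg.synth.seed, cfg.train.seed)
    nyq = cfg.synth.fs / 2
    if cfg.filter.bp_high >= nyq:
        logger.info("filter high edge %.0f Hz will be clamped below Nyquist %.0f Hz",
                    cfg.filter.bp_high, nyq)


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def trials_to_features(trials: list[EMGRecording], cfg: RunConfig):
    return [feature_matrix(preprocess_chain(rec, cfg.filter), spec=cfg.window)
            for rec in trials]


def offline_phase(cfg: RunConfig, out_dir, synthesize: bool = True
                  ) -> tuple[BPNNModel, TrainReport]:
    """Train the force estimator and persist model + training report."""
    _log_run_header(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = Path(cfg.data_dir)
    if data_dir.is_dir() and any(data_dir.glob("trial_[0-9]*.csv")):
        trials = load_dataset(data_dir)
        logger.info("loaded %d trials from %s", len(trials), data_dir)
    elif synthesize:
        trials = make_dataset(cfg.n_trials, cfg.synth)
        logger.info("synthesized %d trials (seed %d)", len(trials), cfg.synth.seed)
    else:
        raise FileNotFoundError(
            f"no trials under {data_dir} and synthesis disabled")
    feats = trials_to_features(trials, cfg)
    model, report = fit_trials(feats, cfg.train)
    model.save(out_dir / cfg.model_file)
    _write_json(out_dir / "training_report.json", report.to_dict())
    return model, report


def online_phase(cfg: RunConfig, model_path, out_dir,
                 recording: EMGRecording | None = None) -> ValidationReport:
    """Gate a trained model on a fresh trial; persist the accept/reject report."""
    model = BPNNModel.load(model_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if recording is None:
        recording = make_trial(cfg.synth, seed=cfg.synth.seed + VALIDATION_SEED_OFFSET,
                               meta={"phase": "online-validation"})
    report = validate_online(model, recording, threshold=cfg.accept_threshold,
                             filter_spec=cfg.filter, window_spec=cfg.window)
    # per-window estimates for downstream evaluation
    processed = preprocess_chain(recording, cfg.filter)
    feats = feature_matrix(processed, spec=cfg.window)
    est = model.predict(feats.X)
    import pandas as pd
    pd.DataFrame({"t_s": feats.t, "est_n": est, "act_n": feats.y}).to_csv(
        out_dir / "validation_estimates.csv", index=False, float_format="%.9g")
    _write_json(out_dir / "validation_report.json", report.to_dict())
    logger.info("online validation: r2=%.4f rmse=%.3f N -> %s",
                report.r2, report.rmse, "ACCEPT" if report.accepted else "REJECT")
    return report


def _require_validation(out_dir: Path, override: bool) -> None:
    rp = out_dir / "validation_report.json"
    if override:
        return
    if not rp.is_file():
        raise FileNotFoundError(
            f"no validation report at {rp}; run the online phase first "
            "(or pass the override flag)")
    if not json.loads(rp.read_text()).get("accepted", False):
        raise RuntimeError(
            "online validation rejected the model; retrain or override")


def assist_phase(cfg: RunConfig, model_path, out_dir,
                 override: bool = False) -> AssistSimResult:
    """Closed-loop assist simulation plus the estimation overlay.

    The healthy side's (synthetic) force, smoothed, is the tracking
    reference; the affected side contributes a human torque and its sEMG
    is streamed through the validated estimator to produce the
    participation-assessment overlay.  The overlay is produced even when
    the assist current is clamped to zero (assessment is decoupled from
    assist).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _require_validation(out_dir, override)
    model = BPNNModel.load(model_path)

    healthy = make_trial(cfg.synth, seed=cfg.synth.seed + ASSIST_SEED_OFFSET,
                         meta={"phase": "assist", "side": "healthy"})
    affected_cfg = cfg.synth
    affected = make_trial(affected_cfg, seed=cfg.synth.seed + ASSIST_SEED_OFFSET + 1,
                          meta={"phase": "assist", "side": "affected"})

    f_ref = moving_average(healthy.force, healthy.fs, 0.2)
    # resample onto the controller clock if it differs from the recording clock
    t_rec = healthy.t
    t_sim = np.arange(0, t_rec[-1] + cfg.gains.dt / 2, cfg.gains.dt)
    f_ref_sim = np.interp(t_sim, t_rec, f_ref)
    # affected side contributes only a fraction of its force (paresis stand-in)
    participation = 0.5
    tau_human = np.interp(t_sim, t_rec,
                          participation * moving_average(affected.force, affected.fs, 0.2)
                          ) * cfg.plant.lever_arm

    result = simulate_assist(f_ref_sim, tau_human, cfg.plant, cfg.gains)
    result.to_csv(out_dir / "assist_result.csv")

    processed = preprocess_chain(affected, cfg.filter)
    feats = feature_matrix(processed, spec=cfg.window)
    est = model.predict(feats.X)
    import pandas as pd
    pd.DataFrame({"t_s": feats.t, "est_active_force_n": est,
                  "true_force_n": feats.y}).to_csv(
        out_dir / "assist_overlay.csv", index=False, float_format="%.9g")
    _write_json(out_dir / "assist_summary.json", {
        "f_err_rms_n": float(np.sqrt(np.mean(result.F_err**2))),
        "f_err_max_abs_n": float(np.max(np.abs(result.F_err))),
        "i_cmd_max_abs_a": float(np.max(np.abs(result.i_cmd))),
        "overlay_r2": float(r_squared(est, feats.y)),
        "overlay_rmse_n": float(rmse(est, feats.y)),
    })
    return result


def simulate_data_phase(cfg: RunConfig, out_dir=None) -> list[EMGRecording]:
    """Generate and (optionally) persist the synthetic trial dataset."""
    trials = make_dataset(cfg.n_trials, cfg.synth)
    if out_dir is not None:
        save_dataset(trials, out_dir, cfg.synth)
    return trials
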