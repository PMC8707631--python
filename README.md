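# emgforce

sEMG-driven isometric elbow force estimation and mirror bilateral assist
simulation, end to end and hardware-free:

- **`emgforce.synth`** — seeded generator of paired biceps/triceps sEMG
  (amplitude-modulated band-limited Gaussian noise, 0.2 mV rest to
  0.6 mV maximal-effort envelope, optional 50 Hz mains line) and a
  co-varying isometric force label.
- **`emgforce.preprocess`** — DC removal, 50 Hz notch, 4th-order
  Butterworth band-pass (10–500 Hz nominal; high edge clamped below
  Nyquist), full-wave rectification, MVC normalization. Causal by
  default, zero-phase behind a flag.
- **`emgforce.features`** — 0.2 s sliding-window MAV / RMS / DASDV / WL
  per channel, assembled into the 8-dimensional input vector with
  window-mean force labels.
- **`emgforce.bpnn`** — hand-rolled 8-3-1 backpropagation network
  (symmetric-sigmoid hidden layer, linear output, min-max feature and
  target normalization with anti-normalization back to newtons), batch
  gradient descent with momentum and early stopping, JSON model files,
  and an online accept/reject validation gate.
- **`emgforce.control`** — closed-loop PID force tracking on a modeled
  constant-stiffness (118.49 N·m/rad) series-elastic elbow actuator
  under the isometric constraint, with gravity feed-forward, current
  saturation, anti-windup, and semi-implicit Euler integration.
- **`emgforce.evaluation`** — per-trial RMSE, squared Pearson
  correlation, bilateral mean absolute error, and aggregates.
- **`emgforce.pipeline` / CLI** — the three-phase protocol: offline
  learning, online validation, real-time assist (simulated in replay).

## CLI

All commands accept `--config <yaml>` (see `emgforce.config.RunConfig`
for the schema) and a master `--seed`; every stage is deterministic
under fixed seeds.

```sh
emgforce simulate-data --seed 42 --out data            # trial CSVs + config sidecar
emgforce preprocess data/trial_00.csv --out proc.csv
emgforce extract-features data/trial_00.csv --out feats.csv
emgforce train --seed 42 --out out                     # offline phase -> model.json
emgforce validate --model out/model.json --out out     # online phase (gates at r2 >= 0.90)
emgforce assist-sim --model out/model.json --out out   # assist phase (needs accepted validation)
emgforce evaluate out/validation_estimates.csv
```

`assist-sim` refuses to run without an accepting validation report
unless `--force` is given; `validate` exits non-zero on rejection.

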