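"""Closed-loop mirror bilateral assist simulation.

A PID controller tracks the healthy-side reference force with the motor
current of a series-elastic (constant-stiffness) elbow actuator.  Under
the isometric constraint the output link is kinematically frozen at
``theta_j0``; only the motor-side mainframe angle moves, winding the
joint spring against the reflected load:

    J1 * theta1_dd + B1 * theta1_d = tau_vsa / gamma - km1 * i

with ``tau_vsa = K * (theta_j - theta1)``.  Positive current is defined
as the polarity that tensions the spring toward positive output torque.
The force sensor reads the joint torque beyond the gravity preload,
``F = max(0, (tau_vsa + tau_human - mgl*cos(theta_j)) / lever_arm)``;
the gravity preload itself is carried by a feed-forward current.

Integration is semi-implicit Euler at the controller step ``dt`` with an
optional sub-stepping factor for refinement studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PlantParams:
    """Actuator model constants.

    Only the joint stiffness ``K`` (118.49 N.m/rad, high-stiffness mode)
    comes from the device; the remaining numeric defaults are invented,
    config-exposed stand-ins.
    """

    J1: float = 5e-4        # mainframe inertia, kg m^2
    B1: float = 0.05        # mainframe damping, N m s/rad
    Jm: float = 5e-4        # output-link inertia (frozen; kept for completeness)
    Bm: float = 0.01        # output-link damping (frozen)
    gamma: float = 10.0     # transmission ratio
    km1: float = 0.06       # motor torque constant, N m/A
    K: float = 118.49       # joint stiffness, N m/rad
    lever_arm: float = 0.25  # elbow-to-force-sensor distance, m
    grav_mgl: float = 1.5   # combined m*g*l_c of forearm + device, N m
    theta_j0: float = 0.0   # fixed joint angle, rad (0 = horizontal forearm)

    def __post_init__(self) -> None:
        for name in ("J1", "B1", "Jm", "Bm", "gamma", "km1", "K", "lever_arm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ControllerGains:
    kp: float = 0.5   # A/N
    ki: float = 2.0   # A/(N s)
    kd: float = 0.0   # A s/N
    i_max: float = 10.0  # current saturation, A
    dt: float = 0.001    # controller/plant step, s

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("PID gains must be nonnegative")
        if self.i_max <= 0:
            raise ValueError("i_max must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def force_error(f_health: float, f_affected: float):
    """Assist metric: F_health - F_affected (sign preserved)."""
    return f_health - f_affected


def vsa_torque(theta_j: float, theta_1: float, K: float = 118.49):
    """Series-elastic joint torque K * (theta_j - theta_1)."""
    return K * (theta_j - theta_1)


def motor_torque(i: float, km1: float):
    """Motor torque from current: km1 * i."""
    return km1 * i


def gravity_torque(theta_j: float, grav_mgl: float):
    """Gravity load mgl * cos(theta_j); theta_j = 0 at horizontal forearm."""
    return grav_mgl * math.cos(theta_j) if np.isscalar(theta_j) else grav_mgl * np.cos(theta_j)


@dataclass
class PIDState:
    """Controller memory: trapezoid integral and previous error."""

    integral: float = 0.0
    prev_error: float | None = None


def pid_step(state: PIDState, error: float, gains: ControllerGains,
             feedforward: float = 0.0) -> float:
    """One discrete PID update returning the clamped current command (A).

    Trapezoid integral, backward-difference derivative.  Anti-windup:
    the integral update is discarded while the command is saturated.
    """
    dt = gains.dt
    if state.prev_error is None:
        d_int = 0.0
        deriv = 0.0
    else:
        d_int = dt * (error + state.prev_error) / 2.0
        deriv = (error - state.prev_error) / dt
    integral = state.integral + d_int
    u = gains.kp * error + gains.ki * integral + gains.kd * deriv + feedforward
    if abs(u) > gains.i_max:
        u = math.copysign(gains.i_max, u)
    else:
        state.integral = integral  # commit only when unsaturated
    state.prev_error = error
    return u


@dataclass
class AssistSimResult:
    t: np.ndarray
    F_ref: np.ndarray
    F_aff: np.ndarray
    F_err: np.ndarray
    i_cmd: np.ndarray
    theta1: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t, "f_ref_n": self.F_ref, "f_aff_n": self.F_aff,
            "f_err_n": self.F_err, "i_cmd_a": self.i_cmd, "theta1_rad": self.theta1,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def measured_force(theta1: float, tau_human: float, plant: PlantParams) -> float:
    """Sensor force: joint torque beyond the gravity preload, clamped at 0."""
    tau = vsa_torque(plant.theta_j0, theta1, plant.K) + tau_human \
        - gravity_torque(plant.theta_j0, plant.grav_mgl)
    return max(tau / plant.lever_arm, 0.0)


def gravity_feedforward_current(plant: PlantParams) -> float:
    """Feed-forward current whose spring torque carries the gravity load."""
    return gravity_torque(plant.theta_j0, plant.grav_mgl) / (plant.gamma * plant.km1)


def simulate_assist(F_ref: np.ndarray, human_torque: np.ndarray | float,
                    plant: PlantParams | None = None,
                    gains: ControllerGains | None = None,
                    substeps: int = 1,
                    theta1_0: float | None = None,
                    omega1_0: float = 0.0) -> AssistSimResult:
    """Run the PID force-tracking loop over a reference force series.

    Per controller step the sensor force is measured from the current
    state, the PID (plus gravity feed-forward) issues a clamped current
    command, and the mainframe dynamics are advanced by semi-implicit
    Euler (``substeps`` internal sub-intervals per controller step).
    """
    plant = plant or PlantParams()
    gains = gains or ControllerGains()
    F_ref = np.asarray(F_ref, dtype=float)
    n = F_ref.size
    if np.isscalar(human_torque):
        human_torque = np.full(n, float(human_torque))
    else:
        human_torque = np.asarray(human_torque, dtype=float)
        if human_torque.size != n:
            raise ValueError("human_torque and F_ref must share one time grid")

    dt = gains.dt
    h = dt / max(int(substeps), 1)
    if theta1_0 is None:
        # start with the spring pre-wound to carry the gravity preload, the
        # "initial position" the gravity compensation establishes
        theta1 = plant.theta_j0 - gravity_torque(plant.theta_j0, plant.grav_mgl) / plant.K
    else:
        theta1 = theta1_0
    omega1 = omega1_0
    pid = PIDState()
    i_ff = gravity_feedforward_current(plant)

    t = np.arange(n) * dt
    F_aff = np.empty(n)
    F_err = np.empty(n)
    i_cmd = np.empty(n)
    th = np.empty(n)
    for k in range(n):
        f_meas = measured_force(theta1, human_torque[k], plant)
        err = force_error(F_ref[k], f_meas)
        i = pid_step(pid, err, gains, feedforward=i_ff)
        F_aff[k] = f_meas
        F_err[k] = err
        i_cmd[k] = i
        th[k] = theta1
        for _ in range(max(int(substeps), 1)):
            tau_load = vsa_torque(plant.theta_j0, theta1, plant.K) / plant.gamma
            omega1 += h * (tau_load - motor_torque(i, plant.km1)
                           - plant.B1 * omega1) / plant.J1
            theta1 += h * omega1
        if not (math.isfinite(theta1) and math.isfinite(omega1)):
            raise FloatingPointError(
                f"simulation diverged at step {k} (t={k * dt:.4f} s); "
                "check gains/plant parameters")
    return AssistSimResult(
        t=t, F_ref=F_ref, F_aff=F_aff, F_err=F_err, i_cmd=i_cmd, theta1=th,
        meta={"substeps": substeps, "dt": dt},
    )
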