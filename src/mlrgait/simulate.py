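"""Forward simulation of the coupled neural-musculoskeletal system.

Fixed-step 4th-order Runge-Kutta at dt = 0.1 ms, 15 s horizon by
default, with fall detection (hip height below 60% of standing, or
trunk pitch beyond +/- 1 rad), 100 Hz trajectory recording, step-event
detection from vertical GRF onsets, and extraction of the scalar gait
metrics D (distance), S (steps), T (duration), V (speed) and C (gross
metabolic cost of transport).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as _config
from . import neural, rigid_body
from ._engine import run_core
from .muscle import pack_muscle_params


@dataclass
class GaitMetrics:
    """Scalar gait summaries entering the fitness function."""

    distance: float  # D, m (until fall or end)
    steps: int  # S
    duration: float  # T, s
    speed: float  # V = D/T, m/s (0 if T == 0)
    cost_of_transport: float | None  # C; None when undefined (T or D == 0)
    fell: bool
    distance_3s: float = 0.0  # distance in the first 3 s


@dataclass
class Trajectory:
    """Uniformly sampled simulation record (decimated to ~100 Hz)."""

    t: np.ndarray
    q: np.ndarray  # (n, 9) generalized coordinates
    qd: np.ndarray  # (n, 9)
    grf: np.ndarray  # (n, 2) vertical GRF left/right
    mlr: np.ndarray  # (n, 2) u_PPN, u_CnF
    y: np.ndarray  # (n, 12) CPG outputs
    alpha: np.ndarray  # (n, 18) muscle activations
    edot: np.ndarray  # (n,) total metabolic rate (W)
    fall_time: float | None
    dt_sample: float
    shank_accel: np.ndarray = field(default=None)  # (n, 2) AP accel L/R
    shank_omega: np.ndarray = field(default=None)  # (n, 2) angular velocity L/R

    def __post_init__(self):
        if self.shank_omega is None:
            self.shank_omega = self.qd[:, [rigid_body.ITH_SH_L, rigid_body.ITH_SH_R]]
        if self.shank_accel is None:
            self.shank_accel = np.zeros((self.q.shape[0], 2))

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt_sample

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy export: one row per sample, named columns."""
        cols = {
            "t": self.t,
            "x_hip": self.q[:, 0],
            "y_hip": self.q[:, 1],
            "pitch": self.q[:, 2],
            "grf_left": self.grf[:, 0],
            "grf_right": self.grf[:, 1],
            "u_ppn": self.mlr[:, 0],
            "u_cnf": self.mlr[:, 1],
            "accel_left": self.shank_accel[:, 0],
            "accel_right": self.shank_accel[:, 1],
            "omega_left": self.shank_omega[:, 0],
            "omega_right": self.shank_omega[:, 1],
            "edot": self.edot,
        }
        for i, name in enumerate(
            ["theta_hat", "thigh_l", "shank_l", "foot_l", "thigh_r", "shank_r", "foot_r"]
        ):
            cols[name] = self.q[:, 2 + i]
        for i in range(12):
            cols[f"y{i + 1}"] = self.y[:, i]
        for s, side in enumerate("lr"):
            for i, mname in enumerate(_config.MUSCLE_NAMES):
                cols[f"alpha_{mname.lower()}_{side}"] = self.alpha[:, 9 * s + i]
        return pd.DataFrame(cols)


def shank_ap_acceleration(traj_q: np.ndarray, cfg: dict, h: float) -> np.ndarray:
    """AP acceleration of the shank midpoints (second central difference).

    The 'lower-leg acceleration' consumed by the freeze-ratio detector is
    the anteroposterior acceleration of each shank midpoint, evaluated on
    the decimated (wearable-sensor-rate) series.
    """
    seg = cfg["body"]["segments"]
    L1, L2 = seg["thigh"]["length"], seg["shank"]["length"]
    out = np.zeros((traj_q.shape[0], 2))
    if traj_q.shape[0] < 3:
        return out
    for s, (ith, ish) in enumerate(((3, 4), (6, 7))):
        pos = traj_q[:, 0] + L1 * np.sin(traj_q[:, ith]) + 0.5 * L2 * np.sin(traj_q[:, ish])
        out[1:-1, s] = (pos[2:] - 2.0 * pos[1:-1] + pos[:-2]) / h**2
        out[0, s] = out[1, s]
        out[-1, s] = out[-2, s]
    return out


def rk4_step(f, t: float, x: np.ndarray, dt: float) -> np.ndarray:
    """One classical Runge-Kutta step of dx/dt = f(t, x)."""
    k1 = f(t, x)
    k2 = f(t + 0.5 * dt, x + 0.5 * dt * k1)
    k3 = f(t + 0.5 * dt, x + 0.5 * dt * k2)
    k4 = f(t + dt, x + dt * k3)
    return x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _controller_arrays(controller) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Accept a flat 49-vector or a dict of named parameter groups."""
    if isinstance(controller, dict):
        u0 = float(controller["u0"])
        w_feed = np.asarray(controller["w_feed"], dtype=np.float64)
        w_cpg = np.asarray(controller["w_cpg"], dtype=np.float64)
        w_pos = np.asarray(controller["w_pos"], dtype=np.float64)
    else:
        vec = np.asarray(controller, dtype=np.float64)
        if vec.shape != (49,):
            raise ValueError("free-parameter vector must have length 49")
        u0 = float(vec[0])
        w_feed = vec[1:17]
        w_cpg = vec[17:26]
        w_pos = vec[26:49]
    if w_feed.shape != (16,) or w_cpg.shape != (9,) or w_pos.shape != (23,):
        raise ValueError("controller groups must have sizes 16 / 9 / 23")
    return u0, w_feed, w_cpg, w_pos


def initial_state(cfg: dict, s_ppn: float = 1.0, s_cnf: float = 1.0) -> np.ndarray:
    """Initial 44-state: standing posture, zero velocity, CPG at rest.

    The MLR states start at their fixed point under the initial
    higher-center drive (the nuclei are equilibrated to their input
    before gait initiation); a small bias on the left hip-flexor CPG
    unit breaks the left/right symmetry so stepping can begin.
    """
    x0 = np.zeros(44)
    x0[:9] = rigid_body.standing_posture(cfg)
    u_ppn0, u_cnf0 = neural.mlr_fixed_point(cfg, hc=(s_ppn, s_cnf))
    x0[18] = u_ppn0
    x0[19] = u_cnf0
    x0[20 + neural.HF_L] = cfg["cpg"]["initial_kick"]
    return x0


def _engine_args(cfg, controller, s_ppn, s_cnf):
    u0, w_feed, w_cpg9, w_pos = _controller_arrays(controller)
    seg, foot_geom, jvis, klim, alim, cont, grav, ground_h = rigid_body.pack_body_params(cfg)
    mus = pack_muscle_params(cfg)
    mref = cfg["muscle_reference"]
    refs = np.array([mref["hip"], mref["knee"], mref["ankle"]])
    walpha = neural.build_motoneuron_map(cfg)
    m = cfg["mlr"]
    mlr = np.array(
        [
            m["tau_ppn"], m["tau_cnf"], m["beta_ppn"], m["beta_cnf"],
            m["w_ppn_from_cnf"], m["w_cnf_from_ppn"], m["w_hc"],
        ]
    )
    cpgp = np.array([cfg["cpg"]["tau"], cfg["cpg"]["tau_adapt"], cfg["cpg"]["beta"]])
    wcpg = neural.build_cpg_matrix(w_cpg9)
    pr = cfg["posture_reference"]
    pref = np.array([pr["pitch"], pr["hip"], pr["knee"], pr["ankle"]])
    mg = _config.total_mass(cfg) * grav
    hc = cfg["higher_center"]
    met = cfg["metabolics"]
    return (
        seg, foot_geom, jvis, klim, alim, cont, grav, ground_h, mus, refs,
        walpha, mlr, float(m["u_ppn_floor"]), cpgp, wcpg, u0, w_feed, w_pos,
        pref, mg, float(cfg["motoneuron"]["sigmoid_gain"]),
        float(s_ppn), float(s_cnf),
        float(hc["switch_time"]), float(hc["post_switch_value"]),
        float(met["c_act"]), float(met["c_short"]), float(met["c_basal"]),
    )


def run(cfg: dict, controller, s_ppn: float = 1.0, s_cnf: float = 1.0,
        duration: float | None = None, dt: float | None = None) -> Trajectory:
    """Integrate the full model and return the recorded trajectory.

    ``controller`` is the 49-element free-parameter vector (or a dict of
    named groups). Abnormal brainstem conditions are expressed through
    (s_ppn, s_cnf), which modify the higher-center inputs during the
    first 3 s only. Identical inputs give bitwise-identical output.
    """
    sim = cfg["simulation"]
    dt = float(sim["dt"] if dt is None else dt)
    duration = float(sim["duration"] if duration is None else duration)
    decim = int(sim["decimation"])
    n_steps = int(round(duration / dt))
    n_max = n_steps // decim + 3
    rec_t = np.zeros(n_max)
    rec_q = np.zeros((n_max, 9))
    rec_qd = np.zeros((n_max, 9))
    rec_grf = np.zeros((n_max, 2))
    rec_mlr = np.zeros((n_max, 2))
    rec_y = np.zeros((n_max, 12))
    rec_alpha = np.zeros((n_max, 18))
    rec_edot = np.zeros(n_max)
    args = _engine_args(cfg, controller, s_ppn, s_cnf)
    y_stand = rigid_body.standing_hip_height(cfg)
    fall = sim["fall"]
    x0 = initial_state(cfg, s_ppn, s_cnf)
    n_rec, fall_step = run_core(
        x0, dt, n_steps, decim, *args,
        y_stand, float(fall["hip_height_fraction"]), float(fall["max_pitch"]),
        rec_t, rec_q, rec_qd, rec_grf, rec_mlr, rec_y, rec_alpha, rec_edot,
    )
    fall_time = fall_step * dt if fall_step >= 0 else None
    sl = slice(0, n_rec)
    accel = shank_ap_acceleration(rec_q[sl], cfg, dt * decim)
    return Trajectory(
        shank_accel=accel,
        t=rec_t[sl].copy(),
        q=rec_q[sl].copy(),
        qd=rec_qd[sl].copy(),
        grf=rec_grf[sl].copy(),
        mlr=rec_mlr[sl].copy(),
        y=rec_y[sl].copy(),
        alpha=rec_alpha[sl].copy(),
        edot=rec_edot[sl].copy(),
        fall_time=fall_time,
        dt_sample=dt * decim,
    )


def detect_steps(trajectory: Trajectory, force_threshold: float = 30.0,
                 min_unloaded: float = 0.05) -> list[tuple[float, str]]:
    """Step events: vertical-GRF onsets after an unloaded interval.

    An event is recorded when a limb's vertical GRF rises through
    ``force_threshold`` after being below it for at least
    ``min_unloaded`` seconds, and stays loaded for at least as long
    (debounces brief spikes in either direction).
    """
    events = []
    fs = trajectory.sampling_rate
    min_samples = max(1, int(round(min_unloaded * fs)))
    for leg, name in ((0, "left"), (1, "right")):
        f = trajectory.grf[:, leg]
        loaded = f >= force_threshold
        run_len = 0
        for i in range(len(f)):
            if not loaded[i]:
                run_len += 1
                continue
            if run_len >= min_samples:
                ahead = loaded[i : i + min_samples]
                if ahead.all():  # sustained touchdown, not a spike
                    events.append((trajectory.t[i], name))
            run_len = 0
    events.sort(key=lambda e: e[0])
    return events


def gait_metrics(trajectory: Trajectory, cfg: dict) -> GaitMetrics:
    """Scalar gait metrics D, S, T, V, C from a trajectory."""
    sd = cfg["simulation"]["step_detection"]
    events = detect_steps(trajectory, sd["force_threshold"], sd["min_unloaded"])
    x = trajectory.q[:, 0]
    D = float(x[-1] - x[0])
    T = float(trajectory.fall_time if trajectory.fall_time is not None else trajectory.t[-1])
    fell = trajectory.fall_time is not None
    V = D / T if T > 0 else 0.0
    mask3 = trajectory.t <= 3.0
    D3 = float(x[mask3][-1] - x[0]) if mask3.any() else 0.0
    C = None
    if T > 0 and D > 0:
        energy = float(np.trapezoid(trajectory.edot, trajectory.t))
        C = energy / (T * _config.total_mass(cfg) * V)
    return GaitMetrics(
        distance=D,
        steps=len(events),
        duration=T,
        speed=V,
        cost_of_transport=C,
        fell=fell,
        distance_3s=D3,
    )


def export_trajectory(trajectory: Trajectory, cfg: dict, out_dir: str | Path) -> None:
    """Write trajectory.csv and metrics.json into ``out_dir``."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trajectory.to_dataframe().to_csv(out / "trajectory.csv", index=False)
    m = gait_metrics(trajectory, cfg)
    with open(out / "metrics.json", "w") as fh:
        json.dump(
            {
                "distance": m.distance,
                "steps": m.steps,
                "duration": m.duration,
                "speed": m.speed,
                "cost_of_transport": m.cost_of_transport,
                "fell": m.fell,
                "distance_3s": m.distance_3s,
            },
            fh,
            indent=2,
        )


def plot_stick_figure(trajectory: Trajectory, cfg: dict, ax=None, stride: int = 25):
    """Static stick-figure plot of the gait (inspection utility)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    seg = cfg["body"]["segments"]
    L0, L1, L2 = seg["HAT"]["length"], seg["thigh"]["length"], seg["shank"]["length"]
    fg = cfg["body"]["foot_geometry"]
    for i in range(0, trajectory.q.shape[0], stride):
        q = trajectory.q[i]
        hip = q[:2]
        head = hip + L0 * np.array([-np.sin(q[2]), np.cos(q[2])])
        ax.plot(*zip(hip, head), color="k", lw=1)
        for ath in (3, 6):
            knee = hip + L1 * np.array([np.sin(q[ath]), -np.cos(q[ath])])
            ankle = knee + L2 * np.array([np.sin(q[ath + 1]), -np.cos(q[ath + 1])])
            c, s = np.cos(q[ath + 2]), np.sin(q[ath + 2])
            heel = ankle + np.array(
                [c * fg["heel"][0] - s * fg["heel"][1], s * fg["heel"][0] + c * fg["heel"][1]]
            )
            toe = ankle + np.array(
                [c * fg["toe"][0] - s * fg["toe"][1], s * fg["toe"][0] + c * fg["toe"][1]]
            )
            col = "tab:blue" if ath == 3 else "tab:red"
            ax.plot(*zip(hip, knee, ankle), color=col, lw=1)
            ax.plot(*zip(heel, toe), color=col, lw=1)
    ax.axhline(cfg["body"]["contact"]["ground_height"], color="gray", lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax
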