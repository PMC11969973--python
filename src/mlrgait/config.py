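"""Master model configuration: every constant of the simulator in one place.

The configuration is a plain nested dict so it round-trips losslessly
through YAML. Printed model constants (joint viscosities, joint-limit and
ground-contact coefficients, MLR connection weights, muscle-model
formula constants) carry their literature values; quantities whose exact
values are not published (anthropometry, muscle geometry, neural time
constants, posture/feedback structural forms) are surrogates from the
same model lineage and are listed under ``surrogates``.

Coordinate convention (enforced in tests): x forward, y up, segment
angles counterclockwise-positive. HAT/thigh/shank angles are measured
from the vertical, foot angles from the horizontal (0 = sole flat).
Joint angles: hip = theta_thigh - theta_HAT (flexion positive),
knee = theta_shank - theta_thigh (flexion negative, range [-2.8, -0.1] rad),
ankle = phi_foot - theta_shank (dorsiflexion positive, range [-1.0, 0.54] rad).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

#: Muscle order used everywhere: left leg 0-8, right leg 9-17.
MUSCLE_NAMES = ["GM", "IL", "BFL", "RF", "BFS", "VA", "GC", "SO", "TA"]

# Per-muscle constants. Moment arms rho are signed: positive drives the
# joint angle positive (hip flexion, knee extension, ankle dorsiflexion).
# F_CE: max isometric tension (N); L_bar: optimum length (m);
# V_bar: contraction-speed normalizer (m/s); c_PD: damping (N s/m);
# k_PE: passive-elastic modulus (N).
_MUSCLES = {
    #        F_CE   L_bar  c_PD   k_PE   rho_hip rho_knee rho_ankle
    "GM": [1100.0, 0.200, 15.0, 40.0, -0.062, 0.000, 0.000],
    "IL": [900.0, 0.180, 12.0, 30.0, 0.055, 0.000, 0.000],
    "BFL": [900.0, 0.260, 12.0, 30.0, -0.055, -0.035, 0.000],
    "RF": [700.0, 0.240, 10.0, 25.0, 0.040, 0.042, 0.000],
    "BFS": [500.0, 0.160, 8.0, 18.0, 0.000, -0.035, 0.000],
    "VA": [1600.0, 0.160, 18.0, 50.0, 0.000, 0.042, 0.000],
    "GC": [1100.0, 0.230, 12.0, 35.0, 0.000, -0.020, -0.048],
    "SO": [2400.0, 0.120, 20.0, 70.0, 0.000, 0.000, -0.048],
    "TA": [700.0, 0.140, 8.0, 22.0, 0.000, 0.000, 0.037],
}

DEFAULT_CONFIG = {
    "body": {
        # ~70 kg, ~1.7 m adult; segment tables are surrogate anthropometry.
        "segments": {
            # mass (kg), length (m), com offset from proximal joint (m),
            # moment of inertia about com (kg m^2)
            "HAT": {"mass": 48.0, "length": 0.80, "com": 0.32, "inertia": 3.0},
            "thigh": {"mass": 7.3, "length": 0.44, "com": 0.19, "inertia": 0.13},
            "shank": {"mass": 3.4, "length": 0.43, "com": 0.19, "inertia": 0.055},
            "foot": {"mass": 1.0, "inertia": 0.0065},
        },
        # foot geometry in the foot frame (origin = ankle, x toward toe):
        "foot_geometry": {
            "heel": [-0.07, -0.07],  # heel contact point
            "toe": [0.18, -0.07],  # toe contact point
            "com": [0.04, -0.04],
        },
        "gravity": 9.81,  # m/s^2
        "joints": {
            # linear viscous coefficients, N m s / rad
            "viscosity": {"hip": 1.09, "knee": 3.17, "ankle": 0.943},
            # ranges (rad) and limit stiffness/damping beyond them
            "knee": {"range": [-2.8, -0.1], "stiffness": 2.0e3, "damping": 3.0e2},
            "ankle": {"range": [-1.0, 0.54], "stiffness": 2.0e3, "damping": 3.0e1},
        },
        "contact": {
            # unilateral spring-damper ground model
            "horizontal": {"stiffness": 5.0e3, "damping": 1.0e2},
            "vertical": {"stiffness": 2.5e4, "damping": 1.0e3},
            "ground_height": 0.0,
        },
    },
    "muscles": {
        name: {
            "F_CE": vals[0],
            "L_bar": vals[1],
            # eta = Ldot / V_bar; V_bar = 10 optimum lengths per second
            "V_bar": round(10.0 * vals[1], 6),
            "c_PD": vals[2],
            "k_PE": vals[3],
            "rho": {"hip": vals[4], "knee": vals[5], "ankle": vals[6]},
        }
        for name, vals in _MUSCLES.items()
    },
    # joint-angle reference posture at which each muscle sits at optimum length
    "muscle_reference": {"hip": 0.0, "knee": -0.35, "ankle": 0.0},
    "metabolics": {
        # E_m = F_CE*V_bar*(c_act*alpha + c_short*alpha*max(0,-eta)) + c_basal*F_CE*V_bar
        # surrogate activation/shortening-heat rate model; linear in F_CE
        "c_act": 0.03,
        "c_short": 0.15,
        "c_basal": 0.0005,
    },
    "mlr": {
        # calibrated so the unit-input fixed point is exactly (1.0, 1.0)
        "tau_ppn": 0.5,  # s; PPN slower than CnF (long-lasting response)
        "tau_cnf": 0.05,  # s
        "beta_ppn": 0.19,
        "beta_cnf": 0.10,
        "w_ppn_from_cnf": 0.10,
        "w_cnf_from_ppn": 0.01,
        "w_hc": 1.09,
        "u_ppn_floor": 1.0e-3,  # floor inside the 1/u_PPN posture gain
    },
    "higher_center": {"switch_time": 3.0, "post_switch_value": 1.0},
    "cpg": {
        # 12 Matsuoka units: per leg hip/knee/ankle flexor-extensor pairs
        "tau": 0.04,  # s, rise time constant
        "tau_adapt": 0.30,  # s, self-inhibition (adaptation) time constant
        "beta": 2.5,  # adaptation strength
        # initial rhythm kick: small bias on the left hip flexor unit,
        # breaks the left/right symmetry of the standing start
        "initial_kick": 0.05,
    },
    "motoneuron": {
        "sigmoid_gain": 0.25,
        # fixed CPG->muscle routing weights (negative = excitatory through
        # the sigmoid); primary 1.0, biarticular secondaries below
        "w_alpha_primary": 1.5,
        "w_alpha_antagonist": 1.0,
        "w_alpha_bfl_knee": 0.5,
        "w_alpha_gc_knee": 0.3,
    },
    "posture_reference": {
        # upright stance references used by the posture controller
        "pitch": -0.04,  # HAT angle, slight forward lean
        "hip": 0.0,
        "knee": -0.25,
        "ankle": 0.0,
    },
    "simulation": {
        "dt": 1.0e-4,  # s (0.1 ms)
        "duration": 15.0,  # s
        "decimation": 100,  # record at 100 Hz
        "seed": 0,
        "initial_posture": {
            # gait-initiation stance: both feet slightly behind the hip and
            # the trunk leaned forward (anticipatory weight shift), so the
            # reaction of the first swing does not topple the body backward
            "pitch": -0.08,
            "thigh_left": -0.06,
            "thigh_right": -0.16,
            "knee": -0.12,
            "foot": 0.0,  # soles flat
        },
        "fall": {"hip_height_fraction": 0.6, "max_pitch": 1.0},
        "step_detection": {"force_threshold": 30.0, "min_unloaded": 0.05},
    },
    "fog": {
        "freeze_band": [3.0, 10.0],  # Hz
        "locomotor_band": [0.0, 3.0],  # Hz
        "window": 2.0,  # s
        "hop": 0.5,  # s
        "freeze_ratio_threshold": 1.5,
        "correlation_threshold": 0.5,
        "min_episode": 1.0,  # s
        "merge_gap": 1.0,  # s; bridge brief negative gaps within an episode
        "ratio_cap": 1.0e6,
        "power_floor": 1.0e-12,
        "leg_mode": "max",  # ratio = max over the two legs
    },
    "cluster": {
        "k_max": 10,
        "min_jump": 20.0,  # % change below which the profile is featureless
        "plateau_ratio": 0.7,  # subsequent changes must stay below this x jump
    },
    "ga": {
        "population": 64,
        "generations": 2000,
        "crossover_rate": 0.9,
        "mutation_rate": 0.15,
        "mutation_sigma": 0.05,  # fraction of each bound range
        "elitism": 2,
        "tournament": 2,
        "seed": 0,
        "workers": 1,
    },
    "bounds": {
        # nonnegative magnitudes; structural signs live in the network skeleton
        "u0": [0.0, 5.0],
        "w_feed": [0.0, 10.0],
        "w_cpg": [0.0, 4.0],
        "w_pos": [0.0, 40.0],
    },
    "sweep": {"s_min": 0.0, "s_max": 2.0, "s_step": 0.01},
    # quantities whose exact published values are unavailable and were
    # chosen from the cited model lineage
    "surrogates": {
        "body": ["segments", "foot_geometry"],
        "muscles": ["F_CE", "L_bar", "V_bar", "c_PD", "k_PE", "rho"],
        "mlr": ["tau_ppn", "tau_cnf", "beta_ppn", "beta_cnf", "w_hc"],
        "cpg": ["tau", "tau_adapt", "beta"],
        "metabolics": ["c_act", "c_short", "c_basal"],
        "neural_forms": ["sensory_feedback", "posture_control", "w_alpha"],
    },
}


def default_config() -> dict:
    """Return a deep copy of the packaged default configuration."""
    return copy.deepcopy(DEFAULT_CONFIG)


def total_mass(cfg: dict) -> float:
    """Total body mass M (kg): HAT plus two of each leg segment."""
    seg = cfg["body"]["segments"]
    return seg["HAT"]["mass"] + 2.0 * (
        seg["thigh"]["mass"] + seg["shank"]["mass"] + seg["foot"]["mass"]
    )


def validate_config(cfg: dict) -> None:
    """Raise ValueError on physically inadmissible parameter values."""
    seg = cfg["body"]["segments"]
    for name, s in seg.items():
        if s["mass"] <= 0 or s["inertia"] <= 0:
            raise ValueError(f"segment {name}: mass and inertia must be positive")
        if name != "foot" and s["length"] <= 0:
            raise ValueError(f"segment {name}: length must be positive")
    joints = cfg["body"]["joints"]
    for j in ("knee", "ankle"):
        lo, hi = joints[j]["range"]
        if not lo < hi:
            raise ValueError(f"{j} range lower bound must be below upper bound")
        if joints[j]["stiffness"] <= 0 or joints[j]["damping"] <= 0:
            raise ValueError(f"{j} limit coefficients must be positive")
    for direction in ("horizontal", "vertical"):
        c = cfg["body"]["contact"][direction]
        if c["stiffness"] <= 0 or c["damping"] <= 0:
            raise ValueError("contact coefficients must be positive")
    for name, m in cfg["muscles"].items():
        if m["F_CE"] <= 0 or m["L_bar"] <= 0 or m["V_bar"] <= 0:
            raise ValueError(f"muscle {name}: F_CE, L_bar, V_bar must be positive")
    mlr = cfg["mlr"]
    if not mlr["tau_ppn"] > mlr["tau_cnf"] > 0:
        raise ValueError("require tau_ppn > tau_cnf > 0")
    if not mlr["w_ppn_from_cnf"] > mlr["w_cnf_from_ppn"]:
        raise ValueError("require w_ppn_from_cnf > w_cnf_from_ppn")
    sim = cfg["simulation"]
    if sim["dt"] <= 0 or sim["duration"] <= 0:
        raise ValueError("dt and duration must be positive")


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration and validate it."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    """Write a configuration to YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
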