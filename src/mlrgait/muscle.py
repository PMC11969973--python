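"""Hill-type muscle model: contractile, damping and passive-elastic elements.

Tension of muscle m is

    F_m = F_CE * k(xi) * h(eta) * alpha + c_PD * Ldot + k_PE * (exp(15 (L - L_bar)) - 1)

with the force-length relation ``k`` and force-velocity relation ``h``
evaluated at the normalized length xi = L / L_bar and normalized velocity
eta = Ldot / V_bar. The sign convention is eta > 0 while lengthening, so
h > 1 for eccentric contractions and the damping term resists stretch.

Muscle-joint geometry uses constant (angle-independent) moment arms:
L = L_bar - sum_j rho_j (theta_j - theta_ref_j), and a tension F applies
torque rho_j * F at each spanned joint (virtual work consistent).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import config as _config

#: columns of the packed per-muscle parameter matrix
MUSCLE_COLS = (
    "F_CE",
    "L_bar",
    "V_bar",
    "c_PD",
    "k_PE",
    "rho_hip",
    "rho_knee",
    "rho_ankle",
)


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def force_length(xi: float) -> float:
    """Force-length relation k(xi); k(1) is within 1e-4 of 1."""
    return 0.32 + 0.71 * np.exp(-1.112 * (xi - 1.0)) * np.sin(3.722 * (xi - 0.656))


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def force_velocity(eta: float) -> float:
    """Force-velocity relation h(eta) = 1 + tanh(3 eta), range (0, 2)."""
    return 1.0 + np.tanh(3.0 * eta)


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def passive_force(L: float, L_bar: float, k_PE: float) -> float:
    """Passive-elastic element, exponential in stretch beyond optimum length."""
    return k_PE * (np.exp(15.0 * (L - L_bar)) - 1.0)


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def muscle_tension(
    F_CE: float,
    L_bar: float,
    V_bar: float,
    c_PD: float,
    k_PE: float,
    L: float,
    Ldot: float,
    alpha: float,
) -> float:
    """Raw tension of the three-element muscle (may be slightly negative).

    The value applied to the skeleton is ``max(0, muscle_tension(...))``:
    muscles pull, never push. The raw value is returned unclamped so the
    damping contribution remains inspectable.
    """
    xi = L / L_bar
    eta = Ldot / V_bar
    f_ce = F_CE * force_length(xi) * force_velocity(eta) * alpha
    return f_ce + c_PD * Ldot + passive_force(L, L_bar, k_PE)


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def metabolic_rate(
    F_CE: float,
    V_bar: float,
    alpha: float,
    eta: float,
    c_act: float,
    c_short: float,
    c_basal: float,
) -> float:
    """Instantaneous metabolic rate (W), activation/shortening-heat surrogate.

    Nonnegative, nondecreasing in alpha, and linear in F_CE at fixed
    normalized state. Shortening (eta < 0) adds heat in proportion to
    activation and shortening speed.
    """
    shortening = -eta if eta < 0.0 else 0.0
    return F_CE * V_bar * (c_act * alpha + c_short * alpha * shortening + c_basal)


def pack_muscle_params(cfg: dict) -> np.ndarray:
    """Pack the 18-muscle table (left leg rows 0-8, right rows 9-17).

    Columns follow :data:`MUSCLE_COLS`.
    """
    rows = []
    for name in _config.MUSCLE_NAMES:
        m = cfg["muscles"][name]
        rows.append(
            [
                m["F_CE"],
                m["L_bar"],
                m["V_bar"],
                m["c_PD"],
                m["k_PE"],
                m["rho"]["hip"],
                m["rho"]["knee"],
                m["rho"]["ankle"],
            ]
        )
    one_leg = np.asarray(rows, dtype=np.float64)
    return np.vstack([one_leg, one_leg])


def muscle_kinematics(
    joint_angles: np.ndarray,
    joint_velocities: np.ndarray,
    mus: np.ndarray,
    refs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lengths, velocities and unit-tension torque arms for all 18 muscles.

    Parameters
    ----------
    joint_angles, joint_velocities
        (6,) arrays ordered [hip_L, knee_L, ankle_L, hip_R, knee_R, ankle_R].
    mus
        (18, 8) packed muscle table from :func:`pack_muscle_params`.
    refs
        (3,) reference joint angles [hip, knee, ankle] at optimum length.

    Returns
    -------
    L, Ldot : (18,) arrays
    arms : (18, 3) signed moment arms toward the ipsilateral
        [hip, knee, ankle]; torque at joint j of a unit tension is arms[m, j].
    """
    L = np.empty(18)
    Ldot = np.empty(18)
    arms = np.empty((18, 3))
    for m in range(18):
        side = 0 if m < 9 else 3
        rho = mus[m, 5:8]
        excursion = joint_angles[side : side + 3] - refs
        L[m] = mus[m, 1] - rho @ excursion
        Ldot[m] = -(rho @ joint_velocities[side : side + 3])
        arms[m] = rho
    return L, Ldot, arms
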