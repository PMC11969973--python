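"""Planar rigid-body dynamics of the 7-link chain.

Segments: HAT (head-arms-torso), left/right thigh, shank, foot. All
joints are pin joints with linear viscosity; knee and ankle additionally
carry linear elastic-damping torques outside their ranges of motion.
Heels and toes interact with the ground through unilateral spring-damper
contacts (vertical force clamped at >= 0; the horizontal spring is
anchored at the touchdown point and released when the vertical force
vanishes).

Generalized coordinates q (9):

    [x_hip, y_hip, theta_HAT, theta_thigh_L, theta_shank_L, phi_foot_L,
     theta_thigh_R, theta_shank_R, phi_foot_R]

HAT/thigh/shank angles counterclockwise from vertical, foot angles
counterclockwise from horizontal. The dynamics are assembled in the
standard M(q) qdd = Q form with segment-Jacobian mass-matrix
accumulation and solved directly (the chain is a tree, M is SPD).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import config as _config

# generalized-coordinate indices
IX, IY, ITH_HAT = 0, 1, 2
ITH_TH_L, ITH_SH_L, IPH_FT_L = 3, 4, 5
ITH_TH_R, ITH_SH_R, IPH_FT_R = 6, 7, 8

#: contact point order: left heel, left toe, right heel, right toe
CONTACT_NAMES = ("heel_L", "toe_L", "heel_R", "toe_R")


@njit(cache=True)
def joint_limit_torque(angle, velocity, lo, hi, stiffness, damping):
    """Restoring torque outside [lo, hi]; zero inside, continuous at bounds."""
    if angle > hi:
        return -stiffness * (angle - hi) - damping * velocity
    if angle < lo:
        return -stiffness * (angle - lo) - damping * velocity
    return 0.0


@njit(cache=True)
def vertical_contact_force(height, v_y, ground_height, stiffness, damping):
    """Unilateral vertical spring-damper force; >= 0, zero when airborne."""
    penetration = ground_height - height
    if penetration <= 0.0:
        return 0.0
    f = stiffness * penetration - damping * v_y
    return f if f > 0.0 else 0.0


@njit(cache=True)
def horizontal_contact_force(x, v_x, anchor_x, stiffness, damping, f_vertical):
    """Horizontal spring (anchored at touchdown) + damper, needs load."""
    if f_vertical <= 0.0:
        return 0.0
    return -stiffness * (x - anchor_x) - damping * v_x


def contact_force(point_height, point_velocity, reference_height, params,
                  x=0.0, anchor_x=0.0):
    """(Fx, Fz) of one contact point; spec-level convenience wrapper.

    ``params`` is the ``body.contact`` section of the configuration.
    """
    if not (np.isfinite(point_height) and np.all(np.isfinite(point_velocity))):
        raise ValueError("non-finite contact input")
    v = params["vertical"]
    h = params["horizontal"]
    fz = vertical_contact_force(
        point_height, point_velocity[1], reference_height, v["stiffness"], v["damping"]
    )
    fx = horizontal_contact_force(
        x, point_velocity[0], anchor_x, h["stiffness"], h["damping"], fz
    )
    return fx, fz


def pack_body_params(cfg: dict):
    """Pack the body section into flat float64 arrays for the compiled core.

    Returns (seg, foot_geom, jvis, klim, alim, cont, grav, ground_h):
      seg (4,4): [mass, length, com, inertia] for HAT/thigh/shank/foot
      foot_geom (3,2): heel, toe, com offsets in the foot frame
      jvis (3,): hip/knee/ankle viscosity
      klim, alim (4,): [lo, hi, stiffness, damping]
      cont (4,): [kx, cx, ky, cy]
    """
    b = cfg["body"]
    s = b["segments"]
    seg = np.array(
        [
            [s["HAT"]["mass"], s["HAT"]["length"], s["HAT"]["com"], s["HAT"]["inertia"]],
            [s["thigh"]["mass"], s["thigh"]["length"], s["thigh"]["com"], s["thigh"]["inertia"]],
            [s["shank"]["mass"], s["shank"]["length"], s["shank"]["com"], s["shank"]["inertia"]],
            [s["foot"]["mass"], 0.0, 0.0, s["foot"]["inertia"]],
        ]
    )
    fg = b["foot_geometry"]
    foot_geom = np.array([fg["heel"], fg["toe"], fg["com"]], dtype=np.float64)
    jv = b["joints"]["viscosity"]
    jvis = np.array([jv["hip"], jv["knee"], jv["ankle"]])
    kj = b["joints"]["knee"]
    klim = np.array([kj["range"][0], kj["range"][1], kj["stiffness"], kj["damping"]])
    aj = b["joints"]["ankle"]
    alim = np.array([aj["range"][0], aj["range"][1], aj["stiffness"], aj["damping"]])
    c = b["contact"]
    cont = np.array(
        [
            c["horizontal"]["stiffness"],
            c["horizontal"]["damping"],
            c["vertical"]["stiffness"],
            c["vertical"]["damping"],
        ]
    )
    return seg, foot_geom, jvis, klim, alim, cont, b["gravity"], c["ground_height"]


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def spd_solve(M, Q):
    """Solve M x = Q for symmetric positive-definite M via Cholesky.

    The mass matrix of a tree-structured chain with positive masses and
    inertias is SPD; a singular factorization raises (ZeroDivisionError
    surfaces as a LinAlgError-equivalent in the caller).
    """
    n = M.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = M[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    raise ValueError("mass matrix not positive definite")
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    x = np.empty(n)
    for i in range(n):
        s = Q[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(n - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, n):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def joint_angles(q, qd):
    """Joint angles/velocities (6,): [hip_L, knee_L, ankle_L, hip_R, knee_R, ankle_R]."""
    ja = np.empty(6)
    jv = np.empty(6)
    for side in range(2):
        th = 3 + 3 * side
        base = 3 * side
        ja[base] = q[th] - q[ITH_HAT]          # hip flexion positive
        ja[base + 1] = q[th + 1] - q[th]       # knee flexion negative
        ja[base + 2] = q[th + 2] - q[th + 1]   # ankle dorsiflexion positive
        jv[base] = qd[th] - qd[ITH_HAT]
        jv[base + 1] = qd[th + 1] - qd[th]
        jv[base + 2] = qd[th + 2] - qd[th + 1]
    return ja, jv


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def contact_kinematics(q, qd, seg, foot_geom):
    """Positions (4,2) and velocities (4,2) of heel/toe contact points."""
    L1 = seg[1, 1]
    L2 = seg[2, 1]
    pos = np.empty((4, 2))
    vel = np.empty((4, 2))
    for side in range(2):
        ath = 3 + 3 * side
        ash = ath + 1
        aph = ath + 2
        sth, cth = np.sin(q[ath]), np.cos(q[ath])
        ssh, csh = np.sin(q[ash]), np.cos(q[ash])
        sph, cph = np.sin(q[aph]), np.cos(q[aph])
        ax = q[IX] + L1 * sth + L2 * ssh
        ay = q[IY] - L1 * cth - L2 * csh
        avx = qd[IX] + L1 * cth * qd[ath] + L2 * csh * qd[ash]
        avy = qd[IY] + L1 * sth * qd[ath] + L2 * ssh * qd[ash]
        for p in range(2):
            ox, oy = foot_geom[p, 0], foot_geom[p, 1]
            rx = cph * ox - sph * oy
            ry = sph * ox + cph * oy
            k = 2 * side + p
            pos[k, 0] = ax + rx
            pos[k, 1] = ay + ry
            vel[k, 0] = avx - ry * qd[aph]
            vel[k, 1] = avy + rx * qd[aph]
    return pos, vel


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def eom_core(q, qd, tau_joints, seg, foot_geom, jvis, klim, alim, cont,
             grav, ground_h, anch_active, anch_x):
    """Forward dynamics of the full chain.

    Parameters
    ----------
    tau_joints : (6,) muscle torques [hip_L, knee_L, ankle_L, hip_R, ...],
        flexion-positive at hip, extension-positive at knee (angle
        convention), dorsiflexion-positive at ankle.
    anch_active : (4,) int8 flags, anch_x : (4,) horizontal spring anchors.

    Returns
    -------
    qdd (9,), contact_forces (4,2) [Fx, Fz], contact_x (4,),
    loaded (4,) int8 (vertical force > 0).
    """
    m0, hL0, c0, I0 = seg[0, 0], seg[0, 1], seg[0, 2], seg[0, 3]
    m1, L1, c1, I1 = seg[1, 0], seg[1, 1], seg[1, 2], seg[1, 3]
    m2, L2, c2, I2 = seg[2, 0], seg[2, 1], seg[2, 2], seg[2, 3]
    m3, I3 = seg[3, 0], seg[3, 3]

    Jx = np.zeros((7, 9))
    Jy = np.zeros((7, 9))
    hx = np.zeros(7)
    hy = np.zeros(7)
    mass = np.empty(7)
    mass[0] = m0
    for s in range(2):
        mass[1 + 3 * s] = m1
        mass[2 + 3 * s] = m2
        mass[3 + 3 * s] = m3

    # HAT: com = p_hip + c0 * (-sin, cos)
    sH, cH = np.sin(q[ITH_HAT]), np.cos(q[ITH_HAT])
    Jx[0, IX] = 1.0
    Jy[0, IY] = 1.0
    Jx[0, ITH_HAT] = -c0 * cH
    Jy[0, ITH_HAT] = -c0 * sH
    w = qd[ITH_HAT]
    hx[0] = c0 * sH * w * w
    hy[0] = -c0 * cH * w * w

    cvx = foot_geom[2, 0]
    cvy = foot_geom[2, 1]
    for side in range(2):
        ath = 3 + 3 * side
        ash = ath + 1
        aph = ath + 2
        sth, cth = np.sin(q[ath]), np.cos(q[ath])
        ssh, csh = np.sin(q[ash]), np.cos(q[ash])
        sph, cph = np.sin(q[aph]), np.cos(q[aph])
        wth, wsh, wph = qd[ath], qd[ash], qd[aph]
        i_th = 1 + 3 * side
        i_sh = 2 + 3 * side
        i_ft = 3 + 3 * side
        # thigh com = p + c1 * (sin, -cos)
        Jx[i_th, IX] = 1.0
        Jy[i_th, IY] = 1.0
        Jx[i_th, ath] = c1 * cth
        Jy[i_th, ath] = c1 * sth
        hx[i_th] = -c1 * sth * wth * wth
        hy[i_th] = c1 * cth * wth * wth
        # shank com = p + L1 d(th) + c2 d(sh)
        Jx[i_sh, IX] = 1.0
        Jy[i_sh, IY] = 1.0
        Jx[i_sh, ath] = L1 * cth
        Jy[i_sh, ath] = L1 * sth
        Jx[i_sh, ash] = c2 * csh
        Jy[i_sh, ash] = c2 * ssh
        hx[i_sh] = -L1 * sth * wth * wth - c2 * ssh * wsh * wsh
        hy[i_sh] = L1 * cth * wth * wth + c2 * csh * wsh * wsh
        # foot com = ankle + R(phi) com_offset
        rcx = cph * cvx - sph * cvy
        rcy = sph * cvx + cph * cvy
        Jx[i_ft, IX] = 1.0
        Jy[i_ft, IY] = 1.0
        Jx[i_ft, ath] = L1 * cth
        Jy[i_ft, ath] = L1 * sth
        Jx[i_ft, ash] = L2 * csh
        Jy[i_ft, ash] = L2 * ssh
        Jx[i_ft, aph] = -rcy
        Jy[i_ft, aph] = rcx
        hx[i_ft] = -L1 * sth * wth * wth - L2 * ssh * wsh * wsh - rcx * wph * wph
        hy[i_ft] = L1 * cth * wth * wth + L2 * csh * wsh * wsh - rcy * wph * wph

    # mass matrix and bias
    M = np.zeros((9, 9))
    Q = np.zeros(9)
    for i in range(7):
        mi = mass[i]
        for a in range(9):
            jxa = Jx[i, a]
            jya = Jy[i, a]
            if jxa == 0.0 and jya == 0.0:
                continue
            for b in range(a, 9):
                M[a, b] += mi * (jxa * Jx[i, b] + jya * Jy[i, b])
            Q[a] -= mi * (jxa * hx[i] + jya * hy[i])  # Coriolis/centripetal
            Q[a] -= mi * grav * jya                    # gravity
    for a in range(9):
        for b in range(a):
            M[a, b] = M[b, a]
    M[ITH_HAT, ITH_HAT] += I0
    for side in range(2):
        M[3 + 3 * side, 3 + 3 * side] += I1
        M[4 + 3 * side, 4 + 3 * side] += I2
        M[5 + 3 * side, 5 + 3 * side] += I3

    # joint torques: muscle + viscosity + limits
    ja, jv = joint_angles(q, qd)
    for side in range(2):
        ath = 3 + 3 * side
        base = 3 * side
        tau_hip = tau_joints[base] - jvis[0] * jv[base]
        tau_knee = (
            tau_joints[base + 1]
            - jvis[1] * jv[base + 1]
            + joint_limit_torque(ja[base + 1], jv[base + 1], klim[0], klim[1], klim[2], klim[3])
        )
        tau_ank = (
            tau_joints[base + 2]
            - jvis[2] * jv[base + 2]
            + joint_limit_torque(ja[base + 2], jv[base + 2], alim[0], alim[1], alim[2], alim[3])
        )
        Q[ath] += tau_hip
        Q[ITH_HAT] -= tau_hip
        Q[ath + 1] += tau_knee
        Q[ath] -= tau_knee
        Q[ath + 2] += tau_ank
        Q[ath + 1] -= tau_ank

    # ground contact
    pos, vel = contact_kinematics(q, qd, seg, foot_geom)
    cf = np.zeros((4, 2))
    loaded = np.zeros(4, dtype=np.int8)
    cx = np.empty(4)
    for k in range(4):
        cx[k] = pos[k, 0]
        fz = vertical_contact_force(pos[k, 1], vel[k, 1], ground_h, cont[2], cont[3])
        if fz <= 0.0:
            continue
        loaded[k] = 1
        fx = 0.0
        if anch_active[k] == 1:
            fx = horizontal_contact_force(pos[k, 0], vel[k, 0], anch_x[k], cont[0], cont[1], fz)
        cf[k, 0] = fx
        cf[k, 1] = fz
        side = k // 2
        ath = 3 + 3 * side
        ash = ath + 1
        aph = ath + 2
        sth, cth = np.sin(q[ath]), np.cos(q[ath])
        ssh, csh = np.sin(q[ash]), np.cos(q[ash])
        sph, cph = np.sin(q[aph]), np.cos(q[aph])
        ox, oy = foot_geom[k % 2, 0], foot_geom[k % 2, 1]
        rx = cph * ox - sph * oy
        ry = sph * ox + cph * oy
        Q[IX] += fx
        Q[IY] += fz
        Q[ath] += L1 * (cth * fx + sth * fz)
        Q[ash] += L2 * (csh * fx + ssh * fz)
        Q[aph] += -ry * fx + rx * fz

    qdd = spd_solve(M, Q)
    return qdd, cf, cx, loaded


def equations_of_motion(q, qd, muscle_joint_torques, cfg,
                        anch_active=None, anch_x=None):
    """Generalized accelerations of the chain (spec-level wrapper).

    Includes gravity, joint viscosity, joint-limit torques and ground
    contact. ``muscle_joint_torques`` is the (6,) per-joint muscle torque
    vector; pass zeros for a passive chain.
    """
    q = np.asarray(q, dtype=np.float64)
    qd = np.asarray(qd, dtype=np.float64)
    tau = np.asarray(muscle_joint_torques, dtype=np.float64)
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd)) and np.all(np.isfinite(tau))):
        raise ValueError("non-finite state or torque input")
    if tau.shape != (6,):
        raise ValueError("expected torques for all six joints")
    seg, foot_geom, jvis, klim, alim, cont, grav, ground_h = pack_body_params(cfg)
    if anch_active is None:
        anch_active = np.zeros(4, dtype=np.int8)
    if anch_x is None:
        anch_x = np.zeros(4)
    qdd, cf, _, _ = eom_core(
        q, qd, tau, seg, foot_geom, jvis, klim, alim, cont,
        grav, ground_h, anch_active, anch_x,
    )
    return qdd, cf


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def mechanical_energy(q, qd, seg, foot_geom, grav):
    """Kinetic + gravitational potential energy of the chain (J)."""
    m0, _, c0, I0 = seg[0, 0], seg[0, 1], seg[0, 2], seg[0, 3]
    m1, L1, c1, I1 = seg[1, 0], seg[1, 1], seg[1, 2], seg[1, 3]
    m2, L2, c2, I2 = seg[2, 0], seg[2, 1], seg[2, 2], seg[2, 3]
    m3, I3 = seg[3, 0], seg[3, 3]
    cvx, cvy = foot_geom[2, 0], foot_geom[2, 1]
    e = 0.0
    # HAT
    sH, cH = np.sin(q[ITH_HAT]), np.cos(q[ITH_HAT])
    vx = qd[IX] - c0 * cH * qd[ITH_HAT]
    vy = qd[IY] - c0 * sH * qd[ITH_HAT]
    e += 0.5 * m0 * (vx * vx + vy * vy) + 0.5 * I0 * qd[ITH_HAT] ** 2
    e += m0 * grav * (q[IY] + c0 * cH)
    for side in range(2):
        ath = 3 + 3 * side
        ash = ath + 1
        aph = ath + 2
        sth, cth = np.sin(q[ath]), np.cos(q[ath])
        ssh, csh = np.sin(q[ash]), np.cos(q[ash])
        sph, cph = np.sin(q[aph]), np.cos(q[aph])
        # thigh
        vx = qd[IX] + c1 * cth * qd[ath]
        vy = qd[IY] + c1 * sth * qd[ath]
        e += 0.5 * m1 * (vx * vx + vy * vy) + 0.5 * I1 * qd[ath] ** 2
        e += m1 * grav * (q[IY] - c1 * cth)
        # shank
        vx = qd[IX] + L1 * cth * qd[ath] + c2 * csh * qd[ash]
        vy = qd[IY] + L1 * sth * qd[ath] + c2 * ssh * qd[ash]
        e += 0.5 * m2 * (vx * vx + vy * vy) + 0.5 * I2 * qd[ash] ** 2
        e += m2 * grav * (q[IY] - L1 * cth - c2 * csh)
        # foot
        rcx = cph * cvx - sph * cvy
        rcy = sph * cvx + cph * cvy
        vx = qd[IX] + L1 * cth * qd[ath] + L2 * csh * qd[ash] - rcy * qd[aph]
        vy = qd[IY] + L1 * sth * qd[ath] + L2 * ssh * qd[ash] + rcx * qd[aph]
        e += 0.5 * m3 * (vx * vx + vy * vy) + 0.5 * I3 * qd[aph] ** 2
        e += m3 * grav * (q[IY] - L1 * cth - L2 * csh + rcy)
    return e


def standing_posture(cfg: dict) -> np.ndarray:
    """Initial generalized coordinates: upright double-support stance.

    Feet are placed with soles at ground height; the hip height follows
    from the leg geometry.
    """
    ip = cfg["simulation"]["initial_posture"]
    seg = cfg["body"]["segments"]
    L1, L2 = seg["thigh"]["length"], seg["shank"]["length"]
    h_ank = -cfg["body"]["foot_geometry"]["heel"][1]
    ground = cfg["body"]["contact"]["ground_height"]
    q = np.zeros(9)
    q[ITH_HAT] = ip["pitch"]
    for side, th in ((0, ip["thigh_left"]), (1, ip["thigh_right"])):
        ath = 3 + 3 * side
        q[ath] = th
        q[ath + 1] = th + ip["knee"]  # knee angle = theta_sh - theta_th
        q[ath + 2] = ip["foot"]
    y_left = L1 * np.cos(q[ITH_TH_L]) + L2 * np.cos(q[ITH_SH_L]) + h_ank
    y_right = L1 * np.cos(q[ITH_TH_R]) + L2 * np.cos(q[ITH_SH_R]) + h_ank
    # pre-load the contacts at the static-equilibrium penetration so the
    # model starts settled rather than dropping onto the springs
    from .config import total_mass

    weight = total_mass(cfg) * cfg["body"]["gravity"]
    penetration = weight / (4.0 * cfg["body"]["contact"]["vertical"]["stiffness"])
    q[IY] = ground + min(y_left, y_right) - penetration
    return q


def standing_hip_height(cfg: dict) -> float:
    """Hip height of the standing reference posture (m above ground)."""
    return standing_posture(cfg)[IY] - cfg["body"]["contact"]["ground_height"]
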