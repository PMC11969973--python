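"""Brainstem (MLR) and spinal (CPG) neural model, reflexes and motoneurons.

The midbrain locomotor region (MLR) is modeled as two coupled rate
neurons, the pedunculopontine nucleus (PPN) and the cuneiform nucleus
(CnF):

    tau_PPN du_PPN/dt = -u_PPN + w_PPN<-CnF max(0, u_CnF) - beta_PPN u_PPN + w_HC HC_PPN(t)
    tau_CnF du_CnF/dt = -u_CnF + w_CnF<-PPN max(0, u_PPN) - beta_CnF u_CnF + w_HC HC_CnF(t)

with piecewise-constant higher-center inputs HC(t) = s for t <= 3 s and
1 afterwards. CnF output drives a 12-unit Matsuoka central pattern
generator (flexor/extensor half-center pairs for hip, knee and ankle of
each leg); PPN output divides the posture-control contribution inside
the alpha-motoneuron sigmoid, so high PPN activity lowers muscle tone.

The sensory-feedback (16 weights) and posture-control (23 weights)
operators are mirror-symmetric linear combinations of segment angles,
joint angles and normalized vertical ground-reaction forces; their
structural signs implement standard load/position locomotor reflexes and
upright ankle/hip balance strategies. These functional forms are
surrogates for unpublished supplementary material and are isolated here
so they can be swapped without touching the rest of the model.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# CPG unit indices: per leg flexor/extensor pairs for hip, knee, ankle.
HF_L, HE_L, KF_L, KE_L, AF_L, AE_L = 0, 1, 2, 3, 4, 5
HF_R, HE_R, KF_R, KE_R, AF_R, AE_R = 6, 7, 8, 9, 10, 11

#: names of the 9 free CPG coupling magnitudes (all inhibitory)
CPG_FREE_NAMES = (
    "hip_pair",       # mutual inhibition within the hip half-center pair
    "knee_pair",
    "ankle_pair",
    "contra_hip_f",   # left/right hip-flexor mutual inhibition
    "contra_hip_e",
    "hipf_to_kneee",  # ipsilateral phase couplings
    "hipe_to_kneef",
    "kneee_to_ankf",
    "kneef_to_anke",
)

N_FEED_WEIGHTS = 16
N_POS_WEIGHTS = 23


@njit(cache=True)
def higher_center_input(t, s_ppn, s_cnf, switch_time, post_value):
    """Piecewise-constant higher-center drive (HC_PPN, HC_CnF)."""
    if t <= switch_time:
        return s_ppn, s_cnf
    return post_value, post_value


@njit(cache=True)
def mlr_derivatives(u_ppn, u_cnf, hc_ppn, hc_cnf,
                    tau_ppn, tau_cnf, beta_ppn, beta_cnf,
                    w_ppn_from_cnf, w_cnf_from_ppn, w_hc):
    """Time derivatives (du_PPN/dt, du_CnF/dt) of the MLR rate model."""
    du_p = (
        -u_ppn + w_ppn_from_cnf * max(0.0, u_cnf) - beta_ppn * u_ppn + w_hc * hc_ppn
    ) / tau_ppn
    du_c = (
        -u_cnf + w_cnf_from_ppn * max(0.0, u_ppn) - beta_cnf * u_cnf + w_hc * hc_cnf
    ) / tau_cnf
    return du_p, du_c


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def cpg_derivatives(u, v, wcpg, tau, tau_adapt, beta, u0, u_cnf, feed):
    """Matsuoka-network derivatives (du/dt, dv/dt) for the 12 units."""
    n = u.shape[0]
    du = np.empty(n)
    dv = np.empty(n)
    for i in range(n):
        syn = 0.0
        for j in range(n):
            uj = u[j]
            if uj > 0.0:
                syn += wcpg[i, j] * uj
        du[i] = (-u[i] + syn - beta * v[i] + u0 * u_cnf + feed[i]) / tau
        yi = u[i] if u[i] > 0.0 else 0.0
        dv[i] = (-v[i] + yi) / tau_adapt
    return du, dv


def build_cpg_matrix(w_free: np.ndarray) -> np.ndarray:
    """Map the 9 free coupling magnitudes into the 12x12 CPG weight matrix.

    All structural entries are inhibitory (enter with a minus sign); the
    skeleton is identical for the left and right halves, giving exact
    left/right mirror symmetry. The diagonal is zero.
    """
    w_free = np.asarray(w_free, dtype=np.float64)
    if w_free.shape != (9,):
        raise ValueError("expected 9 free CPG weights")
    (hip_pair, knee_pair, ankle_pair, c_hf, c_he,
     hf_ke, he_kf, ke_af, kf_ae) = w_free
    W = np.zeros((12, 12))
    for off in (0, 6):
        hf, he, kf, ke, af, ae = (i + off for i in range(6))
        W[hf, he] = W[he, hf] = -hip_pair
        W[kf, ke] = W[ke, kf] = -knee_pair
        W[af, ae] = W[ae, af] = -ankle_pair
        W[ke, hf] = -hf_ke
        W[kf, he] = -he_kf
        W[af, ke] = -ke_af
        W[ae, kf] = -kf_ae
    W[HF_L, HF_R] = W[HF_R, HF_L] = -c_hf
    W[HE_L, HE_R] = W[HE_R, HE_L] = -c_he
    return W


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def sensory_feedback_core(th_hat, th_th_l, th_sh_l, th_th_r, th_sh_r,
                          ghat_l, ghat_r, w):
    """Feedback vector (12,) to the CPG from body state.

    Inputs: segment angles relative to vertical and vertical GRFs
    normalized by body weight (ghat). Linear in all inputs; exact
    left/right mirror structure.
    """
    feed = np.zeros(12)
    for side in range(2):
        off = 6 * side
        if side == 0:
            th_th, th_sh, g_s, g_o = th_th_l, th_sh_l, ghat_l, ghat_r
        else:
            th_th, th_sh, g_s, g_o = th_th_r, th_sh_r, ghat_r, ghat_l
        feed[HF_L + off] = -w[0] * th_th + w[1] * g_o - w[2] * g_s
        feed[HE_L + off] = w[3] * th_th + w[4] * g_s - w[13] * th_hat
        feed[KF_L + off] = -w[5] * g_s - w[6] * th_sh + w[14] * g_o
        feed[KE_L + off] = w[7] * g_s + w[8] * th_th
        feed[AF_L + off] = -w[9] * g_s + w[10] * th_sh + w[15] * g_o
        feed[AE_L + off] = w[11] * g_s - w[12] * th_th
    return feed


def sensory_feedback(seg_angles, grf, total_weight, weights):
    """Spec-level wrapper: Feed vector from segment angles and GRFs.

    Parameters
    ----------
    seg_angles : mapping with keys 'HAT', 'thigh_L', 'shank_L', 'thigh_R',
        'shank_R' (foot angles do not enter the surrogate form).
    grf : (grf_left, grf_right) vertical ground-reaction forces (N).
    total_weight : body weight M g (N), the GRF normalizer.
    weights : (16,) nonnegative feedback gains.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (N_FEED_WEIGHTS,):
        raise ValueError(f"expected {N_FEED_WEIGHTS} feedback weights")
    return sensory_feedback_core(
        seg_angles["HAT"],
        seg_angles["thigh_L"], seg_angles["shank_L"],
        seg_angles["thigh_R"], seg_angles["shank_R"],
        grf[0] / total_weight, grf[1] / total_weight, w,
    )


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def posture_control_core(th_hat, ja, ghat_l, ghat_r, w, refs):
    """Posture-control vector P (18,) feeding the motoneuron sigmoid.

    ``ja`` is the (6,) joint-angle vector, ``refs`` the (4,) reference
    [pitch, hip, knee, ankle]. Negative entries excite the muscle (the
    sigmoid argument is decreasing); antigravity muscles receive
    stance-gated support terms and the trunk-pitch error drives
    extensors monotonically (ankle and hip strategies).
    """
    P = np.zeros(18)
    p = th_hat - refs[0]
    for side in range(2):
        off = 9 * side
        g_s = ghat_l if side == 0 else ghat_r
        g_o = ghat_r if side == 0 else ghat_l
        base = 3 * side
        dh = ja[base] - refs[1]
        dk = ja[base + 1] - refs[2]
        da = ja[base + 2] - refs[3]
        e_gm = w[0] * g_s + w[1] * (-p) * g_s + w[2] * dh * g_s
        e_il = w[3] * p * g_s + w[4] * (-dh) * g_s + w[22] * g_o
        e_bfl = w[5] * g_s + w[6] * (-p) * g_s + w[20] * dh * g_s
        e_rf = w[7] * g_s + w[8] * (-dk) * g_s + w[21] * (-p) * g_s
        e_bfs = w[9] * dk * g_s
        e_va = w[10] * g_s + w[11] * (-dk) * g_s + w[12] * (-p) * g_s
        e_gc = w[13] * g_s + w[14] * da * g_s
        e_so = w[15] * g_s + w[16] * da * g_s + w[17] * (-p) * g_s
        e_ta = w[18] * (-da) + w[19] * p * g_s
        P[off + 0] = -e_gm
        P[off + 1] = -e_il
        P[off + 2] = -e_bfl
        P[off + 3] = -e_rf
        P[off + 4] = -e_bfs
        P[off + 5] = -e_va
        P[off + 6] = -e_gc
        P[off + 7] = -e_so
        P[off + 8] = -e_ta
    return P


def posture_control(seg_angles, joint_angles, grf, total_weight, weights, refs):
    """Spec-level wrapper around :func:`posture_control_core`."""
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (N_POS_WEIGHTS,):
        raise ValueError(f"expected {N_POS_WEIGHTS} posture weights")
    return posture_control_core(
        seg_angles["HAT"],
        np.asarray(joint_angles, dtype=np.float64),
        grf[0] / total_weight, grf[1] / total_weight,
        w, np.asarray(refs, dtype=np.float64),
    )


@njit(cache=True, fastmath={'contract', 'reassoc', 'arcp'})
def motoneuron_output_core(y, P, u_ppn, walpha, gain, floor):
    """Alpha-motoneuron activations (18,), each clamped to [0, 1].

    alpha_m = 2 / (1 + exp(gain * (sum_i walpha[m,i] y_i + P_m / u_PPN))) - 1

    u_PPN is floored at ``floor`` inside the division only, keeping the
    'low PPN -> strong posture control' behaviour integrable at zero
    brainstem drive.
    """
    up = u_ppn if u_ppn > floor else floor
    n = walpha.shape[0]
    alpha = np.empty(n)
    for m in range(n):
        a = P[m] / up
        for i in range(12):
            a += walpha[m, i] * y[i]
        arg = gain * a
        if arg > 60.0:
            arg = 60.0
        elif arg < -60.0:
            arg = -60.0
        val = 2.0 / (1.0 + np.exp(arg)) - 1.0
        if val < 0.0:
            val = 0.0
        elif val > 1.0:
            val = 1.0
        alpha[m] = val
    return alpha


def motoneuron_output(y, P, u_ppn, walpha, gain=0.25, floor=1e-3):
    """Spec-level wrapper for the motoneuron sigmoid."""
    return motoneuron_output_core(
        np.asarray(y, dtype=np.float64),
        np.asarray(P, dtype=np.float64),
        float(u_ppn),
        np.asarray(walpha, dtype=np.float64),
        float(gain),
        float(floor),
    )


def build_motoneuron_map(cfg: dict) -> np.ndarray:
    """Fixed CPG-to-muscle routing matrix walpha (18, 12).

    Negative weights are excitatory through the decreasing sigmoid.
    Primary routes: hip flexor unit -> IL/RF, hip extensor -> GM/BFL,
    knee flexor -> BFS/BFL, knee extensor -> VA/RF, ankle plantar ->
    SO/GC, ankle dorsi -> TA. Biarticular muscles get reduced secondary
    weights. Each primary route is paired with reciprocal inhibition
    from the antagonist unit (positive weight), so the rhythm can
    suppress antagonist posture tone, not just add excitation — without
    it the oscillator cannot unload a muscle the posture controller
    holds active (e.g. the plantarflexor release that initiates gait).
    """
    mn = cfg["motoneuron"]
    wp = mn["w_alpha_primary"]
    wa = mn["w_alpha_antagonist"]
    W = np.zeros((18, 12))
    for side in range(2):
        moff = 9 * side
        coff = 6 * side
        hf, he, kf, ke, af, ae = (i + coff for i in range(6))
        W[moff + 0, he] = -wp            # GM
        W[moff + 0, hf] = wa
        W[moff + 1, hf] = -wp            # IL
        W[moff + 1, he] = wa
        W[moff + 2, he] = -wp            # BFL (hip extensor...)
        W[moff + 2, kf] = -mn["w_alpha_bfl_knee"]  # ... and knee flexor
        W[moff + 2, hf] = wa * 0.5
        W[moff + 3, hf] = -wp * 0.5      # RF hip flexor
        W[moff + 3, ke] = -wp * 0.5      # RF knee extensor
        W[moff + 3, kf] = wa * 0.5
        W[moff + 4, kf] = -wp            # BFS
        W[moff + 4, ke] = wa
        W[moff + 5, ke] = -wp            # VA
        W[moff + 5, kf] = wa
        W[moff + 6, ae] = -wp            # GC plantarflexor
        W[moff + 6, kf] = -mn["w_alpha_gc_knee"]
        W[moff + 6, af] = wa
        W[moff + 7, ae] = -wp            # SO
        W[moff + 7, af] = wa
        W[moff + 8, af] = -wp            # TA
        W[moff + 8, ae] = wa
    return W


def mlr_fixed_point(cfg: dict, hc=(1.0, 1.0)) -> tuple[float, float]:
    """Closed-form MLR equilibrium under constant positive inputs.

    Solves the linear 2x2 system (valid while both states are positive,
    which holds for positive HC inputs).
    """
    m = cfg["mlr"]
    A = np.array(
        [
            [1.0 + m["beta_ppn"], -m["w_ppn_from_cnf"]],
            [-m["w_cnf_from_ppn"], 1.0 + m["beta_cnf"]],
        ]
    )
    b = np.array([m["w_hc"] * hc[0], m["w_hc"] * hc[1]])
    u = np.linalg.solve(A, b)
    return float(u[0]), float(u[1])
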