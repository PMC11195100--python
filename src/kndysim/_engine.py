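"""Compiled numerical core: packed parameter layout, HH right-hand side and
an adaptive Dormand-Prince RK5(4) integrator.

Everything here operates on flat float64 arrays so the whole integration loop
can be numba-compiled.  The public, documented surface lives in
:mod:`kndysim.model`; this module is internal.

Units package-wide: mV, ms, nS, pA, pF, uM.  With these, nS*mV = pA and
pA/pF = mV/ms, so the membrane equation needs no conversion factors.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------- state layout
IV, ICA = 0, 1
IM_NAT, IH_NAT = 2, 3
IM_NAP = 4
IM_A, IH_A = 5, 6
IB_BK = 7
IR_H = 8
IS_SK = 9
IW_M = 10
IM_T, IH_T = 11, 12
IM_CA, IH_CA = 13, 14
IC_T5 = 15
IA_NKB, IA_DYN = 16, 17
NSTATE = 18

GATE_SLICE = slice(2, 16)  # all gating variables (drive states excluded)

# ------------------------------------------------------------ parameter layout
P_CM, P_CA0, P_TAUCA, P_KCA = 0, 1, 2, 3
PL_G, PL_E = 4, 5
PNAT_G, PNAT_E = 6, 7
PNAT_MVH, PNAT_MK, PNAT_MP, PNAT_MTMIN, PNAT_MTAMP, PNAT_MTVP, PNAT_MTSIG = range(8, 15)
PNAT_HVH, PNAT_HK, PNAT_HP, PNAT_HTMIN, PNAT_HTAMP, PNAT_HTVP, PNAT_HTSIG = range(15, 22)
PNAP_G, PNAP_E, PNAP_VH, PNAP_K, PNAP_P, PNAP_TAU = range(22, 28)
PA_G, PA_E, PA_MVH, PA_MK, PA_MP, PA_MTAU, PA_HVH, PA_HK, PA_HP, PA_HTAU = range(28, 38)
PBK_G, PBK_E, PBK_VH, PBK_K, PBK_P, PBK_TAU, PBK_KCA, PBK_NCA = range(38, 46)
PH_G, PH_E, PH_VH, PH_K, PH_P, PH_TMIN, PH_TAMP, PH_TVP, PH_TSIG = range(46, 55)
PSK_G, PSK_E, PSK_KCA, PSK_NCA, PSK_P, PSK_TAU = range(55, 61)
PM_G, PM_E, PM_VH, PM_K, PM_P, PM_TAU = range(61, 67)
PT_G, PT_E, PT_MVH, PT_MK, PT_MP, PT_MTAU = range(67, 73)
PT_HVH, PT_HK, PT_HP, PT_HTMIN, PT_HTAMP, PT_HTVP, PT_HTSIG = range(73, 80)
PCA_G, PCA_E, PCA_MVH, PCA_MK, PCA_MP, PCA_MTAU = range(80, 86)
PCA_HVH, PCA_HK, PCA_HP, PCA_HTAU, PCA_HFLOOR = range(86, 91)
PT5_G, PT5_E, PT5_KCA, PT5_NCA, PT5_P, PT5_TAU = range(91, 97)
PGIRK_G, PGIRK_E, PGIRK_FC = range(97, 100)
P_KON_NKB, P_TAU_NKB, P_KON_DYN, P_TAU_DYN = range(100, 104)
PT5_WNKB = 104
PA_HFLOOR = 105
NPARAM = 106

# per-current index in the decomposition (paper order)
CURRENT_NAMES = (
    "NaT", "NaP", "A", "BK", "h", "SK", "M", "T", "Ca", "TRPC5", "GIRK", "leak",
)
NCURR = 12

# ---------------------------------------------------------------- segment spec
# seg = [mode, dur, cmd0, cmd_rate, nkb_mode, nkb_a, nkb_b, nkb_dur,
#        dyn_mode, dyn_a, dyn_b, dyn_dur]
SEG_MODE, SEG_DUR, SEG_CMD0, SEG_RATE = 0, 1, 2, 3
SEG_NKB_MODE, SEG_NKB_A, SEG_NKB_B, SEG_NKB_DUR = 4, 5, 6, 7
SEG_DYN_MODE, SEG_DYN_A, SEG_DYN_B, SEG_DYN_DUR = 8, 9, 10, 11
SEG_LEN = 12
MODE_CC, MODE_VC = 0.0, 1.0


@njit(cache=True, inline="always")
def _rise(v, vh, k):
    return 1.0 / (1.0 + math.exp((vh - v) / k))


@njit(cache=True, inline="always")
def _fall(v, vh, k):
    return 1.0 / (1.0 + math.exp((v - vh) / k))


@njit(cache=True, inline="always")
def _bell(v, tmin, tamp, vp, sig):
    x = (v - vp) / sig
    return tmin + tamp * math.exp(-x * x)


@njit(cache=True, inline="always")
def _hill(ca, half, n):
    if ca <= 0.0:
        return 0.0
    r = (ca / half) ** n
    return r / (1.0 + r)


@njit(cache=True)
def gate_inf(y, p, out):
    """Steady-state value of every gating variable at the current (V, Ca)."""
    v = y[IV]
    ca = y[ICA]
    out[IM_NAT] = _rise(v, p[PNAT_MVH], p[PNAT_MK])
    out[IH_NAT] = _fall(v, p[PNAT_HVH], p[PNAT_HK])
    out[IM_NAP] = _rise(v, p[PNAP_VH], p[PNAP_K])
    out[IM_A] = _rise(v, p[PA_MVH], p[PA_MK])
    out[IH_A] = p[PA_HFLOOR] + (1.0 - p[PA_HFLOOR]) * _fall(v, p[PA_HVH], p[PA_HK])
    out[IB_BK] = _hill(ca, p[PBK_KCA], p[PBK_NCA]) * _rise(v, p[PBK_VH], p[PBK_K])
    out[IR_H] = _fall(v, p[PH_VH], p[PH_K])
    out[IS_SK] = _hill(ca, p[PSK_KCA], p[PSK_NCA])
    out[IW_M] = _rise(v, p[PM_VH], p[PM_K])
    out[IM_T] = _rise(v, p[PT_MVH], p[PT_MK])
    out[IH_T] = _fall(v, p[PT_HVH], p[PT_HK])
    out[IM_CA] = _rise(v, p[PCA_MVH], p[PCA_MK])
    out[IH_CA] = p[PCA_HFLOOR] + (1.0 - p[PCA_HFLOOR]) * _fall(v, p[PCA_HVH], p[PCA_HK])
    # receptor drive opens TRPC5 with partial efficacy; intracellular
    # calcium potentiates up to full opening (and gates the channel alone)
    a = p[PT5_WNKB] * y[IA_NKB]
    out[IC_T5] = a + (1.0 - a) * _hill(ca, p[PT5_KCA], p[PT5_NCA])


@njit(cache=True)
def ionic_currents(y, p, out):
    """Per-channel membrane currents (pA, outward positive), paper order."""
    v = y[IV]
    out[0] = p[PNAT_G] * y[IM_NAT] ** p[PNAT_MP] * y[IH_NAT] ** p[PNAT_HP] * (v - p[PNAT_E])
    out[1] = p[PNAP_G] * y[IM_NAP] ** p[PNAP_P] * (v - p[PNAP_E])
    out[2] = p[PA_G] * y[IM_A] ** p[PA_MP] * y[IH_A] ** p[PA_HP] * (v - p[PA_E])
    out[3] = p[PBK_G] * y[IB_BK] ** p[PBK_P] * (v - p[PBK_E])
    out[4] = p[PH_G] * y[IR_H] ** p[PH_P] * (v - p[PH_E])
    out[5] = p[PSK_G] * y[IS_SK] ** p[PSK_P] * (v - p[PSK_E])
    out[6] = p[PM_G] * y[IW_M] ** p[PM_P] * (v - p[PM_E])
    out[7] = p[PT_G] * y[IM_T] ** p[PT_MP] * y[IH_T] ** p[PT_HP] * (v - p[PT_E])
    out[8] = p[PCA_G] * y[IM_CA] ** p[PCA_MP] * y[IH_CA] ** p[PCA_HP] * (v - p[PCA_E])
    out[9] = p[PT5_G] * y[IC_T5] ** p[PT5_P] * (v - p[PT5_E])
    gk = p[PGIRK_FC] + (1.0 - p[PGIRK_FC]) * y[IA_DYN]
    out[10] = p[PGIRK_G] * gk * (v - p[PGIRK_E])
    out[11] = p[PL_G] * (v - p[PL_E])


@njit(cache=True, inline="always")
def _drive_u(t_rel, mode, a, b, dur):
    """Receptor drive input in [0, 1] at segment-relative time t_rel."""
    if mode < 0.5:  # constant level
        return a
    if t_rel >= dur or a <= 0.0:
        return 0.0
    period = 1000.0 / a  # a = frequency in Hz
    return 1.0 if (t_rel % period) < b else 0.0


@njit(cache=True)
def rhs(t_rel, y, p, seg, dy, icurr, ginf):
    """Time derivative of the full state.  t_rel is time from segment start."""
    gate_inf(y, p, ginf)
    ionic_currents(y, p, icurr)
    v = y[IV]

    total = 0.0
    for i in range(NCURR):
        total += icurr[i]

    if seg[SEG_MODE] < 0.5:  # current clamp
        i_inj = seg[SEG_CMD0] + seg[SEG_RATE] * t_rel
        dy[IV] = (i_inj - total) / p[P_CM]
    else:  # ideal voltage clamp: V follows the command exactly
        dy[IV] = seg[SEG_RATE]

    # calcium pool fed by the HVA Ca current (SK/BK couple to HVA channels;
    # the T-type current is electrogenic only)
    influx = -p[P_KCA] * icurr[8]
    if influx < 0.0:
        influx = 0.0
    dy[ICA] = influx - (y[ICA] - p[P_CA0]) / p[P_TAUCA]

    # first-order gate relaxation
    dy[IM_NAT] = (ginf[IM_NAT] - y[IM_NAT]) / _bell(v, p[PNAT_MTMIN], p[PNAT_MTAMP], p[PNAT_MTVP], p[PNAT_MTSIG])
    dy[IH_NAT] = (ginf[IH_NAT] - y[IH_NAT]) / _bell(v, p[PNAT_HTMIN], p[PNAT_HTAMP], p[PNAT_HTVP], p[PNAT_HTSIG])
    dy[IM_NAP] = (ginf[IM_NAP] - y[IM_NAP]) / p[PNAP_TAU]
    dy[IM_A] = (ginf[IM_A] - y[IM_A]) / p[PA_MTAU]
    dy[IH_A] = (ginf[IH_A] - y[IH_A]) / p[PA_HTAU]
    dy[IB_BK] = (ginf[IB_BK] - y[IB_BK]) / p[PBK_TAU]
    dy[IR_H] = (ginf[IR_H] - y[IR_H]) / _bell(v, p[PH_TMIN], p[PH_TAMP], p[PH_TVP], p[PH_TSIG])
    dy[IS_SK] = (ginf[IS_SK] - y[IS_SK]) / p[PSK_TAU]
    dy[IW_M] = (ginf[IW_M] - y[IW_M]) / p[PM_TAU]
    dy[IM_T] = (ginf[IM_T] - y[IM_T]) / p[PT_MTAU]
    dy[IH_T] = (ginf[IH_T] - y[IH_T]) / _bell(v, p[PT_HTMIN], p[PT_HTAMP], p[PT_HTVP], p[PT_HTSIG])
    dy[IM_CA] = (ginf[IM_CA] - y[IM_CA]) / p[PCA_MTAU]
    dy[IH_CA] = (ginf[IH_CA] - y[IH_CA]) / p[PCA_HTAU]
    dy[IC_T5] = (ginf[IC_T5] - y[IC_T5]) / p[PT5_TAU]

    # receptor drives
    u = _drive_u(t_rel, seg[SEG_NKB_MODE], seg[SEG_NKB_A], seg[SEG_NKB_B], seg[SEG_NKB_DUR])
    dy[IA_NKB] = p[P_KON_NKB] * u * (1.0 - y[IA_NKB]) - y[IA_NKB] / p[P_TAU_NKB]
    u = _drive_u(t_rel, seg[SEG_DYN_MODE], seg[SEG_DYN_A], seg[SEG_DYN_B], seg[SEG_DYN_DUR])
    dy[IA_DYN] = p[P_KON_DYN] * u * (1.0 - y[IA_DYN]) - y[IA_DYN] / p[P_TAU_DYN]
    return total


# ------------------------------------------------- Dormand-Prince 5(4) stepper
_DP_C = np.array([0.0, 1.0 / 5, 3.0 / 10, 4.0 / 5, 8.0 / 9, 1.0, 1.0])
_DP_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1.0 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3.0 / 40, 9.0 / 40, 0.0, 0.0, 0.0, 0.0],
    [44.0 / 45, -56.0 / 15, 32.0 / 9, 0.0, 0.0, 0.0],
    [19372.0 / 6561, -25360.0 / 2187, 64448.0 / 6561, -212.0 / 729, 0.0, 0.0],
    [9017.0 / 3168, -355.0 / 33, 46732.0 / 5247, 49.0 / 176, -5103.0 / 18656, 0.0],
    [35.0 / 384, 0.0, 500.0 / 1113, 125.0 / 192, -2187.0 / 6784, 11.0 / 84],
])
_DP_B5 = np.array([35.0 / 384, 0.0, 500.0 / 1113, 125.0 / 192, -2187.0 / 6784, 11.0 / 84, 0.0])
_DP_E = np.array([  # b5 - b4 (error estimator)
    71.0 / 57600, 0.0, -71.0 / 16695, 71.0 / 1920, -17253.0 / 339200, 22.0 / 525, -1.0 / 40,
])


@njit(cache=True)
def integrate_segment(y, p, seg, dt_out, n_out, rtol, atol, max_step, out):
    """Integrate one protocol segment, writing the state at dt_out intervals.

    ``out`` must be (n_out, NSTATE); out[i] is the state at (i+1)*dt_out from
    segment start.  Returns the segment-relative time of the first non-finite
    state, or -1.0 on success.  ``y`` is advanced in place to segment end.
    """
    k = np.empty((7, NSTATE))
    ytmp = np.empty(NSTATE)
    y5 = np.empty(NSTATE)
    dy = np.empty(NSTATE)
    icurr = np.empty(NCURR)
    ginf = np.empty(NSTATE)

    if seg[SEG_MODE] > 0.5:
        y[IV] = seg[SEG_CMD0]

    t = 0.0
    h = min(0.05, max_step)
    for iout in range(n_out):
        t_goal = (iout + 1) * dt_out
        while t < t_goal - 1e-12:
            if h > max_step:
                h = max_step
            if t + h > t_goal:
                h = t_goal - t
            # FSAL not used; 6 fresh stages + final
            rhs(t, y, p, seg, dy, icurr, ginf)
            for j in range(NSTATE):
                k[0, j] = dy[j]
            for s in range(1, 7):
                for j in range(NSTATE):
                    acc = 0.0
                    for q in range(s):
                        acc += _DP_A[s, q] * k[q, j]
                    ytmp[j] = y[j] + h * acc
                rhs(t + _DP_C[s] * h, ytmp, p, seg, dy, icurr, ginf)
                for j in range(NSTATE):
                    k[s, j] = dy[j]
            errnorm = 0.0
            for j in range(NSTATE):
                acc5 = 0.0
                erj = 0.0
                for s in range(7):
                    acc5 += _DP_B5[s] * k[s, j]
                    erj += _DP_E[s] * k[s, j]
                y5[j] = y[j] + h * acc5
                sc = atol + rtol * max(abs(y[j]), abs(y5[j]))
                e = h * erj / sc
                errnorm += e * e
            errnorm = math.sqrt(errnorm / NSTATE)
            if errnorm <= 1.0:
                t += h
                for j in range(NSTATE):
                    y[j] = y5[j]
                # keep gates and calcium in their physical ranges; the
                # dynamics only graze the bounds through roundoff
                for j in range(2, 16):
                    if y[j] < 0.0:
                        y[j] = 0.0
                    elif y[j] > 1.0:
                        y[j] = 1.0
                for j in range(16, 18):
                    if y[j] < 0.0:
                        y[j] = 0.0
                    elif y[j] > 1.0:
                        y[j] = 1.0
                if y[ICA] < 0.0:
                    y[ICA] = 0.0
                if not math.isfinite(y[IV]) or not math.isfinite(y[ICA]):
                    return t
                fac = 0.9 * errnorm ** -0.2 if errnorm > 1e-10 else 5.0
            else:
                fac = max(0.2, 0.9 * errnorm ** -0.2)
            h *= min(5.0, max(0.2, fac))
            if h < 1e-10:
                return t
        if seg[SEG_MODE] > 0.5:
            y[IV] = seg[SEG_CMD0] + seg[SEG_RATE] * t
        for j in range(NSTATE):
            out[iout, j] = y[j]
    return -1.0


@njit(cache=True)
def currents_for_states(ys, p, out):
    """Vectorized per-sample current decomposition for stored states."""
    for i in range(ys.shape[0]):
        ionic_currents(ys[i], p, out[i])
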