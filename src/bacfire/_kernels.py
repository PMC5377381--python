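"""Numba-compiled right-hand sides.

The packed parameter vectors are produced by ``ModelParameters.pack_5d`` /
``pack_extended``; the index constants below define the layout.  Keeping the
kernels free of Python objects lets the adaptive integrator evaluate them
cheaply inside long sweeps.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# packed 5D parameter layout
(P_CM, P_GNA, P_ENA, P_MHALF, P_MSLOPE,
 P_GK, P_EK, P_WHALF, P_WSLOPE, P_TAUW,
 P_GSL, P_ESL, P_GC, P_P,
 P_GCA, P_ECA, P_GDL, P_EDL,
 P_NHALF, P_NSLOPE, P_TAUN, P_HHALF, P_HSLOPE, P_TAUH) = range(24)

# extended tail
(P_GKC, P_GKAHP, P_EKD, P_CAIN, P_CADEC,
 P_CHISAT, P_VSHIFT, P_AQS, P_AQMAX, P_BQ) = range(24, 34)

# state layout
VS, W, VD, N, H, CA, C, Q = range(8)


@njit(cache=False)
def rhs_5d_kernel(t, y, I_S, I_D, pv):
    vs, w, vd, n, h = y[0], y[1], y[2], y[3], y[4]
    minf = 0.5 * (1.0 + math.tanh((vs - pv[P_MHALF]) / pv[P_MSLOPE]))
    winf = 0.5 * (1.0 + math.tanh((vs - pv[P_WHALF]) / pv[P_WSLOPE]))
    tw = pv[P_TAUW] / math.cosh((vs - pv[P_WHALF]) / (2.0 * pv[P_WSLOPE]))
    i_na = pv[P_GNA] * minf * (vs - pv[P_ENA])
    i_k = pv[P_GK] * w * (vs - pv[P_EK])
    i_sl = pv[P_GSL] * (vs - pv[P_ESL])
    i_ca = pv[P_GCA] * n * h * (vd - pv[P_ECA])
    i_dl = pv[P_GDL] * (vd - pv[P_EDL])
    i_ds = pv[P_GC] * (vd - vs)
    ninf = 1.0 / (1.0 + math.exp(-(vd - pv[P_NHALF]) / pv[P_NSLOPE]))
    hinf = 1.0 / (1.0 + math.exp((vd - pv[P_HHALF]) / pv[P_HSLOPE]))
    out = np.empty(5)
    out[0] = (-i_na - i_k - i_sl + (i_ds + I_S) / pv[P_P]) / pv[P_CM]
    out[1] = (winf - w) / tw
    out[2] = (-i_ca - i_dl + (-i_ds + I_D) / (1.0 - pv[P_P])) / pv[P_CM]
    out[3] = (ninf - n) / pv[P_TAUN]
    out[4] = (hinf - h) / pv[P_TAUH]
    return out


# Divisor of the low-voltage alpha_c branch.  The published rounded value
# 18.975 leaves a ~4e-5 jump at the 50 mV branch point and lets beta_c dip
# slightly negative just below it; exp(40/11)/2 is the exact value at which
# the two branches join continuously and beta_c >= 0 everywhere.
ALPHA_C_DIV = math.exp(40.0 / 11.0) / 2.0


@njit(cache=False)
def kc_kahp_rates_kernel(vd, ca, pv):
    """Pinsky–Rinzel forward/backward rates for the c and q gates (1/ms)."""
    v = vd + pv[P_VSHIFT]
    if v <= 50.0:
        alpha_c = math.exp((v - 10.0) / 11.0 - (v - 6.5) / 27.0) / ALPHA_C_DIV
        beta_c = 2.0 * math.exp((6.5 - v) / 27.0) - alpha_c
    else:
        alpha_c = 2.0 * math.exp((6.5 - v) / 27.0)
        beta_c = 0.0
    alpha_q = pv[P_AQS] * ca
    if alpha_q > pv[P_AQMAX]:
        alpha_q = pv[P_AQMAX]
    beta_q = pv[P_BQ]
    return alpha_c, beta_c, alpha_q, beta_q


@njit(cache=False)
def rhs_extended_kernel(t, y, I_S, I_D, pv):
    vs, w, vd, n, h = y[0], y[1], y[2], y[3], y[4]
    ca, c, q = y[5], y[6], y[7]
    minf = 0.5 * (1.0 + math.tanh((vs - pv[P_MHALF]) / pv[P_MSLOPE]))
    winf = 0.5 * (1.0 + math.tanh((vs - pv[P_WHALF]) / pv[P_WSLOPE]))
    tw = pv[P_TAUW] / math.cosh((vs - pv[P_WHALF]) / (2.0 * pv[P_WSLOPE]))
    i_na = pv[P_GNA] * minf * (vs - pv[P_ENA])
    i_k = pv[P_GK] * w * (vs - pv[P_EK])
    i_sl = pv[P_GSL] * (vs - pv[P_ESL])
    i_ca = pv[P_GCA] * n * h * (vd - pv[P_ECA])
    i_dl = pv[P_GDL] * (vd - pv[P_EDL])
    i_ds = pv[P_GC] * (vd - vs)
    chi = ca / pv[P_CHISAT]
    if chi > 1.0:
        chi = 1.0
    i_kc = pv[P_GKC] * c * chi * (vd - pv[P_EKD])
    i_kahp = pv[P_GKAHP] * q * (vd - pv[P_EKD])
    ninf = 1.0 / (1.0 + math.exp(-(vd - pv[P_NHALF]) / pv[P_NSLOPE]))
    hinf = 1.0 / (1.0 + math.exp((vd - pv[P_HHALF]) / pv[P_HSLOPE]))
    a_c, b_c, a_q, b_q = kc_kahp_rates_kernel(vd, ca, pv)
    out = np.empty(8)
    out[0] = (-i_na - i_k - i_sl + (i_ds + I_S) / pv[P_P]) / pv[P_CM]
    out[1] = (winf - w) / tw
    out[2] = (-i_ca - i_dl - i_kc - i_kahp + (-i_ds + I_D) / (1.0 - pv[P_P])) / pv[P_CM]
    out[3] = (ninf - n) / pv[P_TAUN]
    out[4] = (hinf - h) / pv[P_TAUH]
    out[5] = -pv[P_CAIN] * i_ca - pv[P_CADEC] * ca
    out[6] = a_c * (1.0 - c) - b_c * c
    out[7] = a_q * (1.0 - q) - b_q * q
    return out
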