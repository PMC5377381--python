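"""Independent second transcriptions used as oracles.

These re-implement the model equations directly from their definitions with
vectorized numpy, sharing no code with the package's kernels; the tests
compare the two transcriptions at random states.
"""

import numpy as np


def gating_oracle(V, params):
    """All four steady states and tau_w, straight from the sigmoid forms."""
    s, d = params.soma, params.dend
    V = np.asarray(V, dtype=float)
    return {
        "m": 0.5 * (1 + np.tanh((V - s.m_half) / s.m_slope)),
        "w": 0.5 * (1 + np.tanh((V - s.w_half) / s.w_slope)),
        "tau_w": s.tau_w_base / np.cosh((V - s.w_half) / (2 * s.w_slope)),
        "n": 1.0 / (1 + np.exp(-(V - d.n_half) / d.n_slope)),
        "h": 1.0 / (1 + np.exp((V - d.h_half) / d.h_slope)),
    }


def rhs_5d_oracle(y, I_S, I_D, params):
    """Current-balance equations of the 5D model, independent transcription."""
    s, d, c = params.soma, params.dend, params.coupling
    vs, w, vd, n, h = y[..., 0], y[..., 1], y[..., 2], y[..., 3], y[..., 4]
    g = gating_oracle(vs, params)
    i_na = s.g_Na * g["m"] * (vs - s.E_Na)
    i_k = s.g_K * w * (vs - s.E_K)
    i_sl = s.g_SL * (vs - s.E_SL)
    i_ca = d.g_Ca * n * h * (vd - d.E_Ca)
    i_dl = d.g_DL * (vd - d.E_DL)
    i_ds = c.g_c * (vd - vs)
    gd = gating_oracle(vd, params)
    return np.stack([
        (-i_na - i_k - i_sl + (i_ds + I_S) / c.p) / s.C_m,
        (g["w"] - w) / g["tau_w"],
        (-i_ca - i_dl + (-i_ds + I_D) / (1 - c.p)) / s.C_m,
        (gd["n"] - n) / d.tau_n,
        (gd["h"] - h) / d.tau_h,
    ], axis=-1)


def pr_rates_oracle(vd, ca, params):
    """Pinsky–Rinzel c/q rate functions, independent transcription."""
    e = params.extended
    v = np.asarray(vd, dtype=float) + e.v_shift
    ca = np.asarray(ca, dtype=float)
    low = v <= 50.0
    a_c_low = np.exp((v - 10.0) / 11.0 - (v - 6.5) / 27.0) / (np.exp(40.0 / 11.0) / 2.0)
    a_c_high = 2.0 * np.exp((6.5 - v) / 27.0)
    alpha_c = np.where(low, a_c_low, a_c_high)
    beta_c = np.where(low, a_c_high - a_c_low, 0.0)
    alpha_q = np.minimum(e.alpha_q_scale * ca, e.alpha_q_max)
    beta_q = np.full_like(alpha_q, e.beta_q)
    return alpha_c, beta_c, alpha_q, beta_q


def rhs_extended_oracle(y, I_S, I_D, params):
    """Extended 8D balance: 5D plus I_KC, I_KAHP and the Ca pool."""
    e = params.extended
    base = rhs_5d_oracle(y[..., :5], I_S, I_D, params)
    vs, w, vd, n, h = (y[..., i] for i in range(5))
    ca, c, q = y[..., 5], y[..., 6], y[..., 7]
    d = params.dend
    i_ca = d.g_Ca * n * h * (vd - d.E_Ca)
    chi = np.minimum(ca / e.chi_saturation, 1.0)
    i_kc = e.g_KC * c * chi * (vd - e.E_K)
    i_kahp = e.g_KAHP * q * (vd - e.E_K)
    a_c, b_c, a_q, b_q = pr_rates_oracle(vd, ca, params)
    out = np.empty(y.shape)
    out[..., :5] = base
    out[..., 2] = base[..., 2] - (i_kc + i_kahp) / params.soma.C_m
    out[..., 5] = -e.ca_influx_scale * i_ca - e.ca_decay * ca
    out[..., 6] = a_c * (1 - c) - b_c * c
    out[..., 7] = a_q * (1 - q) - b_q * q
    return out


def random_states(rng, n, extended=False):
    """Physiologically scattered random states for oracle comparisons."""
    vs = rng.uniform(-90, 40, n)
    vd = rng.uniform(-90, 40, n)
    gates = rng.uniform(0, 1, (n, 3))
    cols = [vs, gates[:, 0], vd, gates[:, 1], gates[:, 2]]
    if extended:
        cols += [rng.uniform(0, 400, n), rng.uniform(0, 1, n), rng.uniform(0, 1, n)]
    return np.stack(cols, axis=-1)
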