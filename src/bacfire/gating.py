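"""Gating steady states and time constants.

Two sigmoid families are used.  The somatic gates (instantaneous Na⁺
activation ``m``, slow K⁺ activation ``w``) use the symmetric tanh form

    x_inf(V) = 0.5 * (1 + tanh((V - half) / slope)),

while the dendritic Ca²⁺ gates use the logistic form, rising for the
activation ``n`` and falling for the inactivation ``h``:

    n_inf(V) = 1 / (1 + exp(-(V - half) / slope))
    h_inf(V) = 1 / (1 + exp(+(V - half) / slope)).

Both families take the value 1/2 at their half-activation voltage and
saturate to {0, 1}; the tanh and logistic forms differ only in how the slope
constant is quoted.  All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "m_inf", "w_inf", "tau_w", "n_inf", "h_inf", "gating_steady_state",
]


def m_inf(V, params: ModelParameters):
    s = params.soma
    return 0.5 * (1.0 + np.tanh((V - s.m_half) / s.m_slope))


def w_inf(V, params: ModelParameters):
    s = params.soma
    return 0.5 * (1.0 + np.tanh((V - s.w_half) / s.w_slope))


def tau_w(V, params: ModelParameters):
    """Voltage-dependent time constant of the slow K⁺ gate (ms)."""
    s = params.soma
    return s.tau_w_base / np.cosh((V - s.w_half) / (2.0 * s.w_slope))


def n_inf(V, params: ModelParameters):
    d = params.dend
    return 1.0 / (1.0 + np.exp(-(V - d.n_half) / d.n_slope))


def h_inf(V, params: ModelParameters):
    d = params.dend
    return 1.0 / (1.0 + np.exp((V - d.h_half) / d.h_slope))


_GATES = {"m": m_inf, "w": w_inf, "n": n_inf, "h": h_inf}


def gating_steady_state(V, gate: str, params: ModelParameters):
    """Steady-state activation of one gate at membrane potential ``V`` (mV).

    ``gate`` is one of ``m`` (somatic Na⁺ activation, instantaneous), ``w``
    (slow somatic K⁺), ``n`` (dendritic Ca²⁺ activation) or ``h`` (dendritic
    Ca²⁺ inactivation).  Returns a value in [0, 1]; monotone increasing in
    ``V`` for m, w, n and decreasing for h.
    """
    try:
        fn = _GATES[gate]
    except KeyError:
        raise ValueError(
            f"unknown gate {gate!r}; valid gates are {sorted(_GATES)}"
        ) from None
    return fn(V, params)
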