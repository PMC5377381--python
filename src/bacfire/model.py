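"""Core 5D two-compartment model: currents and the full right-hand side.

State vector order is ``(V_S, w, V_D, n, h)``; the extended model appends
``([Ca], c, q)``.  Sign convention: each ionic current is written
``g · gate · (V - E)`` so a positive value is outward (hyperpolarizing) and
enters the voltage balance with a minus sign; the inward Ca²⁺ current is
therefore negative when flowing.  ``I_DS = g_c (V_D - V_S)`` is positive when
the internal current depolarizes the soma; the somatic balance scales it by
``1/p`` and the dendritic balance by ``-1/(1-p)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import rhs_5d_kernel
from .parameters import ModelParameters

__all__ = [
    "STATE_5D", "STATE_EXTENDED", "CurrentBreakdown",
    "membrane_currents", "rhs_5d", "resting_guess",
]

STATE_5D = ("V_S", "w", "V_D", "n", "h")
STATE_EXTENDED = STATE_5D + ("Ca", "c", "q")


@dataclass(frozen=True)
class CurrentBreakdown:
    """Instantaneous current densities (µA/cm²) at one state."""

    I_Na: float
    I_K: float
    I_SL: float
    I_Ca: float
    I_DL: float
    I_DS: float


def membrane_currents(state, params: ModelParameters) -> CurrentBreakdown:
    """Evaluate every ionic and coupling current at ``state``.

    ``state`` is any 5- or 8-element sequence ordered as ``STATE_5D`` /
    ``STATE_EXTENDED``.  The Na⁺ current uses the instantaneous activation
    ``m_inf(V_S)``; I_Ca uses the dynamic gates ``n`` and ``h``.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite values")
    from .gating import m_inf

    vs, w, vd, n, h = state[:5]
    s, d, c = params.soma, params.dend, params.coupling
    return CurrentBreakdown(
        I_Na=s.g_Na * float(m_inf(vs, params)) * (vs - s.E_Na),
        I_K=s.g_K * w * (vs - s.E_K),
        I_SL=s.g_SL * (vs - s.E_SL),
        I_Ca=d.g_Ca * n * h * (vd - d.E_Ca),
        I_DL=d.g_DL * (vd - d.E_DL),
        I_DS=c.g_c * (vd - vs),
    )


def rhs_5d(t: float, state, I_S: float, I_D: float,
           params: ModelParameters) -> np.ndarray:
    """Time derivative of the 5D state (per ms).

    Current balance for each chamber divides the coupling and injected
    currents by its area fraction (``p`` somatic, ``1-p`` dendritic); the
    three gates relax first-order towards their steady states.
    """
    y = np.asarray(state, dtype=np.float64)
    return rhs_5d_kernel(float(t), y, float(I_S), float(I_D), params.pack_5d())


def resting_guess(params: ModelParameters, extended: bool = False) -> np.ndarray:
    """Hyperpolarized starting state used to seed relaxation runs."""
    from .gating import h_inf, n_inf, w_inf

    v0 = params.soma.E_SL
    y = [v0, float(w_inf(v0, params)), v0,
         float(n_inf(v0, params)), float(h_inf(v0, params))]
    if extended:
        pv = params.pack_extended()
        a_c, b_c, _, _ = _kernels.kc_kahp_rates_kernel(v0, 0.0, pv)
        y += [0.0, a_c / (a_c + b_c) if a_c + b_c > 0 else 0.0, 0.0]
    return np.array(y, dtype=np.float64)
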