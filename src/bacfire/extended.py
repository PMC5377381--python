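"""Extended 8D model: intracellular Ca²⁺ pool and Ca²⁺-activated K⁺ currents.

The dendrite gains a short-duration Ca²⁺-dependent K⁺ current I_KC, a
long-duration after-hyperpolarization current I_KAHP, and a single-pool Ca²⁺
concentration driven by the Ca²⁺ influx.  Gate kinetics follow the
Pinsky–Rinzel two-rate form ``dx/dt = alpha (1 - x) - beta x``; the rate
functions themselves are transcribed in ``_kernels.kc_kahp_rates_kernel`` and
parameterized through the registry.  [Ca] is in the dimensionless internal
units of that model, never molar.

With ``g_KC = g_KAHP = 0`` and ``ca_influx_scale = 0`` the first five
components of the extended right-hand side equal the 5D model exactly.
"""

from __future__ import annotations

import numpy as np

from ._kernels import kc_kahp_rates_kernel, rhs_extended_kernel
from .parameters import ModelParameters

__all__ = ["kc_kahp_rates", "chi", "rhs_extended"]


def kc_kahp_rates(V_D: float, Ca: float, params: ModelParameters):
    """Forward/backward rates ``(alpha_c, beta_c, alpha_q, beta_q)`` in 1/ms.

    The c-gate rates are voltage-dependent and piecewise (the two branches
    join continuously at the breakpoint); the q-gate opening rate grows
    linearly with [Ca] up to a cap, so ``alpha_q = 0`` when ``Ca = 0``.
    """
    if Ca < 0:
        raise ValueError("Ca must be non-negative")
    return kc_kahp_rates_kernel(float(V_D), float(Ca), params.pack_extended())


def chi(Ca, params: ModelParameters):
    """Saturating Ca²⁺ dependence of I_KC: ``min([Ca]/chi_saturation, 1)``."""
    sat = params.extended.chi_saturation if params.extended else 250.0
    return np.minimum(np.asarray(Ca, dtype=float) / sat, 1.0)


def rhs_extended(t: float, state, I_S: float, I_D: float,
                 params: ModelParameters) -> np.ndarray:
    """Time derivative of the 8D state ``(V_S, w, V_D, n, h, Ca, c, q)``.

    The dendritic voltage balance additionally subtracts I_KC and I_KAHP;
    ``d[Ca]/dt`` is proportional to the inward Ca²⁺ flux (``-I_Ca``) minus
    first-order removal.
    """
    y = np.asarray(state, dtype=np.float64)
    return rhs_extended_kernel(float(t), y, float(I_S), float(I_D),
                               params.pack_extended())
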