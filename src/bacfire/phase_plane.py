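"""Moving-nullcline analysis of the somatic (V_S, w) subsystem.

During a dendritic Ca²⁺ spike the internal current I_DS delivered to the
soma varies slowly compared with the somatic spike cycle.  Freezing I_DS at
a snapshot instant turns the soma into a 2D system whose V_S- and
w-nullclines, fixed points and their stability explain when the somatic
limit cycle appears, moves and disappears.  The dendritic state enters the
somatic voltage balance only through I_DS, so freezing I_DS is equivalent to
freezing (V_D, n, h) for this analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .engine import SimulationResult
from .gating import m_inf, tau_w, w_inf
from .parameters import ModelParameters

__all__ = [
    "FrozenDriveContext", "NullclineSet", "FixedPoint2D",
    "vs_nullcline", "fixed_points_2d",
]


@dataclass(frozen=True)
class FrozenDriveContext:
    """Somatic drive snapshot: constant I_S plus frozen internal current."""

    I_S: float = 0.0              # µA/cm²
    I_DS_eff: float = 0.0         # µA/cm², internal current frozen at the snapshot
    time: float | None = None     # ms, snapshot instant (provenance)

    @classmethod
    def from_snapshot(cls, result: SimulationResult, t: float,
                      I_S: float | None = None) -> "FrozenDriveContext":
        """Freeze I_DS from a simulation at time ``t``.

        ``I_S`` defaults to the protocol's somatic current at ``t``.
        """
        i = int(np.argmin(np.abs(result.t - t)))
        if I_S is None:
            I_S = result.protocol.currents(float(result.t[i]))[0]
        return cls(I_S=float(I_S), I_DS_eff=float(result.I_DS[i]),
                   time=float(result.t[i]))


@dataclass(frozen=True)
class NullclineSet:
    """Sampled nullclines of the frozen somatic subsystem."""

    V_S: np.ndarray               # mV grid
    w_vs_nullcline: np.ndarray    # w solving dV_S/dt = 0 at each grid V_S
    w_w_nullcline: np.ndarray     # w_inf(V_S)


@dataclass(frozen=True)
class FixedPoint2D:
    """Intersection of the two nullclines with its 2×2 linearization."""

    V_S: float
    w: float
    eigenvalues: tuple[complex, complex]
    kind: str                     # stable node/focus, saddle, unstable node/focus

    @property
    def stable(self) -> bool:
        return self.kind.startswith("stable")


def _dvs_dt(V, w, context: FrozenDriveContext, params: ModelParameters) -> float:
    s, c = params.soma, params.coupling
    i_na = s.g_Na * float(m_inf(V, params)) * (V - s.E_Na)
    i_k = s.g_K * w * (V - s.E_K)
    i_sl = s.g_SL * (V - s.E_SL)
    return (-i_na - i_k - i_sl + (context.I_DS_eff + context.I_S) / c.p) / s.C_m


def vs_nullcline(context: FrozenDriveContext, params: ModelParameters,
                 V_S_grid: np.ndarray | None = None) -> NullclineSet:
    """Both nullclines on a common V_S grid.

    Because I_K is linear in w, the V_S-nullcline has the closed form
    ``w(V) = [-I_Na(V) - I_SL(V) + (I_DS_eff + I_S)/p] / [g_K (V - E_K)]``;
    increasing I_S or I_DS_eff shifts it upward pointwise.  The w-nullcline
    is exactly ``w_inf``.
    """
    if V_S_grid is None:
        V_S_grid = np.linspace(-90.0, 50.0, 1401)
    V = np.asarray(V_S_grid, dtype=float)
    s, c = params.soma, params.coupling
    i_na = s.g_Na * m_inf(V, params) * (V - s.E_Na)
    i_sl = s.g_SL * (V - s.E_SL)
    drive = (context.I_DS_eff + context.I_S) / c.p
    w = (-i_na - i_sl + drive) / (s.g_K * (V - s.E_K))
    return NullclineSet(V_S=V, w_vs_nullcline=w, w_w_nullcline=np.asarray(w_inf(V, params)))


def _jacobian_2d(V, w, context, params, eps=1e-7):
    def f(v_, w_):
        return np.array([_dvs_dt(v_, w_, context, params),
                         (float(w_inf(v_, params)) - w_) / float(tau_w(v_, params))])
    J = np.empty((2, 2))
    J[:, 0] = (f(V + eps, w) - f(V - eps, w)) / (2 * eps)
    J[:, 1] = (f(V, w + eps) - f(V, w - eps)) / (2 * eps)
    return J


def _classify(eigs: np.ndarray) -> str:
    re, im = eigs.real, eigs.imag
    if re[0] * re[1] < 0:
        return "saddle"
    stable = bool(np.all(re < 0))
    focus = bool(np.any(np.abs(im) > 1e-12))
    return ("stable " if stable else "unstable ") + ("focus" if focus else "node")


def fixed_points_2d(context: FrozenDriveContext, params: ModelParameters,
                    V_S_grid: np.ndarray | None = None) -> list[FixedPoint2D]:
    """Fixed points of the frozen subsystem, classified by their eigenvalues.

    Roots of ``dV_S/dt = 0`` along the w-nullcline are bracketed by sign
    changes on the grid and refined by Brent's method; an empty list is a
    valid outcome (the suprathreshold regime after the node and saddle have
    annihilated).
    """
    if V_S_grid is None:
        V_S_grid = np.arange(-90.0, 50.0 + 1e-9, 0.01)
    V = np.asarray(V_S_grid, dtype=float)

    def g(v):
        return _dvs_dt(v, float(w_inf(v, params)), context, params)

    gv = np.array([g(v) for v in V])
    points = []
    for i in np.nonzero(np.sign(gv[:-1]) * np.sign(gv[1:]) < 0)[0]:
        v_star = brentq(g, V[i], V[i + 1], xtol=1e-12)
        w_star = float(w_inf(v_star, params))
        eigs = np.linalg.eigvals(_jacobian_2d(v_star, w_star, context, params))
        points.append(FixedPoint2D(V_S=float(v_star), w=w_star,
                                   eigenvalues=(complex(eigs[0]), complex(eigs[1])),
                                   kind=_classify(eigs)))
    return points
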