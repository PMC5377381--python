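"""Time integration of the 5D / extended model and equilibrium location."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ._kernels import rhs_5d_kernel, rhs_extended_kernel
from .model import STATE_5D, STATE_EXTENDED, resting_guess
from .parameters import ModelParameters
from .protocols import SolverSettings, StimulusProtocol

__all__ = [
    "IntegrationError", "NoStableRestingState", "SimulationResult",
    "integrate", "find_resting_state", "finite_difference_jacobian",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the time at which the step size underflowed."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:.6g} ms)")
        self.t_fail = t_fail


class NoStableRestingState(RuntimeError):
    """No stable equilibrium exists at the requested constant inputs."""


def _kernel_for(model: str):
    if model == "5d":
        return rhs_5d_kernel, 5
    if model == "extended":
        return rhs_extended_kernel, 8
    raise ValueError(f"unknown model {model!r}; use '5d' or 'extended'")


def _pack(model: str, params: ModelParameters) -> np.ndarray:
    return params.pack_5d() if model == "5d" else params.pack_extended()


@dataclass
class SimulationResult:
    """Trajectory on a uniform grid plus run provenance.

    Derived traces (I_Ca, I_DS) are recomputed from the stored states, never
    integrated separately, so they are always consistent with the states.
    """

    t: np.ndarray                 # ms, strictly increasing uniform grid
    y: np.ndarray                 # (n_state, n_t)
    model: str
    params: ModelParameters
    protocol: StimulusProtocol
    settings: SolverSettings
    state_names: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.state_names = STATE_5D if self.model == "5d" else STATE_EXTENDED

    def __getitem__(self, name: str) -> np.ndarray:
        return self.y[self.state_names.index(name)]

    @property
    def V_S(self) -> np.ndarray:
        return self.y[0]

    @property
    def V_D(self) -> np.ndarray:
        return self.y[2]

    @property
    def I_Ca(self) -> np.ndarray:
        d = self.params.dend
        return d.g_Ca * self.y[3] * self.y[4] * (self.y[2] - d.E_Ca)

    @property
    def I_DS(self) -> np.ndarray:
        return self.params.coupling.g_c * (self.y[2] - self.y[0])

    def final_state(self) -> np.ndarray:
        return self.y[:, -1].copy()

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.t}
        data.update({name: self.y[i] for i, name in enumerate(self.state_names)})
        data["I_Ca"] = self.I_Ca
        data["I_DS"] = self.I_DS
        return pd.DataFrame(data)

    def save(self, path: str | Path) -> None:
        """Write the tidy trace CSV plus a JSON run manifest alongside it."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        from . import __version__
        from .parameters import _SECTIONS  # flat dump of the parameters used

        flat = {}
        for section, cls in _SECTIONS.items():
            obj = getattr(self.params, section)
            if obj is None:
                continue
            from dataclasses import fields as dc_fields
            for f in dc_fields(cls):
                flat[f"{section}.{f.name}"] = getattr(obj, f.name)
        manifest = {
            "model": self.model,
            "version": __version__,
            "parameters": flat,
            "protocol": {
                "duration": self.protocol.duration,
                "soma": vars(self.protocol.soma),
                "dend": vars(self.protocol.dend),
            },
            "settings": vars(self.settings),
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def integrate(model: str, params: ModelParameters, protocol: StimulusProtocol,
              initial=None, settings: SolverSettings | None = None,
              ) -> SimulationResult:
    """Integrate the model under ``protocol`` from ``initial``.

    The solver is restarted at every stimulus onset/offset so that the
    discontinuities are resolved exactly; within each segment the injected
    currents are constant.  Output is dense on the uniform ``output_dt``
    grid.  ``initial`` defaults to the resting state at zero input.
    """
    settings = settings or SolverSettings()
    kernel, nstate = _kernel_for(model)
    pv = _pack(model, params)
    if initial is None:
        initial = find_resting_state(model, params, 0.0, 0.0)
    y0 = np.asarray(initial, dtype=np.float64)
    if y0.shape != (nstate,):
        raise ValueError(f"initial state must have {nstate} components for model {model!r}")

    edges = np.concatenate([[0.0], protocol.breakpoints(), [protocol.duration]])
    n_out = int(round(protocol.duration / settings.output_dt)) + 1
    t_grid = np.arange(n_out) * settings.output_dt
    out = np.empty((nstate, n_out))

    y = y0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        I_S, I_D = protocol.currents((t0 + t1) / 2.0)
        sol = solve_ivp(kernel, (t0, t1), y, method=settings.method,
                        rtol=settings.rel_tol, atol=settings.abs_tol,
                        max_step=settings.max_step, dense_output=True,
                        args=(I_S, I_D, pv))
        if not sol.success:
            raise IntegrationError(sol.message, sol.t[-1] if len(sol.t) else t0)
        lo = int(np.searchsorted(t_grid, t0, side="left" if t0 == 0 else "right"))
        hi = int(np.searchsorted(t_grid, t1, side="right"))
        seg = t_grid[lo:hi]
        if len(seg):
            out[:, lo:hi] = sol.sol(seg)
        y = sol.y[:, -1]
    return SimulationResult(t=t_grid, y=out, model=model, params=params,
                            protocol=protocol, settings=settings)


def finite_difference_jacobian(fun, y, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with per-variable step ``eps``."""
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    for i in range(n):
        yp, ym = y.copy(), y.copy()
        yp[i] += eps
        ym[i] -= eps
        J[:, i] = (np.asarray(fun(yp)) - np.asarray(fun(ym))) / (2.0 * eps)
    return J


def find_resting_state(model: str, params: ModelParameters,
                       I_S: float = 0.0, I_D: float = 0.0,
                       relax_time: float | None = None) -> np.ndarray:
    """Stable equilibrium at constant inputs, or raise ``NoStableRestingState``.

    A long relaxation run seeds a Newton-type root refinement of the RHS;
    the result is accepted only if the residual is at root tolerance and all
    eigenvalues of the finite-difference Jacobian have negative real part.
    """
    kernel, nstate = _kernel_for(model)
    pv = _pack(model, params)
    if relax_time is None:
        # the AHP gate q relaxes on the 1/beta_q timescale
        relax_time = 2000.0 if model == "5d" else 8000.0
    y0 = resting_guess(params, extended=(model == "extended"))
    sol = solve_ivp(kernel, (0.0, relax_time), y0, method="RK23",
                    rtol=1e-8, atol=1e-10, max_step=0.25, args=(I_S, I_D, pv))
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1])

    def fun(y):
        return kernel(0.0, y, I_S, I_D, pv)

    eq = None
    for method in ("hybr", "lm"):
        res = root(fun, sol.y[:, -1], method=method)
        # accept on residual: hybr can stop with "no progress" at machine accuracy
        if np.max(np.abs(fun(res.x))) <= 1e-10:
            eq = res.x
            break
    if eq is None:
        raise NoStableRestingState(
            f"root refinement failed at I_S={I_S}, I_D={I_D}")
    eigs = np.linalg.eigvals(finite_difference_jacobian(fun, eq))
    if np.max(eigs.real) >= 0.0:
        raise NoStableRestingState(
            f"no stable resting state at I_S={I_S}, I_D={I_D} "
            f"(leading eigenvalue {np.max(eigs.real):.3g}/ms)")
    return eq
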