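"""One-parameter bifurcation structure in I_S or I_D.

Equilibrium branches are traced by pseudo-arclength continuation (secant
predictor, Newton-type corrector on the augmented system), which rounds
folds without a mode switch; stability comes from the finite-difference
Jacobian of the full right-hand side.  Stable limit cycles are swept by
direct integration with end-state inheritance, so comparing an upward and a
downward sweep delimits bistable intervals.  Unstable cycles are not
continued; their existence interval is inferred from that bistability.

Onset classification: a SNIC (saddle-node on invariant circle) is declared
when the cycle onset coincides with the equilibrium fold and the firing rate
grows as sqrt(param - param_c); a plain SN (fold off the cycle) when a
stable cycle persists below the fold; a saddle-homoclinic-orbit (SHO)
boundary when the cycle period diverges logarithmically at the down-sweep
boundary.  Ambiguous evidence yields an "unclassified" event, never a
silent guess.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root
from scipy.stats import linregress

from ._kernels import rhs_5d_kernel, rhs_extended_kernel
from .engine import finite_difference_jacobian, find_resting_state
from .parameters import ModelParameters
from .protocols import SolverSettings, StimulusProtocol, step, zero
from .spikes import detect_spikes

__all__ = [
    "EquilibriumBranch", "LimitCycleBranch", "BifurcationEvent",
    "continue_equilibria", "sweep_limit_cycles", "classify_onset",
]

log = logging.getLogger(__name__)


@dataclass
class EquilibriumBranch:
    """Equilibria along a swept input, with stability and folds."""

    sweep_param: str                  # "I_S" or "I_D"
    params_values: np.ndarray         # µA/cm², along the branch
    states: np.ndarray                # (n_points, n_state)
    leading_eig: np.ndarray           # max real part of the Jacobian spectrum
    stable: np.ndarray                # bool
    folds: list[dict] = field(default_factory=list)

    @property
    def fold_params(self) -> list[float]:
        return [f["param"] for f in self.folds]


@dataclass
class LimitCycleBranch:
    """Stable-cycle extrema and period from a hysteresis sweep."""

    sweep_param: str
    direction: str                    # "up" or "down"
    params_values: np.ndarray         # in sweep order
    v_max: np.ndarray
    v_min: np.ndarray
    period: np.ndarray                # ms, nan where no cycle
    exists: np.ndarray                # bool: sustained spiking observed

    def onset_param(self) -> float | None:
        """First swept value (in sweep order) at which the cycle exists."""
        idx = np.nonzero(self.exists)[0]
        return float(self.params_values[idx[0]]) if idx.size else None


@dataclass(frozen=True)
class BifurcationEvent:
    """A labelled transition with the evidence that supports the label."""

    param: float
    kind: str                         # SNIC | SN | SHO_onset | unclassified
    evidence: dict


def _rhs_for(model: str, params: ModelParameters):
    if model == "5d":
        return rhs_5d_kernel, params.pack_5d()
    if model == "extended":
        return rhs_extended_kernel, params.pack_extended()
    raise ValueError(f"unknown model {model!r}")


def continue_equilibria(model: str, params: ModelParameters, sweep_param: str,
                        sweep_range: tuple[float, float], step_size: float | None = None,
                        fixed_other: float = 0.0,
                        eig_eps: float = 1e-6) -> EquilibriumBranch:
    """Trace the equilibrium branch over ``sweep_range``.

    Pseudo-arclength continuation with a secant predictor and a Newton-type
    corrector on the augmented system ``[rhs(y; lam); arclength constraint]``.
    The step is halved on corrector failure down to a floor, at which point
    the branch is truncated with a logged warning.  Folds are recorded where
    the parameter reverses along the branch; at each the smallest-magnitude
    Jacobian eigenvalue is attached as evidence.
    """
    if sweep_param not in ("I_S", "I_D"):
        raise ValueError("sweep_param must be 'I_S' or 'I_D'")
    lam0, lam1 = float(sweep_range[0]), float(sweep_range[1])
    if not np.isfinite([lam0, lam1]).all():
        raise ValueError("sweep range must be finite")
    if step_size is None:
        step_size = abs(lam1 - lam0) / 400.0
    kernel, pv = _rhs_for(model, params)

    def fun(y, lam):
        if sweep_param == "I_S":
            return kernel(0.0, y, lam, fixed_other, pv)
        return kernel(0.0, y, fixed_other, lam, pv)

    # starting point: relaxed + refined equilibrium at lam0
    try:
        y = find_resting_state(model, params,
                               I_S=lam0 if sweep_param == "I_S" else fixed_other,
                               I_D=lam0 if sweep_param == "I_D" else fixed_other)
    except Exception:
        guess = np.array([-65.0, 0.05, -65.0, 0.0, 1.0] if model == "5d" else
                         [-65.0, 0.05, -65.0, 0.0, 1.0, 0.0, 0.0, 0.0])
        res = root(lambda yy: fun(yy, lam0), guess, method="hybr")
        if np.max(np.abs(fun(res.x, lam0))) > 1e-10:
            raise RuntimeError(f"no equilibrium found at {sweep_param}={lam0}")
        y = res.x

    n = y.size
    direction = 1.0 if lam1 >= lam0 else -1.0
    # state scaling keeps the arclength metric balanced between mV and gates
    y_scale = np.where(np.abs(y) > 1.0, 50.0, 1.0)

    lams = [lam0]
    ys = [y.copy()]
    ds = step_size
    tangent = None
    max_points = 20000
    while len(lams) < max_points:
        lam_prev, y_prev = lams[-1], ys[-1]
        if tangent is None:
            t_y = np.zeros(n)
            t_lam = direction
        else:
            t_y, t_lam = tangent
        norm = np.sqrt(np.sum((t_y / y_scale) ** 2) + t_lam ** 2)
        t_y, t_lam = t_y / norm, t_lam / norm

        converged = False
        ds_try = ds
        while ds_try >= step_size / 1024.0:
            y_pred = y_prev + ds_try * t_y
            lam_pred = lam_prev + ds_try * t_lam

            def aug(z):
                yy, ll = z[:n], z[n]
                con = (np.sum((yy - y_pred) * t_y / y_scale ** 2)
                       + (ll - lam_pred) * t_lam)
                return np.concatenate([fun(yy, ll), [con]])

            sol = root(aug, np.concatenate([y_pred, [lam_pred]]),
                       method="hybr")
            resid = np.max(np.abs(aug(sol.x)))
            if resid < 1e-10:
                converged = True
                break
            ds_try /= 2.0
        if not converged:
            log.warning("continuation corrector failed near %s=%.6g; branch truncated",
                        sweep_param, lam_prev)
            warnings.warn("equilibrium branch truncated before end of range")
            break
        y_new, lam_new = sol.x[:n], float(sol.x[n])
        lams.append(lam_new)
        ys.append(y_new)
        tangent = (y_new - y_prev, lam_new - lam_prev)
        ds = min(ds_try * 1.3, step_size)
        done = lam_new > max(lam0, lam1) + step_size or lam_new < min(lam0, lam1) - step_size
        if done:
            break

    lams_arr = np.array(lams)
    states = np.array(ys)
    leading = np.empty(len(lams))
    stable = np.empty(len(lams), dtype=bool)
    for i, (lam, yy) in enumerate(zip(lams_arr, states)):
        J = finite_difference_jacobian(lambda z: fun(z, lam), yy, eps=eig_eps)
        eigs = np.linalg.eigvals(J)
        leading[i] = float(np.max(eigs.real))
        stable[i] = leading[i] < 0.0

    folds = []
    dlam = np.diff(lams_arr)
    for i in np.nonzero(dlam[:-1] * dlam[1:] < 0)[0]:
        lam_f, y_f = _refine_fold(fun, states[i + 1], lams_arr[i + 1], eig_eps)
        J = finite_difference_jacobian(lambda z: fun(z, lam_f), y_f, eps=eig_eps)
        eigs = np.linalg.eigvals(J)
        folds.append({"param": float(lam_f), "state": y_f,
                      "min_abs_eig": float(np.min(np.abs(eigs)))})
    return EquilibriumBranch(sweep_param=sweep_param, params_values=lams_arr,
                             states=states, leading_eig=leading, stable=stable,
                             folds=folds)


def _refine_fold(fun, y0, lam0, eps):
    """Refine a fold by extremizing lam along the branch.

    Near a simple fold the branch is parametrizable by V_S; pinning V_S and
    solving the remaining components together with lam gives a smooth
    lam(V_S) whose extremum is the fold.  Brent search on a small bracket
    around the detected reversal locates it; the unrefined point is kept if
    the reduced solves fail.
    """
    from scipy.optimize import minimize_scalar

    n = y0.size
    cache = {}

    def lam_of_vs(vs):
        if vs in cache:
            return cache[vs]

        def reduced(z):
            y = np.concatenate([[vs], z[:n - 1]])
            return fun(y, z[n - 1])

        z0 = np.concatenate([y0[1:], [lam0]])
        sol = root(reduced, z0, method="hybr")
        if np.max(np.abs(reduced(sol.x))) > 1e-8:
            cache[vs] = None
            return None
        cache[vs] = (float(sol.x[n - 1]), np.concatenate([[vs], sol.x[:n - 1]]))
        return cache[vs]

    probe = [lam_of_vs(y0[0] + d) for d in (-0.5, 0.0, 0.5)]
    if any(p is None for p in probe):
        return float(lam0), y0
    # fold is a max of lam if the middle probe dominates the mean, else a min
    sign = -1.0 if probe[1][0] >= (probe[0][0] + probe[2][0]) / 2.0 else 1.0
    res = minimize_scalar(
        lambda vs: (lam_of_vs(vs) or (sign * np.inf,))[0] * sign,
        bracket=None, bounds=(y0[0] - 0.5, y0[0] + 0.5), method="bounded",
        options={"xatol": 1e-10})
    out = lam_of_vs(float(res.x))
    if out is None:
        return float(lam0), y0
    return out[0], out[1]


def sweep_limit_cycles(model: str, params: ModelParameters, sweep_param: str,
                       values: np.ndarray, direction: str = "up",
                       fixed_other: float = 0.0,
                       settle: float = 300.0, measure: float = 500.0,
                       settings: SolverSettings | None = None,
                       initial=None, min_spikes: int = 3) -> LimitCycleBranch:
    """Follow the stable attractor across ``values`` with state inheritance.

    For each parameter value the model is integrated for ``settle`` ms and
    measured for ``measure`` ms, seeding from the previous value's final
    state so a bistable attractor is retained across the sweep.  Sustained
    spiking in the measurement window marks cycle existence; V_S extrema and
    the mean ISI period are recorded there.  Non-spiking points are valid
    records, not errors.
    """
    from .engine import integrate

    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    values = np.asarray(sorted(values, reverse=(direction == "down")), dtype=float)
    settings = settings or SolverSettings(output_dt=0.05)
    thr = params.analysis.spike_threshold
    refr = params.analysis.spike_refractory

    if initial is None:
        if direction == "up":
            try:
                initial = find_resting_state(
                    model, params,
                    I_S=values[0] if sweep_param == "I_S" else fixed_other,
                    I_D=values[0] if sweep_param == "I_D" else fixed_other)
            except Exception:
                initial = find_resting_state(model, params, 0.0, 0.0)
        else:
            # seed the downward sweep from the attractor at its largest value
            rest0 = find_resting_state(model, params, 0.0, 0.0)
            proto = _sweep_protocol(sweep_param, values[0], fixed_other,
                                    settle + measure)
            initial = integrate(model, params, proto, rest0, settings).final_state()

    y = np.asarray(initial, dtype=float)
    v_max = np.empty(values.size)
    v_min = np.empty(values.size)
    period = np.full(values.size, np.nan)
    exists = np.zeros(values.size, dtype=bool)
    for i, lam in enumerate(values):
        proto = _sweep_protocol(sweep_param, lam, fixed_other, settle + measure)
        res = integrate(model, params, proto, y, settings)
        y = res.final_state()
        sel = res.t >= settle
        vs = res.V_S[sel]
        v_max[i] = float(vs.max())
        v_min[i] = float(vs.min())
        train = detect_spikes(res.t[sel], vs, thr, refr)
        if len(train) >= min_spikes:
            exists[i] = True
            period[i] = float(np.mean(train.isis))
    return LimitCycleBranch(sweep_param=sweep_param, direction=direction,
                            params_values=values, v_max=v_max, v_min=v_min,
                            period=period, exists=exists)


def _sweep_protocol(sweep_param, lam, fixed_other, duration):
    if sweep_param == "I_S":
        return StimulusProtocol(duration=duration, soma=step(lam),
                                dend=step(fixed_other) if fixed_other else zero())
    return StimulusProtocol(duration=duration,
                            soma=step(fixed_other) if fixed_other else zero(),
                            dend=step(lam))


def _sqrt_scaling_fit(lc: LimitCycleBranch, param_c: float, n_points: int = 6):
    """Log-log slope of f(param) near onset against (param - param_c)."""
    mask = lc.exists & (lc.params_values > param_c)
    lam = lc.params_values[mask]
    per = lc.period[mask]
    order = np.argsort(lam)
    lam, per = lam[order][:n_points], per[order][:n_points]
    if lam.size < 3:
        return None
    f = 1000.0 / per
    fit = linregress(np.log(lam - param_c), np.log(f))
    return {"exponent": float(fit.slope), "r2": float(fit.rvalue ** 2),
            "n_points": int(lam.size)}


def _sho_period_fit(lc: LimitCycleBranch, n_points: int = 8):
    """Fit period ~ a - b*log(param - param_c) at the down-sweep boundary.

    ``param_c`` is chosen within one sweep step below the last surviving
    value to maximize R²; a logarithmic divergence is the SHO signature.
    """
    idx = np.nonzero(lc.exists)[0]
    if idx.size < 4:
        return None
    lam_all = lc.params_values[idx]
    boundary = lam_all.min()
    stp = np.abs(np.median(np.diff(lc.params_values))) or 1.0
    sel = idx[np.argsort(lam_all)][:n_points]
    lam = lc.params_values[sel]
    per = lc.period[sel]

    best = None
    for frac in np.linspace(0.05, 0.999, 60):
        param_c = boundary - frac * stp
        x = -np.log(lam - param_c)
        fit = linregress(x, per)
        r2 = fit.rvalue ** 2
        if best is None or r2 > best["r2"]:
            best = {"param_c": float(param_c), "slope": float(fit.slope),
                    "r2": float(r2), "boundary": float(boundary),
                    "n_points": int(lam.size)}
    return best


def classify_onset(eq: EquilibriumBranch, lc_up: LimitCycleBranch,
                   lc_down: LimitCycleBranch, step_size: float | None = None,
                   ) -> list[BifurcationEvent]:
    """Label the transition(s) from rest to spiking.

    Evidence combined: fold position on the equilibrium branch, coincidence
    of the up-sweep cycle onset with that fold, sqrt scaling of the rate
    above onset, bistability between the sweeps, and period divergence at
    the down-sweep boundary.
    """
    if step_size is None:
        diffs = np.abs(np.diff(lc_up.params_values))
        step_size = float(np.median(diffs)) if diffs.size else 1.0
    events: list[BifurcationEvent] = []
    fold = eq.folds[0] if eq.folds else None
    onset_up = lc_up.onset_param()
    onset_dn = lc_down.onset_param()   # in sweep order: largest surviving value

    if fold is None or onset_up is None:
        events.append(BifurcationEvent(
            param=float("nan"), kind="unclassified",
            evidence={"reason": "missing fold or cycle onset",
                      "fold": fold and fold["param"], "onset_up": onset_up}))
        return events

    lam_fold = fold["param"]
    down_exists = lc_down.params_values[lc_down.exists]
    lowest_down = float(down_exists.min()) if down_exists.size else None
    bistable_width = (lam_fold - lowest_down) if lowest_down is not None else 0.0
    onset_coincides = abs(onset_up - lam_fold) <= step_size * 1.5

    if onset_coincides and bistable_width <= step_size:
        scal = _sqrt_scaling_fit(lc_up, param_c=lam_fold)
        ev = {"fold_param": lam_fold, "onset_up": onset_up,
              "min_abs_eig_at_fold": fold["min_abs_eig"],
              "scaling": scal, "bistable_width": bistable_width}
        if scal is not None and abs(scal["exponent"] - 0.5) <= 0.1:
            events.append(BifurcationEvent(param=lam_fold, kind="SNIC", evidence=ev))
        else:
            events.append(BifurcationEvent(param=lam_fold, kind="unclassified",
                                           evidence=ev))
        return events

    if lowest_down is not None and bistable_width > step_size:
        events.append(BifurcationEvent(
            param=lam_fold, kind="SN",
            evidence={"fold_param": lam_fold, "onset_up": onset_up,
                      "min_abs_eig_at_fold": fold["min_abs_eig"],
                      "bistable_interval": (lowest_down, lam_fold)}))
        sho = _sho_period_fit(lc_down)
        if sho is not None and sho["r2"] > 0.95 and sho["slope"] > 0:
            events.append(BifurcationEvent(param=sho["boundary"],
                                           kind="SHO_onset", evidence=sho))
        else:
            events.append(BifurcationEvent(
                param=lowest_down, kind="unclassified",
                evidence={"reason": "no clear period divergence", "fit": sho}))
        return events

    events.append(BifurcationEvent(
        param=lam_fold, kind="unclassified",
        evidence={"fold_param": lam_fold, "onset_up": onset_up,
                  "onset_down": onset_dn, "bistable_width": bistable_width}))
    return events
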