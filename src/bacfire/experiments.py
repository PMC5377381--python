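"""Protocol-level experiments: f–I curves, rheobase, response maps, BAC
facilitation, pulse-evoked Ca²⁺ spikes, and extended-model bursting.

Every experiment simulates from the resting state at zero input, applies a
step or pulse after a settling delay, and analyses the stimulus-on window,
so the initial burst is part of the measured rate — the average rate jumps
at a discontinuous onset rather than being smoothed away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import NoStableRestingState, SimulationResult, find_resting_state, integrate
from .parameters import ModelParameters
from .protocols import SolverSettings, StimulusProtocol, pulse, step, zero
from .spikes import (BurstSummary, CaSpikeEvent, detect_ca_spikes, detect_spikes,
                     summarize_burst)

__all__ = [
    "FICurve", "ResponseMap", "BACReport", "PulseReport",
    "fi_curve", "rheobase", "two_param_map", "bac_firing_protocol",
    "pulse_protocol", "run_step",
]

_DEFAULT_ONSET = 100.0      # ms of settling before the step
_DEFAULT_STIM = 1000.0      # ms of stimulus-on analysis window


def run_step(model: str, params: ModelParameters, I_S: float, I_D: float,
             stim_duration: float = _DEFAULT_STIM, onset: float = _DEFAULT_ONSET,
             tail: float = 0.0, settings: SolverSettings | None = None,
             initial=None) -> SimulationResult:
    """One step-stimulus simulation from rest (the building block here)."""
    proto = StimulusProtocol(
        duration=onset + stim_duration + tail,
        soma=step(I_S, onset) if I_S != 0.0 else zero(),
        dend=step(I_D, onset) if I_D != 0.0 else zero())
    if initial is None:
        initial = find_resting_state(model, params, 0.0, 0.0)
    return integrate(model, params, proto, initial, settings or SolverSettings(output_dt=0.05))


def _stim_train(result: SimulationResult):
    t0, t1 = result.protocol.stimulus_window()
    a = result.params.analysis
    return detect_spikes(result.t, result.V_S, a.spike_threshold,
                         a.spike_refractory, window=(t0, t1))


@dataclass
class FICurve:
    """Average-rate transfer curve for one injection site."""

    site: str                      # "soma" or "dendrite"
    amplitudes: np.ndarray         # µA/cm², ascending
    f_S: np.ndarray                # Hz
    continuity_cutoff: float = 5.0
    onset_amplitude: float | None = field(init=False)
    continuity: str = field(init=False)

    def __post_init__(self) -> None:
        nz = np.nonzero(self.f_S > 0)[0]
        self.onset_amplitude = float(self.amplitudes[nz[0]]) if nz.size else None
        if nz.size == 0:
            self.continuity = "undefined"
        else:
            self.continuity = ("continuous"
                               if float(np.min(self.f_S[nz])) < self.continuity_cutoff
                               else "discontinuous")

    @property
    def min_nonzero_rate(self) -> float | None:
        nz = self.f_S[self.f_S > 0]
        return float(nz.min()) if nz.size else None


def fi_curve(model: str, params: ModelParameters, site: str,
             amplitudes, fixed_other_input: float = 0.0,
             stim_duration: float = _DEFAULT_STIM,
             settings: SolverSettings | None = None) -> FICurve:
    """f_S–I curve: one simulation from rest per amplitude.

    The curve classifies as continuous when its smallest nonzero rate falls
    below the registry cutoff — the operational form of "able to fire
    low-frequency APs".
    """
    if site not in ("soma", "dendrite"):
        raise ValueError("site must be 'soma' or 'dendrite'")
    amplitudes = np.asarray(sorted(amplitudes), dtype=float)
    rest = find_resting_state(model, params, 0.0, 0.0)
    rates = np.empty(amplitudes.size)
    for i, amp in enumerate(amplitudes):
        I_S, I_D = (amp, fixed_other_input) if site == "soma" else (fixed_other_input, amp)
        res = run_step(model, params, I_S, I_D, stim_duration,
                       settings=settings, initial=rest)
        rates[i] = _stim_train(res).f_S
    return FICurve(site=site, amplitudes=amplitudes, f_S=rates,
                   continuity_cutoff=params.analysis.fi_continuity_cutoff)


def rheobase(model: str, params: ModelParameters, site: str,
             fixed_other_input: float = 0.0, tolerance: float = 0.05,
             bracket: tuple[float, float] = (0.0, 100.0),
             stim_duration: float = 600.0,
             settings: SolverSettings | None = None) -> float:
    """Minimal step amplitude eliciting at least one AP, by bisection.

    The bracket is expanded geometrically (up to 2⁶×) if the upper edge is
    still subthreshold; failure to find a spiking amplitude raises.
    """
    if site not in ("soma", "dendrite"):
        raise ValueError("site must be 'soma' or 'dendrite'")
    rest = find_resting_state(model, params, 0.0, 0.0)

    def spikes_at(amp: float) -> bool:
        I_S, I_D = (amp, fixed_other_input) if site == "soma" else (fixed_other_input, amp)
        res = run_step(model, params, I_S, I_D, stim_duration,
                       settings=settings, initial=rest)
        return len(_stim_train(res)) >= 1

    lo, hi = float(bracket[0]), float(bracket[1])
    expansions = 0
    while not spikes_at(hi):
        lo, hi = hi, hi + 2.0 * (hi - lo)
        expansions += 1
        if expansions > 6:
            raise RuntimeError(f"no spiking found up to amplitude {hi}")
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class ResponseMap:
    """f_S and event masks over an (I_S, I_D) grid."""

    I_S_grid: np.ndarray
    I_D_grid: np.ndarray
    f_S: np.ndarray                # (n_IS, n_ID)
    ca_spike_mask: np.ndarray      # bool, same shape
    ap_mask: np.ndarray


def two_param_map(model: str, params: ModelParameters, I_S_grid, I_D_grid,
                  stim_duration: float = 600.0,
                  settings: SolverSettings | None = None) -> ResponseMap:
    """Simulate every (I_S, I_D) node from rest; rates and masks come from
    the same simulations."""
    I_S_grid = np.asarray(I_S_grid, dtype=float)
    I_D_grid = np.asarray(I_D_grid, dtype=float)
    rest = find_resting_state(model, params, 0.0, 0.0)
    shape = (I_S_grid.size, I_D_grid.size)
    f_S = np.zeros(shape)
    ca_mask = np.zeros(shape, dtype=bool)
    ap_mask = np.zeros(shape, dtype=bool)
    for i, i_s in enumerate(I_S_grid):
        for j, i_d in enumerate(I_D_grid):
            if i_s == 0.0 and i_d == 0.0:
                continue
            res = run_step(model, params, i_s, i_d, stim_duration,
                           settings=settings, initial=rest)
            train = _stim_train(res)
            f_S[i, j] = train.f_S
            ap_mask[i, j] = len(train) >= 1
            ca_mask[i, j] = len(detect_ca_spikes(res)) >= 1
    return ResponseMap(I_S_grid=I_S_grid, I_D_grid=I_D_grid, f_S=f_S,
                       ca_spike_mask=ca_mask, ap_mask=ap_mask)


@dataclass
class BACReport:
    """Ca²⁺-spike thresholds with and without coincident somatic drive."""

    I_S_values: np.ndarray
    ca_spike_at_moderate_I_D: np.ndarray   # bool per I_S
    threshold_solo: float                  # I_D threshold at I_S = 0
    threshold_coincident: float            # I_D threshold at suprathreshold I_S
    I_S_coincident: float

    @property
    def facilitation(self) -> float:
        """Drop of the Ca²⁺-spike I_D threshold caused by somatic drive."""
        return self.threshold_solo - self.threshold_coincident


def _ca_threshold(model, params, I_S, tolerance=0.25, bracket=(0.0, 120.0),
                  stim_duration=600.0, settings=None, rest=None):
    if rest is None:
        rest = find_resting_state(model, params, 0.0, 0.0)

    def has_ca(i_d):
        res = run_step(model, params, I_S, i_d, stim_duration,
                       settings=settings, initial=rest)
        return len(detect_ca_spikes(res)) >= 1

    lo, hi = bracket
    if not has_ca(hi):
        raise RuntimeError(f"no Ca spike up to I_D={hi} at I_S={I_S}")
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if has_ca(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def bac_firing_protocol(model: str, params: ModelParameters,
                        I_D_moderate: float, I_S_values,
                        I_S_coincident: float | None = None,
                        stim_duration: float = 600.0,
                        settings: SolverSettings | None = None) -> BACReport:
    """Back-propagation-activated Ca²⁺-spike facilitation.

    For each I_S the report records whether a Ca²⁺ spike occurs at the
    moderate (solo-subthreshold) I_D, and compares the Ca²⁺-spike I_D
    threshold with and without a coincident suprathreshold somatic step.
    """
    I_S_values = np.asarray(I_S_values, dtype=float)
    rest = find_resting_state(model, params, 0.0, 0.0)
    occurs = np.zeros(I_S_values.size, dtype=bool)
    for i, i_s in enumerate(I_S_values):
        res = run_step(model, params, i_s, I_D_moderate, stim_duration,
                       settings=settings, initial=rest)
        occurs[i] = len(detect_ca_spikes(res)) >= 1
    if I_S_coincident is None:
        I_S_coincident = float(I_S_values.max())
    thr_solo = _ca_threshold(model, params, 0.0, stim_duration=stim_duration,
                             settings=settings, rest=rest)
    thr_coin = _ca_threshold(model, params, I_S_coincident,
                             stim_duration=stim_duration, settings=settings,
                             rest=rest)
    return BACReport(I_S_values=I_S_values, ca_spike_at_moderate_I_D=occurs,
                     threshold_solo=thr_solo, threshold_coincident=thr_coin,
                     I_S_coincident=I_S_coincident)


@dataclass
class PulseReport:
    """Outcome of a brief dendritic pulse."""

    ca_events: list[CaSpikeEvent]
    n_spikes: int
    burst: BurstSummary | None
    transient_burst: bool          # >=3 APs confined to the Ca-spike episode
    returned_to_rest: bool
    final_V_S_deviation: float     # mV from rest over the final 200 ms
    pulse_end: float               # ms


def pulse_protocol(model: str, params: ModelParameters, amplitude: float,
                   pulse_duration: float = 20.0, onset: float = 50.0,
                   total: float = 1000.0,
                   settings: SolverSettings | None = None) -> PulseReport:
    """A single brief dendritic pulse: does one Ca²⁺ spike outlast it?

    Reports the detected Ca²⁺-spike episodes, the somatic burst summary,
    and whether V_S returns to within 1 mV of rest over the final 200 ms.
    """
    rest = find_resting_state(model, params, 0.0, 0.0)
    proto = StimulusProtocol(duration=total,
                             dend=pulse(amplitude, onset, pulse_duration))
    res = integrate(model, params, proto, rest,
                    settings or SolverSettings(output_dt=0.05))
    events = detect_ca_spikes(res)
    a = params.analysis
    train = detect_spikes(res.t, res.V_S, a.spike_threshold, a.spike_refractory)
    burst = None
    if len(train) >= 3:
        t_spk = train.times
        burst = summarize_burst(
            type(train)(times=t_spk, window=(float(t_spk[0]), float(t_spk[-1]))),
            adapting_ratio=a.burst_adapting_ratio)
    tail = res.t >= total - 200.0
    dev = float(np.max(np.abs(res.V_S[tail] - rest[0])))
    returned = dev < 1.0
    # a transient burst: several APs riding the Ca spike, silence afterwards
    transient = bool(len(train) >= 3 and events
                     and train.times[0] >= onset
                     and train.times[-1] <= events[-1].offset + 20.0
                     and returned)
    return PulseReport(ca_events=events, n_spikes=len(train), burst=burst,
                       transient_burst=transient,
                       returned_to_rest=returned, final_V_S_deviation=dev,
                       pulse_end=onset + pulse_duration)
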