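"""Detection and quantification of somatic APs and dendritic Ca²⁺ spikes.

Somatic spikes are upward threshold crossings of V_S with a refractory
guard; the instantaneous rate f_inst is the reciprocal of each interspike
interval, and the average rate f_S is count-based over the analysis window.
A dendritic Ca²⁺-spike episode is a maximal interval in which the dendrite
is both depolarized above a voltage threshold and carrying appreciable Ca²⁺
current, so passive depolarizations are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SimulationResult

__all__ = [
    "SpikeTrain", "CaSpikeEvent", "BurstSummary",
    "detect_spikes", "average_rate", "detect_ca_spikes", "summarize_burst",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Detected somatic APs within an analysis window."""

    times: np.ndarray             # ms, strictly increasing
    window: tuple[float, float]   # ms

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def f_inst(self) -> np.ndarray:
        """Instantaneous rate, one value per ISI (Hz)."""
        return 1000.0 / self.isis

    @property
    def f_S(self) -> float:
        """Count-based average rate over the window (Hz)."""
        return average_rate(self, self.window)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CaSpikeEvent:
    """One dendritic Ca²⁺-spike episode."""

    onset: float                  # ms
    offset: float
    peak_abs_I_Ca: float          # µA/cm²
    peak_V_D: float               # mV

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class BurstSummary:
    """Peak-versus-plateau structure of the instantaneous rate."""

    peak_f_inst: float            # Hz
    plateau_f_inst: float         # Hz, mean over final quarter of the window
    time_of_peak: float           # ms
    adapting_ratio: float = 1.5   # flag threshold on peak/plateau
    adapting: bool = field(init=False)

    @property
    def ratio(self) -> float:
        return self.peak_f_inst / self.plateau_f_inst

    def __post_init__(self) -> None:
        object.__setattr__(self, "adapting", self.ratio > self.adapting_ratio)


def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float = 0.0,
                  refractory: float = 2.0,
                  window: tuple[float, float] | None = None) -> SpikeTrain:
    """Somatic APs as upward threshold crossings on a uniformly sampled trace.

    Crossing times are refined by linear interpolation between samples; a
    crossing closer than ``refractory`` to the previous accepted spike is
    discarded.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size == 0 or v.size == 0:
        raise ValueError("empty trace")
    idx = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    times = t[idx] + (threshold - v[idx]) / (v[idx + 1] - v[idx]) * (t[idx + 1] - t[idx])
    accepted = []
    for ts in times:
        if not accepted or ts - accepted[-1] >= refractory:
            accepted.append(ts)
    times = np.asarray(accepted)
    if window is None:
        window = (float(t[0]), float(t[-1]))
    else:
        times = times[(times >= window[0]) & (times <= window[1])]
    return SpikeTrain(times=times, window=window)


def average_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Count-based firing rate over ``window`` (Hz)."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("zero-length analysis window")
    count = int(np.count_nonzero((train.times >= t0) & (train.times <= t1)))
    return count / (t1 - t0) * 1000.0


def detect_ca_spikes(result: SimulationResult,
                     vd_threshold: float | None = None,
                     ica_floor: float | None = None,
                     merge_gap: float | None = None) -> list[CaSpikeEvent]:
    """Dendritic Ca²⁺-spike episodes in a simulation result.

    An episode is a maximal interval with ``V_D > vd_threshold`` and
    ``|I_Ca| > ica_floor`` simultaneously; episodes separated by less than
    ``merge_gap`` are merged.  Defaults come from the parameter registry.
    With ``g_Ca = 0`` the current criterion can never hold and the list is
    empty.
    """
    a = result.params.analysis
    vd_threshold = a.ca_spike_vd_threshold if vd_threshold is None else vd_threshold
    ica_floor = a.ca_spike_ica_floor if ica_floor is None else ica_floor
    merge_gap = a.ca_spike_merge_gap if merge_gap is None else merge_gap

    t, vd, ica = result.t, result.V_D, result.I_Ca
    active = (vd > vd_threshold) & (np.abs(ica) > ica_floor)
    if not active.any():
        return []
    edges = np.diff(active.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)   # exclusive
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(len(active))
    # merge episodes separated by short gaps
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if t[s] - t[merged[-1][1] - 1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        events.append(CaSpikeEvent(
            onset=float(t[s]), offset=float(t[e - 1]),
            peak_abs_I_Ca=float(np.max(np.abs(ica[s:e]))),
            peak_V_D=float(np.max(vd[s:e]))))
    return events


def summarize_burst(train: SpikeTrain, adapting_ratio: float = 1.5) -> BurstSummary:
    """Peak and plateau of f_inst over the train's analysis window.

    The plateau is the mean of the f_inst values whose ISIs end in the final
    quarter of the window; the train is flagged adapting when the
    peak-to-plateau ratio exceeds 1.5.
    """
    if len(train) < 3:
        raise ValueError("insufficient spikes: need at least 3")
    f = train.f_inst
    ends = train.times[1:]
    t0, t1 = train.window
    tail = f[ends >= t1 - (t1 - t0) / 4.0]
    if tail.size == 0:
        tail = f[-1:]
    peak_idx = int(np.argmax(f))
    return BurstSummary(peak_f_inst=float(f[peak_idx]),
                        plateau_f_inst=float(tail.mean()),
                        time_of_peak=float(ends[peak_idx]),
                        adapting_ratio=adapting_ratio)
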