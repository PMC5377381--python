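"""Stimulus protocols and solver settings.

A protocol assigns one waveform per injection site (soma, dendrite): a step
(constant from onset), a rectangular pulse, or nothing.  Waveform
discontinuities are exposed as breakpoints so the integrator can restart
exactly at them instead of smoothing through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Waveform", "step", "pulse", "zero", "StimulusProtocol", "SolverSettings"]


@dataclass(frozen=True)
class Waveform:
    """Piecewise-constant injected current (µA/cm²)."""

    kind: str = "zero"            # zero | step | pulse
    amplitude: float = 0.0
    onset: float = 0.0            # ms
    duration: float | None = None  # ms, pulses only

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "step", "pulse"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.kind == "pulse" and (self.duration is None or self.duration <= 0):
            raise ValueError("pulse duration must be positive")

    def value(self, t: float) -> float:
        if self.kind == "zero" or t < self.onset:
            return 0.0
        if self.kind == "pulse" and t >= self.onset + self.duration:
            return 0.0
        return self.amplitude

    def breakpoints(self) -> list[float]:
        if self.kind == "zero":
            return []
        if self.kind == "step":
            return [self.onset]
        return [self.onset, self.onset + self.duration]

    @property
    def offset(self) -> float:
        """End of the driven interval (inf for steps)."""
        if self.kind == "zero":
            return 0.0
        if self.kind == "step":
            return np.inf
        return self.onset + self.duration


def step(amplitude: float, onset: float = 0.0) -> Waveform:
    return Waveform("step", amplitude, onset)


def pulse(amplitude: float, onset: float, duration: float) -> Waveform:
    return Waveform("pulse", amplitude, onset, duration)


def zero() -> Waveform:
    return Waveform("zero")


@dataclass(frozen=True)
class StimulusProtocol:
    """Injected currents for one run: ``I_S(t)`` somatic, ``I_D(t)`` dendritic."""

    duration: float               # ms, total simulated span
    soma: Waveform = field(default_factory=zero)
    dend: Waveform = field(default_factory=zero)

    def __post_init__(self) -> None:
        largest_onset = max(self.soma.onset, self.dend.onset)
        if self.duration <= largest_onset:
            raise ValueError("total duration must exceed the largest onset")

    def currents(self, t: float) -> tuple[float, float]:
        return self.soma.value(t), self.dend.value(t)

    def breakpoints(self) -> np.ndarray:
        pts = [b for wf in (self.soma, self.dend) for b in wf.breakpoints()
               if 0.0 < b < self.duration]
        return np.unique(np.asarray(pts, dtype=float))

    def stimulus_window(self) -> tuple[float, float]:
        """Interval over which any site is driven (used as the f_S window)."""
        on = []
        off = []
        for wf in (self.soma, self.dend):
            if wf.kind != "zero" and wf.amplitude != 0.0:
                on.append(wf.onset)
                off.append(min(wf.offset, self.duration))
        if not on:
            return 0.0, self.duration
        return min(on), max(off)


@dataclass(frozen=True)
class SolverSettings:
    """Integration accuracy contract.

    An adaptive explicit 2nd/3rd-order pair (Bogacki–Shampine) controls the
    local error at ``rel_tol``/``abs_tol``; the trajectory is reported on a
    uniform ``output_dt`` grid via dense output.  The 0.01 ms default grid
    matches the resolution the analyses are quoted at.  ``max_step`` keeps
    the explicit pair inside its linear stability region near equilibria
    (the fastest relaxation rate at rest is a few 1/ms), so a trajectory
    started at an equilibrium stays there to roundoff.
    """

    method: str = "RK23"
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    max_step: float = 0.25        # ms, see note above
    output_dt: float = 0.01       # ms

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.output_dt <= 0 or self.max_step <= 0:
            raise ValueError("output_dt and max_step must be positive")
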