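"""Parameter registry for the two-compartment pyramidal-neuron model.

Every numeric constant of the model — conductances, reversal potentials,
capacitance, the coupling conductance ``g_c``, the morphological fraction
``p``, and all gating-kinetics constants — lives in a single flat-key JSON
registry (``data/default_params.json``).  The dataclasses below are the typed
in-memory view of that registry.  Units are mV, ms, µA/cm², mS/cm² and µF/cm²
throughout; no operation performs unit conversion.

The intracellular Ca²⁺ concentration of the extended model is kept in the
dimensionless internal units of the Pinsky–Rinzel calcium pool and is never
converted to molar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "SomaticParameters",
    "DendriticParameters",
    "CouplingParameters",
    "ExtendedParameters",
    "AnalysisDefaults",
    "ModelParameters",
    "default_parameters",
    "load_parameters",
    "dump_parameters",
]


@dataclass(frozen=True)
class SomaticParameters:
    """Somatic chamber: fast Na⁺, delayed-rectifier-like slow K⁺, leak.

    The Na⁺ activation is instantaneous (``m = m_inf(V_S)``); the slow K⁺
    gate ``w`` relaxes to ``w_inf(V_S)`` with voltage-dependent time constant
    ``tau_w(V_S) = tau_w_base / cosh((V_S - w_half) / (2 w_slope))``.
    Steady states are the symmetric tanh sigmoids
    ``x_inf(V) = 0.5 (1 + tanh((V - x_half) / x_slope))``.
    """

    C_m: float = 2.0          # µF/cm²
    g_Na: float = 20.0        # mS/cm²
    E_Na: float = 50.0        # mV
    g_K: float = 20.0
    E_K: float = -100.0
    g_SL: float = 2.0
    E_SL: float = -70.0
    m_half: float = -1.2      # mV, midpoint of m_inf
    m_slope: float = 18.0     # mV
    w_half: float = 0.0
    w_slope: float = 10.0
    tau_w_base: float = 20.0 / 3.0   # ms, peak of tau_w(V)

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        for name in ("g_Na", "g_K", "g_SL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.E_Na > self.E_K:
            raise ValueError("E_Na must exceed E_K")
        if self.tau_w_base <= 0 or self.m_slope <= 0 or self.w_slope <= 0:
            raise ValueError("slopes and tau_w_base must be positive")


@dataclass(frozen=True)
class DendriticParameters:
    """Dendritic chamber: high-threshold Ca²⁺ current and leak.

    The Ca²⁺ current ``I_Ca = g_Ca n h (V_D - E_Ca)`` carries a first-order
    activation gate ``n`` (logistic ``n_inf``, rising) and inactivation gate
    ``h`` (logistic ``h_inf``, falling), each with a constant time constant.
    ``g_Ca = 0`` is a valid setting and means the channel is blocked.
    """

    g_Ca: float = 3.0
    E_Ca: float = 120.0
    g_DL: float = 2.0
    E_DL: float = -70.0
    n_half: float = 0.0
    n_slope: float = 3.0
    tau_n: float = 4.0        # ms
    h_half: float = -15.0
    h_slope: float = 8.0
    tau_h: float = 150.0      # ms

    def __post_init__(self) -> None:
        if self.g_Ca < 0 or self.g_DL < 0:
            raise ValueError("conductances must be non-negative")
        if self.tau_n <= 0 or self.tau_h <= 0:
            raise ValueError("tau_n and tau_h must be positive")
        if self.n_slope <= 0 or self.h_slope <= 0:
            raise ValueError("sigmoid slopes must be positive")


@dataclass(frozen=True)
class CouplingParameters:
    """Internal coupling between the chambers.

    ``I_DS = g_c (V_D - V_S)`` is the internal current through ``g_c``; the
    somatic balance divides coupling and injected terms by the somatic area
    fraction ``p``, the dendritic balance by ``1 - p``.
    """

    g_c: float = 1.0
    p: float = 0.5

    def __post_init__(self) -> None:
        if self.g_c <= 0:
            raise ValueError("g_c must be positive")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie strictly between 0 and 1")


@dataclass(frozen=True)
class ExtendedParameters:
    """Ca²⁺ pool and Ca²⁺-activated K⁺ currents (Pinsky–Rinzel kinetics).

    ``I_KC = g_KC c chi([Ca]) (V_D - E_K)`` with ``chi([Ca]) =
    min([Ca]/chi_saturation, 1)``; ``I_KAHP = g_KAHP q (V_D - E_K)``.
    ``d[Ca]/dt = -ca_influx_scale * I_Ca - ca_decay * [Ca]``.  The
    Pinsky–Rinzel rate functions for ``c`` are expressed in a voltage frame
    whose rest sits at 0 mV; ``v_shift`` maps this model's dendritic voltage
    into that frame (``V_PR = V_D + v_shift``).
    """

    g_KC: float = 5.0
    g_KAHP: float = 3.0
    E_K: float = -100.0
    ca_influx_scale: float = 0.02
    ca_decay: float = 0.075           # 1/ms
    chi_saturation: float = 250.0     # [Ca] units
    v_shift: float = 60.0             # mV
    alpha_q_scale: float = 2.0e-5     # 1/(ms·[Ca])
    alpha_q_max: float = 0.01         # 1/ms
    beta_q: float = 0.001             # 1/ms

    def __post_init__(self) -> None:
        if self.g_KC < 0 or self.g_KAHP < 0:
            raise ValueError("g_KC and g_KAHP must be non-negative")
        if self.ca_decay < 0:
            raise ValueError("ca_decay must be non-negative")
        if self.chi_saturation <= 0:
            raise ValueError("chi_saturation must be positive")


@dataclass(frozen=True)
class AnalysisDefaults:
    """Registry defaults for the detection/classification thresholds."""

    spike_threshold: float = 0.0       # mV
    spike_refractory: float = 2.0      # ms
    ca_spike_vd_threshold: float = -25.0
    ca_spike_ica_floor: float = 2.0    # µA/cm²
    ca_spike_merge_gap: float = 2.0    # ms
    fi_continuity_cutoff: float = 5.0  # Hz
    burst_adapting_ratio: float = 1.5


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set; ``extended`` is None for the 5D model."""

    soma: SomaticParameters = field(default_factory=SomaticParameters)
    dend: DendriticParameters = field(default_factory=DendriticParameters)
    coupling: CouplingParameters = field(default_factory=CouplingParameters)
    extended: ExtendedParameters | None = None
    analysis: AnalysisDefaults = field(default_factory=AnalysisDefaults)

    def with_g_ca(self, g_Ca: float) -> "ModelParameters":
        """Copy with a different dendritic Ca²⁺ conductance."""
        return replace(self, dend=replace(self.dend, g_Ca=g_Ca))

    def with_extended(self, **kwargs) -> "ModelParameters":
        ext = self.extended if self.extended is not None else ExtendedParameters()
        return replace(self, extended=replace(ext, **kwargs))

    # -- packed float vectors consumed by the compiled right-hand sides --

    def pack_5d(self) -> np.ndarray:
        s, d, c = self.soma, self.dend, self.coupling
        return np.array(
            [s.C_m, s.g_Na, s.E_Na, s.m_half, s.m_slope,
             s.g_K, s.E_K, s.w_half, s.w_slope, s.tau_w_base,
             s.g_SL, s.E_SL, c.g_c, c.p,
             d.g_Ca, d.E_Ca, d.g_DL, d.E_DL,
             d.n_half, d.n_slope, d.tau_n, d.h_half, d.h_slope, d.tau_h],
            dtype=np.float64,
        )

    def pack_extended(self) -> np.ndarray:
        if self.extended is None:
            raise ValueError("parameter set has no 'extended' section")
        e = self.extended
        tail = np.array(
            [e.g_KC, e.g_KAHP, e.E_K, e.ca_influx_scale, e.ca_decay,
             e.chi_saturation, e.v_shift, e.alpha_q_scale, e.alpha_q_max,
             e.beta_q],
            dtype=np.float64,
        )
        return np.concatenate([self.pack_5d(), tail])


_SECTIONS = {
    "soma": SomaticParameters,
    "dend": DendriticParameters,
    "coupling": CouplingParameters,
    "extended": ExtendedParameters,
    "analysis": AnalysisDefaults,
}


def _from_flat(flat: dict) -> ModelParameters:
    buckets: dict[str, dict] = {name: {} for name in _SECTIONS}
    for key, value in flat.items():
        if key.startswith("_"):
            continue
        try:
            section, name = key.split(".", 1)
        except ValueError:
            raise KeyError(f"malformed registry key {key!r}; expected 'section.name'")
        if section not in _SECTIONS:
            raise KeyError(f"unknown registry section {section!r} in key {key!r}")
        valid = {f.name for f in fields(_SECTIONS[section])}
        if name not in valid:
            raise KeyError(f"unknown registry key {key!r}")
        buckets[section][name] = float(value)
    extended = ExtendedParameters(**buckets["extended"]) if buckets["extended"] else None
    return ModelParameters(
        soma=SomaticParameters(**buckets["soma"]),
        dend=DendriticParameters(**buckets["dend"]),
        coupling=CouplingParameters(**buckets["coupling"]),
        extended=extended,
        analysis=AnalysisDefaults(**buckets["analysis"]),
    )


def default_parameters(extended: bool = True) -> ModelParameters:
    """Load the packaged default registry.

    Parameters
    ----------
    extended
        If False, drop the ``extended`` section so the set describes the
        plain 5D model.
    """
    text = resources.files("bacfire.data").joinpath("default_params.json").read_text()
    params = _from_flat(json.loads(text))
    if not extended:
        params = replace(params, extended=None)
    return params


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a flat-key JSON parameter file.

    Unknown keys are rejected so that transcription errors surface loudly.
    Absence of every ``extended.*`` key means the 5D model.
    """
    with open(path) as fh:
        return _from_flat(json.load(fh))


def dump_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set back out as a flat-key JSON file."""
    flat: dict[str, float] = {}
    for section_name, cls in _SECTIONS.items():
        obj = getattr(params, section_name)
        if obj is None:
            continue
        for f in fields(cls):
            flat[f"{section_name}.{f.name}"] = getattr(obj, f.name)
    with open(path, "w") as fh:
        json.dump(flat, fh, indent=2)
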