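{
  "_comment": "Default parameter registry for the two-compartment pyramidal-neuron model. Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2. [Ca] and the chi saturation constant are in the dimensionless internal units of the Pinsky-Rinzel calcium pool. Every numeric constant of the model lives here; code never hard-codes them.",
  "_changelog": [
    "v1: somatic compartment transcribed from the Morris-Lecar-type reduction used by the reduced Pinsky-Rinzel two-compartment family (instantaneous Na+ activation, single slow K+ gate); w_half chosen so that somatic onset is a saddle-node on invariant circle in the coupled model.",
    "v1: dendritic Ca2+ channel uses first-order Boltzmann activation n and inactivation h (Larkum-style HVA kinetics); half-activation/slope/time constants chosen so that the Ca2+-spike threshold sits above the subthreshold dendritic operating range, making the somatic-AP threshold independent of g_Ca.",
    "v1: I_KC, I_KAHP, chi([Ca]) and the [Ca] pool are exact transcriptions of the Pinsky-Rinzel 1994 rate functions; their voltage convention (rest at 0 mV) is mapped onto this model's mV scale by the extended.v_shift offset.",
    "v2: the divisor of the low-voltage alpha_c branch is taken as exp(40/11)/2 = 18.97644..., the exact value at which the two Pinsky-Rinzel branches join continuously, instead of their rounded 18.975 (which leaves a 4e-5 jump and a slightly negative beta_c near the branch point).",
    "v2: g_KC, g_KAHP and the [Ca] influx scale are rescaled from the Pinsky-Rinzel originals (15, 0.8, 0.13) because this model's I_Ca density and dendritic load differ from theirs; the values chosen place the constant-apical-drive regime in periodic bursting with multi-spike bursts separated by long quiescent gaps."
  ],
  "soma.C_m": 2.0,
  "soma.g_Na": 20.0,
  "soma.E_Na": 50.0,
  "soma.g_K": 20.0,
  "soma.E_K": -100.0,
  "soma.g_SL": 2.0,
  "soma.E_SL": -70.0,
  "soma.m_half": -1.2,
  "soma.m_slope": 18.0,
  "soma.w_half": 0.0,
  "soma.w_slope": 10.0,
  "soma.tau_w_base": 6.666666666666667,
  "dend.g_Ca": 3.0,
  "dend.E_Ca": 120.0,
  "dend.g_DL": 2.0,
  "dend.E_DL": -70.0,
  "dend.n_half": 0.0,
  "dend.n_slope": 3.0,
  "dend.tau_n": 4.0,
  "dend.h_half": -15.0,
  "dend.h_slope": 8.0,
  "dend.tau_h": 150.0,
  "coupling.g_c": 1.0,
  "coupling.p": 0.5,
  "extended.g_KC": 5.0,
  "extended.g_KAHP": 3.0,
  "extended.E_K": -100.0,
  "extended.ca_influx_scale": 0.02,
  "extended.ca_decay": 0.075,
  "extended.chi_saturation": 250.0,
  "extended.v_shift": 60.0,
  "extended.alpha_q_scale": 2e-05,
  "extended.alpha_q_max": 0.01,
  "extended.beta_q": 0.001,
  "analysis.spike_threshold": 0.0,
  "analysis.spike_refractory": 2.0,
  "analysis.ca_spike_vd_threshold": -25.0,
  "analysis.ca_spike_ica_floor": 2.0,
  "analysis.ca_spike_merge_gap": 2.0,
  "analysis.fi_continuity_cutoff": 5.0,
  "analysis.burst_adapting_ratio": 1.5
}
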