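"""Apical drive with an active Ca2+ channel: burst then plateau.

A suprathreshold current step into the dendrite triggers a dendritic Ca2+
spike.  The inward Ca2+ current is funnelled to the soma through the
coupling conductance, so the instantaneous firing rate shoots to a peak and
then sags to a plateau as the Ca2+ current partially inactivates.
"""

import bacfire as bf

p = bf.default_parameters()

res = bf.run_step("5d", p, I_S=0.0, I_D=70.0, stim_duration=1500.0)
train = bf.detect_spikes(res.t, res.V_S, window=res.protocol.stimulus_window())
events = bf.detect_ca_spikes(res)
burst = bf.summarize_burst(train)

print(f"{len(train)} somatic APs, average rate f_S = {train.f_S:.1f} Hz")
print(f"dendritic Ca2+ spike episodes: {len(events)}; "
      f"peak |I_Ca| = {events[0].peak_abs_I_Ca:.0f} uA/cm^2, "
      f"peak V_D = {events[0].peak_V_D:.1f} mV")
print(f"f_inst peak {burst.peak_f_inst:.0f} Hz -> plateau "
      f"{burst.plateau_f_inst:.0f} Hz (ratio {burst.ratio:.2f}, "
      f"adapting burst: {burst.adapting})")
print("The peak/plateau structure is the somatic readout of the rise and "
      "sag of the dendritic Ca2+ current.")
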