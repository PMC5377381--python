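"""BAC firing: back-propagating APs lower the Ca2+-spike threshold.

Somatic APs invade the dendrite through the coupling conductance.  On their
own they never reach the Ca2+ activation threshold, but riding on a
moderate apical input they push V_D over it — so the apical current needed
to evoke a Ca2+ spike is much lower when the soma is also driven.
"""

import numpy as np

import bacfire as bf

p = bf.default_parameters()

rep = bf.bac_firing_protocol("5d", p, I_D_moderate=40.0,
                             I_S_values=np.array([0.0, 10.0, 20.0, 35.0, 50.0]),
                             stim_duration=500.0)
print("Ca2+ spike at I_D = 40 uA/cm^2 (solo-subthreshold) as I_S grows:")
for i_s, hit in zip(rep.I_S_values, rep.ca_spike_at_moderate_I_D):
    print(f"   I_S = {i_s:5.1f} -> Ca2+ spike: {bool(hit)}")
print(f"Ca2+-spike I_D threshold alone:       {rep.threshold_solo:.2f} uA/cm^2")
print(f"... with coincident I_S = {rep.I_S_coincident:.0f}:        "
      f"{rep.threshold_coincident:.2f} uA/cm^2")
print(f"facilitation by somatic drive:        {rep.facilitation:.2f} uA/cm^2")
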