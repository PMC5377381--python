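"""A brief apical pulse evokes a single regenerative Ca2+ spike.

The 20 ms pulse only seeds the event: the Ca2+ spike is all-or-none and
outlasts the pulse, driving a transient somatic burst before the dendrite
deactivates and the neuron settles back to rest.
"""

import bacfire as bf

p = bf.default_parameters()

for amp in (40.0, 100.0):
    rep = bf.pulse_protocol("5d", p, amplitude=amp, total=1000.0)
    print(f"20 ms dendritic pulse of {amp:.0f} uA/cm^2:")
    if not rep.ca_events:
        print("   subthreshold: no Ca2+ spike, "
              f"{rep.n_spikes} APs, back at rest: {rep.returned_to_rest}")
        continue
    ev = rep.ca_events[0]
    print(f"   {len(rep.ca_events)} Ca2+ spike, duration {ev.duration:.1f} ms "
          f"({ev.offset - rep.pulse_end:.1f} ms beyond the pulse)")
    print(f"   somatic burst of {rep.n_spikes} APs "
          f"(transient: {rep.transient_burst}); "
          f"returned to rest: {rep.returned_to_rest}")
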