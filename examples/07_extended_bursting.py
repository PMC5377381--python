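"""Extended model: periodic bursting under constant apical drive.

Adding the Ca2+ pool and the Ca2+-activated K+ currents I_KC/I_KAHP gives
each Ca2+ spike an afterhyperpolarizing tail: the burst terminates itself,
the AHP decays over hundreds of milliseconds, and the Ca2+ spike re-ignites
— so a constant apical step yields rhythmic multi-spike bursts.
"""

import numpy as np

import bacfire as bf

p = bf.default_parameters()

res = bf.run_step("extended", p, I_S=0.0, I_D=72.0, stim_duration=4000.0)
train = bf.detect_spikes(res.t, res.V_S)
groups = np.split(np.arange(len(train)),
                  np.nonzero(train.isis > 50.0)[0] + 1)
bursts = [g for g in groups if len(g) >= 2]
print(f"{len(train)} APs in 4 s of constant I_D = 72 uA/cm^2")
print(f"{len(bursts)} bursts, sizes {[len(g) for g in bursts]}")
gaps = [train.times[groups[k + 1][0]] - train.times[groups[k][-1]]
        for k in range(len(groups) - 1)]
print(f"interburst gaps: {np.round(gaps).astype(int).tolist()} ms")
print(f"peak [Ca] reached: {res['Ca'].max():.0f} (model units)")
print("Each burst is one dendritic Ca2+ spike terminated by the "
      "Ca2+-activated K+ currents.")
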