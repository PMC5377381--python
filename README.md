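# bacfire

A two-compartment conductance-based model of a cortical pyramidal neuron
with an active apical dendrite, together with the analysis apparatus needed
to dissect how dendritic Ca²⁺ spikes shape action-potential (AP) initiation:
stimulus protocols, adaptive integration, spike/burst/Ca²⁺-spike detection,
f–I curves, (I_S, I_D) response maps, frozen-drive phase-plane analysis, and
numerical bifurcation scans that distinguish SNIC, SN and saddle-homoclinic
transitions.

It is written for computational neuroscientists who want a model small
enough for dynamical-systems analysis yet rich enough to reproduce the
hallmark behaviours of layer-5 pyramidal cells in vitro: dendritic Ca²⁺
spikes, Ca²⁺-spike-driven somatic bursts, BAC firing, and the switch from a
continuous to a discontinuous input–output relation when the dendritic Ca²⁺
conductance is active.

## The model

Two chambers (soma + axon initial segment, and apical dendrite) are coupled
by an internal conductance g_c, with the somatic membrane fraction p:

    C_m dV_S/dt = −I_Na − I_K − I_SL + (I_DS + I_S)/p
    C_m dV_D/dt = −I_Ca − I_DL + (−I_DS + I_D)/(1−p),   I_DS = g_c (V_D − V_S)

Somatic currents: I_Na = g_Na m∞(V_S)(V_S − E_Na) with instantaneous
activation, I_K = g_K w (V_S − E_K) with a slow gate
dw/dt = (w∞(V_S) − w)/τ_w(V_S), and leak I_SL.  Dendritic currents: a
high-threshold Ca²⁺ current I_Ca = g_Ca n h (V_D − E_Ca) with first-order
Boltzmann activation n and slow inactivation h, and leak I_DL.  That is the
5D model (V_S, w, V_D, n, h).

The extended (8D) model adds an intracellular Ca²⁺ pool driven by the Ca²⁺
influx and two Ca²⁺-activated K⁺ currents in the dendrite,
I_KC = g_KC c χ([Ca])(V_D − E_K) and I_KAHP = g_KAHP q (V_D − E_K), with
Pinsky–Rinzel two-rate gate kinetics.  Every numeric constant lives in a
single JSON registry (`src/bacfire/data/default_params.json`); the code
never hard-codes model constants.  Units are mV, ms, µA/cm², mS/cm²,
µF/cm² throughout.

## Worked example

A 20 ms suprathreshold current pulse into the dendrite
(`python examples/06_pulse_ca_spike.py`):

```
20 ms dendritic pulse of 40 uA/cm^2:
   subthreshold: no Ca2+ spike, 0 APs, back at rest: True
20 ms dendritic pulse of 100 uA/cm^2:
   1 Ca2+ spike, duration 48.3 ms (30.5 ms beyond the pulse)
   somatic burst of 9 APs (transient: True); returned to rest: True
```

The Ca²⁺ spike is all-or-none: below threshold the pulse passes without a
single AP, above it a regenerative dendritic depolarization outlasts the
pulse by 30 ms and drives a 9-spike somatic burst before the neuron
returns to rest.  The bifurcation structure behind the input–output
relation (`python examples/04_dendritic_bifurcation.py`):

```
g_Ca = 0.0: equilibrium fold at I_D = 67.787 uA/cm^2
   SNIC at 67.787
g_Ca = 3.0: equilibrium fold at I_D = 67.590 uA/cm^2
   SN at 67.590
      stable cycle persists 2.50 uA/cm^2 below the fold (up/down hysteresis)
   SHO_onset at 65.090
      period-divergence fit R^2 = 0.988
```

With the Ca²⁺ channel blocked the onset of firing is a saddle-node on an
invariant circle (continuous f–I curve, rates from 0 Hz).  With the channel
active the spiking/Ca²⁺-spike state survives below the fold of equilibria,
the onset becomes a plain saddle-node (rate jumps to ~100 Hz), and the
cycle is destroyed at a saddle-homoclinic-orbit boundary where its period
diverges logarithmically.

The other examples cover the somatic f–I curve (`01`), the Ca²⁺-spike
burst (`02`), the moving-nullcline picture (`03`), BAC facilitation (`05`)
and extended-model periodic bursting (`07`).

## Command line

A thin CLI wraps the same library calls and writes tidy CSV plus a JSON run
manifest:

```sh
bacfire simulate --i-d 75 --duration 1000 --out run/
bacfire fi-curve --site dendrite --amin 60 --amax 80 --n 21 --g-ca 0
bacfire bifurcate --sweep I_D --lo 60 --hi 75
bacfire bac --i-d-moderate 40
```

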