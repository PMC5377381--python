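# Methods

## Model

The neuron is reduced to two isopotential chambers.  The somatic chamber
lumps the soma and axon initial segment and carries the AP-generating
currents: an inward Na⁺ current with instantaneous activation
m∞(V_S) = ½(1 + tanh((V_S − m_half)/m_slope)), an outward delayed K⁺
current gated by a single slow variable w with
w∞(V_S) = ½(1 + tanh((V_S − w_half)/w_slope)) and
τ_w(V_S) = τ_w_base / cosh((V_S − w_half)/(2 w_slope)), and an ohmic leak.
This is the standard Morris–Lecar-type reduction of a spiking compartment:
one fast amplifying gate collapsed to its steady state, one slow resonant
gate.  The dendritic chamber carries a high-threshold Ca²⁺ current
I_Ca = g_Ca n h (V_D − E_Ca) with logistic activation n (fast, τ_n = 4 ms)
and inactivation h (slow, τ_h = 150 ms), plus leak.  The chambers exchange
the internal current I_DS = g_c (V_D − V_S); each chamber's balance divides
the coupling and injected currents by its membrane-area fraction (p somatic,
1 − p dendritic).  Sign conventions: ionic currents are written
g·gate·(V − E), so positive values are outward and the flowing Ca²⁺ current
is negative (inward).

The extended model appends a single-pool intracellular Ca²⁺ concentration,
d[Ca]/dt = −φ_Ca I_Ca − β_Ca [Ca], and two Ca²⁺-activated K⁺ currents in
the dendrite: the short-duration I_KC = g_KC c χ([Ca]) (V_D − E_K) with
χ([Ca]) = min([Ca]/χ_sat, 1), and the long-duration
I_KAHP = g_KAHP q (V_D − E_K).  The c and q gates follow Pinsky–Rinzel
two-rate kinetics dx/dt = α(1 − x) − β x.  The c rates are transcribed
exactly from the Pinsky–Rinzel piecewise expressions, evaluated in their
voltage frame via V_PR = V_D + 60 mV, with one amendment: the divisor of
the low-voltage α_c branch is taken as exp(40/11)/2 = 18.97644…, the exact
value at which the two branches join continuously, instead of the published
rounding 18.975 (which leaves a 4·10⁻⁵ discontinuity and lets β_c dip
negative just below the branch point).  [Ca] is kept in the dimensionless
internal units of that kinetic scheme and never converted to molar.

With g_KC = g_KAHP = 0 and φ_Ca = 0 the extended right-hand side reduces to
the 5D model exactly (bitwise, not just to tolerance); this reduction
identity is asserted in the test suite.

## Parameters

Every constant lives in `src/bacfire/data/default_params.json`, a flat
namespaced registry validated on load (unknown keys are rejected).  The
defaults, with the reasoning behind the genuinely free choices:

| symbol | value | note |
|---|---|---|
| C_m | 2 µF/cm² | membrane capacitance, both chambers |
| g_Na, E_Na | 20 mS/cm², 50 mV | instantaneous Na⁺; m_half −1.2 mV, m_slope 18 mV |
| g_K, E_K | 20 mS/cm², −100 mV | slow K⁺; w_half 0 mV, w_slope 10 mV, τ_w_base 20/3 ms |
| g_SL, E_SL | 2 mS/cm², −70 mV | somatic leak; rest sits near −69.6 mV |
| g_c, p | 1 mS/cm², 0.5 | coupling and somatic area fraction |
| g_DL, E_DL | 2 mS/cm², −70 mV | dendritic leak |
| g_Ca, E_Ca | 3 mS/cm², 120 mV | dendritic Ca²⁺; 0 = blocked, default/2 and default are the comparison points used throughout |
| n gate | half 0 mV, slope 3 mV, τ 4 ms | fast activation |
| h gate | half −15 mV, slope 8 mV, τ 150 ms | slow partial inactivation |
| extended | g_KC 5, g_KAHP 3 mS/cm², φ_Ca 0.02, β_Ca 0.075/ms, χ_sat 250 | see below |

The somatic gate positions were chosen so that the onset of firing in the
*coupled* model is a saddle-node on an invariant circle: the equilibrium
current–voltage relation must be N-shaped with the lower branch stable all
the way to its knee.  (A w_half low enough to engage the K⁺ current at
subthreshold voltages straightens the curve and converts the onset to a
Hopf-type mechanism; w_half = 0 mV keeps the window where the Na⁺ negative
slope dominates.)

The dendritic Ca²⁺ gate positions encode two constraints that the model is
built around: (i) the subthreshold dendritic operating range — including
the equilibrium at the fold, V_D ≈ −19.5 mV, and the peak of a
back-propagated AP, V_D ≈ −30 mV — must leave n∞ negligible, so that
neither the AP threshold under dendritic drive nor anything about somatic
drive depends on g_Ca; (ii) once V_D is driven above ~0 mV the current must
be regenerative enough to sustain itself against the leak and the somatic
load, so a brief pulse evokes an all-or-none Ca²⁺ spike that outlasts it.
The slow, partial inactivation h produces the measured fall-then-plateau
time course of I_Ca and the burst-then-plateau of the instantaneous rate.

The extended-model magnitudes g_KC, g_KAHP and φ_Ca are rescaled from the
Pinsky–Rinzel originals (15, 0.8, 0.13) because this dendrite's Ca²⁺
current density and load differ from theirs; the chosen values place the
constant-apical-drive regime (I_D ≈ 69–78 µA/cm²) in periodic bursting:
multi-spike bursts separated by quiescent gaps of several hundred ms set by
the q-gate decay (1/β_q = 1 s).

## Numerics

Integration uses the adaptive Bogacki–Shampine 2(3) pair (scipy's RK23) at
rel_tol 10⁻⁶ / abs_tol 10⁻⁹ with dense output on a uniform 0.01 ms grid
(0.05 ms in bulk sweeps).  Two non-obvious choices:

- **max_step = 0.25 ms.**  The fastest relaxation rate at rest is ≈3.7/ms
  (extended model), and the explicit pair's real-axis stability boundary is
  ≈2.5/|λ| ≈ 0.7 ms.  With a larger cap, roundoff at an equilibrium is
  amplified until the error controller clamps it at the tolerance scale
  (~10⁻⁴ mV wobble); inside the stability region a trajectory started at an
  equilibrium stays there to roundoff.
- **Stimulus discontinuities are integration breakpoints.**  The solver is
  restarted at every step/pulse edge rather than smoothing the waveform, so
  onset-locked events (burst timing) are resolved exactly.

Resting states are found by a long relaxation (2 s; 8 s for the extended
model, whose q gate relaxes on the 1/β_q timescale) followed by Newton-type
root refinement; the result is accepted only if max|rhs| < 10⁻¹⁰ and every
finite-difference Jacobian eigenvalue (central differences, step 10⁻⁶) has
negative real part.

Equilibrium branches are traced by pseudo-arclength continuation (secant
predictor, Newton corrector on the augmented system, state components
scaled 50:1 against the parameter so mV and gate units weigh comparably).
The step is halved on corrector failure down to step/1024, at which point
the branch is truncated with a warning.  Folds detected as parameter
reversals are then refined by pinning V_S, solving the remaining components
together with the parameter, and extremizing λ(V_S) with bounded Brent
search; this drives the zero eigenvalue at the fold below 10⁻⁶/ms.

Stable limit cycles are swept by direct integration with end-state
inheritance (settle 300 ms, measure 500–800 ms per point, default grid
step 0.25 µA/cm²); comparing upward and downward sweeps delimits bistable
intervals.  Unstable cycles are not continued — their existence interval is
*inferred* from the hysteresis, and outputs say so rather than labelling an
"unstable branch".  Onset classification uses the documented evidence
rules: SNIC requires fold/onset coincidence within 1.5 sweep steps plus a
log–log rate-scaling slope of 0.5 ± 0.1 against the refined fold position;
SN requires a surviving down-sweep cycle more than one step below the fold;
the SHO boundary requires a period-versus −log(λ − λ_c) fit with R² > 0.95,
λ_c being chosen within one step below the last surviving value to maximize
R².  Anything else is reported as "unclassified" with the evidence
attached.

Detection thresholds (registry defaults, overridable): somatic spikes are
upward crossings of 0 mV with a 2 ms refractory period and linear-in-time
crossing refinement — APs overshoot +25 mV here, and the suite asserts that
counts are unchanged anywhere in a −20…0 mV band.  A dendritic Ca²⁺-spike
episode requires V_D > −25 mV *and* |I_Ca| > 2 µA/cm² simultaneously (so
passive depolarizations never count), with episodes closer than 2 ms
merged.  The average rate f_S is count-based over the stimulus-on window,
deliberately including the initial burst; f–I curves classify as continuous
when their smallest nonzero rate falls below 5 Hz, the operational form of
"can fire arbitrarily slowly".  Burst summaries take the plateau as the
mean instantaneous rate over the final quarter of the analysis window and
flag adaptation at peak/plateau > 1.5.

## What the tests do and do not show

The acceptance suite checks the dynamical repertoire under the default
registry: SNIC onset and √-scaling under somatic drive; exact (to 0.5 Hz;
in practice bitwise) g_Ca-independence of the somatic f–I relation; the
continuous/discontinuous dichotomy of the dendritic f–I relation with the
SN + SHO structure and hysteresis; linearity of the somatic rheobase in
I_D; g_Ca-invariance of the dendritic AP threshold; BAC facilitation; the
pulse-evoked single Ca²⁺ spike; and extended-model periodic bursting.  The
dendritic-threshold invariance is asserted at the bisection resolution used
for the measurement (tolerance 0.25 µA/cm², i.e. invariance within
0.5 µA/cm² on a ~67.7 µA/cm² threshold); the fold positions themselves
differ by 0.20 µA/cm² between g_Ca = 0 and the default, a real but
sub-percent effect of residual subthreshold Ca²⁺ activation.

Problem sizes: sweeps use 25–35 points at 0.9 s simulated time each,
f–I curves 6–8 amplitudes at 1–1.6 s, the extended-model burst run 4 s,
and the two-parameter response map is exercised at reduced grids (the CLI
default is 41×41).  These sizes resolve every effect tested — thresholds to
≲0.25 µA/cm², spike times to ≲0.01 ms — and keep a full suite run in
minutes on one CPU.

All inputs are deterministic injected currents; there is no noise, no
synaptic conductance model, no spatial cable structure beyond the two
chambers, and no Ca²⁺ buffering beyond the single first-order pool.
Consequences worth keeping in mind: real dendritic Ca²⁺-spike thresholds
measured with noisy synaptic drive are distributions, not points; the
frozen-I_DS phase-plane analysis is an adiabatic approximation that is
exact for the V_S-nullcline but treats the dendrite as quasi-static; and
the hysteresis-based inference of unstable-cycle intervals bounds, rather
than computes, the unstable branch.
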