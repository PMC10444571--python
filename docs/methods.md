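# Methods

`measim` simulates the spontaneous activity of cultured human excitatory
(*Ngn2*-induced) neuronal networks as recorded on 12-electrode MEA wells, and
analyzes those recordings exactly the way in vitro MEA recordings are
analyzed, so that simulated and experimental feature tables are directly
comparable.

## Neuron model

Each of the N = 100 neurons is a single-compartment Hodgkin-Huxley model with
voltage-gated sodium, delayed-rectifier potassium and leak currents:

    Cm dVm/dt = −ḡK n⁴(Vm−EK) − ḡNa m³h(Vm−ENa) − ḡl(Vm−El)
                + [I + IsAHP + Isyn]/A + noise,

with rate constants of the Traub-Miles form for cortical pyramidal neurons,
shifted by a threshold-adjustment potential VT (αm, βm, αn have removable
singularities which are evaluated as their analytic limits whenever the
denominator argument is within 1e-9 mV of zero).  Control values (µF·cm⁻²,
mS·cm⁻², mV): Cm = 1, ḡK = 5, ḡNa = 50, ḡl = 0.3, EK = −80, ENa = 70,
El = −39.2, VT = −30.4.  With these values the cell rests at ≈ −39.3 mV,
i.e. these neurons sit unusually close to their spike threshold — a property
of immature hiPSC-derived neurons that makes spontaneous noise-driven firing
possible at all.

**Spike-frequency adaptation (sAHP).** A slow afterhyperpolarization current
IsAHP = −gAHP(Vm−EK) models calcium- and sodium-activated potassium currents:
every registered spike increments gAHP by αCa = 0.0035 nS and gAHP decays
with τAHP = 6 s.  The sAHP is the slow negative feedback that terminates
population bursts and suppresses firing during the inter-burst interval.

**Noise and heterogeneity.** Every neuron receives additive voltage noise
integrated with the Euler-Maruyama scheme, ΔV = σ·√(2·(ḡl/Cm)·dt)·N(0,1).
This scaling makes the stationary standard deviation of Vm on a passive
(leak-only) membrane equal σ = 4.1 mV for any timestep — σ is defined as the
std of the resulting membrane-potential noise, and that definition is the
contract the implementation satisfies.  Heterogeneous excitability comes from
a constant per-neuron bias current drawn uniformly from ±9.5 pA; the most
depolarized neurons act as noise-driven pacemakers whose firing seeds network
bursts.

**Unit reconciliation (membrane area).** HH conductances are per-area while
the sAHP increment (nS), synaptic conductances (nS) and applied currents (pA)
are absolute, so a membrane area A is needed to put them in one equation.
The area is a free effective constant of the model: it sets how strong all
absolute quantities are relative to the membrane leak, and thereby the
network's operating regime (silent → weakly bursting → strongly bursting).
We calibrate it once so that the control network reproduces the in
vitro-like phenotype (regular synchronous network bursts on all electrodes
with high PSIB, seeded by sparse inter-burst firing) and keep it fixed for
every condition; the calibrated default is A = 3.2e-6 cm² (see "Calibration"
below).  All absolute quantities enter the membrane equation divided by A.

## Synapses

Directed connections (30% probability, no autapses) carry conductance-based
AMPA and NMDA synapses with reversal 0 mV:

    IAMPA = ḡA (Vm−E) Σj wj sjᴬ,   INMDA = ḡN u(Vm) (Vm−E) Σj wj sjᴺ.

AMPA gating decays with τA = 2 ms and jumps by 1 per (delayed) presynaptic
spike arrival; the AMPA rise time is neglected.  NMDA uses the saturating
two-variable scheme ds/dt = −s/τdecay + αN·x·(1−s), dx/dt = −x/τrise + Σδ
(τdecay = 100 ms, τrise = 2 ms, αN = 0.5 kHz), gated by the magnesium-block
unblock fraction u(V) = 1/(1+exp(−aV)[Mg]/b) with a = 0.062 mV⁻¹,
b = 3.57 mM, [Mg] = 1 mM.  ḡA = 0.2808 nS and ḡN = 0.0981 nS per synapse.
Weights are drawn once per network from N(1, 0.7), clipped to [0, 2] (the
left tail silences Φ(−1/0.7) ≈ 7.7% of synapses).  A global scaling factor S
(1 in control) multiplies all weights.

**Short-term depression.** Every synapse transmits w·x, where the resource
fraction x recovers as (1−x)/τD (τD = 813 ms) and is depressed by U·x = 1.5%
at each presynaptic spike, with x taken immediately before the decrement
(Tsodyks-Markram convention).  STD is weak per spike but accumulates over
the hundreds of spikes of a network burst.

**Delays.** Neurons sit on a 10×10 grid (100 µm pitch) spanning the 4×3
virtual-electrode array (300 µm spacing); each edge has conduction delay
distance/velocity rounded up to a whole timestep.  The conduction velocity is
not constrained by any measurement here; we use a fast default
(3000 µm·ms⁻¹, i.e. sub-millisecond delays across the grid) because spike
coincidence across the culture is what lets the brief AMPA currents recruit
an avalanche — see "Calibration".

## Integration

Gates use exponential Euler with rates frozen at the step-start voltage
(tabulated on a 0.01 mV grid and linearly interpolated); the voltage uses
forward Euler plus the Euler-Maruyama noise term; linear synaptic decays use
exact exponential factors; the saturating NMDA equation uses forward Euler.
dt = 0.1 ms.  Spikes are registered at upward crossings of 0 mV with a 3 ms
lockout; registration drives the sAHP increment, STD decrement and delayed
synaptic transmission.  A simulation aborts with a diagnostic error if
|Vm| > 200 mV.  Initial conditions: the deterministic resting potential with
steady-state gates, gAHP = 0; the discarded transient absorbs any residual
initialization effect.

For performance the inner loop is compiled with numba; AMPA drives are
aggregated per postsynaptic neuron (exact, because the AMPA ODE is linear),
NMDA gating is kept per edge (its saturating ODE does not aggregate), and
normal deviates are pre-generated in chunks.  All randomness derives from
(master seed, network id) through `numpy.random.SeedSequence`, so any network
is reproducible in isolation and condition re-runs are exactly paired.

## Virtual electrodes and analysis chain

Each of the 12 electrodes records the weighted sum of nearby membrane
potentials, with pickup weight exp(−d/150 µm), zero beyond 300 µm, sampled at
10 kHz.  Analysis — identical for simulated and external recordings —
band-pass filters at 100–3500 Hz (5th-order Butterworth, causal), detects
spikes where |signal| exceeds 4× the whole-trace RMS (2 ms dead time), and
detects network bursts on the 10 ms-binned, 3-bin-smoothed population rate: a
burst opens when the rate stays ≥ max/4 for 60 ms, closes below max/100, and
is discarded if more than 80% of its spikes come from one electrode.
Features: NBR (bursts/min), NBD (mean duration, NaN when no bursts), PSIB
(% spikes in bursts), MFR (spikes/s per electrode).

Two consequences of this chain are worth knowing.  First, a 4×RMS threshold
on a noisy but spike-free trace still crosses at the Gaussian-tail rate
(~0.5 false events/s/electrode here), so detected MFR never reaches zero even
for silent networks; statements about truly abolished spiking are therefore
checked against the simulator's ground-truth spike times.  Second, the
burst threshold is relative to the recording's own maximum rate, so on
featureless (Poisson-like) rasters occasional fluctuations open short
spurious bursts; the burst features are meaningful for recordings that do
have burst structure or are nearly silent.

## Conditions

- control — the calibrated defaults above.
- sAHP_half — αCa × 0.5 (KCNQ-channel block by linopirdine).
- Na_block — ḡNa = 0 (TTX).
- NMDA_block — ḡN = 0 (MK-801).
- AMPA_block — ḡA = 0 (NBQX/NASPM).
- DS — the Dravet-syndrome parameter set: αCa × 0.5, S × 0.62, U × 0.7 and
  sodium activation rates (αm, βm) × 0.7.  These factors are this package's
  defaults, tuned so the three phenotype directions (NBR↓, NBD↑, PSIB↓
  versus paired control) hold in most network realizations across seeds
  while DS networks keep bursting at all (stronger synaptic downscaling
  pushes some realizations below the burst-ignition threshold entirely);
  they are exposed in the configuration.
- sodium_mod — an arbitrary RateModifier (kinetic scales, activation or
  inactivation voltage shifts, ḡNa scale), the scan axis for SCN1A-type
  channelopathies.

Condition batteries re-simulate the same network ids, so every comparison is
paired (same adjacency, weights, bias currents and noise stream).

## Calibration and the operating regime

With the tabulated parameters fixed, the membrane area (and with it the
relative strength of synapses, bias heterogeneity and sAHP) selects the
network regime.  We calibrated A on the control phenotype only: regular
network bursts on all 12 electrodes, high PSIB, inter-burst firing carried
by a minority of depolarized neurons.  At the calibrated point the model
reproduces, in paired batteries: the large NBD increase (with much smaller
NBR change) under sAHP halving; shortened bursts under NMDA block; complete
silence under sodium-channel block; and the DS phenotype triplet.

One validation observation is only partially reproduced: blocking AMPA
abolishes the fast, AMPA-led recruitment — time-locked avalanches vanish —
but the saturating NMDA synapses alone can still ignite slower synchronous
events from sustained subthreshold drive.  In this parameter family the
NMDA:AMPA charge ratio at subthreshold voltages is ≈ 2.5:1 (u(−39 mV) ≈ 0.24
with the stated Mg-block constants), so a regime in which AMPA block silences
all collective events while NMDA block leaves burst initiation intact does
not exist along the calibration axis: both ignition thresholds scale
identically with the coupling strength, and NMDA-alone ignition always
engages first.  We therefore report burst features under AMPA block as the
model produces them, and document this as a known limitation of the
implementation rather than hiding it behind a re-tuned special case.

## Problem sizes used in tests and reproduction runs

The full study protocol (650 s per network, 12–30 networks per condition) is
supported and configurable.  The packaged tests and the reproduction script
use scaled batteries — 170 s per network (50 s transient + 120 s retained)
and 4-6 networks per condition — which keep every qualitative comparison
intact while each simulation takes seconds rather than minutes.

## Known limitations

- Excitatory neurons only, one compartment, no astrocytes — as in the
  modeled culture system's design simplifications.
- The area constant is an effective electrotonic scale, not a measured cell
  size; all absolute parameters should be interpreted relative to it.
- The analysis chain inherits the false-positive floor and the
  relative-threshold burst pathology described above.
- The AMPA/NMDA ignition dissociation is only partly reproduced (see
  "Calibration and the operating regime").
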