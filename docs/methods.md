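# Methods

## Cell model

The electrophysiological substrate is a human atrial cardiomyocyte ODE
model of the Grandi–Pandit–Voigt family: Hodgkin–Huxley membrane currents
(INa, background Na⁺, Ito, IKr, IKs, IK1, plateau K⁺, Ca²⁺-activated and
background Cl⁻, L-type Ca²⁺ with GHK driving force, Na⁺/Ca²⁺ exchange,
Na⁺/K⁺ and sarcolemmal/SR Ca²⁺ pumps), a four-compartment Ca²⁺ system
(junctional cleft, subsarcolemmal space, bulk cytosol, SR) with
calsequestrin/troponin/calmodulin/myosin/SL buffering, and a four-state
RyR release model.  [K⁺]ᵢ is held constant, as in the source formulation.
The full state vector has 49 entries: membrane potential, 11 gating
variables, 3 RyR states, 14 buffer occupancies, 8 ion concentrations and
the 12 Markov channel occupancies below.

The model's equation set and constants were transcribed into
`atriakur.cell` from the published formulation; the cited source code
location was not available, so the transcription was validated against the
model's published steady-state outputs (resting potential, AP morphology,
rate-dependent Ca²⁺ biomarkers).  One constant deserves mention: the SERCA
forward affinity is the atrial value Kmf = 0.615 µM (2.5× the ventricular
0.246 µM); with the ventricular value every steady-state Ca²⁺ biomarker is
systematically displaced (diastolic [Ca²⁺]ᵢ roughly halved).

The 18 maximal conductances/transport rates (the sensitivity-analysis
parameter set) live in `data/baseline_parameters.yaml`, the versioned
parameter file, together with the chronic-AF remodeling multipliers.  The
adopted cAF set is: INa −10%, Ito −70%, ICaL −50%, G_Kur −50%, IK1 +100%,
IKs +100%, NCX +40%, RyR Ca²⁺ sensitivity ×3, SR leak +25%.  This
reproduces the cAF phenotype the screening relies on: shorter APD, more
depolarized plateau, depressed Ca²⁺ transient, abbreviated ERP.

## Markov Kv1.5 (I_Kur) model

I_Kur gates through a six-state Markov chain C1–C2–C3–C4–O–I.  The
activation chain uses per-gate rates (4α, β), (3α, 2β), (2α, 3β), (α, 4β)
constructed so that the chain's stationary open probability and dominant
relaxation time exactly reproduce the published Hodgkin–Huxley activation
gate of the same current (x_kur: V½ = −6 mV, slope 8.6 mV, τ 0.5–9.5 ms).
O↔I uses the HH inactivation-gate steady state (V½ = −7.5 mV, slope
10 mV) with kinetics **10× the HH gate**, i.e. a slow-inactivation time
constant of ≈300 ms at plateau potentials, in the range reported for Kv1.5
currents.  The drug-free AP is insensitive to this choice (APD90 moves
<0.5 ms between 1× and 10×), but it makes the inactivated state
pharmacologically meaningful for O&I blockers: the channel inactivates
appreciably during the depolarized cAF plateau, more so at 3 Hz.
Current through the open state is ohmic, I_Kur = G_Kur·P_O·(V−E_K).

Drug binding is pure state occlusion: bound states carry no current and no
drug-free rate is altered.  Three blocker classes are supported:

* **open**: O ⇌ Od with k_on·[D] / k_off;
* **open+inactivated**: additionally I ⇌ Id; with the *bridged* variant
  the bound states communicate, Od ⇌ Id carrying the drug-free O↔I rates
  (the mirror convention — the source does not state whether bridged
  transitions are scaled);
* **closed**: each C_i ⇌ C_id with identical rates; transitions among
  bound closed states mirror the drug-free closed-closed rates.

Units: k_on is interpreted as µM⁻¹s⁻¹ and k_off as s⁻¹, so Kd [µM] =
k_off/k_on and "k_on = k_off" means Kd = 1 µM exactly.  This is the only
reading that makes the equal-rates/Kd-1 µM convention dimensionally
consistent.  All internal kinetics are ms⁻¹; bath concentration is
constant over a simulation.

## Numerics

Beat-by-beat stiff integration (LSODA through `scipy.integrate.odeint`)
with the 5-ms stimulus as a piecewise-constant segment boundary; rtol
1e-6 with per-state absolute tolerances (1e-4 mV for V, 1e-10 mM for
cytosolic Ca²⁺, 1e-8 elsewhere); recorded output resampled at 0.1 ms for
biomarker extraction.  Halving the tolerance changes APD90 by <0.5 ms
(tested).  Markov occupancies are conserved to <1e-6 along every trace.
The GHK expressions and the L-type activation time constant use a 1e-6-mV
guard at their removable singularities.  The right-hand side is compiled
with numba; one 300-beat equilibration takes a few seconds on one core.

Equilibration uses fixed beat counts — 300 beats at 1 Hz, 900 at 3 Hz —
not a convergence criterion.  Default stimulus: 12.5 A/F for 5 ms
(roughly 3× diastolic threshold; configurable, and stored in the
parameter file).  Simulations at other rates scale the beat count to
300 s of pacing.

## Protocols

**ERP (S1–S2).**  After steady S1 pacing, a 5-ms S2 at 2× the measured
diastolic threshold is delivered at decreasing S1–S2 intervals from
700 ms in 2-ms decrements (lower bound 50 ms, with a flagged sentinel if
reached).  Capture requires membrane-driven dV/dt_max ≥ 5 V/s **and** AP
amplitude ≥ 50% of the preceding S1 amplitude; the stimulus artifact
(dV/dt = I_stim inside the pulse) is subtracted before applying the
upstroke criterion, so a passive electrotonic hump cannot register as
capture.  The ERP is the longest failing interval.  All S2 trials share
one pre-computed post-S1 trajectory, and an optional coarse-first
bracketing pass (16× decrement, then fine) precedes the prescribed linear
scan; under monotone capture it returns the identical grid point (tested
against the fine-only scan).  The diastolic threshold itself is found by
bisection to 1% between 0 and 60 A/F.

**Irregular pacing.**  Cycle lengths are independent uniform draws on
[285.7, 400] ms (2.5–3.5 Hz), truncated when cumulative time exceeds 20 s,
applied from the 3-Hz steady state; per-beat APD90 and the mean over the
run are reported.  Note the uniform distribution on that CL interval has
mean 342.85 ms; the "mean of 333.3 ms" sometimes quoted for this protocol
corresponds to the mean *frequency* (3 Hz), not the mean CL.  The sampling
is implemented exactly as specified (CL-uniform); the inconsistency is
documented here rather than resolved.

**IC50 down-ramp clamp.**  The channel is clamped to a 200-ms linear ramp
from +30 to −60 mV once per pacing cycle, holding at the resting potential
(−80 mV, not stated in the protocol's source and adopted here) in between.
Because the clamp prescribes V(t), only the 12-state Markov subsystem
evolves; it is propagated by matrix exponentials over 0.5-ms
piecewise-constant voltage steps, and cycles repeat until the
beat-to-beat peak I_Kur changes by <0.1% (error after 2000 cycles).
Block = 1 − peak/peak_drug-free; IC50 is found by bisection on
log-concentration in [1 nM, 1 M] (block is monotone in concentration,
verified on coarse grids), and agrees with a 40-point log-grid scan to
within the grid resolution.

**Rate matching.**  AP simulations at rate r use the IC50 computed at
rate r (the alternative — applying the 1-Hz IC50 everywhere — is
selectable, `rate_matched` being the default).

## Biomarkers

AP onset = time of maximum upstroke velocity after the stimulus; AP
amplitude = peak E_m − pre-stimulus diastolic E_m; APD₄₀/APD₉₀ = time from
onset to first crossing of peak − 0.4/0.9 × amplitude, linearly
interpolated.  (The repolarization reference is not defined in the
protocol's source; the amplitude-fraction convention above is standard.)
CaT: diastolic [Ca²⁺]ᵢ at stimulus onset, amplitude = peak − diastolic,
t50 = time from peak to half-decay.  Ca²⁺ biomarkers are reported in nM.
Beats without an AP (amplitude <10 mV) yield NaN-flagged biomarkers.

## Kinetic sweeps and AF-selectivity

The binding-rate grid is the nine half-log values 0.01–100 s⁻¹.  Sweep
grids: the k_on = k_off diagonal (9 scenarios), all 81 (k_on, k_off)
permutations, and the 3⁴ = 81 state-affinity design varying (k_on,O,
k_off,O, k_on,I, k_off,I) over {0.01, 3, 100} independently, with K_O/K_I
derived, never set.  Every scenario runs at its own, rate-matched IC50
(cached by scheme and rate).  Each sweep table carries four reference
rows per condition: drug-free, constant 50% and 100% G_Kur reduction, and
nSR drug-free.  Scenario failures become flagged rows, not aborts, and
tables are independent of execution order.

AF-selectivity flags on cAF rows: *efficacy* (ERP at 3 Hz above the nSR
drug-free reference), *safety* (APD90 at 1 Hz below the nSR drug-free
reference), *inotropy* (CaT amplitude at 1 Hz above drug-free cAF);
*best-performing* drugs satisfy all three.  When a sweep is run without
ERP measurement the efficacy flag can use APD90 at 3 Hz as the
refractoriness surrogate (ERP changes mirror APD changes under this
protocol family).

A structural property of IC50-normalized sweeps is worth stating: for an
equal-affinity O&I blocker the only drug parameters entering the dynamics
are (k_on·c, k_off), and requiring 50% peak block under the clamp pins
k_on·IC50 to a value determined by k_off alone.  Dosing every scenario at
its own rate-matched IC50 therefore makes sweep outputs *exactly*
invariant along k_on at fixed k_off; the whole kinetics–effect relation is
carried by the unbinding rate, with the intermediate-rate peak
(k_off ≈ 3–10 s⁻¹) that drives the biphasic curves.  Superpotent corners
(k_on = 100, k_off = 0.01 s⁻¹; Kd = 0.1 nM) need IC50s below the nominal
1-nM scan floor; the bisection extends its lower bound by decades when the
floor concentration already half-blocks.

A caveat found in this implementation: open-state blockers with the
fastest kinetics (k ≥ 30 s⁻¹) lose their use-dependent potency ordering —
binding equilibrates within a single ramp, and the residual rate
dependence of the IC50 is small and can invert.  O&I blockers remain
use-dependent across the whole grid, and closed-state blockers
reverse-rate-dependent across the whole grid.

## Parameter sensitivity analysis

Populations of model variants are built by multiplying each of the 18
parameters by exp(z), z ~ N(0, 0.1²) i.i.d. ("standard deviation 0.1"
is read as the SD of the natural-log factor; log₁₀ is selectable).  The
study configuration is 900 variants; regression coefficients are the
mean ± SD over 30 random subsets of 300 variants of full-component
NIPALS PLS (scikit-learn's `PLSRegression`) on z-scored log outputs vs
z-scored log factors.  With all components retained this equals ordinary
least squares on well-conditioned data (tested to 1e-6); the subset
resampling supplies the error bars.  Variants with repolarization failure
or no capture (undefined biomarkers) are excluded and counted.  ERP is
expensive per variant; a documented fast mode measures it on a subsample
and regresses it separately.  Scaled-down populations (e.g. 60–120
variants re-settled for 150 beats from the fully equilibrated baseline)
preserve coefficient signs but carry visibly larger subset SDs.

## What the scaled-down modes do and do not show

Drug scenarios in test/CI configurations warm-start from the fully
equilibrated drug-free steady state and re-settle for 50 beats (1 Hz) or
150 beats (3 Hz) — enough for binding kinetics ≥0.01 s⁻¹ to approach
their periodic orbit, but a documented approximation to the printed
300/900-beat protocol used by `scripts/acceptance.py` and the full mode.
Conclusions that depend on slow ionic accumulation (Na⁺ drift over
hundreds of beats) require the full equilibration; the 3-Hz baseline in
particular is always equilibrated for 900 beats before any S1–S2 or
population work, because INa availability at the 3-Hz takeoff potential
is still drifting at 300 beats.

## Known limitations

* The transcribed constant set reproduces the published model's printed
  Ca²⁺ biomarkers to within a few percent across eight conditions, but
  drug-free APD90 in nSR at 1 Hz sits ≈7% short (297 vs 320 ms); the
  residual lives in the late-repolarization current balance and was left
  as transcribed rather than fitted.
* The Markov activation chain reproduces the HH gate's steady state and
  dominant time constant, not its full transient; sub-millisecond
  activation detail differs.
* Single cell only: no tissue coupling, no multi-channel (off-target)
  drug effects, no β-adrenergic or cholinergic modulation, no trapping or
  allosteric binding models.
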