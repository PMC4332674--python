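# Methods

## Gating schemes

All models are linear chains of conformational states.  The 6-state scheme
(C1…C5, O) has four independent voltage-sensor steps with statistical
multiplicities 4α/β, 3α/2β, 2α/3β, α/4β — equivalent to four identical
two-state sensors — followed by a voltage-independent ("thermal") opening
step with equilibrium constant L = k_o/k_c, which caps the open probability
at L/(1+L).  The 7-state wild-type scheme inserts a concerted
voltage-dependent pre-opening C5↔C6 (rates f, b) before the thermal step;
the concerted step carries z_f + z_b = 1 e of the 9 e total for WT, and
1.8 e of 13.8 e (13 %) for the sensor-uncoupled ILT mutant.  The
slow-inactivated state I attaches to the open state with voltage-independent
entry (0.05 s⁻¹) and recovery (0.005 s⁻¹) rates; recovery at −100 mV
therefore takes minutes (1 − e^(−0.005·240 s) ≈ 0.70 available after 4 min).
The attachment point is configurable (`get_scheme(...,
inactivation_attachment=)`); attaching I to O reproduces the multi-minute
recovery the repeated-acquisition simulations need.

Rates follow α = α₀·exp(z_α FV/RT) (and mirror-image backward forms), or
the Hodgkin–Huxley functional forms (linexp/exp) for the excitability-model
variants.  The default thermal voltage is RT/F = 25.3 mV (T ≈ 293 K),
configurable through `PhysicalConstants`; the temperature is not otherwise
pinned by the model and midpoint-type results move by well under 1 mV per
0.5 mV of RT/F.

Stationary occupancies use the detailed-balance product along the chain,
accumulated in log space and normalized with logsumexp, which is exact for
tree topologies and stable at extreme voltages where rates span many
orders of magnitude.  A least-squares null-space solve of the generator is
kept as an independent cross-check (they agree to ≤1e-10 over the
physiological voltage range for every packaged parameter set).

A dimensional note: the per-sensor midpoint is computed as
V0.5 = −(RT/F)·ln(α₀/β₀)/(z_α+z_β) and exposed as a diagnostic
(`sensor_midpoint`); the alternative convention that absorbs V0.5 into the
prefactors is not used because it makes the prefactor dimensionless while
the rate is s⁻¹.

## Mechanosensitive modulation

Tension couples to a transition through the in-plane area change ΔA with
energy −γΔA, multiplying the step's equilibrium constant by
m = exp(γΔA/k_BT) (1 mN/m · 1 nm² = 1e-21 J; m = e at γ ≈ 1.35 mN/m for
ΔA = 3 nm²).  How m splits between the rates depends on the transition
state's fractional area position a\*: forward ×m^a\*, backward ×m^(a\*−1).
The default a\* = 0.5 (symmetric barrier) is the simplest assumption absent
structural data; any a\* gives identical equilibria, and the package keeps
a\* exposed because the kinetics discriminate — with a\* near 1 and m = 60
the forward thermal rate jumps ~49-fold, an onset acceleration far beyond
anything observed, which is the argument against rescuing the LMS
mechanism's stretch-insensitive tails that way.

Modulation modes map onto scheme transitions by role: `lms` targets the
thermal step, `vms_concerted` the concerted step, `vms_last_sensor` the
α/4β step, `vms_tabmor` the C3↔C4 and C4↔C5 steps (default factors
1.3/2.0, chosen once to give the ~7 mV-class left-shift on the 6-state
Table-1 scheme that represents near-lytic stretch), and `ilt_vms`
multiplies the concerted forward rate by 0.75 and divides the backward by
the same factor (the ILT-mutant response, a net equilibrium factor
0.75² = 0.5625).

## Patch mechanics

The patch is a spherical cap spanning a 0.5 µm pipette mouth.  Its area
strain is pinned by two anchors: ε = 1.4 % at 80 mmHg suction and ε = 4 %
(the bilayer's lytic limit) at a full hemisphere.  The cap angle is the
internal variable; the pressure–strain relation uses the Laplace-law shape
ΔP ∝ ε·sinθ with the proportionality fixed by the 80 mmHg anchor, and
tension is γ = K_A·ε with K_A = 250 mN/m.  The printed anchor set is not
simultaneously Laplace-consistent (ΔP·r/2 at the 80 mmHg anchor gives
γ ≈ 2.7 mN/m, while K_A·ε = 3.5 mN/m), so the pressure scale is treated as
calibrated rather than derived; any smooth monotone map through the same
anchors changes the shift-versus-pressure curves only marginally.  Suction
beyond the full-hemisphere point sets a lysis flag and clamps the strain.

Midpoint shift versus suction is quasi-linear (R² > 0.99 over 0–80 mmHg for
both mechanisms) because the shift per e-fold of the equilibrium constant
shrinks as the constant grows, almost exactly cancelling the exponential
growth of m with tension.  The same cancellation makes compression
(m < 1) right-shift g(V) — mirroring stretch in direction but with a
somewhat larger magnitude (≈30 % at 3-fold factors), since compression
moves the constant into the steeper-response region.

## Curves, fits and the shift convention

g(V) curves are stationary open probabilities on a 1 mV grid
(−150…+150 mV), summarized by a least-squares single-Boltzmann fit
max/(1+exp(−(V−V0.5)/s)) initialized at the empirical half-max crossing.
Two shift conventions are implemented:

* `normalized_boltzmann` (default): each curve normalized to its own fitted
  maximum; shift = ΔV0.5 of the fits.
* `fixed_criterion`: the voltage displacement at the reference curve's
  absolute half-max level.

For pure midpoint perturbations (vMS) the two agree to ~0.1 mV.  For
perturbations that also raise the apparent maximum (LMS) they differ by
1–2 mV at the 7 mV scale.  The canonical 7-state comparisons ((f/b)₀:
5→15.6 and L: 4→14.4) are reported under the normalized convention (6.59
and 6.52 mV).  For the HH-matched 6-state scheme the "7.0 mV" label for
L: 4→6.9 is read as the displacement of the absolute curve at the reference
half-maximum (7.1 mV; the normalized convention gives 5.3 mV), the natural
operational definition when the maximum itself grows; both numbers are
reproducible from `measure_shift`.

## Voltage-clamp kinetics

The command voltage is piecewise constant, so within each protocol segment
the master equation has the exact solution p(t) = expm(Qᵀt)p(0).  The
default integrator propagates that matrix exponential on a uniform sample
grid per segment with exact state handoff at voltage steps — exact for
arbitrary segment durations (including the minutes-long holds of the
recovery protocols) at negligible cost for 6–7 state schemes.  A stiff BDF
solve_ivp route (rtol 1e-8, atol 1e-10) is retained and cross-checked in
the tests.

Protocol conventions: holding −100 mV; test pulses −80…+60 mV in 10 mV
steps, 100 ms; tail segment back at the holding potential, 50 ms;
conductance read as the instantaneous Popen at the tail-segment start
(equivalent to the tail-current amplitude extrapolated to the step).  The
repeated-acquisition ("conversion mimicry") runs sweep ascending test
voltages with a 16 s sweep period so one 15-sweep family takes 4 simulated
minutes; four families are acquired back-to-back.  Started with all
channels slow-inactivated, the families grow in amplitude run over run,
and the first run shows an upwardly inclined plateau because availability
recovers measurably *during* the sweep sequence.  Onset half-time is the
time to half the asymptotic Popen change after a step; tail half-time is
measured from the tail-segment start after any rising transient, default
tail voltage −120 mV.

ILT's equilibrium g(V) midpoint computed from its rate constants lies near
−11 mV; the far-right midpoints reported for this mutant are
protocol-limited, so the package provides finite-pulse g(V) (Popen at
pulse end; default 100 ms, a choice, as the experimental pulse duration is
not pinned) whose midpoint lies above +100 mV and converges to the
equilibrium curve as the pulse lengthens.  Under the ILT stretch
modulation the late tail decay rate scales with the backward-rate factor
(1/0.75), but on a 50 ms repolarization the Popen trajectories with and
without stretch differ by <0.02 — the model's account of
"stretch-insensitive tails" is a statement about the experimental
timescale, on which closing is rate-limited by the unmodulated thermal
step.

## Hybrid excitability model

Standard squid-axon HH membrane (g_Na = 120, g_K = 36, g_leak = 0.25
mS/cm²; E_Na = +50, E_K = −77, E_leak = −54.4 mV; C_m = 1 µF/cm²; rates in
s⁻¹, time base seconds) with a fraction f_M = 0.3 of the delayed rectifier
replaced by a 6-state Markov Kv:
I_K = g_K(f_HH n⁴ + f_M P_o/P_o,max(L₀))(V−E_K).  Raising L raises the
apparent maximal conductance by Δg_max = g_K f_M (L−L₀)/(L₀(1+L)).

**Baseline-matching calibration.**  The Markov variants use HH-form rate
functions with modified prefactors (×1.55) and slopes (12 and 85 mV).
Those modifications alone leave the L = 4 variant's normalized activation
midpoint ~24 mV left of the HH n⁴ midpoint (the thermal factor L multiplies
the curve leftward), which would add standing K⁺ conductance at rest and
silence the membrane.  The package therefore applies one common voltage
offset to the rate-function arguments, calibrated once so the L = 4
rest-tension midpoint coincides with the HH n⁴ midpoint (−23.681 mV), and
retains the further +18 mV relative displacement of the L = 1 variant.
The L = 1 family consequently sits ~5.5 mV left of the HH curve — enough
standing K⁺ conductance to raise its excitation threshold (rheobase
≈ 10.5 vs ≈ 6.5 µA/cm²), which is the property the two-stimulus design
(8 vs 13 µA/cm²) relies on.  Exact midpoint matching and the elevated
threshold are mutually exclusive in this architecture; the calibration
keeps the first for the L₀ = 4 family and the second for the L₀ = 1
family.

Left-shift levels LS ∈ {1.5, 2.5, 4.0, 7.0} mV map to fixed schedules:
vMS multiplies α/4β by 1.05/1.079/1.14/1.26, LMS moves L to
4.5/4.8/5.4/6.9 (from L₀ = 4) or 1.13/1.22/1.38/1.76 (from L₀ = 1), always
with the symmetric split.  Note the vMS factors produce smaller actual
midpoint shifts in this model (~0.35–2.8 mV), so vMS braking at these
schedules is mild by construction.

Stimulus: 500 ms current step (default 8 µA/cm²), stretch window covering
the stimulus, 50 ms settle before onset from the relaxed resting state;
spike = upward crossing of 0 mV with a 2 ms refractory.  Integration uses
LSODA (rtol 1e-7) piecewise over the stimulus/stretch breakpoints, sampled
at 50 µs.  The braking comparisons fix the printed amplitudes; the
extinction demonstration for the L₀ = 1 LMS family places the stimulus
marginally suprathreshold by a defined procedure — amplitude = 1.05 ×
rheobase at LS = 0, rheobase found by bisection on the onset of a
sustained (≥5-spike) train — because the phenomenon is precisely that a
small LMS perturbation (ΔL = 0.13) crosses threshold when the margin is
small.  At that margin the baseline fires a ~19-spike train and LS =
1.5 mV leaves ≤1 spike.

## Synthetic-data scope

All inputs are forward simulations from printed parameter tables; there is
no measurement noise, no leak/series-resistance artifact, no channel-count
stochasticity, and no flickery off-pathway open states (the fixed
P_open,max ≈ 0.8 of real Shaker is represented through L = 4, not through
flicker).  Passing tests therefore certify the internal consistency and
the qualitative experimental signatures of the two mechanisms, not
quantitative agreement with any particular recorded dataset.

## Numerical choices and limitations

* Boltzmann fits can mildly bias V0.5 when curves are not exactly
  Boltzmann (the chain product is a sum of Boltzmanns); the 1 mV grid and
  half-max initialization keep fit-induced shift errors below ~0.1 mV.
* The generator row sums are zero to machine precision relative to the
  largest rate; at ±150 mV rates reach 1e5–1e7 s⁻¹.
* `tail_gv_family` carries the full state vector through the entire
  acquisition session, so the acquisition itself slow-inactivates a small
  fraction (~2 %) of channels even from an equilibrated start; this is a
  property of the protocol, not numerical drift.
* Spike counts near threshold are knife-edge by nature; the rheobase
  procedure quantizes them reproducibly, but counts at a fixed amplitude
  can move by ±1 under solver-tolerance changes.
* The mechanics model is a calibrated interpolation between two printed
  anchors, not a mechanical simulation of a real patch (no adhesion,
  pre-stress, or creep).
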