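# Methods

`pigletbrain` models the cerebral haemodynamic and metabolic response of
the neonatal piglet to transient hypoxia-ischaemia (HI) — bilateral
carotid occlusion combined with reduced inspired oxygen — at the level of
the signals that broadband NIRS and ³¹P-MRS can observe: changes in oxy-
and deoxy-haemoglobin (ΔHbO₂, ΔHHb), in oxidised cytochrome-c-oxidase
(ΔoxCCO), intracellular pH, and the NTP (≈ATP) level. It also implements
the surrounding analysis: five-phase/ten-section cohort averaging, Morris
elementary-effects screening, and bound-constrained swarm calibration.

## The reduced model

The full lineage of piglet-brain models couples ~25 state variables and
~100 parameters. This package deliberately implements a reduced eight-state
model containing exactly the mechanisms that the analysis interrogates;
its fidelity target is the qualitative and quantitative behaviour of the
observables (fractional CMRO₂/CBF drops, NTP depletion, pH dip and lag),
not equation-level equality with any larger model.

States: arterial radius `r` (cm), tissue O₂ `o2c` (mM), oxidised CuA
fraction `oxfrac`, ATP, PCr, inorganic phosphate (mM), cytoplasmic lactate
(mM), and free proton concentration (mM).

**Vessel.** `dr/dt = k_r (T_p − T_e − T_act)` balances distending pressure
tension `T_p = ½(Pa+Pv)·r` against passive elastic tension
`T_e = σ_e0 (exp(k_σ(r−r_0)/r_0) − 1) − σ_coll` and an active muscular
tension `T_act = μ·T_max·exp(−(|r−r_t|/(r_t−r_m))^{n_m})`, a bell-shaped
curve peaked at `r_t` whose width is set by the special radius `r_m`. The
peak radius sits *above* the baseline radius so that the operating point
lies on the ascending (stabilising) limb; with the peak below baseline the
balance is bistable and the vessel latches onto a dilated branch — a
failure mode we found and designed out. Activation
`μ = μ_n·softplus(1 + k_aut·(g_pa·ΔPa − g_o2·Δo2c) − g_co2·ΔCO₂)` blends a
myogenic pressure response and metabolic (low-O₂) vasodilation, both gated
by the autoregulation constant `k_aut ∈ [0,1]` (1 = intact regulation,
0 = passive vessel), plus CO₂ reactivity. `μ_n` is derived from the tension
balance at the reference operating point, so baseline `r = r_n` exactly.

**Perfusion and oxygen.** Relative CBF is Poiseuille-like:
`q = (r/r_n)⁴ · (Pa−Pv)/(Pa_n−Pv) · (1 − f_carotid·occ)`; carotid
occlusion removes the fraction `f_carotid` of conductance. Venous blood
leaves equilibrated with tissue O₂ through a Hill curve `s_v(o2c)`
(calibrated so `s_v(o2c_n) = s_v_n`), giving delivery
`J_in = q·k_hb·(SaO₂ − s_v)` that is flow-limited with extraction rising
as tissue O₂ falls. Oxygen consumption is
`CMRO₂ = CMRO₂_n · dem(ADP) · (1−oxfrac)/(1−oxfrac_n) · MM(o2c)/MM(o2c_n)`
— Michaelis–Menten in tissue O₂ (Km 0.03 mM), stimulated by ADP
availability, and proportional to the reduced CuA pool (the electron donor
to O₂).

**CuA redox.** `d oxfrac/dt = k_ox[(1−oxfrac)·MM̂(o2c) − c·oxfrac·g/g_n]`:
oxidation by O₂, re-reduction by upstream electron supply proportional to
glycolytic flux. During HI oxidation slows and the oxidised fraction falls;
ΔoxCCO = `cco_tot`·(oxfrac − baseline), so the total CCO concentration
scales the NIRS signal linearly without affecting the dynamics.

**Energy metabolism.** Glucose flux `g = g_n(1 + k_pasteur·deficit)` rises
with ATP deficit (Pasteur effect). CMRO₂ stoichiometry (6 O₂ per glucose)
fixes the oxidised share; the remainder is reduced to lactate (2 per
glucose), cleared first-order with rate constant `2·f_an·g_n/lac_n` — this
is where the normal lactate concentration `lac_n` enters the dynamics, and
the normalisation makes baseline lactate equal `lac_n` exactly. ATP is
produced glycolytically (2/glucose) and oxidatively (30/glucose oxidised),
scaled by a Pi-availability factor (which also pins the Pi steady state and
keeps the phosphate pool positive), consumed in proportion to its own
level, and buffered by a creatine-kinase reaction
`PCr + ADP + H⁺ ⇌ Cr + ATP` with mass-action kinetics around a fixed
equilibrium constant. ATP+ADP and PCr+Cr pools are conserved algebraically;
ATP+PCr+Pi is conserved by construction of the fluxes and is checked
against solver error in the tests.

**Protons.** pH integrates a proton load (lactate production, lactate/H⁺
co-efflux, a share of net ATP-turnover imbalance, CK proton consumption)
over a constant buffering capacity β = 20 mM per pH unit, plus slow
extrusion (k = 1.5·10⁻³ s⁻¹) toward the reference pH `ph_m_n`. The buffer
and the CK step together delay and damp acidification relative to lactate
accumulation, reproducing the lagged pH response seen in vivo.

**Calibration convention.** All rate constants that the named parameters
normalise (lactate clearance, ATP turnover, O₂ delivery scale, CuA
re-reduction, baseline activation μ_n, the venous Hill midpoint) are
*derived at parameter-set construction* so that, with default parameters
and reference inputs (SaO₂ 0.96, Pa = `pa_n`, PaCO₂ 40 mmHg, no
occlusion), the steady state sits exactly at the named values (lactate at
`lac_n`, CuA at `oxfrac_n`, pH at `ph_m_n`, ATP at its pool reference).
`steady_state` then polishes the analytic point by root-finding (residual
tolerance 10⁻¹⁰ per scaled component), which also handles perturbed
parameters and off-reference operating points (after a relaxation
integration, since some corners approach their fixed point on multi-hour
lactate/pH timescales).

### Numerical choices

* LSODA with rtol 10⁻⁷/atol 10⁻⁹ (per-state scaled) for presentation runs;
  rtol 10⁻⁶ inside optimisation loops. Halving tolerances moves observable
  extrema by far less than 0.5 % (tested).
* `max_step` is capped at the input-grid spacing. Piecewise-linear drivers
  are invisible to the error estimator once a step spans them; without the
  cap the solver can grow its step during the flat baseline and partially
  skip the insult ramp.
* Inputs are linearly interpolated between samples; the occlusion ramp in
  the generated protocol spans two 60-s samples, so state discontinuities
  never reach the solver.
* Smooth `softplus` floors replace hard clamps (vascular activation,
  anaerobic flux, venous-saturation floor) to keep the right-hand side C¹.
* States with hard physical bounds are kept inside them by construction of
  the rates (multiplicative proton dynamics, redox fraction with
  complementary-rate form, Pi-limited ATP synthesis); trajectories are
  checked after integration and violations raise rather than clip.

### Magnitudes and known compressions

Phosphorus pools use ³¹P-visible magnitudes (ATP 2.4 mM, PCr 6.5 mM at
baseline, total creatine 12 mM). Baseline oxygen extraction is 0.33
(venous saturation 0.64), at the high end of the physiological range; it
sets the extraction reserve and hence the depth of the CMRO₂ drop. The
reduced model reaches the 40 %-of-baseline NTP termination criterion
roughly 15–20 min into the insult, faster than the ~1 h typical in vivo:
with a single well-mixed compartment and linear ATP-use coupling the
energy state tracks oxygen delivery with little additional delay. The
protocol generator therefore produces shorter insult phases than the real
experiment; all relative (fraction-of-baseline) quantities are unaffected.
Absolute NIRS amplitudes (~0.1 mM ΔHbO₂ swing at 4 % blood volume) are
calibrated to the synthetic generator, not to any in-vivo cohort, since
no absolute amplitudes are available to anchor them.

## Cohort averaging

Each piglet record is manually segmented into five phases (baseline;
insult onset to titration start; titration; release and recovery; post
recovery). Phases are split into ten equal-duration *time* bins (not
equal-count bins; sampling is near-uniform at 1 min, and time bins keep
phases comparable across animals), half-open `[start, end)` with the final
bin closed. Cells average within piglet first, then across piglets with
the n−1 SD convention; missing samples are excluded pairwise and every
cell tracks its contributing count. The section means unroll onto a common
timeline (bin centres within mean-duration phases) to drive the model with
cohort-averaged SaO₂ and Pa. A boundary-suggestion helper based on the
ΔHbO₂−ΔHHb difference is advisory only.

## Morris screening

Classic trajectory design: R = 30 trajectories (default), L = 4 levels,
step Δ = L/(2(L−1)) in unit coordinates, one parameter moved per step,
all draws from one seeded generator. Each run is reduced to a scalar per
output — the RMS deviation of the output trace from its baseline value
over the HI protocol — and parameters are ranked per output by the mean
absolute elementary effect μ*, ties broken by σ then name. Failed runs
drop their trajectory with a warning; half failing is an error.

Screening (and fitting) ranges express each parameter's physiological
uncertainty rather than a uniform factor: concentration-like parameters
are loosely constrained (the CCO pool most of all — its calibrated value
is more than triple the nominal one) and get wide multiplicative ranges,
while the reference pressure (±15 %), vessel radius (±10 %), CuA oxidised
fraction (±10 %), pH (6.9–7.2), carotid fraction (0.6–0.95) and the
autoregulation constant (0.5–1.0) are tightly known. A uniform
[0.5×, 2×] box was tried first and rejected: it is dominated by
physiologically absurd reference-pressure excursions and produces frequent
integration failures at its corners.

## Calibration (PSwarm-style fit)

The objective is a normalised sum of squares: for each fitted signal
(ΔHbO₂, ΔHHb, ΔoxCCO, pH; equal weights by default) the
simulated-minus-observed residual is divided by the observed signal's SD
(floor 10⁻⁶) and averaged over the grid. Simulation failures inside the
search return a large finite penalty (10⁶) so the search continues.

The optimiser is a global-best particle swarm (inertia 0.72,
cognitive/social 1.49, reflection at bounds to preserve diversity, seeded
and fully deterministic) followed by a coordinate pattern search from the
best point. The Model surface adds two refinements, both on by default
there and off in the bare functions:

* **Ridge regularisation** (weight 10⁻⁴ on the mean squared displacement
  from the reference set in bound-box coordinates). The four traces do not
  identify all ten parameters: the autoregulation constant is nearly
  unidentifiable, and curved combinations of haemoglobin, CCO pool, vessel
  radius and oxidised fraction are almost trace-equivalent. The ridge is
  negligible wherever the data inform a direction and collapses the flat
  directions to the reference values.
* **Gauss–Newton polish** (bounded trust-region least squares on the
  residual vector), started both from the swarm's best point and from the
  reference point. Coordinate moves cannot follow the curved, nearly flat
  valleys of this objective; the Gauss–Newton steps can, and the reference
  start follows the gradient of the actual displacement rather than a
  mimicking basin.

Joint fitting of all four signals over the complete experiment is used
throughout (per-phase parameter sets are out of scope).

## Synthetic cohorts

The generator emulates the experimental protocol: 10 min baseline; insult
onset with occlusion and a 2-min desaturation ramp to SaO₂ 0.30; arterial
pressure rising ~5 mmHg just after onset and then dipping ~10 mmHg below
baseline; insult terminated when the model-simulated NTP falls to 40 % of
baseline (closed loop with the model; fallback 1 h), then a 10–20 min
titration back to normoxia with occluders released at its end; 1 h
recovery and 1 h post-recovery. PaCO₂ is constant at 40 mmHg. SaO₂ is
parameterised directly (no inspired-oxygen-to-saturation model).

Cohorts draw per-piglet phase durations (lognormal, CV 0.2) and
ground-truth parameters (lognormal CV 0.1; logit jitter for fractions;
additive 0.02 for pH) around a common truth, one draw per piglet, then
add i.i.d. Gaussian noise with SD equal to 10 % of each signal's range.
What this does *not* emulate: autocorrelated instrument noise, motion
artefacts, drift, the occasional total-haemoglobin rise from vertebral
back-circulation (available as an opt-in anomaly hook), or real biological
phase-coupling between parameters. Passing recovery tests therefore
demonstrate that the estimation machinery works under the stated
statistical structure, not that it is robust to everything real data do.

## Known limitations

* Parameter recovery from cohorts with full inter-piglet variability is
  biased for weakly identified parameters (the phase-normalised averaging
  distorts the pH tail that identifies the lactate pool); the
  measurement-noise recovery harness therefore uses homogeneous cohorts.
* No cell death: CMRO₂ recovers fully after release, so the persistent
  post-insult metabolic depression seen in vivo is not reproduced.
* One lumped compartment; no distinction between cortical NIRS and
  deep-white-matter MRS sampling volumes.
* The NTP-depletion timescale is compressed relative to the in-vivo hour
  (see above).
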