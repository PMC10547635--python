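# Model and methods

`scinject` simulates the *injection event* of a subcutaneous (SC) dose: the
physiological state of the adipose tissue receiving it, the geometry and
composition of the formulation depot, the tissue backpressure felt at the
needle, and the formulation lost through the puncture hole if the needle is
withdrawn early. It deliberately stops where absorption modelling begins:
the voxel fields and flow summaries it produces are *initial conditions*
for a downstream disposition model, not predictions of plasma exposure.

Everything is deterministic; there is no random number generator anywhere
in the model.

## Adipose physiology

The capillary blood fraction of adipose tissue is
θ_blood = (V_blood·D_adipose/M_adipose)·(Pblood_cap/100)·(PCO/100); with the
default adult-male covariates (V_blood = 5.21 L, M_adipose = 12.5 kg,
D = 0.92 g/mL, 6% capillary blood, 5% partial cardiac output) this is
≈0.00115. Perfusion is PR = CO·PCO/100 and interstitial-fluid (IF)
production QIF = R_IF/B·PR/M, with R_IF/B = 20/8400 ≈ 0.0024 the resting
IF-to-blood filtration ratio. IF partitions 15% to lymph, 85% to venous
reabsorption; the partition is implemented so the two flows sum to the
input exactly (the lymph share is re-derived from the venous remainder to
cancel rounding).

"Life events" (exercise, posture, sleep, stress, meals, external
temperature, GLP-1 agonists, needle insertion) multiply the resting blood
flow. Simultaneous events compose multiplicatively. Design choices where
only ranges or anchors are reported:

- sleep is a configurable constant factor, default 1.8 (reported range
  1.8–3.0); no time course is imposed;
- the meal response doubles flow at meal start and decays linearly to
  baseline over the event window (recommended 2–3 h); it is suppressed
  entirely in obesity;
- the age effect (−26% between 28 and 63 y) is linear in age and clamped
  outside that interval;
- the temperature response is a linear slope per °C, default 0 (off),
  because no slope value is available to ship;
- needle-insertion hyperaemia (7× at insertion, exponential decay with a
  23-min half-life) is a *local* channel, kept separate from the systemic
  multipliers because it only affects the injection site;
- type-2 diabetes scales the systemic baseline by 0.624 and caps the
  exercise response at 1.2×.

## Interstitial-fluid rheology

IF viscosity is dominated by free hyaluronan (HA). The specific viscosity
is the virial-type fit η_sp = C[η] + 0.42(C[η])² + 7.77e-3(C[η])^4.18
(fitted for C[η] in [0.1, 46]; evaluation outside warns but proceeds — the
dilute lymph states sit below 0.1, where the expansion degrades gracefully
to its linear term). The intrinsic viscosity is [η] = 1.56e-3·MW + 125
mL/g. All lookups use MW = 3.3e6 g/mol, the upper human value. T2D
multiplies adipose HA concentration by 1.5 (105–195 vs 70–130 μg/mL).

The water reference viscosity is 0.719 mPa·s (≈35 °C tissue temperature)
and configurable: relative viscosities are defined "to water" without a
fixed temperature, so the reference is exposed rather than hard-coded. The
"mid" adipose level (100 μg/mL) is the healthy-human average also used as
the enzyme module's initial HA concentration. Shear-rate dependence is
ignored (Newtonian assumption): IF shear stays below the ~3 s⁻¹
rheo-thinning onset for almost all of an injection.

## Tissue hydraulic conductivity

Carman–Kozeny per fibre population: K_i = θ_EC³/(G·S_i²) with S_i = 2φ_i/r_i
and G the Happel–Brenner factor for randomly arranged cylinders
(G(0.103) = 4.84). Populations combine in series, K_app = 1/Σ(1/K_i),
and collagen (thinnest fibres, largest wetted surface) dominates: removing
any other population moves K_app by <1%. Our full-precision evaluation of
the default four-fibre table gives K_app = 5.73e-17 m²; the tabulated
per-fibre conductivities round to slightly different values (~1%), and the
widely quoted figure for this composition is 5.67e-17 m², which is what the
pressure module uses as its default `k` (the ≈1% difference cancels in all
pressure *ratios* and is far below the biological spread — a measured rat
value is 7.12e-18 m²). Fibre volume fractions are shipped as literals with
their %w/w and fluid-uptake provenance columns, because the mass→volume
conversion chain is not fully specified.

## Depot geometry and fields

The depot is an ellipsoid centred at the needle tip: vertical semi-axis WFV
along the needle, two horizontal semi-axes WFH = E·WFV. We use the volume
convention V_app = (4/3)π·WFH²·WFV (two horizontal axes), which is the one
self-consistent with E = WFH/WFV and with horizontally spreading depots.
Elongation follows E = 0.574·(V[mL]·Q[μL/min]^{1/3})^{0.4828}, clamped at 1
(spherical regime at low volume-rate products). Because E grows ≈ t^{0.48},
WFV ∝ (t/E²)^{1/3} ≈ t^{0.01} once elongated — vertical growth effectively
halts, which is what produces the pressure plateau (phase 2). The average
relative content of solution (RCS) ε defaults to 0.13 (reported range
0.14±0.04 up to 0.31 across imaging datasets); geometry contains no
viscosity dependence at all.

The local RCS profile is the error-function sigmoid
RCS(r) = (RCS_max/2)(1 + erf((αWFX − βr)/WFX)) evaluated on the normalised
elliptical radius; defaults RCS_max = 0.2, α = 2.0, β = 2.2 give
RCS(0) ≈ RCS_max, RCS ≈ 0 at the waterfront and a mid-depot inflection.
These are fitting parameters in origin; since they are not published for
any dataset we ship them as configuration, and a global rescale enforces
exact (≤1e-6 relative) conservation of injected volume and dose on the
voxel grid regardless of their values. Mobile interstitial protein starts
at baseline × (1 − RCS/RCS_max), clipped to [0, 1]: zero where the
formulation fully displaced the IF, baseline outside the waterfront. Grid
default 50³ voxels (32³ also used), voxel edge auto-sized so the half-span
is 1.2× the final WFH; voxel centres sit at half-integer offsets with the
needle tip at the grid centre. Convergence: doubling 50³→100³ moves the
pre-scaling enclosed volume by ~0.02%.

## Backpressure (five phases)

Phase 1–2 (injection): P(t) = F·Q_inj·η_app·4π·WFV(t)²/k, a Darcy law in
which the resisting length is proportional to the spherical part of the
depot surface. η_app = 0.1·η_formulation + 0.9·η_IF is the viscosity of
the mixed fluid in the high-resistance "onion ring" at the depot edge
(local RCS ≈ 0.1). The factor F = 2 ln(Q_inj/V_inj²) + 5 is an empirical
fit evaluated with Q in μL/min and V (the *total* planned volume) in mL,
exactly as fitted; its implicit m⁻³ scale is absorbed by a calibration
constant `f_calibration` (default 1), the single acknowledged dimensional
fudge in the model. With the defaults, a 2 mL saline injection at 120 mL/h
plateaus near 13 kPa and 0.5 mL at 6 mL/min near 28 kPa — the few-to-tens
of kPa range seen in porcine measurements.

Throughout, fluid leaves the depot surface into intact tissue at
Q(t) = k·(P_tissue + P_bleb)/(F·η_app·4π·A_eff), with
A_eff = ((WFH^3.2 + 2(WFH·WFV)^1.6)/3)^{1/1.6} an ellipsoid surface-area
mean that reduces exactly to R² for a sphere.

Phase 3 (needle in place): only 2.5% of the injected volume — the stressed
shell at the depot edge — holds the pressure. The tissue component decays
as P_tissue(t) = P_end·max(0, 1 − drained/V_stress), where `drained`
integrates Q(t) (plus any puncture leak) from the end of injection and
V_stress is fixed at its end-of-injection value. The literal product form
(rescaling again at removal) is first-order identical over the 25 ms leak
window; the running-fraction form is used because it is the unique
expression consistent with the phase-3 definition. The tissue component is
monotone non-increasing by construction and floors at zero.

Phase 4 (needle removal): the needle leaves a puncture cylinder of dead
volume π·L_N·R_ext² (1.82 μL for a 6 mm, 0.311 mm-radius needle) that leaks
for Δt = 25 ms by Hagen–Poiseuille, Q_leak = P·πR_ext⁴/(8η_form·L_N),
driven by the *total* pressure (tissue + bleb). Leaked volume depletes the
stressed volume and the bleb alike. Removal during injection stops
delivery immediately; the undelivered device volume is added to the dose
loss. Backflow is insensitive to formulation viscosity because pressure
scales with η_app while the leak resistance scales with η_form — the
cancellation is exact (bit-for-bit in the implementation) when both
viscosities scale together and the bleb term is absent, and approximate
otherwise.

Phase 5 (residual): the bleb — modelled as a spherical cap under a skin
patch — exerts P_b = δ·St_skin with δ = atan(h/a) the cap angle. The cap
base radius is the wider of the configured patch (default 20 mm) and the
depot's horizontal waterfront, which keeps large-volume blebs shallow. The
default stiffness 19.2 kPa/rad is calibrated so a 2 mL abdominal bleb
exerts ≈3 kPa, the residual pressure measured in pigs. Bleb volume is
everything delivered minus puncture losses while the needle track is open;
after the hole collapses, the continuing Darcy outflow dissipates it
slowly. The ~3.75 kPa minimum-injection-pressure observation is *not*
imposed as a floor; no equation uses it.

### Bookkeeping and invariants

delivered = in-depot + relaxed-out + leaked holds to machine precision at
every step; phase labels are non-decreasing 1→5; total pressure is never
negative. Leakage is bounded below by the dead volume, decreases with
injection rate at fixed volume (faster injections leave less pressurised
fluid by a fixed removal time), and for long holds collapses to the dead
volume alone.

### Numerics

Explicit Euler on piecewise-uniform grids: 1 ms during injection, 10 ms
elsewhere, and 0.1 ms inside the 25 ms leak window — at high removal
pressures the leak can drain the stressed volume in under a millisecond,
and the finer step keeps the Euler overshoot of that collapse negligible.
All right-hand sides are smooth and non-stiff at these scales. A time step
larger than the leak window is rejected as a configuration error. Test and
validation runs use 5 ms / 20 ms steps, which change peak pressures and
losses by well under 1%.

## Hyaluronidase

Michaelis–Menten degradation v = V_max·[HA]/([HA] + K_m) with
V_max = 1.7 nM/s, K_m = 0.9 mg/mL, k_cat = 41 s⁻¹; the substrate ratio is
formed on mass concentrations as reported (any molar conversion cancels
inside the ratio). The rate depletes the molar pool of intact chains
(initially [HA]₀ = 100 μg/mL at MW₀ = 3.3e6 → 30.3 nM) and produces an
equal molar pool of 20 kDa fragments, so consumed HA equals produced
fragments in molar equivalents at every step and the apparent molecular
weight MW(t) = ([HA]·MW₀ + [P]·MW_f)/[HA]₀ falls from MW₀ to MW_f. MW₀
defaults to 3.3e6 g/mol (the tissue HA value used everywhere else; a
330 kDa initial MW would be inconsistent with the 1e6 Da floor below). The
pressure factor scales as F(t) = F·MW(t)/MW₀, frozen once MW reaches
MW_end = 1e6 Da — beyond that point degradation no longer reduces the
resistance, leaving a lower plateau roughly 3× below the untreated one.
rHuPH20-containing runs default to a 2× V_max multiplier (the value that
reproduces the observed pressure-drop timing at the 25,000 U/mL anchor);
the multiplier is the only exposed dose→activity mapping. With
V_max = 0 the coupled simulation is bit-identical to the enzyme-free one.

## Scenarios, fixtures and problem sizes

Scenario configs are YAML (plain JSON loads unchanged) with fixed units
per key and unknown keys rejected. Shipped fixtures encode the standard
study conditions: 0.5 mL saline at 6 mL/min through a 6 mm 32G needle
(healthy vs T2D, paired at the *extreme* adipose-IF relative viscosities
1.43 vs 2.47 — the widest tabulated spread, which reproduces the reported
≈60% T2D peak-pressure increase; adjacent pairings give 16–30%); 2 mL
saline at 20/120/360 mL/h in pig (IF viscosity 1.66 mPa·s, the healthy
average); and 10 mL of a 7.2 mPa·s IgG solution at 120 mL/h with and
without rHuPH20. A synthetic pen-needle grid (32G/31G/29G × 100–800 μL ×
two rates, T2D IF viscosity 2.08 mPa·s) exercises the leakage harness; its
observed-leakage fields are placeholders to be filled with measurements,
at which point the harness reports AFE = exp(mean|ln(pred/obs)|) and the
mean absolute percent error. Long fixtures (300 s injections) run at 10 ms
steps; the short ones at the 1 ms default. A full fixture run takes a few
seconds on one core.

## Known limitations

- Validated regime: ≤2 mL/min for viscous (>10 mPa·s) solutions and
  ≤12 mL/min for low-viscosity ones; the model overpredicts backpressure
  for fast viscous injections (a warning is emitted) and imposes no
  poroelastic cap on tissue pressure.
- Non-Newtonian formulations are out of scope (needle-tip shear thinning
  is not modelled).
- The skin/bleb model is a calibrated spherical cap, not a mechanical skin
  model; site- and species-specific stiffness must be supplied.
- The depot fields are initial conditions only: protein back-diffusion,
  drug binding, degradation and absorption are downstream concerns.
- The synthetic leakage grid emulates device geometry and protocol spread
  but not biological variability (tissue heterogeneity, angle effects,
  operator factors), so passing its property checks shows internal
  consistency, not clinical accuracy.
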