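# Methods

`vaoflow` is a desk-scale, fully scripted model of how the vertebro-subclavian
(VA-SCA) bifurcation angle shapes the hemodynamic environment at the
vertebral artery origin (VAO), together with the statistical analysis that
relates that morphology to plaque status in a (synthetic) clinical cohort.
This note records the models, the numerical choices, and what the desk-scale
results do and do not show.

## Geometry: a planar analog of the bifurcation

The lumen is modelled in its bifurcation plane: a straight subclavian (SCA)
channel of width 8.4 mm with a vertebral (VA) side branch of width 3.3 mm
leaving the far wall at angle θ (30°–110°, measured against the distal SCA
direction) and running 40 mm along its centerline to the VA outlet. Channel
widths equal the vessel diameters, so the in-plane separation and
recirculation physics at the ostium — the mechanism under study — is
retained, while the computational cost stays desk-scale. The model does not
capture out-of-plane secondary (Dean-type) flows or the 3D flow split; a 3D
extruded STL surface export is provided for users with external solvers.
The wall thickness of the source anatomy (0.5 mm) is recorded but unused:
the solver assumes a rigid wall, so only the lumen is meshed.

Parameters not fixed by the source model and chosen once here: inlet and
SCA-outlet extensions of 3 SCA diameters (so the boundary conditions do not
contaminate the junction), and a 0.5 mm junction fillet to avoid singular
corners. Both are exposed in the configuration. Realised branch angles are
within ±0.5° of the request at all five study angles.

Meshing is a deterministic structured transfinite triangulation: a tensor
grid in the SCA whose upper-wall nodes conform exactly to the base nodes of
a ruled grid in the VA, each quad split along the better diagonal; boundary
nodes near the two junction corners are snapped onto the fillet arcs with a
short local relaxation. Medial (flow-divider side) and lateral
(ostium-upstream side) VAO walls are tagged by the side of the VA
centerline, and each wall facet carries an arc-length coordinate from the
ostium. "Patient-like" variants apply a smooth seeded sinusoidal
displacement of the VA centerline and a width modulation (≤ 20% of the VA
diameter), vanishing at the ostium and the outlet; amplitude 0.1 keeps the
realised angle within ±5°.

## Blood rheology

Casson shear-thinning apparent viscosity,

μ(γ̇) = (√μ∞ + N∞/√γ̇)²,  N∞ = μ_p (1 − Hct)^(−1/4),

with plasma viscosity μ_p = 0.00145 Pa·s and hematocrit 0.4. The
high-shear asymptote μ∞ defaults to 0.0035 Pa·s (the standard asymptotic
blood viscosity) via an explicit override; a √Hct-proportional coefficient
form (calibrated so Hct = 0.4 gives 0.0035 Pa·s, hence monotone in red-cell
concentration) is kept for sensitivity runs. The γ̇⁻¹ singularity at
stagnation points is regularised by clamping the shear rate below at
γ̇_floor = 10⁻³ s⁻¹, the standard Casson regularisation; at the floor the
apparent viscosity is ≈ 0.012 Pa·s, ~3.5× the asymptote. A `newtonian`
switch replaces the model by a constant 0.0035 Pa·s for benchmarks.

## Boundary waveforms

Flow and pressure over the cardiac cycle (T = 0.8 s, 75 bpm) are a mean
plus four cosine/sine harmonics; the flow series has mean 2.6483 cm³/s and
the pressure series mean 11 328.663 Pa. The flow series is applied at the
SCA inlet as the instantaneous cross-section-mean velocity U(t) = Q(t)/A
with A the circular lumen area of the 8.4 mm vessel (0.5542 cm², mean
velocity 4.78 cm/s); the spatial profile is the closed-form oscillatory
plane-channel (Womersley-type) solution per harmonic, whose cross-channel
average equals U(t) exactly. The pulsatile pressure series, phase-shifted
by π/2 and referenced to zero gauge (only pressure differences matter in
rigid-wall incompressible flow; the 102.3 kPa gauge figure is stored but
subtracted), is imposed weakly as the traction at both outlets, so the
SCA/VA flow split emerges from the geometry rather than being prescribed.
The peak inlet Reynolds number under these conditions is ≈ 130, far below
the 2300 laminar bound. Note the printed harmonics are small (~5% of the
mean): the inflow is only weakly pulsatile, which matters for the OSI
magnitudes discussed below. A nominal "16 cm/s fundamental peak velocity"
constant is stored for reference but is unused, being inconsistent with
Q̄/A for either vessel diameter.

## Flow solver

Incompressible Navier–Stokes with the Casson viscosity on the planar mesh,
discretised with inf-sup-stable Taylor–Hood elements (P2 velocity / P1
pressure, stress form). Time stepping is SBDF2 (backward-Euler first
step): the time derivative and a constant reference viscosity μ_ref
(default μ∞) are implicit, while convection and the shear-dependent part
of the Casson viscosity, μ(γ̇) − μ_ref, are explicit with one Picard sweep
per step (viscosity lagged at the previous step). This yields one constant
saddle-point matrix per run, factorised once (sparse LU) and reused every
step — the dominant cost is then a pair of triangular solves plus one
vectorised residual assembly per step.

Because the velocity–pressure system is solved monolithically, the discrete
continuity rows hold to direct-solver precision, and the inlet/outlet flux
balance closes at machine level (measured defect ~10⁻¹³ every recorded
step). This is the reason a coupled solve was preferred over a
pressure-correction splitting, whose projected velocity satisfies the
constraint only approximately.

Stability: with explicit convection against implicit diffusion the scheme
requires roughly dt ≲ 2ν/u² (≈ 0.8 ms at SCA speeds, ν = μ∞/ρ). The
default dt = T/1600 = 0.5 ms respects this with ~2× margin while resolving
the 4th harmonic with 400 steps per period; dt must divide T exactly. Runs
start from rest; two cycles are simulated and the second is recorded, so
one full cycle washes out the start-up transient (cycle periodicity of the
monitored velocity is within 0.1% on the channel benchmark). A divergence
guard aborts when the speed exceeds 100× the inlet peak.

Wall shear is the tangential part of the viscous traction
μ(γ̇)(∇v + ∇vᵀ)·n evaluated at each wall-facet midpoint from the adjacent
element, with μ from the local shear rate. Recorded magnitudes are capped
at 5 Pa — reproducing the post-processing guard of the source setup — with
capping events counted; the cap never engages under the study conditions
(raw maxima ≈ 0.2 Pa) and can be disabled.

Verification oracles: steady plane Poiseuille is reproduced essentially
exactly (the parabola lies in the P2 space; wall shear matches 6μU/h to
<0.1%); the single-harmonic oscillatory channel matches the analytic
Womersley solution with relative L2 error ~4×10⁻⁵ at the 0.3 mm mesh; and
dt-refinement of that benchmark shows the expected observed order ≈ 2 of
the time discretisation. (Spatial-order measurement on Poiseuille itself is
meaningless here — the exact solution is representable — so the observed-
order check uses the time discretisation instead.)

## Wall metrics and vortex detection

Per wall facet, over the recorded cycle (trapezoidal quadrature):

* TAWSS = (1/T)∫|τ| dt, reported in dyn/cm² (1 Pa = 10 dyn/cm²);
* OSI = ½(1 − |∫τ dt| / ∫|τ| dt) ∈ [0, 0.5], with zero-shear facets and
  exactly time-constant vectors defined as OSI 0.

Region summaries are length-weighted means over the tagged medial and
lateral VAO walls, plus the lateral arc fraction with OSI > 0.2 (the
significant-oscillation threshold; TAWSS < 4 dyn/cm² is the atherogenic
threshold used in interpretation). The segmentation uses the constructive
wall tags; an optional extractor (`oscillation_zone_summary`) instead
averages over the largest arc-connected lateral component with OSI above
threshold, mirroring a feature-zone-based segmentation.

Vortex cores are found from the P1 streamfunction ψ of the peak-flow
snapshot (least-squares fit of ∇ψ to the rotated velocity, exact for
divergence-free fields). Interior local extrema of ψ in the junction
region are candidates; a candidate is a closed recirculation when its ψ
value lies outside the band spanned by the two VAO-wall streamlines — such
a streamline cannot reach any inlet or outlet and must close on itself — a
criterion that remains robust for thin wall-attached eddies that a
velocity-winding test cannot resolve at coarse h (the winding test is kept
as a fallback for free-standing cores). The strongest core (largest ψ
excursion beyond the through-flow band) is labelled lateral-proximal /
central / medial-proximal by cross-channel thirds.

## Mesh convergence

`relative_error` implements the adjacent-level error with the coarser mesh
as reference; `gci` implements three-level Richardson extrapolation with
safety factor 1.25 (standard for three-mesh studies; the source names the
GCI method but no factor) and a fixed-point generalisation for non-constant
refinement ratios (effective 2D ratio (N_fine/N_coarse)^½).
`run_refinement_study` runs the steady solver at the cycle-mean inflow per
level and monitors the section-average velocity on a cross-section through
the VA recirculation zone (1.5 VA diameters downstream of the ostium), the
section most sensitive to the junction flow features; a level is flagged
converged when the error to the next finer level is below 1%.

## Study conditions and desk-scale results

The angle sweep runs θ ∈ {30°, 50°, 70°, 90°, 110°} under identical
settings: mesh size h = 0.4 mm (≈ 7 900 triangles, ≈ 37 000 velocity
unknowns), dt = T/1600, two cycles with the second recorded — about 75 s
per angle on one CPU. These sizes were chosen as the package's desk-scale
operating point; the h-ladder (1.2–0.4 mm) is available for refinement
studies.

What the sweep shows at this scale, robustly across angles: the lateral
VAO wall has lower TAWSS and higher OSI than the medial wall, and a
closed recirculation attached to the lateral wall near the ostium exists at
every angle, strongest at 50° and migrating toward the ostium as θ grows.
Lateral TAWSS means are ≈ 0.3–0.4 dyn/cm² (well inside the < 4 dyn/cm²
atherogenic band) and medial means are ≈ 10–25% higher.

What the planar analog does **not** reproduce: the interior extrema of the
3D study (lateral TAWSS minimum at 50°, lateral OSI maximum at 70°) and
whole-wall lateral OSI magnitudes above 0.2. With the printed, weakly
pulsatile waveform and the pressure-outlet flow split, the VA receives only
a few percent of the inlet flow; the branch flow barely reverses, so
whole-wall lateral OSI means are ~0.003–0.011 and both lateral metrics fall
with θ instead of turning interior extrema (TAWSS decreasing to a shallow
plateau beyond 70° with its sampled minimum at 110°, OSI decreasing
monotonically from its maximum at 30°). Facets
exceeding OSI 0.2 do occur in a small zone near the ostium — the
oscillation-zone extractor reports them — but they do not dominate the
40 mm wall average. The medial/lateral contrast and vortex findings are
therefore the validated desk-scale claims; the angle-trend extrema are
reported as computed and should be read as properties the planar analog
does not carry over from the 3D junction.

## Synthetic clinical arm

No patient data are deposited, so the retrospective analysis runs on
synthetic cohorts whose marginals mirror the published baseline tables:
age ~ N(64.74, 6.9²) years; VA-SCA angle log-normal with median 72° and
log-SD 0.33 (spanning the printed group medians 65.50° and 79.90° and
their IQRs, resampled outside (10°, 175°)); tortuosity straight/mild/severe
with probabilities 124/364, 176/364, 64/364; 50/50 lateralisation; male
0.80, hypertension 0.725, diabetes 0.346, coronary disease 0.209;
log-normal labs fitted to the printed medians and quartiles; VAO length
N(39.3, 8.7²) mm. Plaque status is Bernoulli with planted logit
β₀ + ln(1.84)·(angle/10) + ln(1.34)·I[mild] + ln(2.35)·I[severe]; β₀ is
calibrated by root finding so the expected prevalence equals 158/364. The
angle odds ratio is defined per +10° — the published OR 1.84 states no
increment, and a per-degree effect of that size is implausible against the
printed medians — and this convention is used consistently in generation
and fitting.

The analysis mirrors the published pipeline: a Kolmogorov–Smirnov normality
gate (one-sample, estimated moments, α = 0.05) routes each continuous
variable to a t-test (mean ± SD) or Wilcoxon rank-sum (median, IQR);
categoricals use Pearson chi-square without continuity correction; the
multivariate logistic model (angle per 10° + tortuosity dummies, the
intergroup-differentiated variables; labs and comorbidities are generated
but excluded from the default model) is fit by IRLS maximum likelihood with
Wald 95% CIs, with (quasi-)separation surfaced as an error. Monte-Carlo
recovery over 500 replicates at n = 364 returns a mean angle OR ≈ 1.88
with ~95% CI coverage of the planted truth.

One documented discrepancy: Pearson chi-square on the published tortuosity
counts (80/102/24 vs 44/74/40) is 12.80 (df = 2, p ≈ 0.0017) and on the
lateralisation counts 0.40 (df = 1, p ≈ 0.53), while the source prints
P = 0.014 and 0.468 for these rows; the test variant behind the printed
values is unknown, so the package reports the computed statistics.

What passing these tests shows — and what it does not: the synthetic
cohorts demonstrate that the estimation pipeline is unbiased and correctly
calibrated under the planted model; they say nothing about confounding,
selection, or measurement error in real cohorts, whose covariate
correlations (e.g. angle with tortuosity) are not emulated.

## Known limitations

Planar (2D) flow only; rigid walls (no fluid–structure interaction); left-
sided idealised anatomy; the Casson coefficients follow the source's
parameterisation with a corrupted asymptote equation resolved by the
standard 0.0035 Pa·s override; uniform boundary conditions across angles;
the synthetic cohort has independent covariates apart from the planted
outcome model.
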