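# Methods

This note documents the models, numerical choices and known limitations
behind `cardionuc`, in the order of the analysis chain.

## Strain-coupling assay

The assay treats each paced cell as a periodic system: stimulation
timestamps anchor beat windows of one median inter-stimulus interval,
which are averaged pointwise (`beat_average`), linearly interpolated
onto the 91 Hz nuclear imaging grid (`resample_to`; linear
interpolation because no other kernel is warranted by the data), and
converted to strain against the mean length over the 200 ms window
ending at the first stimulus (`compute_strain`). Strains are stored
signed (compression negative); all coupling-map quantities use
compression magnitudes so "up" means "more compressed", matching how
the assay's outputs are usually plotted. The paired series is shifted
so strain is exactly zero at the stimulus-anchored first sample; this
absorbs baseline noise and enforces the ε(0) = 0 convention.

The coupling curve is split at the sample of maximum |ε_s| (ties to the
earliest sample). Both dampening areas are integrals over |ε_s| — not
time — because they are areas in the strain–strain plane:

- systolic: D_sys = ∫ (|ε_s| − |ε_n|) d|ε_s| over the compression
  branch. Zero for lossless 1:1 coupling; ½·peak² for a rigid nucleus.
- diastolic: the reference line has unit slope and passes through the
  end-systolic point (only its intercept is pinned by the definition;
  the unit slope is this package's choice, configurable in principle
  but fixed here for comparability). D_dia = ∫ (|ε_n| − ref) d|ε_s|
  taken against relaxing |ε_s|, so a nucleus lagging the sarcomere
  yields a positive hysteresis area.

Integration is trapezoidal along the time-ordered arc; sample noise can
make |ε_s| locally non-monotone, which changes nothing about the line
integral, so a warning is emitted only when the backtracking exceeds
10 % of the branch span (a genuine loop). Integrated nuclear strain
uses the absolute length strain only — width strain is not folded in,
and the length axis is the contractile axis the assay is about.

QC gates (resting sarcomere length > 1.7 µm, peak sarcomere strain
> 10 %) are exposed as `qc_filter` but are not applied inside the
pipeline; callers decide which cells enter a summary.

## Finite-element pre-stress model

Geometry (µm): cell radius 35, length 100 (quarter domain r ∈ [0, 35],
z ∈ [0, 50]); nucleus radius 4 with the outer 0.2 µm acting as the
envelope + lamina (NE) shell; MT cage between the nucleus and the
ellipse with semi-axes 8 (axial) × 4.4 (radial), so the cage is thick
at the nuclear tips and thin at the sides — the "8 and 4.4 axis
lengths" are read as semi-axes, since full lengths would put the cage
inside the nucleus.

Constitutive set (kPa, kPa⁻¹):

- cytoplasm (myofibrils): linear elasticity with chemo-mechanically
  renormalised moduli. With K = E/3(1−2ν), μ = E/2(1+ν), E = 1.2,
  ν = 0.3, β = 2.77, α_v = 2.3:
  3K̄ = (3Kβ−1)/(β−α_v), 2μ̄ = (2μβ−1)/(β−α_v), ρ̄₀ = βρ₀/(β−α_v),
  giving K̄ = 5.18, μ̄ = 1.66, ρ̄₀ = 7.07 at ρ₀ = 1.2. The rest
  contractility tensor is recovered as a post-processed field.
- MT cage: same passive constants, plus an isotropic active compressive
  stress σ_MT (0.5 at the physiological point).
- nucleoplasm (chromatin): E = 0.15, ν = 0.49; deviatoric response
  linear, volumetric response the stiffening law σ_m = K ln J / J with
  J = 1 + ε_kk (tangent K at J = 1). Rationale: at the kPa-scale
  pressures this model generates, a constant bulk modulus of 2.5 kPa
  would let the nucleus change volume by tens of percent between
  conditions, contradicting the observed < 10 % inter-condition volume
  changes that motivate the near-incompressibility assumption in the
  first place; the log law is the volumetric behaviour a "linear"
  material exhibits in a finite-deformation setting.
- NE + lamina: E = 15 (10 for the lamin-mutant condition), ν = 0.4999.

Kinematics are small-strain throughout. This is a deliberate model
convention: the active terms enter as eigenstresses, and the
homogeneous-cytoplasm configuration then has an exact uniform solution
(ε_zz = 0 at the held ends, σ_rr = 0 at the free surface) used as the
solver's closed-form oracle — with the defaults, far-field axial
tension σ_zz ≈ 2.04 kPa. The radial contraction this model produces is
large, so the fields should be read as the small-strain projection of a
finite-deformation process; stress magnitudes in the thin cage regions
are systematically lower than a finite-strain treatment would give
(the computed cage axial compression spans ≈ 0.6–1.3 kPa against the
1–1.8 kPa expected at the short sides/long tips respectively; the
spatial pattern — maximum at the long tips, minimum at the short
sides — is reproduced).

Discretisation: quadratic (P2) axisymmetric triangles on a structured
"spider-web" mesh whose rays emanate from the nuclear centre, with all
four material interfaces meshed exactly along ray nodes; 2 element
layers across the NE shell; geometric grading through the cytoplasm;
6-point quadrature. Volumetric locking and pressure checkerboarding in
the nearly incompressible shell are removed by a mean-dilatation
(B-bar) formulation — chosen over a mixed displacement–pressure element
as the simpler equivalent remedy; NE element dilatations stay below
0.5 % (tested). The default mesh has ~1700 elements; aspect ratio
changes < 1 % under uniform refinement.

Loads ramp proportionally from (0, 0) to (ρ₀, σ_MT) in 10 steps (the
solution is load-path independent for this constitutive set; the ramp
supports instability bracketing). Each step is solved by Newton
iteration (relative residual 10⁻⁸, automatic increment halving on
failure, the last converged fraction reported on abort).

Condition mapping: the lamin-mutant condition softens the NE to 10 kPa;
LINC disruption multiplies the cage's **active stress** by
`cage_scale` = 0.1. The cage's passive stiffness is kept at baseline by
default because the subdomain represents the crowded perinuclear space,
not the microtubules alone: driving its stiffness to zero creates a
void that mechanically decouples the nucleus from the contracting
cytoplasm — an artifact of the subdomain topology that contradicts the
observed LINC-disruption phenotype (longer, thinner nuclei at constant
volume, unchanged strain transfer). A separate
`cage_stiffness_scale` is exposed for exploring the combined scaling.
The imaging enrichment ratio maps linearly onto `cage_scale` with the
physiological enrichment set to 2.0 (`enrichment_to_cage_scale`); this
mapping is a stand-in, as no quantitative calibration between the two
exists.

Instability: `detect_instability` scans σ_MT, classifying each solution
by where the maximum principal NE stress sits (tip region: deformed
|z| > 0.7 × deformed half-length; ties to "tip"), and refines the
mid→tip switch by bisection; Newton non-convergence is itself recorded
as loss of continuation. With the default NE the switch occurs near
σ_MT ≈ 2 kPa, well above the physiological 0.5 kPa. Limitation: the
physical tip instability is a finite-strain shell-buckling phenomenon;
this small-strain model reproduces the mid-for-WT / tip-beyond-critical
classification but not the dependence of the critical value on NE
stiffness (a softer NE does not lower the critical stress here).

## Imaging

All geometry is computed in physical units: dilation "rings" are level
sets of the anisotropic Euclidean distance transform, and morphology
comes from spacing-aware region properties. The perinuclear ring for
rupture-reporter foci is implemented as a 1-µm-wide dilation ring
(the width reading of an ambiguous description; configurable). Foci
"touching" the nucleus means ≥ 1 pixel of 8-connected (2-D) /
26-connected (3-D) adjacency. Intensity thresholds are in arbitrary
units and only meaningful relative to the synthetic generator's
intensity scale, which is set so the standard gates (600/200 a.u.
reporter, 2000 a.u. damage foci) sit between background and planted
signal. Pole enrichment automates a manual tracing procedure: the
2-µm perinuclear band is partitioned into long- and short-pole sectors
by the diagonals of the principal-axis ellipse frame, and sector means
are normalised to the cytoplasmic ring mean; outputs carry an
"automated pole tracing" flag. The minimum nucleus size gate
(20 µm² / 50 µm³) rejects debris in noisy synthetic tests and has no
counterpart in the original procedure. Chromatin-protrusion scoring is
deliberately not automated (it is a blinded human judgement); the
generator can plant protrusions for visual QC only.

## Biphasic regression

LOESS is tricube-weighted local linear regression (span 0.6 by
default — a smoothing choice, reported with outputs) evaluated on a
uniform 100-point grid; the deflection is the interior argmax of the
absolute second difference, with a flat-curve guard. The piecewise fit
enforces continuity (a hinge, matching the deflection-point reading of
the relationship); the breakpoint is profiled on a 100-point grid over
the central 80 % of x and refined by bounded scalar minimisation within
one coarse step, ties resolved to smallest SSE then smallest
breakpoint, with ≥ 5 points required on each side. Slope standard
errors and two-sided p-values come from the OLS fit at the selected
breakpoint under homoscedastic normal errors, i.e. they are conditional
on the breakpoint estimate. Collinear segments are flagged
unidentifiable rather than erroring.

## Synthetic data

The trace generator emulates 1 Hz paced contractions sampled at 250 Hz
(sarcomere) and 91 Hz (nucleus): a raised-cosine upstroke (150 ms) to
peak compression, a 40 ms quadratic cap, then exponential relaxation
(τ = 150 ms); the cap bounds the waveform's curvature at the peak so
91 Hz sampling does not clip it (physiological transients are smooth).
Nuclear length strain is the sarcomere strain passed through a
first-order lag (50 ms) and scaled so its peak equals the coupling
gain × sarcomere peak; width moves anti-phase at half gain. Presets
encode the study conditions: WT targets 11.4 % sarcomere / 6.6 %
nuclear peak compression (gain 0.579); the lamin-mutant preset (gain
0.65, lag 80 ms) raises integrated nuclear strain by ≈ 30 % through
deeper compression and slower nuclear relaxation; colchicine
accelerates sarcomere relaxation (τ = 80 ms) at slightly higher peak,
leaving the nuclear lag unchanged, which inflates diastolic hysteresis;
LINC disruption leaves coupling untouched. Cell-to-cell dispersions
(peak s.d. 0.018, gain s.d. 0.074) are chosen to reproduce the reported
standard errors (±0.4 % / ±0.3 %) at n = 20 and are assumptions — the
real cell-to-cell variance structure is not published. Noise is
additive Gaussian on lengths (4 nm sarcomere, 20 nm nuclear dimensions).

The image generator renders exact voxel masks (ellipsoids, distance-
transform shells, spheres) before adding optional Poisson + Gaussian
noise, and emits those masks plus per-focus geometry as ground truth;
default voxels are 0.1 × 0.1 × 0.5 µm. It does not simulate optics
(no point-spread function by default, no depth attenuation, no
shot-noise correlation), so passing tests demonstrate correctness of
the measurement definitions, not robustness to real microscope
degradations. The scatter generator draws x uniformly over (0.8, 3.5)
and adds Gaussian noise (s.d. 0.3) to the hinge with breakpoint 1.9,
slopes −2.1/0 and value 2.0 at the hinge, floored at aspect ratio 1.

All generators require a seed and are bit-reproducible.

## Problem sizes

Default analyses run in seconds on one core: 20-cell trace batches,
~1700-element FE solves (a handful of Newton steps each), 300-point
regression fits, and stacks of ~20 × 400 × 400 voxels. These sizes are
the package defaults chosen for interactive use; every routine accepts
larger inputs.
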