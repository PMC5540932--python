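# Methods

## Kinetic model

The target-tissue curve follows the simplified reference tissue model
(SRTM) with a time-dependent efflux increment (LSSRM):

    dC_T/dt = R1 dC_R/dt + k2 C_R(t) − (k2a + γ h(t)) C_T(t),  C_T(0) = 0.

`h` is the unit-peak simplified gamma variate
`h(τ) = (τ/tp)^λ · exp(λ(1 − τ/tp))` with `τ = t − onset`, zero before
onset. Defaults: onset 55 min post injection (the task starts after a
55-min baseline phase), time-to-peak tp = 8 min 20 s, λ = 3. The form is
the standard choice for activation PET: it satisfies the stated
constraints (fixed peak time, shape parameter, onset) exactly, is
continuous at onset, and decays to zero.

Binding potentials: `BP0 = k2/k2a − 1`. For the activation phase the
efflux rate is time-averaged over the activation window
(onset → scan end): `BP1 = k2/(k2a + γ·h̄) − 1` with
`h̄ = (1/|W|)∫_W h`. This reduces exactly to BP0 at γ = 0 and is monotone
in γ (displacement ⇒ BP1 < BP0). The alternative reading — averaging the
instantaneous `BP(t) = k2/(k2a + γ h(t)) − 1` over the window — is
exposed as `mode="bp_average"` in `bp_activation`; the two differ by
under ~2% at physiological parameters. The rate-average is the default
because the averaged quantity (the apparent efflux rate) is the one the
model perturbs linearly.

## Numerical scheme: one quadrature for simulation and fit

Frame data are averages over acquisition frames, and the running
integrals in the operational equation are known **exactly** at frame
boundaries (cumulative sums of value × duration). All integral
quantities are therefore computed on a fine grid (1 s) from an
average-preserving reconstruction: the cumulative integral is
interpolated by a monotone cubic through its exact boundary knots with
zero initial slope (tissue activity starts at zero at injection), and
the curve is its derivative. The design matrix is the frame average of
each term of the operational equation.

The forward simulator solves the same operational equation as a Volterra
integral equation with trapezoidal quadrature on the same grid — the
exact discrete counterpart of the fitted linear system. `fit_lssrm`
additionally iterates a model-refinement step: the within-frame shape of
the target curve is replaced by the current model prediction, offset per
frame so the data's frame averages are preserved exactly, and the system
is re-solved. On noise-free model data this converges to the generating
parameters at solver precision (measured: < 1e−12 relative over 100
random draws spanning R1 ∈ [0.7, 1.3], k2 ∈ [0.1, 0.5]/min,
BP0 ∈ [0.5, 3], γ ∈ [0, 0.05]/min); against an independent stiff ODE
solver (LSODA) on the differential form the forward curves agree to
< 1e−6 relative. A naive alternative — cumulative trapezoids over the 20
frame mid-times — carries 3–5% parameter bias on this schedule and was
rejected.

On noisy data the refinement converges in a few passes; the voxelwise
default is `n_refine=3` (bias ≪ noise there), and `n_refine=0` gives the
familiar one-shot linear solve. When BP0 = 0 (target ≡ reference) the
individual rates k2, k2a are structurally unidentifiable — only their
equality is determined — and fits are judged on the identifiable
quantities. Voxels returning non-physical estimates (k2a ≤ 0 or a
non-positive activation-phase efflux rate) are flagged NaN and counted,
never raised, so parametric maps degrade gracefully.

## Synthetic data

The phantom emulates a bolus-plus-infusion study: 50% of the dose as a
bolus worth Kbol = 80 min of infusion, 20 frames over 79.9 min
(8×2, 4×3, 2×4, 5, 6, 8, 3×8.3 min).

**Reference curve.** One-compartment tissue response to the B+I plasma
input: infusion rise `P(1 − e^{−k2′t})` plus a bolus-mismatch transient
proportional to `bf/(1−bf)·kbol·λ_p − 1`, which vanishes when the bolus
matches plasma clearance — the design point of the protocol (λ_p defaults
to 1/80 min⁻¹ accordingly, k2′ = 0.15/min, plateau 20 kBq/mL). The curve
is continuous with C_R(0) = 0 and changes by < 0.5% between 40 min and
scan end, comfortably inside the < 5% plateau requirement. A literal
"A·e^{−βt}" bolus term was rejected because it jumps to A at t = 0,
which is unphysical for tissue and breaks the zero anchor of the
integration scheme.

**Phantom geometry.** Ellipsoidal striatal search mask of ~2 960 voxels
at 1.5 mm isotropic (~10 cm³), matching the size of an MNI-space striatal
search volume of 2 934 voxels; a ~230-voxel effect blob inside it; a
disjoint reference-region ellipsoid. `PhantomSpec.mini()` scales the
geometry to a ~280-voxel mask at 3 mm voxels for repeated-cohort
experiments; kinetics and noise are unchanged by scaling.

**Kinetics and effect.** Striatal truth R1 = 1, k2 = 0.35/min,
k2a = 0.10/min (BP0 = 2.5, typical for striatal raclopride). Every scan
carries a task-activation γ = 0.01/min (~7% displacement — the task
effect seen in cognitive-activation raclopride studies); trained-group
post-training scans add γ += 0.01/min inside the blob (the
training-induced release increase). Phantom targets are simulated from
the binned reference curve, so the digital phantom is model-true with
respect to the generative model the fits invert; noise-free voxelwise
BP0 errors are < 1e−6.

**Noise.** Additive Gaussian with variance ∝ value/frame-duration
(`sd = 0.5·sqrt(C/Δt)` kBq/mL, ≈ 3–5% of late-frame signal), preserving
the frame-duration weighting structure of PET count noise; true PET noise
(Poisson in reconstruction, spatially correlated) is more complex, so
passing tests demonstrate correct machinery under the assumed noise law,
not scanner realism. Behavioral scores are bivariate normal pre/post
draws with the study's printed group marginals and a default pre–post
correlation of 0.5 (the study reports no covariance; 0.5 is the
conventional middle ground).

Note on behavioral power: with those printed marginals and correlation
0.5, the analytic noncentrality of the group × time interaction at
n = 12/13 is ≈ 2.6, i.e. ≈ 70% power — the generator cannot
simultaneously match the printed marginals, a 0.5 correlation, and the
much larger printed F (which implies a far higher pre–post correlation).
The suite therefore verifies the empirical detection rate against the
noncentral-t prediction rather than asserting a fixed rate.

## Image pipeline

Masked smoothing is normalized convolution: Gaussian-filter the
mask-zeroed image and the mask, divide inside the mask. Out-of-mask
voxels never contribute (edge-preserving; constants are preserved
exactly); FWHM 0 is the identity. Dynamic frames are smoothed before
fitting (the masks exist precisely to support pre-fit smoothing), and
the order is configurable.

Motion screening consumes the 1-Hz six-channel trace: per frame, the
maximum Euclidean translation excursion from the frame's starting
position; ≥ 2.5 mm spawns one additional subframe. Session exclusion —
originally a visual-inspection judgment — is replaced by a reproducible
proxy: excluded when more than 25% of frames spawn subframes. Rotations
are reported but not thresholded (the threshold is a distance).

## Voxel statistics

The 2×2 mixed-design interaction on ΔBP is algebraically a two-sample
comparison of per-subject (post − pre) change scores, which makes
permuting group labels an exact scheme under group exchangeability. The
statistic is a pseudo-t: the pooled-variance image is smoothed with the
masked Gaussian (10 mm FWHM default; 0 recovers the raw t). Family-wise
control uses the permutation distribution of max |pseudo-t| over the
search mask; the identity permutation is always included, full
enumeration replaces sampling when the number of distinct relabelings
(or sign flips, for the paired test) does not exceed the requested
permutation count, and ties count against rejection (p uses ≥, so
empirical p ≥ 1/n_perm). Suprathreshold voxels are those with corrected
p ≤ α; clusters are 26-connected components strictly exceeding the
5-voxel extent rule, reported with peak statistic and peak coordinates
in both voxel and world (affine) frames. Subjects missing any required
session are dropped per analysis.

Calibration and power at the package's chosen study sizes (mini phantom,
7 + 7 subjects, 400 permutations, 200 null / 50 effect cohorts): the
family-wise type-I error measured 0.045 at α = 0.05, and the injected
training effect was detected — with every surviving cluster at the
effect blob — in 50/50 effect cohorts.

## Behavioral statistics

The 2×2 split-plot ANOVA is computed through the sum/difference
transform (group: two-sample on subject means; time and interaction:
on change scores), which is exact, Type III for unbalanced groups, and
reproduces pingouin's `mixed_anova` to 1e−14 on balanced tables. Effect
sizes: η²p = F·df1/(F·df1 + df2); Cohen's d for one-df effects as
d = 2√(F/df_error) — the convention that reproduces the study's printed
d = 2.07 from its printed F(1, 23) = 24.579, adopted as the default and
documented as such. Quartiles for the 3×IQR extreme-outlier rule use
linear interpolation (type 7); removal is single-pass on pre-training
scores. p-values are two-sided throughout.

## Problem sizes

Region fits use the full 20-frame schedule at 1-s quadrature. The
repeated-cohort experiments use the mini phantom (284-voxel mask, 3 mm
voxels, 7 subjects per group, 6 mm pre-fit smoothing, one-shot fits at
6-s quadrature, 400 permutations); these sizes are the package's chosen
experiment scale, with the generator's kinetic and noise parameters at
their defaults.

## Known limitations

- No plasma-input models, MRTM variants, or partial-volume correction
  beyond masked smoothing; inputs are assumed co-registered (no
  registration or spatial normalization).
- The reference region is whatever mask the user supplies (convention
  for raclopride is cerebellum); the pipeline makes no anatomical claim.
- The phantom's Gaussian noise and piecewise-constant anatomy do not
  emulate reconstruction artifacts, spatially correlated noise, or
  motion-induced signal perturbation; the motion trace exercises the
  screening logic only.
- List-mode histogramming, attenuation/scatter correction, and
  motion-compensated reconstruction internals are out of scope.
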