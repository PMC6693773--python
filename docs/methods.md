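# Methods

## The model problem

In-vivo cardiac imaging shows a ventricle that is never unloaded, while a
finite-element stress analysis must start from a configuration with known
(zero) stress. The package's central construct is the two-reference
("2G") model: two distinct zero-load geometries for the same ventricle —
a diastolic one, in which the sarcomere has its relaxed zero-stress
length, and a smaller systolic one reflecting 10–15% sarcomere
shortening. The filling states (begin-filling BF, end-filling EF) are
solved on the diastolic reference, the ejection states (begin-ejection
BE, end-ejection EE) on the systolic reference. A one-reference ("1G")
model, by contrast, can only visit two states (minimum pressure/volume
and maximum pressure/volume); its EF and EE values are aliased copies of
BE and BF and use the wrong pressures, which is exactly the deficiency
the 2G construction removes. Zero-load is itself an approximation to
zero-stress (residual stress is ignored); the isovolumic phases, which
would require a continuously changing reference, are skipped — only the
four quasi-steady time points are computed.

## Constitutive model

Passive myocardium is modeled as hyperelastic, anisotropic and nearly
incompressible with the modified Mooney–Rivlin energy

    W = c1 (I1b − 3) + c2 (I2b − 3) + D1 [exp(D2 (I1b − 3)) − 1]
      + (K1/K2) [exp(K2 (I4 − 1)^2) − 1] + (kappa/2) (J − 1)^2

where I1b = J^(−2/3) I1 and I2b = J^(−4/3) I2 are the deviatoric
invariants of C = FᵀF, I4 = n_f·C n_f is the squared stretch along the
unit fiber direction, and J = det F. Three numerical choices deserve
explanation:

- **Deviatoric split.** Written on the full invariants, the linear
  c1 (I1 − 3) term has a nonzero stress derivative at F = I, so the
  "reference" configuration would not be stress-free once the
  incompressibility constraint is replaced by a finite penalty. The
  J-normalized invariants restore an exactly stress-free reference and
  coincide with the full invariants on isochoric states — every closed-
  form value quoted for incompressible kinematics (biaxial sheets, the
  thick-sphere solution) is unchanged. This matches how general-purpose
  FE packages implement the same energy.
- **Exponent placement in the fiber term.** The product form
  "K1 K2 [exp(I4−1)² −1]" that sometimes appears in print is not
  dimensionally interpretable; the form adopted here,
  (K1/K2)[exp(K2 (I4−1)²) − 1], is the standard exponential fiber-
  reinforcement term with K1 in kPa and K2 dimensionless.
- **Volumetric penalty.** Near-incompressibility is enforced with
  (kappa/2)(J−1)², kappa = 100 (c1 + D1) by default — stiff enough that
  volumetric strains stay at the percent level under physiologic
  pressures without wrecking the tangent conditioning. kappa scales with
  the material when a stiffness scale factor is applied, so calibration
  does not change the compressibility ratio.

Stress is reported as Cauchy stress (push-forward of the analytic
S = ∂W/∂E), strain as Green–Lagrange strain E = (C − I)/2; both kernels
are verified against central finite differences of the energy at random
states to ~1e-9 relative.

Default parameters are c1 = 1.0 kPa, c2 = 0 kPa, D1 = 0.5 kPa, D2 = 3.0,
K1 = 1.0 kPa, K2 = 3.0. The exponents and c2 are the frozen, cohort-wide
values; the kPa-scale stiffnesses are a package choice representative of
compliant passive myocardium (per-participant values are determined in
the pipeline by the volume-matching calibration, not taken from tables).
The biaxial module reproduces the five-ratio protocol (fiber:cross-fiber
stress ratios 10:10, 7.5:10, 5:10, 10:7.5, 10:5) under incompressible
plane-stress kinematics; because the stress is linear in (c1, D1, K1) at
frozen exponents, the least-squares fit is well posed from two stretch
levels up.

## Geometry and discretization

The synthetic ventricle is a thick-walled truncated half-ellipsoid (base
plane z = 0, apex below), represented both as a short-axis slice stack
(ordered CCW contour pairs plus explicit apex heights, the form the
pre-shrink operates on) and as a structured 8-node hexahedral mesh with
`n_layers` transmural layers. The apex is closed by collapsing the last
ring of nodes onto per-sheet pole nodes (degenerate hexes with positive
Jacobians at all interior Gauss points). Fibers are rule-based: a
constant helix angle per layer, measured from the local circumferential
direction toward the meridian in the wall tangent plane; RV defaults are
+40° (endocardium) and −45° (epicardium), the LV convention (+80°/−60°)
is available through the same interface. The frame is built from the
mesh's own long axis, so the fiber field co-rotates exactly with rigid
motions.

The solver is total-Lagrangian: internal virtual work from S at 2×2×2
Gauss points, endocardial pressure as a follower load on the deformed
surface (with its analytic, unsymmetric load stiffness), full Newton with
line-search halving and adaptive load stepping. The volumetric penalty is
integrated with a single central point per element (selective reduced
integration) to limit dilatational locking; the collapsed pole elements
instead integrate it fully, which removes most of their spurious
compliance. Boundary conditions: base-ring nodes keep only their radial
in-plane degree of freedom (axial and circumferential displacement
fixed — the basal plane neither lifts nor spins but expands freely),
imposed through a congruence transformation of the system. No kinematic
statement accompanies the original surface-traction description, so this
is a package decision; it is symmetric, rotation-equivariant, and lets a
hemispherical shell with a sliding base reproduce the full-sphere
solution exactly.

Verification: (i) the assembled internal force equals the gradient of the
total strain energy and the tangent equals the residual Jacobian to
~1e-8 (finite differences); (ii) inflation of a hemispherical shell with
isotropic parameters matches a semi-analytic incompressible thick-sphere
solution (quadrature of Ŵ′(λ)/(λ³−1), itself checked against the
neo-Hookean closed form to 1e-6) within 2% cavity volume at moderate
resolution; (iii) at small pressure the displacement matches the
compressible Lamé solution with moduli consistent with the energy's
small-strain limit (μ = 2(c1 + c2 + D1 D2), K = kappa) within 5% away
from the apex cap. Known limitations: the collapsed-pole region carries a
local displacement bias of order 20–30% that does not vanish under
in-plane refinement, and high-aspect trilinear elements shear-lock
mildly; cavity volumes — the quantity the calibration controls — are
accurate to ≲1% regardless.

## Pre-shrink calibration

`preshrink` scales each inner contour about its centroid by (1 − r),
scales the outer contour by the closed-form factor that restores the
slice's wall area (divided by the axial compression factor, so wall
*volume* is conserved when slice spacing contracts), compresses slice
spacing, and solves the outer apex height so the apex cap's wall volume
is conserved exactly. Total wall volume is conserved to machine
precision under the prismatic rule. A consequence of area conservation
worth recording: for concentric star-shaped contours the outer scale can
never drop below the inner scale, so the wall cannot invert — the
inversion guard in the code is purely defensive. The short-axis and
long-axis shrink rates are tied (one scalar per phase); nothing in the
source procedure prescribes their coupling, and one unknown per phase
keeps the root-finding one-dimensional.

`calibrate_zero_load` evaluates the signed relative volume error of the
re-inflated candidate geometry (diastolic phase: minimum pressure against
the minimum in-vivo volume; systolic phase: end-systole pressure against
the same minimum volume) and drives it below 0.5% by bracket expansion
plus secant steps, starting from 2% (diastole) or 15% (systole) shrink.
The error is monotone in the shrink rate, so the bracket is always valid;
typical runs converge in 3–5 FE solves. `calibrate_material` scales
(c1, D1, K1) — and kappa with them — by one common factor until inflated
volumes match prescribed pressure–volume pairs within 0.2%, by a
log-scale secant; a single common factor is used because no per-parameter
update rule is published, and the trace format leaves room for richer
schemes. The calibrated systolic shrink always exceeds the diastolic one
(the systolic reference must be smaller to re-inflate to the same volume
at a higher pressure).

The 2G cycle solves the four key states on their phase geometries and
repeats the schedule for three periods, accepting the last period once
consecutive periods differ by < 0.1% in sampled stress. For this
history-free hyperelastic quasi-static model periodicity holds from the
second period identically; the check certifies it rather than discovers
it.

## Extraction

Stress and strain are reduced to the largest principal value and sampled
at 100 evenly spaced (equal arc-length) points on the mid-wall contour of
every slice; the reported summary is the mean over all sampled points per
time point. Gauss-point tensors are first projected to nodes by
volume-averaged recovery and then interpolated at the sample points by
inverse distance over the 4 nearest nodes. Raw Gauss-point interpolation
was tried first and rejected: with a strong transmural stress gradient,
the set of nearest quadrature points mixes transmural depths differently
on every mesh, which floors the mesh-to-mesh L1 difference near 5% and
makes the 2% mesh-independence tolerance unreachable; nodal recovery is
the standard smoothing and restores convergence (the refinement study's
final consecutive-mesh difference falls below 2%). The sampling surface
(mid-wall) and the interpolation are package decisions — the source
protocol specifies only the 100 points per slice.

## Synthetic cohorts

`generate_synthetic_cohort` draws BG stress values around the published
BG group means per time point, WG values offset by the group effect
(default 12.9 kPa at end-filling, other time points scaled by the
published gap structure), with the published heteroscedastic spreads
(end-filling SD 9.0 kPa); strains carry no group effect, matching the
reported null strain comparisons; the post-PVR EF change is coupled to
end-filling stress through a Gaussian copula with rank correlation −0.65.
These defaults are the study conditions, not tuning knobs. The generator
emulates the *statistical* structure of the cohort tables — it does not
emulate imaging noise, segmentation error, or any within-patient
correlation across time points beyond the shared group means, so passing
power/type-I tests says nothing about those error sources in real data.

## Statistics and prediction

Rank tests are exact by construction at cohort sizes: the rank-sum null
distribution is enumerated over group assignments (mid-rank ties kept;
enumeration capped at 2×10⁵ arrangements, beyond which a tie-corrected
normal approximation is used and flagged), the signed-rank distribution
by convolution over sign assignments for n ≤ 25. Two-sided p-values are
twice the smaller tail. Spearman's rho is the Pearson correlation of
mid-ranks; its p is exact by permutation for n ≤ 8 and a t approximation
otherwise (full permutation at n = 9–10 costs minutes for no practical
gain at the cohort's n = 12). The exact implementations are tested
against brute-force enumeration oracles.

Outcome prediction uses logit Pr(y=1) = β0 + β1 W with y = 1 for the
better-outcome group. The predictor is z-scored on the training data
(fixed-step gradient descent on raw kPa-scale predictors is unstable) and
the descent runs from β = 0 with a fixed learning rate (0.5 on the mean
negative log-likelihood) to a 1e-8 gradient norm, coefficients bounded at
|β| ≤ 25 against perfect separation. Cross-validation partitions the 12
TOF patients into 5 stratified-as-possible folds (each class dealt
round-robin, the second in reverse fold order), pools each repeat's
held-out probability predictions into one confusion table (threshold
0.5) and one ROC, and averages the metrics over 200 random repeats. AUC
uses the rank (Mann–Whitney) formulation with ties counted half, which
equals trapezoidal integration of the empirical ROC.

## Reproduction notes and known source inconsistencies

The bundled fixture transcribes the published per-participant tables
verbatim; group summaries are always recomputed from them. Observed
reproduction quality, all computed by the test suite:

- The median ΔEF split (−4.95%, printed as −5%) reproduces the published
  6/6 outcome grouping exactly; Spearman correlations of ΔEF with 2G
  end-filling and begin-ejection stress reproduce the printed −0.650 and
  −0.608 to three decimals; the better-vs-worse exact rank-sum p-values
  match the printed ones digit for digit (0.0411, 0.0260, …), which
  identifies the original test as the exact rank-sum.
- Published group means/SDs are reproduced to one unit in the last
  printed digit. Exact half-unit agreement is impossible from the
  published columns for a few cells (e.g. the all-participant 1G BF
  stress mean: the per-participant column gives 3.456 → 3.46, printed
  3.45), because the source summaries were computed from unrounded
  internals. Percent differences are therefore formed from group means
  rounded to table precision, which reproduces the printed figures to
  ≈1% of their value.
- Three source cells are internally inconsistent and are handled
  explicitly: the healthy BF strain mean printed as "0.308" (its own
  column gives 0.031, as printed in the companion comparison table); the
  worse-group mean ΔEF cell printed as "-12." (recomputed −12.4; the
  fixture stores only per-participant values); and the healthy-vs-TOF
  end-filling stress p-value printed as 0.3355 — identical to its
  begin-ejection neighbour — where every rank-based test of the printed
  data gives ≈0.04. One acceptance test asserts that printed
  non-significance as stated and fails; the failure documents the source
  defect.
- The published prediction table reports accuracy 0.5000 exactly, with
  sensitivity + specificity = 1, for sex, ejection fraction and all
  strain predictors — the signature of a classifier emitting one constant
  label per evaluation. A converged gradient-descent logistic fit cannot
  reproduce this: weakly informative predictors acquire small
  anti-predictive coefficients under leave-out training and score below
  chance (a well-known cross-validation effect). Unstandardized
  gradient descent variants were explored and reproduce neither the
  strong predictors' published accuracy nor the degenerate pattern
  coherently; the published behaviour evidently hinges on an unpublished
  detail of the original optimizer. The corresponding acceptance test
  asserts the printed 0.5000 and fails; the informative predictors'
  accuracy (0.80 vs printed 0.8208) and AUC (0.815 vs 0.8135) reproduce
  within the stochastic tolerance, and the published *AUC ordering*
  across all 13 predictors — including the sub-chance strain and sex
  AUCs near 0.19–0.23 — is reproduced, supporting the pooled-probability
  reading of the original protocol.

## Problem sizes

Default test/acceptance resolutions are deliberately modest: the standard
chamber mesh uses 6–12 slices × 12–24 circumferential divisions × 2
layers (a few hundred to ~1500 hexahedra); the sphere benchmark 12×24×2;
the mesh-independence study 14/20/26 slices. Calibrations converge in
3–10 FE solves each. The full test suite runs in a few minutes on one
CPU; `scripts/acceptance.py` in well under a minute.
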