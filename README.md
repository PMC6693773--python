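# ventmech

Patient-specific right-ventricle (RV) wall stress and strain depend on the
*zero-load* reference geometry the mechanics starts from — and because
active contraction shortens the sarcomere zero-stress length, diastole and
systole do not share one. `ventmech` implements a two-reference-geometry
("2G") ventricle mechanics pipeline for studying repaired Tetralogy of
Fallot (TOF) patients against healthy controls, together with the
biostatistics stage that asks whether model-derived stress predicts which
patients improve after pulmonary valve replacement (PVR).

The package covers, as tested library code:

- **Cohort tables** — 6 healthy (HG) and 12 TOF participants (better/worse
  outcome groups BG/WG split at the median post-PVR ejection-fraction
  change), with per-participant mean max-principal RV stress/strain at
  begin-filling (BF), end-filling (EF), begin-ejection (BE) and
  end-ejection (EE) from one-reference (1G) and two-reference (2G) models.
- **Constitutive model** — modified Mooney–Rivlin hyperelasticity for
  passive myocardium,

  W = c₁(Ī₁−3) + c₂(Ī₂−3) + D₁[exp(D₂(Ī₁−3))−1] + (K₁/K₂)[exp(K₂(I₄−1)²)−1] + (κ/2)(J−1)²,

  with Ī₁, Ī₂ the deviatoric invariants of C = FᵀF, I₄ = n_f·C n_f the
  squared fiber stretch, analytic second Piola–Kirchhoff stress S = ∂W/∂E
  and consistent tangent; a five-ratio biaxial testing protocol and
  least-squares recovery of (c₁, D₁, K₁) with frozen exponents
  (c₂ = 0 kPa, D₂ = 3, K₂ = 3).
- **Finite elements** — total-Lagrangian 8-node hexahedra, follower
  endocardial pressure, full Newton with analytic tangent, selective
  reduced integration of the volumetric penalty, verified against a
  semi-analytic incompressible thick-sphere solution and the neo-Hookean
  closed form.
- **Synthetic geometry** — idealized two-layer truncated-ellipsoid
  ventricles as short-axis slice stacks and hex meshes, rule-based helix
  fiber angles (+40° endo / −45° epi for the RV), pressure schedules, and
  synthetic cohorts with the published group-effect structure.
- **2G calibration** — the pre-shrink procedure (inner contour shrunk
  more, outer just enough less that wall volume is conserved) iterated
  until the re-pressurized cavity volume matches its target within 0.5%,
  separately for the diastolic (2% initial shrink) and systolic (15%)
  phases; stiffness-scale material calibration to 0.2%.
- **Statistics** — exact small-sample Wilcoxon rank-sum and signed-rank
  tests, Spearman correlation, single-predictor logistic regression
  fitted by gradient descent, and stratified 5-fold cross-validation
  repeated 200 times with pooled-confusion accuracy/sensitivity/
  specificity and rank-formulation ROC AUC.

## Worked example

Cross-validated outcome prediction from 2G end-filling stress:

```bash
$ ventmech predict --predictor stress_2g_ef --repeats 200 --seed 1
         predictor       column  sensitivity  specificity    auc  accuracy
Stress_End_Filling stress_2g_ef       0.8192       0.7800 0.7397    0.7996
```

Accuracy ≈ 0.80 means that in 5-fold cross-validation repeated 200 times,
the logistic model on end-filling stress assigns about 80% of the 12 TOF
patients to the correct post-PVR outcome group — stress carries real
prognostic signal, while e.g. ejection fraction or any strain summary
performs at or below chance.

The same stress summary correlates negatively with the post-PVR EF change
(patients with higher end-filling stress improve less):

```python
>>> from ventmech.cohort import load_cohort
>>> from ventmech.stats import spearman
>>> c = load_cohort()
>>> tof = c.tof
>>> r = spearman([p.delta_ef for p in tof], [p.stress_2g["ef"] for p in tof])
>>> round(r.statistic, 3), round(r.p_value, 3)
(-0.65, 0.022)
```

`ventmech group-report --out report/` writes the full set of group
summaries, percent differences (e.g. all-participant 2G end-ejection
stress is ~320% above its 1G counterpart — the 1G model's aliased EE
state badly underestimates end-systolic load), exact-test p-values,
Spearman correlations and the 13-predictor CV table.

`ventmech calibrate-2g --out cal/` runs the full synthetic pipeline:
pre-shrink calibration of diastolic and systolic zero-load geometries,
per-phase material calibration, and the three-period quasi-static cycle
with its BF/EF/BE/EE stress/strain summary.

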