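# Methods

## Quantification model

A subject's muscle mass is quantified on one axial PDFF slice at the lower
endplate of L3. The map encodes fat fraction as intensities 0–1000 ≙ 0–100 %;
intensities are clamped to that range on ingest and the number of clamped
voxels is reported, mirroring how artefactual slices are flagged rather than
silently used. Eight binary compartment masks (left/right psoas major,
quadratus lumborum, rectus abdominis, autochthonous back muscles) are trusted
inputs; no segmentation is performed.

- **CSA_Total** counts every mask voxel times the in-plane voxel area.
  Slice thickness never enters a cross-sectional area.
- **CSA_Fat-free** applies `CSA_Total × N(≤ threshold) / N(≤ 1000)` with the
  default threshold 200 (20 % fat). The comparison is inclusive — a voxel at
  exactly 200 is fat-free — because the exclusion criterion is "intensity
  *greater than* 200 implies extramyocellular fat". With clamped intensities
  the denominator is the full mask count, so the formula reduces to
  fat-free-voxel count × voxel area. Raising the threshold can only grow
  CSA_Fat-free; at 1000 it equals CSA_Total (property-tested).
- **PDFF_muscle** averages intensity over the *entire* mask union, septa
  included, and divides by 10 to yield percent. Whether the original
  workflow excluded septum voxels from this mean is not documented; the
  inclusive reading is a recorded choice, consistent with how total CSA is
  defined.
- **AMMI** indices divide CSA by height squared (m²); heights are carried in
  metres here but in centimetres inside the Janssen equation, matching each
  formula's native units.

## BIA model

Only the Janssen skeletal-muscle-mass regression is implemented:
`SMM (kg) = height²/R × 0.401 + sex × 3.825 − 0.071 × age + 5.102`.
The other BIA quantities in the cohort table (total body fat mass index,
lean body mass index, appendicular muscle mass index) have no printed device
equation; they are *generated covariates* in the synthetic cohort, never
computed from resistance — the module is deliberately not a full BIA model.
The generator samples SMI_BIA and then solves the equation algebraically for
resistance, so the forward equation round-trips to 1e-9 relative error; an
SMI below the sex/age intercept share has no positive resistance and raises
an explicit infeasibility error.

## Synthetic cohort

The study conditions are n = 335 with obese probability 95/335 and stratum
male fractions 136/240 (non-obese) and 52/95 (obese). Continuous covariates
are drawn from a Gaussian copula per (obesity × sex) stratum:

- **Marginals** are truncated normals. Published means ± SDs define the
  *truncated* moments; the parent parameters are solved numerically
  (otherwise truncation would, e.g., inflate the non-obese VAT mean by ~8 %).
  BMI is truncated at the 30 kg/m² boundary per stratum, making the WHO
  obesity flag exact by construction. Physiological floors (height > 1.2 m,
  resistance via the inversion, VAT > 5 cm², ...) are config, not code.
- **Correlation targets.** The published unadjusted standardized estimates
  are pooled Pearson correlations, but sampling happens within strata, so a
  pooled target is converted into the within-stratum latent correlation by a
  closed-form solve that accounts for the between-stratum mean component.
  The AMMI_Total–lean-body-mass-index pair uses obesity-specific targets
  (0.74 non-obese / 0.56 obese), which reproduces both the stratified
  regimes and a pooled value of ≈ 0.71.
- **Unreported pairs.** Pairs the study does not report are filled with
  realistic choices (BIA indices mutually 0.70–0.80, height–muscle-index
  0.25–0.30, myosteatosis–fat-free −0.45, adiposity block 0.2). A flat
  near-zero fill is provably infeasible: with the calibrated muscle
  correlations it makes the matrix indefinite, and blind eigenvalue clipping
  would corrupt the calibrated entries. The final matrix is therefore
  obtained by alternating projections onto the PSD cone with the calibrated
  entries held fixed; residual drift on fixed entries is ~1e-7 and is
  reported if it ever exceeds 0.02.
- **MRI targets** (AMMI_Total, AMMI_Fat-free, PDFF_muscle) are sampled
  jointly with anthropometry using the sex- and obesity-specific published
  marginals, so the sex/obesity gradients emerge. The per-subject ratio is
  AMMI_Fat-free/AMMI_Total clipped to [0.05, 0.98] (the joint tail where the
  clip binds has probability < 1e-3), and target CSA is AMMI × height².

## Slice phantoms

Each subject's phantom places eight disjoint quasi-elliptical compartments
(fixed anatomical area shares: psoas 12 %, quadratus 8 %, rectus 10 %,
autochthonous 20 % per side) in a 2 × 4 cell layout on a 160² grid at 1.5 mm
spacing — the source protocol states a 256 × 256 matrix but no field of
view, so spacing is configuration metadata. Voxel counts are apportioned by
largest remainder, so total mask area equals the target CSA within one
voxel. A fraction (1 − ratio) of mask voxels becomes fatty septa: contiguous
clusters (about one per 150 septum voxels) drawn from the configured septum
fat range (default 20.5–28 %, i.e. intensities 205–280). The remaining
voxels receive intensities uniform around a solved intramyocellular mean so
the mask-wide mean equals 10 × PDFF_muscle; the uniform's half-width is
capped so intramyocellular draws stay ≤ 200 and septum draws stay > 200.

A (ratio, PDFF) pair is feasible for this two-class model only if
`(1 − ratio) × 20.5 ≤ PDFF ≤ ratio × 20 + (1 − ratio) × 28`. Infeasible
draws (about a fifth of subjects, mostly low-ratio/low-PDFF) are projected
to the nearest feasible PDFF and the projection is counted in the run
manifest. The projection slightly raises the realised cohort PDFF_muscle
mean (≈ +0.4 points); ratio and CSA are never altered, so the muscle-mass
calibration is unaffected. The septum range default was chosen so the
published mean pair (ratio 57.7 %, PDFF 11.5 %) is comfortably interior to
the feasible region.

What the phantom does *not* emulate: multi-echo Dixon signal formation and
fat–water swaps, partial-volume voxels at fascia boundaries, anatomically
shaped compartments, 3-D volumes, and segmentation error. Passing tests
therefore validate the quantification arithmetic, calibration machinery and
statistics — not robustness to real acquisition artefacts.

## Statistics

Group comparisons use the Welch t test by default (the source analysis says
only "t test"; Student's is available via a switch) and chi-square without
continuity correction for 2 × k counts; Bonferroni adjustment is
min(1, m·p). Standardized OLS regresses the z-scored outcome on the z-scored
predictor plus z-scored age and a standardized 0/1 sex indicator; CIs are
Wald with t critical values at residual degrees of freedom; missing data are
complete-case per analysis. With no covariates the standardized slope equals
Pearson's r to machine precision (tested), which is how the "unadjusted
estimate" column arises.

Null simulations (2000 replicates at n = 335) check the 5 % type-I error of
both tests. CI coverage is checked at a population standardized slope of
0.2 — within the range of the published adiposity associations — because for
strong correlations the Wald interval of a standardized (correlation-scale)
coefficient is conservative by construction; that conservatism is a known
property of the estimator, not a defect of the implementation.

## Problem sizes and numerical choices

End-to-end reproduction runs average 20 cohorts of n = 335 (6700 phantoms,
~40 s) and one n = 5000 cohort for the correlation checks; calibration
invariants use n = 10 000–25 000 draws. All randomness flows through
`numpy.random.default_rng`; per-subject image streams are spawned from a
single `SeedSequence`, so results are independent of iteration order and
bitwise reproducible for a fixed (config, seed). Truncated-normal moment
matching solves to 1e-6; the copula's uniform variates are clipped to
[1e-12, 1 − 1e-12] before the inverse CDF.

## Known limitations

- Adjusted (age/sex) regression estimates are *not* calibration targets: the
  published adjusted β of 0.80 for SMI_BIA vs AMMI_Total exceeds its
  unadjusted 0.67 through the real age/sex covariance structure, which the
  generator only partially encodes. Unadjusted correlations are calibrated;
  adjusted ones merely emerge.
- Risk-factor covariates (impaired glucose metabolism, hypertension) are
  independent Bernoulli draws at the published stratum prevalences; they
  carry no residual association with muscle measures.
- PDFF_muscle inherits a small upward bias from the feasibility projection
  (see above) and is not used as a reproduction target.
- The phantom's background (uniform fat-like intensities) is arbitrary by
  design; only mask voxels enter any measure.
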