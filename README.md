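# musclemap

MRI-based quantification of abdominal skeletal muscle from proton-density
fat-fraction (PDFF) maps, with a bioelectrical-impedance (BIA) reference and
a cohort-level concordance analysis — exercised end to end on a calibrated
synthetic cohort with digital slice phantoms.

## The problem

Skeletal muscle mass predicts outcome across many diseases, but the common
field method, BIA, is known to misestimate muscle in obesity because it
cannot separate intramuscular fat from contractile tissue. Chemical-shift
MRI offers a direct alternative: on a PDFF map (intensities 0–1000 encoding
0–100 % fat), muscle quantified on a single axial slice at the lower
endplate of L3 is a validated surrogate for whole-body muscle mass. This
package implements that quantification and the statistics used to compare it
with BIA in a population cohort (n = 335, 28.4 % obese), for researchers in
body-composition imaging who need a reproducible, testable reference
implementation without access to individual-level cohort data.

## The measures

For eight segmented compartments (left/right psoas major, quadratus
lumborum, rectus abdominis, autochthonous back muscles):

- **CSA_Total** (mm²) — every mask voxel times the in-plane voxel area,
  fatty septa included.
- **CSA_Fat-free** (mm²) — the threshold rule
  `CSA_Total × N(intensity ≤ 200) / N(intensity ≤ 1000)`: voxels above
  intensity 200 (20 % fat) contain extramyocellular adipose tissue and are
  excluded; voxels at or below 200 hold at most intramyocellular lipids.
- **AMMI_Total, AMMI_Fat-free** (mm²/m²) — the areas normalised to body
  height squared, and their ratio (%) as the share of functionally
  contractile tissue.
- **PDFF_muscle** (%) — mean fat fraction over the full mask union
  (myosteatosis).
- **SMI_BIA** (kg/m²) — the Janssen equation
  `SMM = height²/R × 0.401 + sex × 3.825 − 0.071 × age + 5.102`
  (height cm, R in Ω, male = 1), normalised to height squared.

Because the original cohort data are not public, the `cohort` and `phantom`
modules generate a statistically calibrated stand-in: a stratified Gaussian
copula reproduces the published stratum means ± SDs and the pooled MRI–BIA
correlations, and each subject receives a digital PDFF phantom whose
quantification returns that subject's target values to within one voxel.

## Worked example

```bash
python analysis/01_simulate.py   # cohort + PDFF phantoms
python analysis/02_quantify.py   # threshold quantification
python analysis/03_analyze.py    # stratified concordance analysis
```

prints (seed 20240501):

```
cohort: n=335, 28.7% obese, 54.9% male
SMI_BIA mean 9.12 kg/m^2, BMI mean 27.8 kg/m^2
...
CSA_total   mean 8564.3 mm^2
CSA_fatfree mean 4927.7 mm^2
ratio       mean 57.1 %
PDFF_muscle mean 12.3 %
...
r(AMMI_total, lean body mass index): 0.71 (non-obese 0.74, obese 0.57)
r(AMMI_fatfree, SMI_BIA): 0.55
```

A single cohort of 335 subjects fluctuates around the calibration targets
(total CSA ≈ 8759 mm², fat-free CSA ≈ 5100 mm², ratio ≈ 57.7 %); the
correlation pattern — strong MRI–BIA concordance overall, clearly weaker in
the obese stratum — is the study's central finding and emerges here from
the calibrated generator.

The same stages are available as a CLI (`musclemap simulate | quantify |
bia | analyze | run | fixtures`), e.g.

```bash
musclemap bia --resistance 500 --height-cm 170 --age 56 --sex male
# SMM = 28.129 kg
# SMI_BIA = 9.733 kg/m^2
```

## Layout

- `src/musclemap/` — library: `quant` (threshold quantification), `bia`
  (Janssen equation), `cohort`/`calibration`/`phantom` (synthetic data),
  `stats` (tests, correlations, standardized OLS), `pipeline`/`cli`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model assumptions, calibration details, limitations.
- `tests/` — unit, property and end-to-end acceptance tests.
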