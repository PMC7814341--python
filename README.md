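# cacskit

A toolkit for automatic coronary artery calcium score (CACS) quantification
on non-contrast cardiac CT, built for method development and validation at
desk scale. It provides the full chain a CACS method-comparison study needs:

* **Scoring** — lesion extraction at the clinical 130 HU threshold and
  Agatston (AS), calcium volume (VS) and calcium mass (MS) scores at the
  total and per-vessel level (LM, LAD, LCX, RCA), calcified-vessel counting,
  and CAC-DRS categorisation (A0–A3 from total AS, N0–N4 from the number of
  calcified vessels).
* **Synthetic phantom** — a seeded generator of thorax-like CT volumes with
  four parametric coronary vessel territories, cylindrical calcified lesions
  of controlled size and density, and non-coronary "confuser" calcifications
  in the aortic sinus. Every case ships with an analytic ground-truth
  certificate whose scores are computed by independent brute-force
  summation, so the scoring pipeline can be validated *exactly*.
* **Multiview model** — a compact segmentation + score-regression network
  over axial patches with coronal/sagittal context, trainable on phantom
  cohorts in seconds on one CPU, with deterministic seeded training.
* **Agreement analysis** — the automatic-vs-manual comparison battery used
  in clinical validation studies: ICC(2,1) with 95% CI, Bland–Altman limits
  of agreement, paired t, exact McNemar, Wilcoxon signed-rank on CAC-DRS
  categories, voxelwise per-vessel F1, and reclassification tables.

## The scores

With lesions defined per axial slice as 2-D connected components of voxels
with HU ≥ 130 inside one vessel's mask (8-connectivity, minimum area
1 mm²):

- **Agatston**:  AS = Σ_lesions area(mm²) · w(peak HU), with
  w = 1 for 130–199 HU, 2 for 200–299, 3 for 300–399, 4 for ≥ 400;
  defined on 3 mm axial reconstructions.
- **Volume**:  VS = (number of supra-threshold labelled voxels) · voxel
  volume, in mm³.
- **Mass**:  MS = c · Σ_lesions mean HU · lesion volume (cm³), in mg, with
  calibration c = 0.79 mg·cm⁻³ per HU by default (typical for 120 kV).
- **CAC-DRS**:  A0 (AS = 0), A1 (0 < AS < 100), A2 (100 ≤ AS < 300),
  A3 (AS ≥ 300); N*k* for *k* calcified vessels (AS > 0).

## Worked example

```python
from cacskit import PhantomSpec, LesionSpec, generate_phantom, score_case

spec = PhantomSpec(
    shape=(10, 64, 64),                      # 10 slices of 3 mm, 0.5 mm pixels
    lesions=[LesionSpec(vessel=2,            # LAD
                        center=(21.0, 16.0, 16.0),
                        radius_mm=0.6, axial_extent=1, peak_hu=450.0)],
)
volume, mask, certificate = generate_phantom(spec)
result = score_case(volume, mask)
print(f"Agatston total : {result.agatston['Total']:.2f}")
```

prints

```
Agatston total : 5.00
  per vessel   : LM 0.0  LAD 5.0  LCX 0.0  RCA 0.0
Volume score   : 3.750 mm^3
Mass score     : 1.3331 mg
CAC-DRS        : A1/N1
Certificate AS : 5.00 (exact match: True)
```

The lesion covers five 0.5 mm pixels (area 1.25 mm²) at 450 HU (weight 4),
so AS = 1.25 × 4 = 5.0; five voxels of 3 × 0.5 × 0.5 mm give VS = 3.75 mm³;
MS = 0.79 × 450 × 0.00375 ≈ 1.333 mg. A positive score in one vessel makes
the case CAC-DRS A1/N1, and the pipeline reproduces the phantom's analytic
certificate exactly.

## Command line

```bash
cacs phantom --n-cases 46 --seed 7 --out cohort/        # NIfTI + certificates
cacs score --volume v.nii.gz --mask m.nii.gz --out report.json
cacs train --cohort cohort/cohort.csv --seed 7 --out model/
cacs predict --model model/ --volume v.nii.gz --out-mask pred.nii.gz \
             --out-scores scores.json
cacs agree --auto auto.csv --manual manual.csv --out agreement.json
cacs run --seed 7 --n-cases 10 --out run/                # end-to-end
```

`cacs run` generates a cohort, splits it 80/20 by case, trains the model on
the training split, scores every test case from both the predicted mask
(automatic arm) and the ground-truth mask (manual arm), and writes per-case
JSON reports, the agreement battery, and a markdown summary. With a fixed
seed the JSON artifacts are byte-identical across runs.

## Layout

```
src/cacskit/
  core_io.py     volume/mask data model, NIfTI and cohort-CSV I/O
  phantom.py     synthetic cohort generator + ground-truth certificates
  scoring.py     lesion extraction, AS/VS/MS, CAC-DRS
  mvsc.py        multiview segmentation + regression model
  agreement.py   ICC, Bland-Altman, paired t, McNemar, Wilcoxon, F1
  report.py      end-to-end orchestration and report rendering
  cli.py         the `cacs` command
docs/methods.md  models, assumptions, parameter choices, limitations
```
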