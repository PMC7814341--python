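# Methods

## Scoring conventions

Calcified lesions are defined per axial slice as 2-D connected components
of voxels with attenuation ≥ 130 HU restricted to one vessel label.
Defaults, all configurable through `ScoringConfig`:

| parameter | default | meaning |
|---|---|---|
| `hu_threshold` | 130 HU | detectability floor for calcification |
| `min_area_mm2` | 1.0 mm² | components below this area are noise-suppressed |
| `connectivity_2d` | 8 | in-plane neighbourhood for component labelling |
| `mass_calibration` | 0.79 mg·cm⁻³/HU | mass-score calibration, typical at 120 kV |
| `thickness_policy` | warn | behaviour when slice thickness ≠ 3 mm |

The Agatston score uses the standard density weights (130–199 → 1,
200–299 → 2, 300–399 → 3, ≥ 400 → 4) applied to each 2-D component's peak
HU, times its area in mm². It is defined on 3 mm axial reconstructions;
the package deliberately applies **no** slice-thickness rescaling — a
volume with a different thickness produces a warning (or an error under
`require-3mm`) because a silently "corrected" score would not be an
Agatston score in the standard sense.

The volume score counts every supra-threshold labelled voxel (no minimum
area): it is a pure thresholded-volume measure. The mass score is
lesion-based (minimum area applies) using each component's mean HU and its
slab volume `area × slice thickness`. Mass is reported in mg.

CAC-DRS boundaries are implemented gap-free for continuous scores:
A0 iff AS = 0, A1 iff 0 < AS < 100, A2 iff 100 ≤ AS < 300, A3 iff
AS ≥ 300. The published category labels are stated over integer scores
("1–99", "> 300"), which leaves fractional scores in (0, 1) and
(299, 300] formally unassigned; assigning (0,1) to A1 and [300, ∞) to A3
is the only monotone, gap-free completion.

Geometry conventions: arrays are indexed (axial slice, row, column) with
spacing (dz, dy, dx) in mm; coordinates are 0-based and voxel-centred;
world position = origin + index × spacing. NIfTI is the on-disk format
(HU as int16, so integer-valued fixtures round-trip bit-exactly); DICOM
series assembly is out of scope.

## The phantom and its certificate

The phantom emulates the features of a non-contrast cardiac CT that
matter for calcium scoring, not cardiac anatomy per se: a soft-tissue
background (40 HU) with lateral lung bands (−800 HU) and an elliptical
blood pool (45 HU); four fixed parametric vessel territories — a short
left main segment that bifurcates into LAD and LCX, and a separate RCA
arc — scaled to the volume extent; an aortic-root disk adjacent to the LM
and RCA origins; and cylindrical lesions (uniform or core–rim HU profile)
centred on the vessel curves. Label-5 confuser calcifications are placed
*inside* the aortic root next to the coronary ostia, reproducing the
adjacency that causes false positives/negatives in automatic per-vessel
attribution on real scans.

Defaults: 24 slices of 3 mm (the thickness the Agatston score is defined
on) at 0.5 mm in-plane pixels — an in-plane resolution chosen as a round
value in the range implied by a 220 mm cardiac field of view on a typical
512² matrix; the true reconstruction matrix of any given scanner is a free
parameter of `PhantomSpec`.

Every generated case carries a `GroundTruthCertificate` computed by an
independent brute-force path: its own stack-based flood fill and its own
inline weight table, sharing no code with the scoring module. In oracle
mode — no partial-volume blur, Gaussian noise applied only to non-lesion
voxels — lesion HU profiles are piecewise-constant, the label mask marks
exactly the supra-threshold lesion voxels, and the certificate is exact:
Agatston agreement with the pipeline is to floating-point equality
(areas are multiples of the pixel area; weights are integers), volume and
mass to 1e-9 relative. An optional Gaussian blur mode exists for model
training realism; it voids certificate exactness and is excluded from
oracle tests.

**The standard cohort.** `standard_cohort(n, seed)` draws a mixed-severity
population: target CAC-DRS strata cycle A0→A3 so every stratum is
represented, the number of calcified vessels alternates within a stratum
so N0–N4 all occur (for n ≥ 8), and every third case carries an
aortic-sinus confuser, alternating between the LM-side and RCA-side
sites. Lesion radii (0.6–1.7 mm), peak HU (160–450) and axial extents
(1–3 slices) are drawn per case from documented template grids, with each
seed lesion sized toward its vessel's share of the stratum's score band.
These distributions are the package's own defaults for a plausible
screening mix — they are not an estimate of any real patient population.
Three placement rules keep ground truth unambiguous: lesions of different
vessels may not approach within the sum of their radii plus 1 mm on any
shared slice; a lesion's whole axial extent must stay within its vessel's
z-span (so no labelled voxel sits far from its own centerline); and
LAD/LCX lesions avoid the first 12% of their curves, the shared
bifurcation segment where vessel identity would be a naming convention
rather than a geometric fact. Everything is a pure function of
(spec, seed): identical inputs give bit-identical volumes, masks and
certificates.

`perturb_mask` produces controlled disagreement for testing the agreement
battery: one-voxel in-plane dilation, removal of the smallest 3-D
coronary component (ties broken lexicographically by minimum coordinate),
or relabelling one vessel wholesale.

## The multiview model

The model follows the reading-room workflow of judging a voxel primarily
on the axial slice while consulting coronal and sagittal views. Each
voxel is described by 40 features: its 3×3 axial window plus 3×3 coronal
and sagittal context windows through the same location (HU scaled by
1/1000), its normalised (z, y, x) position, four smooth sigmoid encodings
of its HU against the 130/200/300/400 HU density thresholds, and six
vessel-atlas priors — proximity (exp(−d/2 mm)) to each of the four
coronary centerlines of the package's fixed cardiac atlas, proximity to
the aortic root, and a sharp in-root membership term that separates
aortic-sinus calcification from ostium lesions just outside the root
wall. Atlas priors are the desk-scale analogue of the vessel-territory
knowledge a clinical system obtains from a vessel segmentation stage.

A shared single-hidden-layer encoder (tanh, 48 units) feeds two heads:

* **Segmentation**: per-pixel 6-class softmax (background, LM, LAD, LCX,
  RCA, non-coronary calcification), trained with cross-entropy. At
  prediction time voxels below 130 HU are forced to background, so only
  supra-threshold voxels are ever classified.
* **Regression**: per-slice per-vessel Agatston contributions. Hidden
  features of the slice's supra-threshold pixels are sum-pooled (scaled
  by a nominal 32 pixels/slice) and mapped linearly, without bias, so
  empty slices predict exactly zero and predictions are extensive in
  lesion area. Targets are scaled by 100 to O(1); the loss is mean
  absolute error, which is robust to the long right tail of per-slice
  scores. Case-level estimates are per-slice predictions clipped at zero
  and summed.

Training is joint, loss = cross-entropy + λ·MAE with λ = 0.01 so
segmentation dominates early, using full-batch Adam (lr 0.02, 300 epochs
by default) with a linear learning-rate decay — necessary because the
MAE gradient never vanishes at the optimum and a constant step would
leave the regression head oscillating. Class imbalance is handled by
foreground-biased sampling: every supra-threshold voxel enters the
training set along with an equal-sized seeded sample of background
voxels. All randomness flows from the config seed; fixed
(data, config, seed) reproduces parameters bit-for-bit in this plain
numpy implementation. On an 8-case phantom cohort training takes a few
seconds on one CPU.

**What passing tests show — and don't.** On phantom cohorts the model
reaches Dice ≈ 1 on held-out cases, excludes confuser voxels, and its
mask→scoring composition reproduces certificate scores within a few
percent. The phantom's vessel geometry is fixed across cases and its
lesions are noise-free cylinders, so these results demonstrate that the
architecture, training loop and evaluation plumbing are correct — they
say nothing about performance on real scans, where anatomy varies
between patients, partial-volume effects blur lesion boundaries, and the
vessel-territory prior would have to come from an actual vessel
segmentation.

## Agreement statistics

* **ICC**: two-way random-effects, absolute-agreement, single-measure —
  ICC(2,1) — the standard form for method comparison with one
  measurement per rater; reported with the F-based 95% CI. Perfect
  agreement has zero residual variance, where the F statistic is
  undefined; the CI is then reported as (1, 1).
* **Bland–Altman**: mean difference, sample SD (ddof 1), limits of
  agreement mean ± 1.96 SD, and the count of differences strictly
  outside the limits.
* **Paired t**: two-sided, on automatic-minus-manual differences;
  zero-variance differences are a degenerate case (the battery reports
  p = 1.0 with a note rather than a spurious statistic).
* **McNemar** on paired calcified/not-calcified flags: exact two-sided
  binomial for discordant counts b + c ≤ 25 (the regime of a ~46-case
  validation), chi-square with continuity correction above.
* **Wilcoxon signed-rank** on ordinal CAC-DRS categories: zero
  differences dropped (classical convention), exact null for ≤ 25
  nonzero pairs. A `method="approx"` flag switches to the normal
  approximation without continuity correction — the convention of some
  clinical statistics software, which for a single discordant pair gives
  p = 2(1 − Φ(1)) = 0.317 where the exact test gives 1.0. Both are
  correct answers to differently-specified questions; the default is the
  exact convention.
* **F1** is computed voxelwise in 3-D over the whole volume per coronary
  label (equivalent to Dice); a label absent from both masks has no
  defined F1 and is reported as missing. No multiple-testing correction
  is applied anywhere: the battery reports raw two-sided p-values.

Calibration checks are part of acceptance: under seeded nulls the paired
t rejects at ≈ 5% and the limits of agreement contain ≈ 95% of Gaussian
differences. The McNemar null uses 500 always-discordant pairs so the
test runs in its chi-square regime, where the continuity-corrected level
is ≈ 0.044 — close enough to nominal to verify calibration; at small
discordant counts the exact test is conservative by construction, as any
discrete test must be.

## End-to-end runs

`cacs run` expands one root seed per stage (cohort, split, training), so
a serialized `RunConfig` fully determines all JSON artifacts; wall-clock
times appear only in the JSON-lines log. The 80/20 split is by case,
seeded, without stratification. The automatic arm is
predicted-mask → scoring; the manual arm is ground-truth-mask → scoring;
with only two test cases at the default cohort size of 10, ICC is not
estimable (n < 3) and the report notes this rather than fabricating a
value. Test-set sizes throughout (46-case scoring cohort, 8/2 model
split, 2000-replicate calibrations) are chosen so the full validation
runs in about a minute on a single CPU.

## Known limitations

* The phantom has one fixed cardiac geometry; it cannot test robustness
  to anatomical variation, motion, metal artifacts or contrast.
* Oracle-mode lesions have no partial-volume blur; the blur mode exists
  but then certificates are no longer exact.
* The regression head estimates Agatston contributions only; volume and
  mass estimates come from the mask→scoring path.
* Mass-score calibration is a configurable scalar, not a scanner
  calibration-phantom measurement.
* Density scores and segment-level (18-segment) reporting are not
  implemented.
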