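# Methods

## Scope and design

`stomakit` treats the trained neural detector of an imprint-phenotyping
platform as an exchangeable component behind a contract (`detect`:
in-bounds boxes, scores in [0, 1], score-sorted, bounded count,
deterministic given input + seed). Everything around that component —
data generation, annotation handling, evaluation, trait extraction,
statistics — is implemented here and validated against synthetic ground
truth. The package deliberately does not train, load or emulate network
weights; the template-matching baseline exists so the pipeline runs end
to end without them and makes no accuracy claims.

## Box and image conventions

Boxes are corner-based `(xmin, ymin, xmax, ymax)` in pixels, origin
top-left, half-open intervals; COCO's `[x, y, w, h]` is converted only
at the I/O boundary. Training preprocessing follows the common chain
for large micrographs: bilinear resize by 0.5 (coordinates scaled
exactly), padding with black on the right and bottom only (so the origin
— and therefore every box coordinate — is unchanged), and row-major
splitting into 1024 × 1024 tiles. A box crossing a tile seam is clipped
into each tile it intersects and kept when at least 50% of its area
survives (`min_box_retention_fraction`); the threshold trades losing
seam stomata against keeping uninformative slivers.

## Synthetic imprint model

The generator emulates a wheat abaxial surface imaged at ×4
(1.116 µm/px, 1024 × 768 px, calibrated field area 0.984 mm²):

* **Files.** Stomatal files are horizontal rows; positions along y start
  at a uniform offset and advance by the configured spacing sequence
  (default alternating 130 / 230 µm, the two inter-file distances of the
  emulated surface) with Gaussian jitter (default sd 5 µm).
* **Counts.** The per-field stomata count is Poisson with mean
  `density × field area` (default density 16.8 mm⁻²).
* **Sizes.** Length and width are truncated normals: 87.2 ± 3.7 µm and
  54.4 ± 3.5 µm by default. The printed summaries the defaults emulate
  include a length sd but no width sd; 3.5 µm was chosen once as a
  comparable coefficient of variation. Sizes are drawn in µm and
  converted to pixels through the calibration at generation time, so
  ground truth is exact in both unit systems.
* **Placement.** Each stoma picks a file uniformly, gets a small
  y-jitter (default sd 2 µm), and a uniform x. Non-overlap (real stomata
  never overlap) is enforced by rejection sampling with a retry budget
  of 100 × the target count; exhausting it raises a capacity error
  rather than silently under-filling. By default 10% of stomata may
  straddle the image border (`marginal_fraction`), producing clipped
  ground-truth boxes that exercise the marginal-stoma rule downstream.
* **Density–size coupling.** `sd_ss_coupling` (µm per stoma · mm⁻²)
  shifts a field's mean length in proportion to its realized density
  deviation, emulating the negative local SD–SS correlation seen in
  real leaves; 0 (the default) makes the traits independent.
* **Rendering.** Each stoma is drawn as two filled elliptical guard-cell
  lobes flanking a darker central pore — the grass "dumbbell" as it
  appears in bright-field imprints — inside its ground-truth box, on a
  uniform bright background, optionally with Gaussian blur, additive
  noise and dust specks. The rendering provides controllable contrast
  for detector plumbing; it does not model pavement cells, subsidiary
  cells or illumination gradients, so template-matching performance on
  these images says nothing about performance on real micrographs.

Per-image **count datasets** for the statistics module are negative
binomial with mean `density × area` and variance `µ + µ²/k`
(Poisson at `k = ∞`). Real per-image count variance for the emulated
study is unpublished; the default dispersion `k = 50` (mildly
super-Poisson) is a documented choice, not an estimate. Notably, a
Poisson/NB generator cannot be *under*-dispersed, whereas regularly
spaced real stomata plausibly are — so simulated power at a given
sample size is a conservative analogue, not a reproduction, of the
study it emulates (see Statistics below).

## Calibration

`field_area_mm2` is an explicit calibration constant (default 0.984)
rather than derived from `um_per_px × dims`, because a hardware-
calibrated area and a printed pixel scale are generally inconsistent in
the fourth significant figure (1024 × 768 × 1.116² µm² = 0.979 mm²);
`Calibration.derived_field_area_mm2()` provides the derived value when
no independent area calibration exists (as in the ×10 preset).

## Evaluation protocol

Matching is greedy in descending score; each prediction claims the
unmatched ground-truth box of highest IoU when that IoU meets the
threshold. Ties in score break by smaller box area then lower x, making
every ranking deterministic. AP integrates the precision envelope over
recall (all-points interpolation by default; COCO-style 101-point
averaging is available as `interpolation="coco101"`). mAP pools
predictions from all images into one ranking; with a single category
mAP = AP. The greedy protocol can in principle differ from the optimal
assignment; on layouts where overlaps are local (every prediction
overlaps at most a couple of ground-truth boxes, the realistic case for
non-overlapping stomata) the TP counts coincide, which the test suite
verifies against exhaustive enumeration on 1,000 random instances.

## Traits

SD counts **all** detections, marginal or not — a partially visible
stoma is still a stoma in the field. SS excludes marginal boxes (box
touching x = 0, y = 0, x = width or y = height) because a clipped box
underestimates the true extent; since detector outputs are real-valued,
the border test uses a tolerance `eps` (default 0.5 px; set 0 for exact
ground truth). When every detection is marginal the SS means are
reported as undefined (`None`) rather than 0.

File recovery is 1-D gap clustering: sorted y-centers start a new file
when the gap exceeds `gap_factor` (default 1.5) × the median box
height — within-file scatter is a fraction of a stoma's height while
between-file spacing is several times it, so the clustering is
insensitive to the exact factor. A generated file with no stomata is
invisible to the recovery, so a recovered interval can span two true
intervals; interval summaries should therefore use modes/medians, as
the acceptance script does.

## Statistics

Welch's t statistic, the Welch–Satterthwaite df and the two-sided
t-distribution p-value are computed in closed form (degenerate
convention: both variances zero gives p = 1 on equal means, p = 0
otherwise). The power simulation draws `sample_size` images per group
per rep — without replacement within a rep when resampling a finite
dataset, fresh draws for a generative count model — and tallies reps
with p > α ("nonsignificant"). Optional Gaussian `noise_sd` on every
drawn value emulates automated-count error. The implementation is
vectorized over reps, so 10,000 reps run in well under a second.

Two calibration facts worth knowing when interpreting results:

* Welch's test is inherently conservative at very small samples: for
  identically distributed normal groups it rejects ≈ 4% at n = 4 and
  ≈ 4.9% at n = 10 at α = 0.05. The suite checks type-I calibration at
  n = 10 for this reason.
* For a density contrast of 16.8 vs 23.2 mm⁻² with Poisson per-image
  counts, the attainable Welch power at n = 10 is ≈ 0.85 (less with
  extra dispersion). Higher observed power in real data implies
  under-dispersed counts, which this generator intentionally does not
  fake.

Pearson's r uses the exact t-based p-value with n − 2 df. No
multiple-testing correction is applied anywhere; analyses are reported
test by test.

## Problem sizes and numerical choices

The test and acceptance runs use 1024 × 768-px fields at the ×4
calibration, ~16–23 stomata per field, 15–100 scenes per suite and
10,000 power-simulation reps — sizes at which every Monte-Carlo
assertion has comfortable margin (3–4 standard errors) while the whole
suite runs in well under a minute. All stochastic components take
explicit integer seeds and are bit-reproducible; floating-point
equalities in tests use machine-precision tolerances (1e-10 to 1e-12)
where the algebra is exact and Monte-Carlo bands otherwise.

## Known limitations

* Rendering is stylized; no claim of photorealism or of baseline-
  detector transfer to real imprints.
* The generator models neither under-dispersed counts nor rotated
  stomata (the acquisition protocol aligns files horizontally, so
  length is always the x-extent).
* The Labelbox dialect parsed is the documented minimal rectangle
  export, not any specific platform schema version.
* Greedy matching is standard but not provably optimal on adversarial
  overlapping layouts; see Evaluation protocol.
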