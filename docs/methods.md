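# Methods

## Scope and data model

The package measures body composition from *single* axial CT slices at
three stations — liver, abdomen (L4) and mid-thigh — as acquired by
low-dose multi-slice protocols in large epidemiological studies.  A slice
is a 2D raster of Hounsfield units with (row_mm, col_mm) pixel spacing;
all masks are full-grid booleans, coordinates are row-major and 0-based,
connected components use 8-connectivity and hole filling 4-connectivity
(both configurable).  No 3D segmentation, scanner QA or dose modelling is
attempted.

Global HU bands: body > −300; adipose [−190, −30]; lean (−30, +151];
cortical bone > 400.  The bands follow integer conventions (−30 vs −29),
so for floating HU the adipose band is closed and the lean band half-open
at −30: adjacent bands partition the HU axis with no pixel counted twice.

The patient table is removed from the body mask by discarding
above-threshold components whose centroid lies in the bottom 20% of image
rows, then keeping the largest component (two for the thigh station).
This rule is a package choice — the table is thin, low-area and always at
the image bottom for supine subjects — and both the row fraction and the
connectivity are exposed in configuration.

## The ILT filter

The inside-lean-tissue filter scores how much lean tissue surrounds a
pixel.  HU → lean probability is a linear ramp between L1 and L2 (0 at or
below L1, 1 at or above L2).  From each pixel, `n_dir` equally spaced
rays (angles 2πi/n_dir, directions in physical mm axes) are sampled every
`step_mm` by bilinear interpolation, starting one step from the origin
and stopping at the first sample outside the grid.  The per-pixel
response sums the ⌈dir_percent·n_dir⌉ smallest directional accumulations;
the map is divided by its maximum so it spans [0, 1] (an all-zero map
passes through unchanged).  Thresholding at `pm_threshold`, optionally
keeping the largest component and filling holes, yields the
"inside" mask.

Numerical conventions, fixed so that the vectorised implementation and
the naive per-ray reference (`bodycomp.reference`) agree to better than
1e−9: the origin pixel is excluded (including it adds a constant per
pixel and cannot change any threshold decision); out-of-bounds means
outside the bilinear support [0, n−1]; the smallest-k sum is tie-order
independent; per-step pixel increments are computed as
`k · (step_mm · d / spacing)` in both paths so boundary samples round
identically.  Nearest-neighbour sampling is available as an alternative.
An optional ray cap `max_range_mm` plus a support mask (the body or a
single thigh, zeroing the lean probability elsewhere) is used by the
pipelines: when the probability support fits inside the cap, truncated
samples are exactly zero and the result is identical to unlimited rays,
at a fraction of the cost.  It also makes rays ignore the patient table
and the contralateral leg.

Defaults: n_dir = 32; L1 = −30, L2 = +20 HU (straddling the adipose/lean
boundary); dir_percent = 0.5 (subcutaneous fat sees little lean tissue in
about half of the directions); step_mm = min(spacing).  None of these has
a published value; they are package conventions, with the per-station
`pm_threshold` trained on phantoms (below).

## Liver attenuation

Pipeline on a liver-level slice: (1) lean-band threshold inside the body;
(2) Euclidean distance transform DT1 (mm, spacing-aware); (3) multiply by
the aligned shape atlas P_liver; (4) threshold the positive product at
its 0.90 quantile → a seed sample deep in the liver; (5) attenuation
range R = [p2.5, p97.5] of the seed HU values (mean ± 2·SD as an
alternative), clamped to the lean band; (6) re-threshold the original
image with R; (7) DT2 of that mask; (8) multiply by P_liver; (9)
threshold at the 0.50 quantile of positive values → final mask; (10)
attenuation = centre of a Gaussian least-squares fitted to the 1-HU-bin
histogram of the masked values.

The segmentation is deliberately approximate — the target is the mean
attenuation, not the organ outline — and the tests verify the estimate is
insensitive to one-pixel erosions of the final mask.  The Gaussian fit is
preferred over the plain mean because it locks onto the dominant
histogram mode, discounting secondary modes (vessels, partial-volume
tails).  The subject-specific R is what lets one pipeline track livers
across the clinically relevant 0–60 HU span; the quantile thresholds in
steps (4) and (9) and the histogram bin width have no published values
and are configuration with the stated defaults.  The atlas is multiplied
in as a continuous map (not binarised).  Spleen exclusion relies entirely
on the atlas down-weighting the contralateral side; there is no explicit
spleen detector.  Heterogeneous/focal fatty infiltration is not detected
— strongly heterogeneous livers would bias a range-based estimate and
merit visual screening.

### Shape atlases

An atlas is the per-pixel mean of reference masks after anisotropically
rescaling each mask's reference rectangle — the bounding box of the
abdominal cavity (the ILT inside-mask) — onto a canonical unit rectangle;
no rotation is modelled (supine subjects).  At application time the
canonical map is resampled onto the target's automatically detected
cavity span, giving translation- and scale-equivariant alignment.  In
this repository the reference masks and frames come from the phantom
generator's ground truth, standing in for manual reference segmentations.

## Abdominal VAT/SAT

Adipose tissue is thresholded inside the body; the ILT inside-mask
(largest component, holes filled) is the abdominal cavity; paraspinal
("back") adipose tissue — neither VAT nor SAT — is adipose where the
aligned back atlas P_back ≥ 0.5 (threshold configurable; no published
value).  Then VAT = adipose ∩ cavity ∖ back, SAT = adipose ∖ cavity ∖
back: the three masks partition the adipose pixels by construction, so
depot conservation holds on every input and TAT = VAT + SAT.  Adipose
tissue inside the muscle wall that is not covered by the back model is
assigned by the cavity mask alone — the known overestimation mechanism of
fully automated VAT measurement (intermuscular fat counted as VAT), which
the phantom evaluation reproduces at well under a percent of area.

Manual sub-depot helpers: SAT is split into deep/superficial (DSAT/SSAT)
along a traced fascia polyline interpreted in polar coordinates around
the body centre of gravity — pixels radially inside the fascia are deep —
with anterior/posterior halves delimited by the centroid row (a half is
valid only when the fascia's angular span covers ≥ 98% of that half's SAT
pixels, since the fascia is often visible only partially).  VAT is split
into intra/retroperitoneal (IPAT/RPAT) by a closed traced contour
(simple-polygon check via shapely; pixel centres decide membership).
Automating these splits is out of scope.

## Thigh composition

The two thighs are the two largest non-table body components (one binary
opening is attempted if the legs touch) and every later step runs per
thigh, with left/right named in image coordinates.  Bone is the cortical
threshold plus hole-filled marrow — marrow HU falls inside the adipose
band but is not a fat depot, so muscle and adipose both exclude bone.
SAT is adipose outside the ILT inside-mask.  The remaining inner adipose
tissue is split into SFAT (the rim just beneath the fascia lata) and IMAT
by two methods: (1) a second, stricter ILT pass whose higher threshold
keeps only the region deep inside muscle; (2) morphologically — the
muscle compartment (muscle ∪ inner adipose, closed and hole-filled) is
eroded by `depth_mm`, implemented as a spacing-aware Euclidean-distance
threshold with a +0.25·min(spacing) offset compensating that the EDT
measures to background pixel *centres* rather than the raster boundary
(on an analytic disk this brings eroded areas within ~0.3% of the
continuous erosion at 1 mm pixels).  SAT + SFAT + IMAT = adipose per
thigh for both methods, by construction.  Muscle attenuation is the plain
mean HU over the muscle mask (Gaussian-fit alternative available for
symmetry with the liver).

## Phantoms

Seeded parametric phantoms provide every station's anatomy with exact
ground-truth labels: an elliptical body over a patient table, a SAT ring,
a muscle wall enclosing a cavity with visceral fat, lean organs, spine,
back muscles and paraspinal fat (abdomen); a liver + spleen slice with
adjustable liver HU, swept over 0–60 HU in validation (liver); and two
concentric-structure thighs — cortical ring + marrow, muscle annulus, a
subfascial fat band under a one-pixel fascia lata, SAT, and intermuscular
fat islands (thigh).  Tissues draw from fixed HU means inside the global
bands (fat −95, muscle 45, organs 35, liver 0–60, marrow −80, cortical
bone 1200 HU) with additive Gaussian noise (SD 10 HU for soft tissue);
pixels are deterministic given the spec and seed, and the noise field is
drawn once per grid so geometric variants of the same seed share it
(enabling clean perturbation experiments such as the one-pixel wall gap).
Ensembles jitter geometry uniformly within stated ranges, reproducibly
from a seed.

What the phantoms do *not* emulate: partial-volume mixing at tissue
boundaries, beam hardening, streaks, anatomical asymmetry and truly thin
or discontinuous muscle walls beyond the synthetic gap.  Passing the
phantom suite therefore demonstrates algorithmic correctness and
robustness of the decision logic, not clinical-grade accuracy; real-data
Dice values would be lower (boundary pixels are genuinely mixed) and the
fascia lata is visible in only a small minority of real thigh images,
where SFAT accuracy is accordingly limited.  The phantom fascia can be
disabled to emulate that case.

## Trained parameters

The per-station thresholds have no published values and were trained
once on seeded phantom ensembles (`bodycomp.calibrate`), primarily for
area agreement and secondarily for Dice, then frozen in
`bodycomp.config`: cavity `pm_threshold` 0.10 (abdomen and liver; Dice
plateau 0.04–0.20), thigh SAT pass 0.04 (plateau 0.015–0.08), thigh deep
pass 0.20 (plateau 0.15–0.30), morphological depth 10.5 mm (plateau
8.5–12.5 mm on training; the value sits mid-plateau and was verified on
independent validation seeds).  Ray caps (380 mm abdomen/liver, 180 mm
thigh) equal the largest in-support chord the geometries can produce,
where capping is exactly equivalent to unlimited rays.  Evaluation
ensembles always use seeds disjoint from training.

## Evaluation statistics

Dice = 2·TP/(2·TP+FP+FN), defined as 1 when both masks are empty; FP/FN
ratios are relative to the reference pixel count.  Repeatability CV is
the root-mean-square within-pair CV (two-point SD |m1−m2|/√2 over the
pair mean), with the SD-of-differences variant available; the exact
definition is a package choice.  Pearson r and the two-tailed paired
t-test come from scipy, with zero-variance differences flagged as
degenerate and percent difference reported relative to the reference
series mean.

## Problem sizes and determinism

Validation runs use 128×128 abdominal/liver grids at 3 mm pixels and
96×160 thigh grids at 2.5 mm — coarse enough for fast ensemble studies
while keeping every structure several pixels wide; atlases use 25–50
reference phantoms and evaluation 50 abdominal phantoms (the oracle
comparison uses 200 random 32×32 images).  Everything is deterministic
given the configuration and seed: phantom pixels, all masks and all CSV
outputs are bit-identical across repeated runs.
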