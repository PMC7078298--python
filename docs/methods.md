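# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind `gliaquant`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The measurement model

One *field* is a 20× frame of a flat-mounted retina: a z-stack (planes
every 2 µm by default) of an Iba-1 channel and optionally a P2RY12
channel, covering 0.1502 mm². Layers (OS, OPL, IPL, NFL–GCL) are
distinguished by focal depth at acquisition time; the pipeline treats one
stack as one layer of one field and carries the layer as metadata. All
measurements operate on the maximum-intensity projection — the standard
choice for sparse fluorescent structures; a mean projection is available
behind a flag.

### Cell counting

normalise → threshold → segment → centroid → merge:

1. *Î = I / max I*, so values lie in [0, 1]. An all-zero field is flagged
   `empty_field` and yields count 0 rather than an exception.
2. Pixels with *Î* < *t* are zeroed (default *t* = 0.2 of the per-image
   maximum). The comparison is strict: a pixel exactly at *t* survives.
3. Surviving pixels are labelled into 8-connected segments ("divided into
   segments" admits several readings; 8-connected components are the
   simplest faithful one, and a watershed alternative is deliberately out
   of scope). Segments smaller than `min_segment_px` (default 5 px) are
   discarded; this filter is not part of the original protocol and can be
   disabled (`min_segment_px=1`).
4. Each segment contributes its unweighted centre of mass, in µm.
5. Centroids are merged by single linkage with a strict rule: two
   centroids belong to the same cell iff their distance is
   *strictly less than* `min_distance_um`; chains merge transitively. The
   cluster representative is the arithmetic mean of its members (the
   protocol is silent; the mean is order-independent). The original
   min-distance value is not documented; the default of 25 µm is roughly
   one soma diameter plus margin, and the value is echoed in every output
   row.

Counts are normalised to cells per 0.1502 mm² so fields of different
pixel geometry compare. The end-to-end count is invariant to global
brightness scaling by construction (step 1).

**The exactness contract of the merge rule.** Under noise a cell's
thresholded mask can fragment into several segments whose centroids are
spread over the cell's territory. Counting is exact precisely when (a)
all fragments of one cell lie within `min_distance_um` of each other (or
chain through intermediate fragments) and (b) no part of one cell comes
within `min_distance_um` of any part of another. Condition (b) concerns
cell *territories*, not soma positions: two somata 37 µm apart with
17 µm process reach can bring their tips within ~3 µm of each other, and
a noise-induced tip fragment will then chain-merge both cells into one.
The exact-recovery benchmark therefore uses fields that satisfy the
contract (45 µm soma spacing, 8 ± 1 µm arbors: worst-case cross-cell
part distance 45 − 2·9 = 27 µm > 25 µm). On the denser default cohort
the same effect produces a small systematic undercount at the most
crowded time points; it is monotone-preserving and does not affect the
ordering or significance analyses, but absolute counts on crowded fields
should be read with this bias in mind — as is true of the original
method.

### Area fraction, soma, arbor, puncta

*Iba1-RA* is the fraction of pixels surviving the same
normalise-and-threshold rule (the original "threshold tool" setting is
unstated; the 0.2-of-max rule keeps the two measures consistent, and an
Otsu option is provided, with the choice logged per field). It is
brightness-invariant and monotone non-increasing in the threshold.

*Soma area* accepts a traced contour (shoelace formula; self-intersecting
polygons are rejected) or a mask (pixel count × pixel area). The
automated extractor takes, within each detected cell, the largest
connected component of pixels ≥ 0.6 of the image maximum — somata are
rendered (and stained) brighter than processes.

*Arbor area* is the convex hull of the process-tip set (SciPy Qhull;
< 3 tips or collinear tips give area 0 with a `degenerate` flag). The
hand-drawn polygon through distal tips is not necessarily convex; the
hull is deterministic and oracle-checkable but can overestimate concave
arbors — a documented bias. The polygon necessarily contains the soma;
the soma is not subtracted. Automated tips are skeleton endpoints
(skeleton pixels with exactly one 8-connected skeleton neighbour) of the
cell's binary mask.

*Vertical processes* between OPL and OS appear as puncta in the
interface plane and are counted with the same chain at punctum scale
(`min_segment_px` 2, merge radius 5 µm).

*P2RY12 intensity* is the whole-field mean of the green channel as a
percentage of 255. The average is over *all* pixels (that is how the
measure is defined), so no Iba-1 masking is applied; a mask-restricted
variant exists behind a flag for sensitivity analysis. 16-bit inputs are
rescaled by 1/257 with a log message. Intensity is only comparable
across images of equal exposure; `check_exposure` warns on mixtures.
Whether the original intensities were measured on projections or single
planes is not documented; projections are assumed and recorded in
provenance.

### Statistics

Two-sided throughout (sidedness is not documented in the source
protocol; the reported comparisons are symmetric), α = 0.05. Treated vs
fellow eye matched by animal → Wilcoxon signed-rank, exact for n ≤ 25
with no zeros/ties, otherwise the tie-corrected normal approximation
(flagged). Either eye vs naïve → Mann-Whitney U, exact enumeration when
the smaller group ≤ 8 and the pooled sample is tie-free, otherwise
approximation (flagged). Time-course and zone comparisons → one-way
ANOVA plus pairwise two-sample t contrasts with Bonferroni adjustment
p·m capped at 1; the family (m) is defined per metric × layer over the
day pairs or the 6 zone pairs and recorded in every row. Identical
constant groups make F undefined and are flagged degenerate with p = 1;
a numerically negative F from exactly equal group means is clamped to 0
with p = 1 and flagged. The unit of analysis is the per-animal mean
across that animal's fields, avoiding pseudo-replication (a per-field
mode exists behind a flag).

## The synthetic generator

`synth.render_field` draws ramified cells as a filled soma disc
(`cell_amplitude`, default 200 of 255) with anti-aliased process
segments (`process_amplitude` 120) radiating to tip points; each cell
occupies one randomly chosen z-plane. Somata are placed by dart-throwing
rejection sampling under a pairwise minimum spacing (bounded attempts;
infeasible packings raise). Tips are clipped to half the minimum spacing
so neighbouring cells are guaranteed disjoint — the exclusive-territory
("mosaic") property of quiescent microglia. NFL–GCL mode allows overlap
to mimic non-individualisable signal. Background is uniform; noise is
additive Gaussian per plane, clipped to the bit depth. Coordinates are
in µm; objects are drawn at pixel centres with a pixel-in-shape rule, so
the catalogued soma area is the rasterised pixel count × pixel area
(exact by construction) and the catalogued arbor area is the analytic
convex-hull area of the tip set.

Ground truth is exact and never hidden: the catalogue lists soma
centroids and areas, tip coordinates and hull areas, punctum positions,
the labelled-pixel fraction of the clean image and the planted mean
intensity. Identical specs and seeds give bit-identical pixels; cohort
seeds derive deterministically from the master seed.

The P2RY12 channel is rendered as a homogeneous Gaussian field of the
configured mean level in a single plane, with cells *not* drawn
brighter. Rationale: the intensity measurand is the whole-field mean, so
a homogeneous field makes the planted value exact; the cost is that
synthetic green channels do not look like stained cells, which no
measurement here depends on.

Field geometry: square fields of 0.1502 mm² (side ≈ 388 µm). No pixel
size is documented for the original 20× fields, so it is a free
parameter; the default renders 512 px across a field (≈ 0.76 µm/px),
and reduced sizes (256, 192 px) are used in tests and benchmarks where
resolution is not the quantity under study.

### The cohort profile

`default_cohort_profile()` maps (group, day, layer) to generator
parameters. The qualitative shape encodes the activation time-course the
pipeline is designed to detect: treated-eye counts peaking at days 3–5
(day 5 in the OS), soma size maximal at day 1, arbors most retracted at
days 3–5, NFL–GCL area fraction peaking at days 3–5, vertical processes
peaking at days 3–5, and a P2RY12 collapse at days 3–5; fellow eyes
respond more mildly with a day-3 peak. The P2RY12 levels are the
published group means (percent of 255) verbatim; counts and geometry are
plausible round numbers on the published pattern. The profile is plain
configuration passed to the renderer — the generator never injects an
effect that is not in the profile. Between-animal variability is a
multiplicative count factor (CV 6%), additive soma/arbor radius offsets
(SD 0.15 / 0.5 µm) and an additive intensity offset (SD 1.2 percent
points), shared across an animal's fields.

Mosaic-layer spacing tracks arbor reach (2·(arbor + 2.5) µm) with a
floor of 28 µm so that planted somata always clear the 25 µm merge
radius. For very low planted intensities the green noise SD is capped at
mean/3 so zero-clipping cannot bias the planted mean.

Cohort layout: one naïve group plus one laser group per day
(default 8 animals each; each laser animal contributes a treated and a
fellow eye, paired), every eye imaged in every layer plus the OPL–OS
interface plane, fields cycling through the four retinal zones. The
source study evaluated ~550 fields per retina; the default here is 4
fields per animal per layer (a config knob), which preserves the
statistical structure at desk scale.

## What the benchmarks show — and what they do not

The validation suite (see `gliaquant.benchmark`) establishes: exact
equivalence of the merge rule with independent clustering routes; exact
count recovery on fields satisfying the contract above (100% clean, and
100% in our runs with image-noise SD up to 10% of the cell amplitude on
single-plane fields); machine-precision agreement of area fraction,
intensity, hull area (vs an independent geometry library) and shoelace
area (vs Pick's theorem); exact-test equivalence with full enumeration;
null calibration of rejection rates and family-wise error; recovery of
every well-separated planted ordering (planted separation ≥ 1
between-animal SD and measured separation ≥ 1 pooled SD) with all
planted contrasts significant across 20 seeded cohorts; and bit-level
determinism. Benchmark problem sizes (500 point sets, 100 fields,
5000/2000 replicates, 20 cohorts at 8 animals / 1 field / 256 px) were
chosen to make these properties measurable in minutes on one CPU.

Synthetic fields are not micrographs. They omit the optical PSF,
branching process trees (processes are straight segments), vessels and
dendritiform cells, uneven illumination, staining variability and
layer cross-talk. Passing benchmarks therefore demonstrates the
*algorithmic* correctness and calibration of the implementation under
the stated geometric model, not the biological accuracy of any
particular threshold on real tissue — on real data the threshold, merge
radius and segment filter remain analysis choices to be reported, which
is why all three are surfaced as parameters and echoed in every output.

Noise interacts with projection: the maximum over k noisy planes has a
heavier upper tail than single-plane noise, so heavily noised multi-plane
stacks can shed spurious above-threshold segments that the 5-px filter
does not fully remove. This is a property of the max-projection +
fixed-threshold method itself; the noisy-recovery benchmark states its
noise level at the projected image, where the claim is well-defined.
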