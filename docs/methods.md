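# Methods

`nuctrans` reimplements, as a tested pipeline, the quantification behind an
image-based nuclear-translocation reporter assay: a GFP-tagged chimeric
nuclear receptor that sits in the cytoplasm of unstimulated cells and moves
into the nucleus when a ligand binds. The per-cell read-out is the mean GFP
intensity inside the nucleus divided by the mean intensity in a thin
cytoplasmic "ring" around it; plate-level statistics turn that ratio into
ligand potencies (EC50) and progesterone-equivalent (P4-EQ) concentrations
of unknown samples such as concentrated surface-water extracts.

## The measurement model

**Per cell.** Nuclei are segmented from the nuclear-marker channel (DAPI in
fixed cells, or a constitutive nuclear label in live cells). For nucleus *k*
the cytoplasm proxy is the ring

    ring_k = { p : gap < d(p, nucleus_k) ≤ gap + ring_width,  p on no nucleus }

with contested pixels going to the nearest nucleus (Euclidean distance ties
broken toward the lower label id). The translocation ratio is

    ratio_k = mean GFP over nucleus_k / mean GFP over ring_k

which rises as the reporter translocates. A cell whose ring mean is at or
below 1 count is discarded (and tallied) rather than allowed to produce an
unstable ratio.

**Aggregation.** Field value = mean of its cells' ratios; well value = mean
of its field values (fields weighted equally, not by cell count — this
matches averaging a fixed number of imaging fields per well); sample value =
mean over its replicate wells. Each sample's normalized translocation is

    y = mean(sample wells) / mean(matched vehicle wells)

so the solvent control (DMSO or EtOH, per the layout) has y = 1 by
construction. The SEM of y comes from the sample's replicate wells with the
vehicle mean treated as a constant divisor; no cross-term is propagated
because the replicate structure of the divisor is the same four wells for
every sample on the plate and the summary report treats it as a fixed
reference.

**Statistics.**

- Z′-factor: `1 − 3(sd_pos + sd_neg)/|mean_pos − mean_neg|` over control
  replicate wells (sample SDs). The screening convention calls Z′ > 0.5 an
  excellent assay window; this implementation deliberately computes the
  Z′-factor and *not* a plain z-score, because only the former is bounded by
  1 and matches the 0.5–0.85 ranges the assay is quoted at.
- Dose–response: 4-parameter logistic
  `y = bottom + (top − bottom)/(1 + (EC50/c)^hill)` fitted by nonlinear
  least squares over (top, log EC50, hill), multi-started over
  hill ∈ {0.5, 1, 2}. Vehicle points (c = 0) cannot enter the log-dose term;
  when present they anchor `bottom` at their mean instead of being dropped.
  A monotone-decreasing response is reported with bottom < top plus an
  `inverse` flag; an EC50 outside the tested range is flagged extrapolated.
- P4-EQ calibration: in the low-dose regime (0–1 nM) y is linear in
  concentration, `y = slope·x + intercept`. The intercept is fixed at 1 by
  default because vehicle-normalized y is 1 at x = 0 by construction (the
  slope is then the through-origin least-squares slope of y − 1 on x); an
  unconstrained two-parameter fit is available. Unknowns invert through
  `x = (y − intercept)/slope`; readings below the intercept clamp to 0 nM
  with a warning, readings above the calibrated range are flagged
  extrapolated. Enriched extracts divide by their concentration factor
  (200× for solid-phase-extracted water) and convert nM → ng/L via the
  analyte molar mass (progesterone 314.46 g/mol; configurable).
- Group comparisons: one-way ANOVA gate at α = 0.05, then per-sample
  t-tests versus the control group using the pooled ANOVA error variance
  (df = N − k), Holm–Šidák step-down adjustment
  (`adj_i = max_{j≤i} 1 − (1 − p_j)^(m−j+1)`, via statsmodels). The family
  is all non-control samples in the run.

## The synthetic-data generator

The generator stands in for the microscope so every stage is testable
without data downloads. It emulates the assay's design: 384-well plates
(wells A01–P24), several imaging fields per well (design default 8), four
replicate wells per sample, a 1080×1280 px field mimicking a 2×2-binned
2560×2160 sensor at 325 nm/px.

**Geometry.** Each cell is a nuclear disk (lognormal radius, median 12 px,
σ_log 0.15) inside a concentric cell-body disk (factor 1.8) — the simplest
geometry for which the ring-region estimate is analytically checkable.
Centers are placed by hard-core rejection sampling; by default cell bodies
may not overlap at all (`clustered=True` relaxes this to the 2×-nucleus-
radius floor as a deliberate segmentation stressor). Placement attempts are
bounded; an overcrowded request places fewer cells and records the count.

**Photometry.** Ground truth is parameterized directly by the pipeline's
read-out: each cell carries a true nuclear/cytoplasmic mean-intensity ratio
r. Its GFP total (lognormal, median 5×10⁵ counts) is split so the expected
nucleus-mean over annulus-mean equals r exactly on the discrete pixel masks,
and the expected total is conserved whatever r is. The camera model is
constant background (100 counts) → Gaussian PSF blur (σ 1 px) → Poisson
shot noise → Gaussian read noise (σ 5) → rounding and clipping to 16 bits.
With all noise off the un-rounded expected image is returned, so
conservation and exact-ratio oracles hold to machine precision; images on
disk are always 16-bit TIFF.

**Response.** Well-level true ratios follow either a Hill dose–response
`r(c) = r0·(1 + (f_max·e − 1)·c^h/(EC50^h + c^h))` (defaults r0 = 0.5,
f_max = 4, EC50 = 3 nM, h = 1; partial efficacy e < 1 emulates
partial-agonist-like ligands that plateau below the full-agonist level,
with e ≥ 1/f_max so the plateau never falls below baseline) or a saturating
time-course `r(t) = r0·(1 + (f_max − 1)(1 − e^{−t/τ}))`, τ = 45 min — at
t = 120 min the normalized fold is 3.79, i.e. the "fourfold at 2 h"
operating point.

**Dispersion.** Per-cell ratios are lognormal about the well value
(σ_log 0.15). Replicate wells get a bounded log-uniform effect with
standard deviation 0.065. These two numbers are *design choices, not
measurements*: the assay's cell-level variance is unpublished, and the
well-level dispersion is set so that the realized Z′ between vehicle and
saturating-agonist wells lands in the 0.5–0.8 screening band the assay is
quoted at. A bounded (rather than lognormal) well
effect is used because the sampling spread of 4-well SDs under heavy-tailed
effects pushes too many plates out of that band at any σ. Both parameters
are plain config fields.

**Randomness.** One root seed; per-well and per-field substreams derive
from `SeedSequence(root, spawn_key=...)`, so a single field is reproducible
in isolation and identical seeds give byte-identical plates.

## Segmentation and measurement choices

The reference assay used a commercial analysis package; the recipe here is
chosen for transparency and testability, with every threshold in config:

1. Gaussian smooth (σ 2 px) → Otsu global threshold → hole filling.
2. A contrast guard rejects the threshold when the foreground–background
   separation is under 4 background SDs: Otsu always "finds" a threshold,
   even on a blank field of pure noise, and mid-sized noise blobs would
   otherwise pass the area filter.
3. Watershed split of touching objects, seeded at maxima of the smoothed
   distance map (min peak distance 7 px).
4. Area filter 50–2000 px (nuclei of roughly 4–25 px radius at 325 nm/px);
   border-touching objects removed entirely, because their rings would be
   truncated and bias the cytoplasm estimate.

Rings default to width 4 px (≈1.3 µm) — measured ratios are stable to ~3%
across widths 2–8 on synthetic defaults — with a pipeline gap of 2 px.
Two measurement details matter at this image scale and are defaults in the
pipeline (both can be turned off):

- **Nucleus-mask shrink (2 px).** The threshold boundary sits in the
  PSF-mixed zone between compartments; measuring the nuclear mean over the
  eroded interior keeps cytoplasmic signal out of it. Rings are still built
  from the unshrunk mask so they keep their stand-off from the true
  envelope.
- **Background subtraction (`field_median`).** An additive camera offset
  does not cancel in a ratio: with the default optics (100-count offset
  against a few-hundred-count cytoplasm) raw ratios are biased toward 1 and
  the saturating fold compresses from ~3.9× to ~2.5×. Subtracting the
  median of non-cell pixels (floored at zero) removes the offset robustly.
  `none` remains available, and all exactness oracles are run under ideal
  (zero-background) optics where both modes agree.

With these defaults the full image pipeline recovers true ratios
{0.5, 1, 2, 4} with <1% median error under default noise, and the
saturating-dose normalized fold lands in 3.5–4.1.

## Problem sizes used by the test suite

Tests and the stochastic recovery checks run on reduced fields — 320×384 px
crops with a mean of 16 cells per field and 4 fields per well, 20-plate
fixed-seed batches for the EC50/Z′ checks — chosen as the smallest sizes at
which per-well statistics (≈60 cells/well) are representative of the
full-scale design. Full-sensor defaults remain on `SceneSpec` and are
exercised once in the placement/reconstruction test.

## What the synthetic surface does and does not show

The generator reproduces the *geometry and statistics* of the assay:
compartment ratios, plate structure, replicate dispersion, camera noise.
Passing recovery tests therefore demonstrates that the pipeline measures
what the generator encodes, at the assay's operating points. It does not
demonstrate robustness to things the generator omits: non-disk cell and
nucleus shapes, spatially varying illumination, autofluorescence structure,
cell clumping beyond the optional `clustered` mode, focus drift,
photobleaching, or 3-D effects (a single imaging plane is assumed
throughout). For real images the segmentation thresholds and the
background mode are the first knobs to revisit.

## Known limitations and edge cases

- The published description of the assay's statistics is ambiguous between
  a z-score and the Z′-factor; the Z′-factor is implemented (see above) and
  a plain z-score is deliberately not.
- The source material is internally inconsistent about the partial-agonist
  plateau (a plateau "corresponding to 6 nM" agonist alongside a ~1.7
  normalized value that inverts to ~0.7 nM through the same standard line).
  The implementation follows the explicit inversion formula; the
  discrepancy is noted here rather than resolved.
- Degenerate inputs are contracts, not crashes: empty fields yield empty
  masks and tables; a flat calibration series returns slope 0 flagged
  degenerate; equal control means make Z′ undefined and raise; a 4PL fit
  that fails from every start raises with the best attempt's diagnostics.
- `p4_equivalent` clamps below-vehicle readings to 0 nM; inverting y values
  above the calibrated 0–1 nM range extrapolates beyond the linear regime
  and is warned about, because the true dose–response flattens there and
  the linear inverse understates nothing/overstates the equivalent.
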