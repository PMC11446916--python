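# Methods

This note records the models, conventions and numerical choices behind
`emdmn`, and what the synthetic benchmarks do and do not establish.

## Image model and thresholding

All image operations work on 2-D intensity arrays with a physical pixel
size (µm/px). Auto-thresholding follows the classic ImageJ recipe: a
256-bin histogram, a method-specific level selection, and a configurable
*floor* — a minimum threshold on the 8-bit scale that guards against dim
backgrounds. Images whose intensity range already lies within [0, 255] are
binned on the absolute 8-bit scale, so the floor keeps its meaning (a
noise-only field stays empty rather than being min–max stretched into a
spurious foreground); wider-range images are min–max rescaled to 256 bins
first. The returned cut sits half a bin above the selected level, so for
integer 8-bit images "strictly above threshold" reproduces the
conventional `> level` rule.

- **Otsu** maximizes between-class variance over all 255 splits.
- **Yen** maximizes the maximum-correlation criterion.
- **Intermodes** smooths the histogram with a window-3 moving average
  until exactly two local maxima remain and cuts at their midpoint; a cap
  of 10,000 iterations guards histograms that never become bimodal (an
  error — interpreted by callers that expect possibly-empty signal, such
  as focal-adhesion detection, as "no signal above background").

Tests verify Otsu and Yen against exhaustive-search oracles (criterion
equality, so plateau ties are accepted) and against scikit-image on 8-bit
data.

Particle measurement uses scikit-image connected components
(8-connectivity by default, matching Analyze Particles) and regionprops:
area in µm² (pixel count × pixel size²), perimeter by weighted contour
estimate, circularity 4πA/P² capped at 1.0 (tiny rasterized objects can
exceed 1 before capping), solidity as area over convex-hull area.

## Micronucleus workflow

1. **Nuclei** — Otsu (floor 25) on DAPI, hole filling, removal of objects
   below 20 µm² (which discards micronuclei and debris).
2. **NE reference** — per nucleus, the mean Emerin over the ring
   `dilation(mask, w) − erosion(mask, w)` with w = 0.9 µm. Rings running
   into the image border are flagged truncated.
3. **Detection** — Otsu (floor 25) on Emerin; any particle overlapping a
   nucleus by ≥ 1 pixel is excluded *wholesale* (this removes the bright
   NE rims along with nuclear signal — removing only the overlapping
   pixels would instead fragment rims into arcs that pass the size gate
   as false candidates); survivors are gated to 0.2–12 µm².
4. **Classification** — each candidate is assigned to the nucleus with
   the nearest border within 15 µm (via a distance transform); candidates
   with no nucleus in range are dropped and counted separately. The call
   is *rich* when mean candidate Emerin ≥ 1.2 × that nucleus's NE
   reference, *ne_level* otherwise. The 1.2 default gives noise margin
   below the ≈2× typical of the rich class while staying well above 1.
5. **Summary and stratification** — Emerin-rich MN per nucleus per field;
   cohort stratification at the fixed quartile cutoffs 0.07538 / 0.1280 /
   0.1861 with half-open intervals and ties going to the upper stratum
   (also available data-driven from the cohort itself). A sample is
   called *pauperized* when > 85% of its cells are Emerin-negative/low or
   its MN ratio reaches the upper-quartile cutoff.

## Intensity ratios

- DAPI content: mean DAPI over the MN mask / mean over the parent nucleus.
- MN/NE: mean Emerin over the MN mask / NE-ring mean.
- NE/cytoplasm (pauperization): NE-ring mean over the *median* of a
  cytoplasmic annulus 0.9–3.9 µm beyond the nucleus, restricted to the
  cell region. The cell is delimited by an Intermodes threshold (floor
  25) of the Emerin channel computed on a histogram that *excludes* a
  guard band of twice the ring width around the nucleus: the bright NE
  otherwise contributes a third histogram mode, and since the
  background-to-cytoplasm gap is necessarily smaller than the
  cytoplasm-to-NE gap whenever NE ≈ 2× cytoplasm, iterative smoothing
  merges background into cytoplasm first and the cut lands above the
  cytoplasm level. The median denominator is robust to bright vesicular
  puncta. All ratios are invariant to positive rescaling of the image.

## Phenotype metrics

- **MTOC–nucleus distance**: pericentrin segmented with Yen (floor 25),
  largest component taken as the centrosome; nucleus from Otsu
  (floor 100) on DAPI. Distance is the minimum Euclidean distance from
  the centrosome centroid to nucleus border pixels; the sign is negative
  when the centroid lies inside the nucleus footprint (the 2-D reading of
  "centrosome above the nucleus"). Verified against a per-pixel border
  scan.
- **F-actin coherency**: structure tensor from Gaussian-derivative
  gradients (kernel σ 1 px) averaged with a Gaussian window (σ 2 µm);
  coherency (λ₁−λ₂)/(λ₁+λ₂), defined as 0 where the tensor vanishes.
  Reflective boundary handling makes the measure exactly invariant to
  affine intensity rescaling and to 90° rotation. I.i.d. noise at default
  parameters averages ≈ 0.1; parallel stripes ≥ 0.99.
- **Focal adhesions**: Intermodes (floor 25) within the cell mask; a cell
  with no particles reports count 0 and a *missing* mean (never 0).
- **Spheroids**: largest component is the main body; invading cells are
  nucleus centroids outside it.
- **Tracks**: total path length as the sum of consecutive Euclidean
  steps; mean velocity as length over elapsed time. CSV input with
  columns `track_id,t_min,x_um,y_um` (TrackMate-export compatible).

## Transcriptomic arm

nCounter normalization: per-sample background = mean + 2 SD (population
SD) of negative-control counts, counts clipped up to it; then two
sequential multiplicative scalings — cohort-mean-over-sample-mean of
positive-control means, then the same with the four housekeeping genes
(CNOT4, HDAC3, DDX50, CC2D1B) recomputed on positive-scaled data.
Sequential (rather than joint) application mirrors the vendor software's
default ordering.

Differential expression: two-sided Mann–Whitney per gene (exact for
small tie-free groups), with log2FC = log₂((median₁+ε)/(median₀+ε)),
ε = 0.5 counts.

The pauperization score is the mean of log₂(count + 1) over the 9
signature genes; the +1 pseudocount makes zero counts well-defined and is
configurable (0 for strictly positive matrices). *High* means strictly
above the cohort's upper quartile (linear-interpolation quantile); with
distinct scores this flags ⌊n/4⌋ samples.

Survival: Kaplan–Meier curves and Cox proportional-hazards (Wald 95% CI)
are fitted with `lifelines`; the two-group log-rank statistic is
implemented directly from its (O−E)²/V form and cross-checked against
`lifelines` in the tests. A group with zero events yields a missing
hazard ratio with a recorded warning.

## Synthetic data

**Phantom fields** emulate a 20× widefield field of view at 0.3 µm/px
(512×512 px): 20 elliptical nuclei (semi-axes 3.5–6 µm, uniform
orientation) filled with DAPI at 100 and carrying an Emerin NE rim at 100
painted symmetrically about the nucleus boundary with half-width 0.9 µm —
the same half-width as the NE measurement ring, so the ring reads the rim
level back directly. Micronuclei are disks of 1–8 µm² (within the
detection gate; smaller disks degenerate to 1–2 pixels at this pixel
size), planted by rejection sampling (≤ 1000 attempts per object, else a
placement error naming the object) outside every nucleus but within
12 µm of one — micronuclei bud from a parent nucleus and sit beside it —
and with a 0.6 µm clearance so discrete bodies never abut at the pixel
level (abutting rasterized objects merge after thresholding, which is a
rasterization artifact rather than a property of the biology). Rich MN
are painted at 2.0 × the NE Emerin level with 0.5 × nuclear DAPI;
NE-level MN at 1.0 × both. Additive Gaussian noise (SD 4, ~4% of the
signal level) is applied last and clipped at zero. An optional cytoplasm
(graded Emerin around the nucleus) supports the pauperization-ratio
benchmarks. Fields are float in memory and 16-bit multi-page TIFF on
disk (channel names in page descriptions), with ground truth as JSON.

What the phantoms do **not** model: point-spread-function blur,
uneven illumination, autofluorescence, touching nuclei, chromatin
texture, or 3-D structure. Passing the detection benchmark therefore
shows the workflow's logic is correct under its stated assumptions, not
that it reaches the same concordance on real tissue.

**Cohorts**: gene-by-sample counts are log-normal (per-gene baseline
log₂ mean uniform in 4–10, per-sample spread SD 0.8 log₂ units); the 9
signature genes are shifted upward by 1.0 log₂ unit in a pauperized 25%
of samples. Survival times are exponential — the simplest model in which
a target hazard ratio is exactly defined — with baseline hazard
ln 2 / 60 per month (median ≈ 5 years, biochemical-recurrence-like) and
hazard ratio 1.75 for the pauperized group; censoring uses an independent
uniform administrative time whose horizon is solved numerically so the
expected censored fraction is 0.60. Defaults: n = 500 samples, 100
non-signature noise genes.

## Benchmark sizes and determinism

The headline benchmark (and `scripts/acceptance.py`) uses 50 default
phantom fields (400 planted MN); parameter-recovery checks use 10–20
fields or 50 cohorts of n = 500; oracle-equivalence checks use 100 random
histograms and 50 random MTOC scenes. All randomness flows through
explicit seeds (`numpy.random.default_rng`); the same seed reproduces
bit-identical images, matrices and reports.

## Known limitations

- The intermodes iteration can declare unimodal histograms degenerate;
  callers needing "no signal" semantics must opt in (focal adhesions do).
- Nucleus assignment of an MN uses the nearest border within 15 µm; in
  dense fields the nearest nucleus is not necessarily the parent.
- The NE ring is a fixed-width morphological band; it under-reads rims
  whose apparent width differs strongly from the configured ring width.
- The tissue workflow's pathologist-verified tumor-region selection is
  out of scope; a region-of-interest mask can be applied upstream by
  masking the input channels.
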