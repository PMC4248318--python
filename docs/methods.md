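# Methods

## The model

Shallow whole-genome sequencing (~0.1x coverage) measures DNA copy number
through depth of coverage: the reference genome is tiled into
non-overlapping, fixed-size bins (default 15 kb) and uniquely aligned reads
are counted per bin.  For a profile normalized to mean 1, read counting
alone contributes variance `1/N`, where `N` is the average number of reads
per bin; everything the pipeline does is aimed at bringing real profiles to
that floor.

Raw counts are distorted by two sequence covariates:

* **GC content** — library preparation and sequencing chemistry favor
  intermediate GC, and the shape of the preference varies with DNA quality;
* **mappability** — the fraction of a bin's k-mers that align uniquely.
  Per position, `M_k(x) = 1/F_k(x)` with `F_k(x)` the number of occurrences
  of the k-mer at `x` in the genome and its reverse complement (k = 50, the
  read length); the bin value is the average over k-mer start positions,
  scaled 0-100.

The two effects *interact* in degraded material (the depth optimum along
one axis moves with the other), so they are corrected **simultaneously**
rather than sequentially:

1. usable bins are grouped by integer `(GC, mappability)` cell
   (round-half-to-even) and each populated cell's **median** adjusted count
   is taken — medians resist aberrant bins;
2. a robust 2D local-polynomial (LOESS) surface is fitted through the cell
   medians;
3. each bin's count is divided by the surface value at its *unrounded*
   coordinates.

Before any of this, counts of bins partly covered by uncharacterized (N)
sequence or truncated at chromosome ends are divided by the characterized
fraction `1 - r`.

## The local-regression surface

The LOESS core is implemented directly (no 2D local-regression fitter for
this cell geometry exists in the dependency set, and the surface *is* the
method).  For an evaluation point, the `span` fraction of nearest populated
cells (Euclidean distance; both axes live on the same 0-100 scale) receive
tricube weights, and a degree-2 polynomial centered at the point is solved
by weighted least squares; the constant term is the fitted value.  All
evaluation points are solved in one batched `einsum`/`solve` pass.

* `family="symmetric"` (default) runs 4 bisquare robustness reweightings of
  the cells, so isolated anomalous cells do not bend the surface;
  `family="least-squares"` skips them.  Degree and iteration count follow
  the conventional defaults of the classical LOESS implementation, which
  does not prescribe them beyond the span and family.
* Degenerate geometries are detected by SVD of the centered cell cloud: if
  the cells are collinear (e.g. a genome with a single mappability level),
  the local polynomial is fitted along their principal line instead of
  failing or falling into per-point rank-deficient solves.
* Fitted values must be positive to divide by; non-positive values (possible
  for robust fits near sparse corners) are masked and the affected bins
  flagged rather than floored into the data.
* Span selection is supported by odd/even cross-validation: fit on
  odd-indexed usable bins, correct both parities, and score the mean
  absolute difference of adjacent corrected bins after discarding the top
  10% (which absorbs true breakpoints).  Lower is better.
* An optional iterative mode refits after excluding bins with `|relative
  residual|` above a cutoff (aberrant segments), until the excluded set is
  stable.  It is off by default; it matters only when aberrations are
  massive and GC-confined.

The sequential 1D mode (`correct_counts_separable`: smoothed median-per-GC
curve, then median-per-mappability) is included purely as the comparison
baseline; on an interacting bias it provably cannot reach the counting
floor, which the acceptance suite demonstrates.

## Blacklist derivation from a panel of normals

Bins that misbehave in *every* normal sample — assembly errors, unannotated
repeats, common germline CNVs — are found empirically.  Each panel sample is
corrected as above; the relative residual `(observed - fitted)/fitted` is
recorded per bin (a bin with zero reads has residual -1, the signature of
repetitive sequence whose multi-mapping reads were discarded); the per-bin
median across the panel is thresholded at `±4.0` robust standard deviations
of its central peak.  The numeric thresholds are **frozen after the first
iteration**; subsequent iterations refit the per-sample surfaces without the
excluded bins and re-test *every* bin against the frozen thresholds, so a
bin may re-enter.  Iteration stops at a fixed point (a 2-cycle terminates
with the union and a warning).  The derived blacklist, external blacklist
overlaps, an optional mappability floor (e.g. 50), and the all-N mask
combine into the usable-bin mask, applied *before* surface fitting so
anomalous bins never distort the correction.

## Noise estimation

The profile SD is measured with a mean-scaled, 0.1%-trimmed first-order
estimator: scale the linear profile by its mean, difference consecutive
usable bins within a chromosome, drop the lowest and highest 0.1% of the
differences, and take `sqrt(sum d^2 / 2m)`.  Successive differencing makes
the estimate blind to step-like true copy-number structure and long-range
waviness; trimming makes it blind to isolated spikes.  Two deliberate
numerical choices:

* differences never cross chromosome boundaries;
* the trimmed sum is divided by the closed-form retained-variance fraction
  of a Gaussian core (0.97913 at trim = 0.001).  Without this the estimator
  reads 1.05% low on pure counting noise — harmless for display, but large
  enough to matter when the estimate is compared quantitatively to
  `sqrt(1/N)`.  Set `trim_correction=False` for the raw statistic.

`N` is always the mean **raw** reads per usable bin, while sigma is
measured on the corrected profile: expected vs measured noise pair up as
`E sigma = sqrt(1/N)` against `sigma_hat`.  On the log2 scale the counting
variance inflates to `(log2 e)^2 / N ~ 2.08/N` (delta method), which is why
noise is always estimated on the linear scale and log2 is export-only.
Depth dependence is probed by binomial thinning (`subsample`), which maps
Poisson profiles exactly onto lower-depth Poisson profiles, and summarized
by OLS of measured variance on `1/N` (counting noise alone: slope 1,
intercept 0; the intercept measures depth-independent excess noise).
Aberration detectability is summarized as
`SNR = |mean(segment) - mean(baseline)| / sigma_hat`; this definition is
declared here, not taken from elsewhere.

## The synthetic-data generator

`simulate` realizes the pipeline's data-generating assumptions with known
truth: per-bin counts are Poisson with mean proportional to
`copy ratio x b(GC, mappability) x characterized fraction`, scaled so the
mean over characterized bins equals `mean_reads_per_bin` (default 30, the
depth at which real profiles become routinely usable).

* **GC**: smooth isochore-scale variation (0.9-Mb-period sinusoid over
  `gc_range`, default 35-65%) plus per-bin Gaussian jitter (SD 6) — local
  gradients in both directions, and planted segments sample the whole GC
  spectrum rather than one slice.
* **Mappability**: duplicated intervals hold a source half and a literal
  copy, so their interior 50-mers occur twice (M = 50); everything else in
  a random genome is unique (M = 100).  `make_reference` emits an actual
  FASTA realizing the targets (bins carry their target GC exactly to
  rounding); `truth_annotation` provides the same ground truth without
  building sequence, for large simulations.
* **Bias families**: `flat`, `plane`, `separable` (product form — removable
  by sequential 1D correction), and `saddle`, a bounded bilinear interaction
  `1 + 0.25 * (GC-50)/20 * (map-75)/25` whose GC effect reverses direction
  with mappability: no product `f(GC) g(map)` can represent it, yet its
  amplitude leaves the counting floor reachable by a correct 2D fit.
* **Panels**: independent samples share the recurrent anomaly set (fixed
  multiplicative distortion at the same bins in every sample) and each gets
  a small sample-specific linear bias tilt (SD 3%), since real libraries
  never share an identical bias.

What the generator does **not** emulate: fragment-level artifacts (FFPE
damage chemistry, fragmentomics), mappability at mismatch resolution for
large genomes, correlated residual structure along the genome, and germline
CNV allele structure.  Passing tests therefore demonstrate correctness of
the estimators and the correction machinery under counting noise and smooth
multiplicative bias — not performance on degraded clinical DNA.

## Problem sizes and numerical conventions

Simulation-based checks use 10^5 bins for estimator calibration and the
variance-depth regression, ~20,000-bin genomes with 38-sample panels for
blacklist recovery, and ~12,000-bin genomes for the correction comparisons;
these sizes put Monte-Carlo error well inside each check's tolerance while
keeping the whole suite fast.  Segment recovery is scored on the corrected
profile anchored to the mean of true-neutral bins: the median of a Poisson
variable sits ~0.18 counts below its mean, so genome-median normalization
overshoots every ratio by ~0.6% at N = 30 — a display-scale nicety that
would otherwise leak into a parameter-recovery comparison.  Coordinates are
0-based half-open in memory and 1-based inclusive in all text output.
Exact-match mappability is hash-based and scales to any in-memory genome;
the 2-mismatch mode is a brute-force oracle guarded to tiny genomes.

## Known limitations

* The blacklist's robust SD uses the same 0.1% trim as profile noise; if
  anomalous bins exceed ~0.2% of the genome the iteration-1 sigma (hence
  the frozen thresholds) inflates.  Recovery of strong recurrent anomalies
  is unaffected, but the threshold then no longer tracks the central peak
  width; the trim is a knob for such panels.
* Surfaces extrapolate outside the convex hull of populated cells by local
  polynomial continuation; corners far from data can be poorly constrained
  (non-positive fits are masked, not repaired).
* MAPQ 37 is the right uniqueness cutoff for BWA output only; other
  aligners need their own value.
* Segmentation and calling are deliberately out of scope; SEG/IGV export
  hands the corrected profile to the standard downstream tools.
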