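# Methods

This note records the models, conventions and numerical choices behind
`pluriexit`, including the places where the design was genuinely open and
what the synthetic benchmarks do and do not demonstrate.

## Screen model

A screen table is tidy per-well data: plate, well, replicate, siRNA id
(`CONTROL` for no-siRNA wells), gene id, raw viability (arbitrary units,
non-negative).

**Normalization.** Percent-of-control: each well's raw viability is
divided by the mean raw viability of the control wells on the *same plate
and replicate*. Division (rather than subtraction or robust variants) is
the standard plate normalization for positive viability readouts and makes
downstream scores invariant to per-plate scale factors — a property the
suite tests directly. Plates with no control wells are hard errors naming
the plate; plates whose control mean is ≤ 0 are flagged invalid (NaN) with
a warning rather than silently kept.

**Z-scores.** Wells are collapsed to one value per (replicate, gene) by
averaging (duplicated library entries for the same gene average here);
scores are standardized within each replicate across the gene population
using the sample standard deviation (ddof = 1). With thousands of genes
the ddof choice is numerically immaterial, but it is fixed for
reproducibility. Z can be computed on raw instead of normalized values via
a flag; normalized is the default since plate effects otherwise dominate.
Controls never enter the gene population. A replicate with zero dispersion
is a degenerate run and an error, not a silent NaN.

**Dual-threshold calling.** A gene with replicate scores (z₁, z₂) is
positive iff max(z₁, z₂) > z_hi and min(z₁, z₂) > z_lo, defaults (3, 2.5).
The order-agnostic reading is deliberate — nothing distinguishes which of
the two duplicate runs should carry the stricter threshold — and a config
switch (`order_agnostic=False`) provides the ordered variant. Genes missing a
replicate are unscorable and excluded with a warning, never imputed.

**False-positive probability.** For independent standard-normal nulls the
order-agnostic rule has closed form

    P = 2 Φ̄(z_hi) Φ̄(z_lo) − Φ̄(z_hi)² ,

with Φ̄ the standard-normal survival function (≈ 1.494 × 10⁻⁵ at the
defaults, i.e. ≈ 0.0015%). Because real duplicate runs are correlated, the
same quantity is also computed under a bivariate-normal null with
correlation ρ via rectangle probabilities (at ρ = √0.483 ≈ 0.695, the
replicate concordance a duplicate screen of this type can show, the rate
rises to ≈ 8.1 × 10⁻⁴ — still below 1%). Both have a seeded Monte-Carlo
mode used as an independent cross-check rather than as the estimator.

**Ledger and validation.** Primary hits are screen positives that are
expressed and not manually excluded; the counts of every filter step are
recorded so that `positives = primary + expression-excluded +
manual-excluded` is checkable whenever the exclusion sets are disjoint.
Validation requires at least `min_validating_sirnas` (default 2)
independent siRNAs with fold viability strictly greater than
`validation_fold` (default 2) over no-siRNA control.

## ChIP-seq downstream model

All intervals are BED convention (0-based, half-open); strand matters only
through the TSS (start of a + gene, end − 1 of a − gene). Alignment and
peak calling are upstream tools; this package consumes their outputs.

* **Deduplication** keeps one read per (chrom, start, strand) —
  idempotent by construction.
* **Equal-depth subsampling** draws uniformly without replacement down to
  the smallest sample, IgG included, from one seeded generator per call.
* **Peak filtering** keeps fold enrichment ≥ `min_fold` (default 100);
  the boundary is inclusive ("at least" 100-fold).
* **Read density** is reads with start in [peak.start, peak.end) divided
  by peak width in kb.
* **Bin matrix.** Gene windows (gene body ± 25 kb by default; a TSS ± 25 kb
  anchor is available via `anchor="tss"`) are tiled into 1-kb bins from the
  window start; bins shared between overlapping windows are kept once.
  Entry (factor, bin) is 1 iff any peak *interval* of the factor overlaps
  the bin — overlap, not summit-in-bin, because a binary "binding site in
  this bin" indicator reads most naturally as presence of any part of a
  binding region. A peak spanning a bin edge therefore marks both bins.
* **Association score.** S = Σᵢ exp(−dᵢ/5 kb) over peak summits at
  distance dᵢ = |summit − TSS|. Summits anchor the distance; files without
  summits fall back to interval midpoints. By default only peaks with a
  summit within ±25 kb of the TSS are summed: a peak at the window edge
  already contributes only e⁻⁵ ≈ 0.007, so truncation changes scores by
  less than that per distant peak; `restrict_to_window=False` sums all
  same-chromosome peaks.
* **Bound-gene sets** are presence-based — a gene is bound by a factor iff
  at least one summit lies within ±window of its TSS — not thresholded on
  the decay score, so "bound" is independent of the decay constant and
  implies a positive score.
* **Clustering** uses distance 1 − Pearson r between factor rows and
  average linkage (the distance measure is the fixed design choice; the
  linkage is ours, chosen as the conventional default for correlation
  distances). Zero-variance rows carry no correlation information and are
  dropped with a warning. Dendrograms export to Newick with branch lengths
  from merge heights.
* **Nearest-factor distance** is the minimum |summit − summit| on the same
  chromosome; queries on chromosomes absent from the other factor are NA.
* **Rank enrichment.** The top slice is the first ⌊qN⌋ genes of a ranked
  table; enrichment is (bound fraction in slice)/(bound fraction in
  universe) and the p-value is the hypergeometric upper tail P(X ≥ x).
  The hypergeometric choice (over e.g. a rank-sum test) matches the
  fixed-quantile, set-membership framing of the question; the test suite
  confirms it against full enumeration and a permutation null.

## Image quantification

Nuclei: global Otsu threshold on the DNA channel, connected components,
minimum object area (default 20 px, configurable and logged). Cells: Otsu
foreground on the whole-cell channel (forced to include every nucleus),
partitioned by watershed on the negated distance transform seeded with the
nucleus labels — so each retained cell contains exactly one nucleus and
cells without nuclei cannot arise. Cells touching the image border are
excluded because their truncated cytoplasm biases the ratio. Cytoplasm is
cell minus nucleus; cells with empty cytoplasm are dropped with a warning.
The N/C ratio is mean nuclear over mean cytoplasmic target intensity, which
makes it invariant to any positive rescaling of the target channel.

Group comparison pools per-cell ratios and reports n, Tukey five-number
summaries (whiskers at the most extreme points within 1.5 × IQR) and a
two-sided two-sample Student's t-test (equal variances, as conventional for
this readout; Welch by flag). Pooling cells across images treats cells as
independent observations; users with nested designs (cells within images
within experiments) should aggregate first.

## Synthetic data: what it emulates, and what it does not

**Screen generator.** 96-well plates, 11 evenly spread no-siRNA controls
per plate, one well per gene per replicate, plates filled row-wise (the
last plate may be partially filled but always carries the full control
complement). Readout noise is multiplicative log-normal with coefficient
of variation `noise_cv`: viability readouts are positive and right-skewed,
and no empirical noise model is attached to this assay, so this is an
explicit stand-in. Between-replicate correlation is induced by a shared gene-level
latent term: the log-noise of gene g in run r is
√ρ·u_g + √(1−ρ)·e_{gr}, giving log-scale replicate correlation exactly ρ.
Planted hits multiply the expected viability by their effect size.
Defaults (noise CV 0.15, ρ 0.5) are plausible mid-range values for
plate-reader viability screens with duplicate-run concordance of roughly
R² ≈ 0.3–0.5. No plate-position or edge effects, no siRNA off-target
structure, no batch drift are simulated — calibration results below say
nothing about those failure modes.

A consequence of the log-normal model worth stating: the analytic
false-positive bound assumes *normal* null Z-scores, while standardized
log-normal values have a heavier right tail at any finite CV (at CV 0.3
the exceedance probability at z = 3 is several-fold the normal tail). The
null-calibration suite therefore runs the generator at CV 0.01, where the
noise is normal to excellent approximation; it validates the caller and
the closed form against each other, not the log-normal tail at realistic
CVs.

**Genome generator.** Equally spaced genes (alternating strand, 2-kb
bodies) on uniform-length chromosomes; per factor, peaks of fixed width
whose summits sit at configurable signed offsets from successive gene
TSSs, with fold enrichments drawn from 120–400 (above the default filter);
reads drawn without replacement from positions under each peak (so
zero-duplicate configurations dedup to themselves), an exact-copy
duplicate fraction appended, and a uniform IgG background. The emitted
ground-truth table (factor, peak, gene, signed offset, distance) is exact
by construction and re-verified in tests. No sequence content, mappability
structure or peak-shape realism is attempted.

**Ranked expression.** Plackett–Luce ranking by Gumbel perturbation of
log-weights: bound genes get weight `enrichment`, others 1. At
enrichment 1 all orderings are exchangeable, which the suite exploits as
an exact null: U-smoothed (randomized) hypergeometric tail p-values of the
top-slice bound count are exactly Uniform(0, 1) under this null and are
KS-tested; the library's own reported p-values remain the standard
conservative, non-randomized tails.

**Images.** Non-overlapping disk cells with concentric disk nuclei,
piecewise-constant channel intensities and additive Gaussian noise, placed
by rejection sampling with a bounded retry budget. Ground-truth N/C ratio
is exactly nuclear/cytoplasmic intensity. Real images differ in every
optical respect (PSF blur, shading, intensity gradients, touching cells);
passing the 2%/10% recovery tests shows the measurement logic is correct
on its own terms, not that segmentation is robust to microscopy artifacts.

## Problem sizes and determinism

The test and demo workloads are deliberately desk-scale: screens of
10²–10⁵ genes, toy genomes of ≤ a few Mb with tens of peaks, 512–1024 px
images with ≤ 50 cells, 10⁶–10⁷ Monte-Carlo draws. All stochastic code
draws from one `numpy.random.Generator` seeded per call; identical configs
produce byte-identical outputs (the end-to-end demo is checksum-stable
across runs, TIFFs included), and every CLI stage writes a JSON manifest
with parameters, seed and output checksums.

## Known limitations

* No plate-effect correction (B-score/median polish) or robust (MAD)
  scoring; the Z pipeline assumes plates are exchangeable after
  percent-of-control division.
* The hit caller requires exactly two replicates; higher-order designs
  would need a generalized rule.
* Bin-matrix construction keeps per-gene windows (deduplicated), not a
  globally merged tiling; columns from overlapping gene windows can
  overlap genomically.
* The watershed cell segmentation assumes cells are separable by distance
  from nucleus seeds; heavily confluent fields will under-segment.
* `rank_enrichment` treats the ranking as fixed; it does not model
  correlation between genes induced by shared regulation.
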