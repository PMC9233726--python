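# Methods

This note documents the statistical procedures, the synthetic study the
package ships, the numerical conventions, and the design decisions that were
genuinely open.

## Study design model

All analyses assume an ordered passage series. A `SampleDesign` carries
samples as (id, timepoint index, replicate, series); the default synthetic
study mirrors a typical fibroblast senescence time course: four passages
(P1, P3, P5, P7), 4 RNA-seq replicates per passage, 3 independent RRBS
replicate series each covering all passages, and ATAC-seq replicates
(4, 3, 3, 3). "Series" matters only for DMS calling, where the filter must
hold in every series independently; expression and accessibility pool
replicates within a passage.

## Monotone trajectory selection

* **Normalization** is median-of-ratios: per-sample size factor = median over
  all-positive features of the ratio to the feature's geometric-mean
  reference, rescaled to geometric mean 1. When no feature is positive in
  every sample the code falls back to total-count scaling and warns. The
  factors satisfy the scaling identity (multiplying one library by c
  multiplies its factor by c, relatively) and are checked against an
  independent re-derivation in the tests.
* **Differential testing** runs each non-reference passage against the
  reference: two-sided Welch t on log2(normalized + 1) across replicates,
  BH adjustment within each contrast across features. The paired thresholds
  are adjusted p < alpha (default 0.05) and fold change strictly > 2 or
  < 0.5, computed on group means with pseudocount 1. A feature is *selected*
  when **any** contrast passes both ("any" rather than "all" is deliberate —
  the selection is an any-vs-reference union). The Welch-on-logs test is a
  transparent stand-in for a full negative-binomial GLM; it preserves the
  selection semantics (thresholds, any-vs-reference contrasts, BH) at some
  cost in small-count power, and the test function is pluggable for callers
  who want a different two-sample test. Degenerate inputs (zero variance in
  both groups) get p = 1 rather than NaN.
* **Monotonicity** is strict: a trajectory of per-passage group means is
  monotone-up iff every adjacent difference exceeds `min_step` (default 0 —
  flat segments fail). Monotonicity is assessed on normalized group means,
  not z-scores; with `min_step=0` the label is invariant under any strictly
  increasing transform, so the choice of scale is immaterial.
* **Modules** come from Ward/Euclidean hierarchical clustering of per-feature
  z-scored group-mean vectors, cut at k clusters (defaults 6 genes, 6 DMRs,
  10 peaks). Constant features z-score to zero vectors; duplicated rows have
  zero distance and always co-cluster.
* **RS features** = selected ∧ strictly monotone, split by direction.

## DMS calling

Methylation level is the plain read ratio m/n. A cytosine is an increased
DMS when every adjacent-passage difference exceeds 0.05 in **every** series;
decreased DMSs use 0.03 on the negative steps. Decisions made where the rule
under-specifies:

* Per-series evaluation (the strictest reading of "in all series") is the
  default; a `series-mean` mode applies the rule to the across-series mean
  trajectory instead.
* Cytosines with coverage < 5 reads in any series/passage cell are excluded:
  levels quantized coarser than the 0.03 threshold carry no information.
  Sites missing from any cell are likewise excluded rather than imputed.
* Comparisons are strictly greater-than, as printed. Because levels are
  ratios of integers, an exact-boundary trajectory (steps of exactly 0.05)
  can land a hair's breadth either side of the threshold in binary floating
  point; all strict comparisons therefore use a 1e-12 absolute guard, so
  exact-boundary steps are never called and genuine exceedances (the
  smallest meaningful increment at usual coverage is ≥ 1/n ≈ 0.01 away) are
  unaffected.

The filter is intentionally stringent: at 30× coverage, a planted +0.10/step
site passes all nine series×step comparisons only a few percent of the time,
so noisy runs call few sites — the behaviour such filters show on real RRBS
data, where only the strongest sites survive. Exactness is instead
guaranteed structurally: the vectorized implementation equals an exhaustive
per-cytosine loop oracle on every input, and noise-free data recover planted
sites with precision = recall = 1.

TFBS methylation aggregation is the unweighted mean of cytosine levels per
region (each cytosine counts once; a coverage-weighted variant sits behind a
flag), with an empty region returning an explicit empty marker, never 0.
The passage trend over region means is tested by one-way ANOVA; identical
values give p = 1 by convention. DMR-to-gene mapping associates a region
with every gene whose ±5 kb TSS window it overlaps (half-open).

## Peak atlas and dynamics

Candidate consensus regions are the single-linkage union-merge of all
samples' peaks. Retention requires a group presence fraction **strictly**
above 0.6 in at least one passage group — 3/4 and 2/3 retain, 3/5 (= 0.6)
does not. Per-peak signal is the summed coverage in the consensus interval,
library-size scaled with the same median-of-ratios machinery.

* **MA open/closed counts** restrict to peaks whose mean normalized signal
  over the two compared groups strictly exceeds 800 and call open/closed by
  differential-test significance with direction; the default fold threshold
  here is 1 (direction, not effect size, is being counted) since the
  original colouring criterion is a significance call.
* **Appearing** at passage t means: above the presence threshold at t and at
  or below it at *every* earlier passage — the first crossing. A re-gain
  after a loss is not newly appeared. **Disappearing** mirrors it: present
  at all earlier passages and absent from t onward (default "sustained"
  mode; a `first` mode requires absence only at t itself).
* **Enhancers** are the interval intersection of H3K4me1 and H3K27ac peak
  sets (maximal regions covered by both).
* The **promoter shift test** maps each gene class (up-regulated,
  down-regulated, all) to the unique peaks overlapping its ±1 kb promoter
  windows and compares the classes' peak log2 fold changes by Welch t-test,
  alongside ECDF tables. Promoter windows are strand-agnostic symmetric
  windows around the TSS, clipped at position 0.

## TF layer

* **Scanning**: score = Σ log2((p_base + 1e-3)/bg_base); hit iff score ≥ 0.8
  × maximal attainable score; both strands, minus-strand hits score the
  reverse complement and report on `-` at the same coordinates.
* **Enrichment** counts regions, not hits (a region with five occurrences
  counts once), takes the upper-tail hypergeometric p with the full peak set
  as background, BH-adjusts across motifs and ranks. Targets should be a
  subset of the background; the code warns when they are not.
* **Footprints**: per hit, the motif ± 100 bp window of strand-averaged
  coverage, reversed for minus-strand hits so asymmetric footprints are not
  washed out (orientation by motif edges; a centre-anchored mode would only
  shift the window by half the motif length and is not needed at these
  motif sizes). Depth = mean(flank) − mean(body); the activity change
  between passages is depth(t2) − depth(t1), positive when occupancy rises.
  This flank-minus-body statistic is a deliberately transparent substitute
  for bias-corrected protection scores; Tn5 sequence bias is out of scope.
* **Classification**: pioneer iff CD > 0.45 and COI > 4; settler iff
  CD > 0.45 and COI ≤ 4; migrator iff CD ≤ 0.45. The printed rule uses three
  strict inequalities and leaves the exact boundaries unassigned; this
  implementation sends boundary values to the lesser class by default and
  exposes the policy (`boundary="greater"`). CD and COI are inputs; their
  upstream computation is not reimplemented.

## Synthetic study and what it does (not) show

The generator is a pure function of `SimConfig`; identical seeds give
byte-identical files. Each generator draws from its own fixed-offset
sub-stream, so adding one never perturbs another.

* **Expression**: NB counts, variance μ + 0.1 μ²; null genes constant
  (log-normal baseline, median ≈ 100); 200 + 200 planted genes multiply
  their mean by 2^±1 per passage step from a higher baseline (median 256, so
  falling genes remain measurable at P7). Genes whose promoter peak is
  scheduled to appear/disappear are planted up/down, coupling expression to
  accessibility the way the real system couples them.
* **Methylome**: 1,000 cytosines; planted up sites climb +0.10/step from
  0.2, down sites fall 0.04/step from 0.7 in all 3 series; 300 sites inside
  peaks drift +0.03/step to emulate rising TFBS methylation; binomial calls
  at 30× (an `exact_levels` mode with m = round(level·n) at n = 10,000
  supports noise-free recovery experiments). Config validation rejects
  plantings that would escape [0, 1].
* **Accessibility**: 200 non-overlapping 240 bp peaks on a 400 kb
  chromosome; 15 peaks scheduled to appear and 15 to disappear at each
  later passage; presence noise 0.95/0.05 (chosen so the >60% rule is
  informative at 3–4 replicates); coverage = background 1 + boxcar height 8
  with 10 bp-binned Gaussian noise, split between strands; motif instances
  at peak centres dip coverage ×0.5 over the motif body when bound, with
  per-passage bound fractions (0.2, 0.4, 0.6, 0.8) by default. Histone-mark
  peak sets straddle a subset of constitutive peaks plus decoys; a CD/COI
  table is drawn uniformly.

What the generator does **not** emulate: read-level artefacts (alignment,
duplicates, Tn5 sequence bias), overdispersed beta-binomial methylation
(binomial by default; the rationale is a clean null for exact-recovery
tests), irregular peak shapes, correlated replicate structure, or genome
sequence composition beyond uniform GC. Passing tests therefore demonstrate
the *selection logic* — thresholds, boundary semantics, oracle equivalence,
calibration of the test statistics — not robustness to upstream processing
noise in real libraries.

## Verification sizes and calibration designs

The shipped verification (tests and `scripts/acceptance.py`) uses problem
sizes chosen to make each property measurable with comfortable margins:
1,000-cytosine DMS grids against the loop oracle; the full default
expression study (5,000 genes, 16 libraries) for sensitivity/FDR; 200-peak
atlases against brute-force counting; ten accessibility simulations for
appearance/disappearance rates; a 12,800-region universe for enrichment
calibration, where target sets of varying size are resampled from the
scanned background — the variation keeps the discrete hypergeometric
supports from dominating a Kolmogorov–Smirnov comparison against uniform,
which is a property of the *check*, not of the statistic; 20 simulations for
footprint activity deltas; 40 replicate draws for shift-test calibration
(null significance assessed at p < 0.01, power at the p < 1e-3 level the
planted effect reaches); and two full pipeline runs compared byte for byte.

## Known limitations

* The Welch-on-logs differential test loses power against a dispersion-aware
  NB model for genes with very low counts; the test function is pluggable.
* The DMS filter's per-site sensitivity at finite coverage is intrinsically
  low (see above); callers wanting noisy-data sensitivity should raise
  coverage or use the `series-mean` mode, both exposed.
* `merge_dms_to_regions` is positional plumbing, not a statistical DMR
  caller; externally derived DMR intervals are first-class inputs.
* Interval operations assume within-chromosome coordinates fit in memory as
  per-base arrays for coverage; tracks are dense `float64` per chromosome.
* Chromosome naming is matched exactly; `normalize_chrom_name` exists but is
  never applied implicitly.
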