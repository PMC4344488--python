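# Methods

This note records the models, conventions and numerical choices behind
`eboxchip`, in the order the pipeline runs them. Coordinates are 0-based
half-open internally; emitted GTF is 1-based inclusive, BED/bedGraph
0-based half-open.

## Signal combination and peak calling

The four tiling-array samples — experimental ChIP (#1), experimental
input (#2), control ChIP (#3), control input (#4) — are combined per
probe on log2 intensities as

    C = [(#1 − #2) − (#3 − #4)] + (#1 − #3),

the input-normalized experimental enrichment corrected by the control
arm and reinforced by the direct ChIP-vs-ChIP contrast. Quantile
normalization across the four arrays precedes the combination by default
(flag `quantile_norm`); on identically distributed synthetic arrays it is
a no-op in expectation.

The smoothed score of probe *i* is the 10%-per-tail trimmed mean of C
over probes within ±BandWidth (300 bp default), multiplied by √n of the
window — a MAT-style windowed statistic that grows with both effect size
and local probe support while the trimming guards against single-probe
outliers. Exact MAT internals (probe-sequence baseline regression) are
not reproduced; this is a deliberately fully-specified surrogate with the
same BandWidth/MaxGap/MinProbe semantics. P-values are upper tails of a
Gaussian null whose location is the genome-wide median of the scores and
whose scale is 1.4826·MAD — robust moments, so that genuine peaks in the
upper tail do not inflate the null. Windows holding fewer than MinProbe
probes get p = 1. A degenerate null (MAD = 0, e.g. constant tracks)
assigns p = 0.5 everywhere: nothing deviates.

The caller marks probes with p ≤ 10⁻⁴ significant, merges consecutive
significant probes whose gaps are ≤ MaxGap (300 bp), and keeps merged
runs with ≥ MinProbe (8) significant probes. A peak spans first to last
significant probe plus one probe spacing (median inter-probe distance);
the summit is the leftmost score maximum. Merging is exhaustive, so
called peaks never overlap.

## Gene context

Peak→gene assignment uses the gap between the peak interval and the gene
span, association when gap < 3000 bp (overlap = 0); "proximal endpoint"
is read as the nearest point of the gene span, which matches both a
promoter-proximal and an intronic binding geometry without presuming
either. Profiles are strand-oriented: minus-strand anchors are mirrored
so positive offsets are transcription-downstream. Metagene profiles
rescale each gene span to 100 equal-fraction bins with fixed-width flank
bins. TSS/first-intron/other-intron categories are defined per isoform
(the first intron is the intron adjacent to the TSS-proximal exon in
transcription orientation); positions in several categories count once
with priority TSS > first intron > other intron. The first/other signal
ratio is reported as ±inf when the other-intron mean is exactly zero and
NaN when both are; with near-zero noise means the ratio is unstable and
the per-category means are the quantity to read. Default profile
windows (TSS/TTS ±3 kb, 50-bp bins, 100 metagene body bins) are package
choices; no canonical bin sizes exist for these displays.

## E-box scanning and conservation

Both cores of interest (CATATG, CAGCTG — the "TA" and "GC" E-boxes,
named for their central dinucleotide) are reverse-complement palindromes,
so plus-strand scanning is exhaustive and occurrences are recorded in
plus-strand orientation; profiles are likewise plus-strand aligned.
Peak-relative positions use the interval midpoint by default (summit mode
by flag). Positional densities are normalized per bin by the number of
peaks wide enough to contribute that bin, since peaks have unequal
widths. Prefix-variant frequencies are NaN (not 0) in empty bins. The
unbound background is a uniform without-replacement sample of intronic
core occurrences (first introns by default, ~800 requested) that
excludes peak-overlapping occurrences, so the background is genuinely
unbound; when fewer exist, all are returned with a warning.
Conservation profiles average per-base scores over core ± flank, dropping
sites with missing values at an offset from that offset only.

## DNA shape and classification

Shape features (minor groove width in Å; propeller twist, roll, helix
twist in degrees) are looked up per position from a pentamer table
assigned to the pentamer center; the two terminal positions at each end
of a sequence are undefined, so site windows carry 2 bp of extra genomic
context per side and every window position has defined shape. Step
parameters (Roll, HelT) are stored as single scalars at the pentamer
center. Reverse-complement pentamers follow the table's own values; no
symmetrization is imposed.

The packaged default table is **synthetic**: an additive,
physically-motivated model (A/T content narrows the minor groove and
deepens negative propeller twist, pyrimidine-purine steps roll positive)
plus a small deterministic pentamer-specific term, spanning realistic
ranges (MGW ≈ 2.8–6.3 Å, ProT ≈ −16 to −4°, Roll ≈ ±7°, HelT ≈ 33–37°).
It is generated programmatically (`synthetic_shape_table()`), is not
derived from structural data, and exists so the shape pipeline is fully
exercisable and testable; a user with a measured pentamer table supplies
it as a TSV. A uniform table is provided for degenerate-case tests.

Classification follows the bound-vs-unbound design: windows aligned on a
shared core, label 1 inside peaks, 0 for the random intronic background.
Sequence features one-hot encode flank positions only (the shared core is
constant and carries no information); shape features cover all window
positions, because flanking bases alter shape at the core edges. Models
are ridge regressions on the 0/1 response — w = argmin ‖Xw−y‖² + λ‖w‖²,
intercept unpenalized — scored by the raw linear predictor (no
probability calibration). Columns are standardized with training-fold
moments only. λ defaults to an inner 5-fold grid search over
{0.01, 0.1, 1, 10, 100} on the training folds; a fixed-λ mode exists for
reproducibility-sensitive runs. Evaluation is stratified seeded 10-fold
CV with AUC computed on pooled out-of-fold scores (per-fold AUCs also
reported); the four feature sets share identical folds. Flank length
defaults to 10 bp per side (window 26 bp), enough for flanking sequence
to reach core shape through the pentamer model with margin.

## Expression integration

A transcript passes when FPKM⁺ ≥ 0.983129 **and** FPKM⁺/FPKM⁻ ≥ 1.5.
The 6-decimal cutoff (rather than the rounded 0.98) is the operative
reference-transcript value; both are accepted via configuration. A zero
denominator counts as infinite enrichment and passes the fold test (an
optional pseudocount mode adds ε to both FPKMs instead). The ChIP set is
all isoforms of every peak-associated gene; the transcript universe N
defaults to the supplied annotation's transcript count.

The overlap is scored with the exact cumulative hypergeometric tail

    P(X ≥ k) = Σ_{i=k}^{min(K,n)} C(K,i) C(N−K,n−i) / C(N,n),

summed in log space (gammaln + logsumexp), accurate well beyond six
significant digits and cross-checked against `scipy.stats.hypergeom` and
exhaustive enumeration at small N. Both tail conventions are exposed:
`strict=True` returns P(X > k). The distinction matters when comparing
against historical analyses — spreadsheet-era tools computed strict
tails, and published overlap P-values sometimes correspond to
P(X > k) = P(X ≥ k+1) rather than the inclusive tail their text states;
at the published scale (N = 30459, K = 4105, n = 1809, k = 337) the two
differ by ~1.5-fold (1.441241e-10 vs 9.435933e-11).

## Synthetic data: what it emulates, and what it does not

The generator plants every structure the analysis assumes, under one
seeded configuration (all generators are pure functions of the seed, with
independent substreams, callable in any order):

- **Genome**: i.i.d. bases at a configurable GC fraction (default 0.45,
  fly-euchromatin-like), two chromosomes totalling 0.6 Mb by default.
  Bound cores are planted inside future peak intervals (with a 5′ C
  prefix at probability 0.6, emulating the CCATATG preference), unbound
  cores inside introns; all plants are registered in `PlantedTruth`.
- **Genes**: 50 non-overlapping multi-exon genes (2–5 exons, ~30%
  two-isoform), intergenic gaps 3.5–6.5 kb so that a 3-kb association
  radius selects only the gene a peak was planted in. First introns are
  sized to hold a peak — the first-intron binding preference is planted,
  not emergent.
- **Probe tracks**: probes every 35 bp (Affymetrix-tiling-like), log2
  intensity = baseline 8 + N(0, 0.25); the experimental ChIP alone gains
  log2(4) over the 10 planted 600-bp peak intervals. Values are
  quantized to 6 decimals so emitted bedGraph round-trips bit-exactly.
- **Conservation**: Beta(1, 9) background elevated toward 1 by 0.6
  within ±20 bp of bound cores; quantized to 4 decimals.
- **Expression**: log-normal FPKMs (log-mean ln 8, σ 1.2; sample noise
  σ 0.3); enriched transcripts (all isoforms of peak-target genes, plus
  random transcripts up to 15% of the universe) get FPKM⁺ × 4; one
  registered reference transcript is pinned at exactly 0.983129 / 0.26
  FPKM to exercise the cutoff boundary.
- **Site sets**: aligned windows sharing one central core, flanks i.i.d.
  at the genome GC fraction. The planted shape effect selects, per bound
  site, the candidate flank pair (of 50 draws) whose window-mean MGW is
  closest to background mean + δ — a rejection-style composition bias
  that leaves the core untouched. δ = 0 draws flanks exactly from the
  background, so the null is exact by construction; for δ > 0 the bound
  class also has reduced MGW variance and a correlated base-composition
  shift, so sequence models see signal too (as they do on real data,
  shape being a function of sequence).

Noise models were chosen as the simplest forms matching the analysis's
assumptions (additive log-scale array noise, ratio-filtered log-normal
expression); the originating array experiments publish no noise model, so
these parameters are knobs, not estimates. Passing tests on these data
show the machinery is correct and calibrated — they do not certify
performance on real arrays, where probe-sequence bias,
cross-hybridization, correlated noise and mappability structure exist and
are deliberately out of scope.

Default problem sizes (0.6 Mb genome, 10 peaks, 500/500 site sets,
10–20 seed replicates) are chosen so the statistical claims are testable
with comfortable margins at interactive runtimes.

## Known limitations

- The smoothed score is MAT-like, not MAT: probe-affinity baseline
  modelling is absent (and unneeded on affinity-free synthetic probes).
- The shape table is synthetic; absolute shape values and AUCs on real
  genomes require a measured pentamer table.
- `read_conservation` fills unscored positions with 0, not NaN.
- Peak-set overlap and association scans are O(peaks × genes) — fine at
  tiling-array scale, not built for millions of intervals.
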