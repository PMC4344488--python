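# eboxchip

Tiling-array ChIP analysis of E-box-binding bHLH transcription factors,
built as a reusable, fully testable pipeline. The scientific setting is a
tagged-ChIP experiment on genome tiling microarrays (experimental ChIP,
experimental input, control ChIP, control input) paired with RNA-seq of
FACS-sorted marker-positive vs marker-negative cells — the design used to
map the genome-wide program of neuroendocrine regulators such as the
*Drosophila* factor DIMM, whose binding sites are palindromic CATATG /
CAGCTG E-boxes concentrated in first introns.

The package covers five analysis stages, each usable on its own:

1. **Signal & peaks** (`signal`) — per-probe combination of the four
   samples, `C = [(#1−#2) − (#3−#4)] + (#1−#3)` on (optionally
   quantile-normalized) log2 intensities; a MAT-like smoothed score
   `s_i = trimmed-mean(C, ±BandWidth) · √n`; upper-tail p-values under a
   median/MAD Gaussian null; a naive caller with BandWidth = 300 bp,
   MaxGap = 300 bp, MinProbe = 8, p ≤ 10⁻⁴.
2. **Gene context** (`annotate`) — peak→gene assignment within 3 kb,
   strand-oriented TSS/TTS profiles, metagene, TSS vs first-intron vs
   other-intron preference, peak-set overlap.
3. **E-boxes & conservation** (`motifs`) — exhaustive plus-strand CANNTG
   scanning (CATATG/CAGCTG are their own reverse complements), per-peak
   tallies, center-relative density, 5′-prefix variants, GC profile, and
   per-base conservation of bound vs randomly sampled intronic E-boxes.
4. **Sequence + shape classification** (`shape`, `classify`) — pentamer
   DNA-shape prediction (MGW, ProT, Roll, HelT), flank-derived one-hot and
   shape feature blocks over aligned site windows, L2-regularized linear
   models (w = argmin ‖Xw − y‖² + λ‖w‖²), stratified 10-fold CV, pooled
   out-of-fold ROC/AUC for four feature sets.
5. **Target integration** (`integrate`) — transcripts passing
   FPKM⁺ ≥ 0.983129 and ≥ 1.5-fold enrichment intersected with all isoforms
   of peak-associated genes, collapsed to genes, and scored with an exact
   cumulative hypergeometric tail P(X ≥ k) computed in log space.

A first-class synthetic-data module (`simulate`) generates every input —
genome with planted E-box cores, intron-bearing gene models (GTF), four
probe tracks (bedGraph), conservation (bedGraph), FPKM tables (TSV) — with
registered ground truth, so every stage is testable without external data.

## Worked example

```python
import eboxchip as ec

cfg = ec.SyntheticConfig(seed=42)          # ~0.6 Mb genome, 10 planted peaks
genome, truth = ec.gen_genome(cfg)
tracks = ec.gen_probe_tracks(cfg, genome, truth)
peaks = ec.call_peaks(ec.smooth_score(ec.normalize_tracks(*tracks)))
print(len(peaks))
```

Running `python examples/01_peak_calling.py` prints

```
planted intervals : 10
called peaks      : 10
recovered (>=50% reciprocal overlap): 10/10
strongest peak    : chr2L:64330-65135 score=9.0 p=9.11e-28 (23 probes)
```

i.e. every planted 4-fold-enriched interval is recovered with no spurious
calls; the score is the trimmed-mean·√n window statistic and the p-value
its upper-tail probability under the robust genome-wide null. The other
scripts in `examples/` walk through gene-context profiles, E-box
conservation, shape-based classification (AUC ≈ 0.89 for a planted 0.4 Å
minor-groove shift vs 0.5 at chance) and expression integration, where the
hypergeometric tail at published scale evaluates to
`P(X ≥ 337) = 1.441241e-10` for N = 30459, K = 4105, n = 1809 (the strict
tail P(X > 337) is 9.435933e-11).

A thin CLI mirrors the library (`eboxchip simulate|callpeaks|annotate|
motifs|shape|integrate|all --config pipeline.yaml`), writing peaks as
BED6+4, tables as TSV and a deterministic JSON summary.

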