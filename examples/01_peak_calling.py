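"""Call binding peaks on a simulated four-sample tiling-ChIP experiment.

Simulates a small genome with 10 enriched intervals planted in first
introns, combines the four array samples with the double-normalization
C = [(chip_exp - input_exp) - (chip_ctl - input_ctl)] + (chip_exp - chip_ctl),
smooths with the MAT-like windowed statistic and calls peaks, then checks
the calls against the planted truth.
"""

import eboxchip as ec

cfg = ec.SyntheticConfig(seed=42)
genome, truth = ec.gen_genome(cfg)
tracks = ec.gen_probe_tracks(cfg, genome, truth)

combined = ec.normalize_tracks(*tracks)
scored = ec.smooth_score(combined, ec.CallerParams())
peaks = ec.call_peaks(scored)

print(f"planted intervals : {len(truth.peak_intervals)}")
print(f"called peaks      : {len(peaks)}")
hits = sum(
    any(pk.chrom == c and min(pk.end, b) - max(pk.start, a)
        >= 0.5 * max(pk.end - pk.start, b - a) for pk in peaks)
    for c, a, b in truth.peak_intervals)
print(f"recovered (>=50% reciprocal overlap): {hits}/{len(truth.peak_intervals)}")
top = max(peaks, key=lambda p: p.score)
print(f"strongest peak    : {top.chrom}:{top.start}-{top.end} "
      f"score={top.score:.1f} p={top.p_value:.2e} ({top.n_probes} probes)")
# Every planted interval should be recovered and no spurious peak called:
# the enrichment (4-fold over a 0.25-SD log2 noise floor) is strong.
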