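"""E-boxes inside peaks: tallies, central enrichment and conservation.

Scans called peaks for the palindromic CATATG/CAGCTG E-box cores, counts
peaks with one or more cores, and contrasts per-base conservation of
peak (bound) CATATG cores against randomly sampled intronic (unbound)
cores -- bound cores sit on a planted conservation plateau.
"""

import warnings

import numpy as np

import eboxchip as ec

cfg = ec.SyntheticConfig(seed=3)
genome, truth = ec.gen_genome(cfg)
genes = ec.gen_annotation(cfg, genome)
tracks = ec.gen_probe_tracks(cfg, genome, truth)
peaks = ec.call_peaks(ec.smooth_score(ec.normalize_tracks(*tracks)))
cons = ec.gen_conservation(cfg, genome, truth)

occs = ec.scan_eboxes(genome, [(p.chrom, p.start, p.end) for p in peaks])
occs = ec.attach_peak_offsets(occs, peaks)
_, tallies = ec.peak_ebox_counts(occs, peaks)
print(f"peaks: {len(peaks)};  E-box occurrences inside peaks: {len(occs)}")
print(f"peaks with >=1 TA/GC E-box: {tallies['n_peaks_with_ebox']}; "
      f"with more than one: {tallies['n_peaks_with_multiple']}")

bound = [o for o in occs if o.core == "CATATG"]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    rand = ec.sample_random_intronic_eboxes(genome, genes, "CATATG", n=800,
                                            seed=3, exclude_peaks=peaks)
pb = ec.conservation_profile(bound, cons, flank=10)
pr = ec.conservation_profile(rand, cons, flank=10)
core = slice(10, 16)
print(f"mean conservation over the core, bound  : {np.nanmean(pb.mean_score[core]):.3f}")
print(f"mean conservation over the core, random : {np.nanmean(pr.mean_score[core]):.3f}")
# Bound cores should be far more conserved than the intronic background.
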