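"""E-box scanning, positional/prefix/GC profiles, background sampling, conservation."""

import re
import warnings

import numpy as np
import pytest

import eboxchip as ec
from eboxchip.motifs import attach_peak_offsets, expand_core

COMP = str.maketrans("ACGT", "TGCA")


def peak(start, end, chrom="chr1"):
    return ec.Peak(chrom, start, end, (start + end) // 2, 1.0, 1e-9, 8)


class TestScan:
    def test_single_occurrence_with_prefix(self):
        occs = ec.scan_eboxes({"chr1": "GCATATGC"}, None, cores=["CATATG"])
        assert len(occs) == 1
        o = occs[0]
        assert (o.position, o.prefix_base, o.core_class) == (1, "G", "TA")

    def test_cacgtg_is_other_class(self):
        occs = ec.scan_eboxes({"chr1": "ACACGTGA"}, None, cores=["CANNTG"])
        assert len(occs) == 1 and occs[0].core_class == "other"

    def test_tandem_occurrences(self):
        occs = ec.scan_eboxes({"chr1": "CATATGCATATG"}, None, cores=["CATATG"])
        assert [o.position for o in occs] == [0, 6]

    def test_overlapping_matches_all_reported(self):
        # CATATG at 0 and degenerate CANNTG overlapping is impossible for this
        # string, but ATATGCATATG style overlaps of CANNTG-any must all appear
        seq = "CACATGCATGTG"
        got = {o.position for o in ec.scan_eboxes({"chr1": seq}, None, cores=["CANNTG"])}
        oracle = {m.start() for m in re.finditer(r"(?=CA[ACGT][ACGT]TG)", seq)}
        assert got == oracle

    def test_region_beyond_chromosome_raises(self):
        with pytest.raises(ValueError, match="beyond chromosome end"):
            ec.scan_eboxes({"chr1": "ACGT" * 10}, [("chr1", 0, 100)])

    def test_regex_oracle_random_100kb(self):
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        got = {(o.position, o.core) for o in ec.scan_eboxes({"c": seq}, None, cores=["CANNTG"])}
        oracle = {(m.start(), seq[m.start(): m.start() + 6])
                  for m in re.finditer(r"(?=(CA[ACGT]{2}TG))", seq)}
        assert got == oracle

    def test_palindromy_under_reverse_complement(self):
        rng = np.random.default_rng(6)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)])
        rc = seq.translate(COMP)[::-1]
        for core in (ec.TA_CORE, ec.GC_CORE):
            fwd = {o.position for o in ec.scan_eboxes({"c": seq}, None, cores=[core])}
            rev = {len(seq) - o.position - 6
                   for o in ec.scan_eboxes({"c": rc}, None, cores=[core])}
            assert fwd == rev


class TestCountsAndProfiles:
    def test_count_summary_enumeration(self):
        # 3 peaks holding 0, 1 and 2 TA/GC occurrences -> summary (2, 1)
        genome = {"chr1": "T" * 100 + "CATATG" + "T" * 94 + "CAGCTGTTCATATG" + "T" * 86}
        peaks = [peak(0, 100), peak(100, 200), peak(200, 300)]
        occs = ec.scan_eboxes(genome, None)
        counts, summary = ec.peak_ebox_counts(occs, peaks)
        assert counts == [0, 1, 2]
        assert summary == {"n_peaks_with_ebox": 2, "n_peaks_with_multiple": 1}

    def test_positional_profile_central_mass(self):
        peaks = [peak(i * 1000, i * 1000 + 400) for i in range(5)]
        occs = [ec.EboxOccurrence("chr1", p.center, "CATATG", "TA", "C") for p in peaks]
        edges, dens = ec.positional_profile(occs, peaks, bin_width=50)
        centers = (edges[:-1] + edges[1:]) / 2
        near = np.abs(centers) < 50  # offset 0 sits on a bin edge
        assert dens[near].sum() > 0
        assert dens[~near].sum() == 0

    def test_positional_profile_empty_occurrences(self):
        _, dens = ec.positional_profile([], [peak(0, 400)], bin_width=50)
        assert np.all(dens == 0)

    def test_prefix_all_c(self):
        occs = [ec.EboxOccurrence("c", 0, "CATATG", "TA", "C", peak_offset=o)
                for o in (-120, -20, 40, 130)]
        _, freqs = ec.prefix_variant_profile(occs, bin_width=100)
        populated = ~np.isnan(freqs["C"])
        assert np.allclose(freqs["C"][populated], 1.0)
        assert np.isnan(freqs["A"][~populated]).all()

    def test_prefix_equal_counts_quarter_each(self):
        occs = [ec.EboxOccurrence("c", 0, "CATATG", "TA", b, peak_offset=10)
                for b in "ACGT"]
        _, freqs = ec.prefix_variant_profile(occs, bin_width=100)
        j = ~np.isnan(freqs["A"])
        assert all(freqs[b][j] == pytest.approx(0.25) for b in "ACGT")

    @pytest.mark.parametrize("base,expected", [("G", 1.0), ("A", 0.0)])
    def test_gc_profile_degenerate_genomes(self, base, expected):
        genome = {"chr1": base * 2000}
        _, gc = ec.gc_profile(genome, [peak(500, 1500)], bin_width=100)
        assert np.allclose(gc[~np.isnan(gc)], expected)

    def test_gc_profile_acgt_repeat(self):
        genome = {"chr1": "ACGT" * 500}
        _, gc = ec.gc_profile(genome, [peak(500, 1500)], bin_width=100)
        assert np.allclose(gc[~np.isnan(gc)], 0.5)


class TestRandomIntronic(object):
    def test_sample_constraints_and_determinism(self, tiny_cfg, tiny_dataset):
        genome, truth, genes = tiny_dataset
        peaks = [peak(a, b, chrom=c) for c, a, b in truth.peak_intervals]
        s1 = ec.sample_random_intronic_eboxes(genome, genes, n=10, seed=3,
                                              exclude_peaks=peaks)
        s2 = ec.sample_random_intronic_eboxes(genome, genes, n=10, seed=3,
                                              exclude_peaks=peaks)
        assert [(o.chrom, o.position) for o in s1] == [(o.chrom, o.position) for o in s2]
        introns = [(g.chrom, iv[0], iv[1]) for g in genes
                   for t in g.transcripts.values()
                   for iv in ([t.first_intron] if t.first_intron else [])]
        for o in s1:
            assert any(c == o.chrom and a <= o.position < b for c, a, b in introns)
            assert not any(c == o.chrom and a <= o.position < b
                           for c, a, b in truth.peak_intervals)

    def test_requesting_more_than_available_returns_all_with_warning(self, tiny_dataset):
        genome, truth, genes = tiny_dataset
        with pytest.warns(UserWarning, match="available"):
            s = ec.sample_random_intronic_eboxes(genome, genes, n=10_000, seed=0)
        assert 0 < len(s) < 10_000


class TestConservationProfile:
    def test_constant_track_gives_constant_profile(self):
        occs = [ec.EboxOccurrence("c", 50, "CATATG", "TA", "C")]
        prof = ec.conservation_profile(occs, {"c": np.ones(200)}, flank=10)
        assert np.allclose(prof.mean_score, 1.0)

    def test_single_site_equals_its_score_vector(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 200)
        occs = [ec.EboxOccurrence("c", 80, "CATATG", "TA", "C")]
        prof = ec.conservation_profile(occs, {"c": scores}, flank=5)
        assert np.allclose(prof.mean_score, scores[75:91])

    def test_bound_vs_random_difference(self):
        occs_b = [ec.EboxOccurrence("b", 50, "CATATG", "TA", "C")]
        occs_r = [ec.EboxOccurrence("r", 50, "CATATG", "TA", "C")]
        cons = {"b": np.ones(200), "r": np.zeros(200)}
        pb = ec.conservation_profile(occs_b, cons, flank=8)
        pr = ec.conservation_profile(occs_r, cons, flank=8)
        assert np.allclose(pb.mean_score - pr.mean_score, 1.0)

    def test_planted_elevation_separates_bound_from_random(self):
        # generator property: elevated conservation at bound sites is recovered
        for seed in range(5):
            cfg = ec.SyntheticConfig(seed=seed, chrom_lengths={"chrA": 140_000},
                                     n_genes=10, n_planted_peaks=4,
                                     n_bound_sites=12, n_unbound_sites=40,
                                     conservation_elevation=0.5)
            genome, truth = ec.gen_genome(cfg)
            genes = ec.gen_annotation(cfg, genome)
            cons = ec.gen_conservation(cfg, genome, truth)
            bound = [ec.EboxOccurrence(c, p, core, "TA", "N")
                     for c, p, core in truth.bound_sites]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rand = ec.sample_random_intronic_eboxes(genome, genes, n=40, seed=seed)
            pb = ec.conservation_profile(bound, cons, flank=5)
            pr = ec.conservation_profile(rand, cons, flank=5)
            core_cols = slice(5, 11)
            assert np.nanmean(pb.mean_score[core_cols]) > np.nanmean(pr.mean_score[core_cols])


def test_expand_core_concrete_count():
    assert len(expand_core("CANNTG")) == 16
    assert expand_core("CATATG") == ["CATATG"]


def test_attach_peak_offsets_midpoint_and_summit():
    pk = ec.Peak("c", 100, 300, 150, 2.0, 1e-9, 8)
    occ = ec.EboxOccurrence("c", 220, "CATATG", "TA", "C")
    mid = attach_peak_offsets([occ], [pk])[0]
    smt = attach_peak_offsets([occ], [pk], use_summit=True)[0]
    assert mid.peak_offset == 220 - 200
    assert smt.peak_offset == 220 - 150
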