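"""Synthetic-data generators: determinism, planted-truth registry, degenerate knobs."""

import numpy as np
import pytest

import eboxchip as ec
from eboxchip.classify import PAD
from eboxchip.shape import predict_shape


class TestGenome:
    def test_same_config_identical_output(self, tiny_cfg):
        g1, t1 = ec.gen_genome(tiny_cfg)
        g2, t2 = ec.gen_genome(tiny_cfg)
        assert g1 == g2
        assert t1.peak_intervals == t2.peak_intervals
        assert t1.bound_sites == t2.bound_sites

    def test_registered_bound_sites_contain_planted_cores(self):
        cfg = ec.SyntheticConfig(seed=2, chrom_lengths={"chrA": 140_000},
                                 n_genes=10, n_planted_peaks=4,
                                 n_bound_sites=5, n_unbound_sites=10)
        genome, truth = ec.gen_genome(cfg)
        assert len(truth.bound_sites) == 5
        for chrom, pos, core in truth.bound_sites:
            assert genome[chrom][pos: pos + 6] == core
        for chrom, pos, core in truth.unbound_sites:
            assert genome[chrom][pos: pos + 6] == core

    def test_bound_sites_inside_peaks_unbound_outside(self, tiny_dataset):
        _, truth, _ = tiny_dataset
        for chrom, pos, _ in truth.bound_sites:
            assert any(c == chrom and a <= pos < b for c, a, b in truth.peak_intervals)
        for chrom, pos, _ in truth.unbound_sites:
            assert not any(c == chrom and a <= pos < b for c, a, b in truth.peak_intervals)

    def test_gc_fraction_one_makes_noncore_bases_gc(self):
        cfg = ec.SyntheticConfig(seed=3, chrom_lengths={"chrA": 140_000},
                                 n_genes=10, n_planted_peaks=2, gc_fraction=1.0,
                                 n_bound_sites=2, n_unbound_sites=2)
        genome, truth = ec.gen_genome(cfg)
        planted = set()
        for chrom, pos, core in truth.bound_sites + truth.unbound_sites:
            planted.update(range(pos - 1, pos + 6))  # core + possible prefix plant
        seq = genome["chrA"]
        non_core = [seq[i] for i in range(len(seq)) if i not in planted]
        assert set(non_core) <= {"G", "C"}

    def test_oversized_request_raises_sizing_error(self):
        with pytest.raises(ValueError, match="cannot place|host at most"):
            cfg = ec.SyntheticConfig(seed=0, chrom_lengths={"chrA": 30_000}, n_genes=40,
                                     n_planted_peaks=10)
            ec.gen_genome(cfg)


class TestAnnotation:
    def test_gene_count_and_first_introns(self, tiny_cfg, tiny_dataset):
        _, _, genes = tiny_dataset
        assert len(genes) == tiny_cfg.n_genes
        for g in genes:
            t = g.transcripts[f"{g.gene_id}.t1"]
            assert t.first_intron is not None

    def test_minus_strand_tss_is_larger_coordinate(self, tiny_dataset):
        _, _, genes = tiny_dataset
        minus = [g for g in genes if g.strand == "-"]
        assert minus, "fixture should contain minus-strand genes"
        for g in minus:
            t = g.transcripts[f"{g.gene_id}.t1"]
            assert t.tss == g.span[1] - 1

    def test_genes_do_not_overlap(self, tiny_dataset):
        _, _, genes = tiny_dataset
        spans = sorted((g.chrom, *g.span) for g in genes)
        for (c1, _, e1), (c2, s2, _) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 <= s2


class TestProbeTracks:
    def test_shared_grid_across_samples(self, tiny_cfg, tiny_dataset):
        genome, truth, _ = tiny_dataset
        tracks = ec.gen_probe_tracks(tiny_cfg, genome, truth)
        for chrom in genome:
            ref = tracks[0][chrom].positions
            for s in tracks[1:]:
                assert np.array_equal(s[chrom].positions, ref)

    def test_no_noise_no_enrichment_all_identical(self, tiny_dataset):
        genome, truth, _ = tiny_dataset
        cfg = ec.SyntheticConfig(seed=11, chrom_lengths={"chrA": 140_000},
                                 n_genes=10, n_planted_peaks=4, noise_sd=0.0,
                                 enrichment_fold=1.0, n_bound_sites=12, n_unbound_sites=40)
        t = ec.gen_probe_tracks(cfg, genome, truth)
        for chrom in genome:
            for s in t[1:]:
                assert np.array_equal(s[chrom].values, t[0][chrom].values)

    def test_exact_two_log2_units_inside_planted_peaks(self, tiny_dataset):
        genome, truth, _ = tiny_dataset
        cfg = ec.SyntheticConfig(seed=11, chrom_lengths={"chrA": 140_000},
                                 n_genes=10, n_planted_peaks=4, noise_sd=0.0,
                                 enrichment_fold=4.0, n_bound_sites=12, n_unbound_sites=40)
        chip, inp, _, _ = ec.gen_probe_tracks(cfg, genome, truth)
        for chrom in genome:
            diff = chip[chrom].values - inp[chrom].values
            pos = chip[chrom].positions
            inside = np.zeros(pos.size, bool)
            for c, a, b in truth.peak_intervals:
                if c == chrom:
                    inside |= (pos >= a) & (pos < b)
            assert np.allclose(diff[inside], 2.0)
            assert np.allclose(diff[~inside], 0.0)


class TestExpression:
    def test_reference_transcript_exercises_cutoff(self, tiny_cfg, tiny_dataset):
        genome, truth, genes = tiny_dataset
        expr = ec.gen_expression(tiny_cfg, genes, truth)
        ref = expr[expr.transcript_id == truth.reference_transcript_id].iloc[0]
        assert ref.fpkm_plus == 0.983129
        assert ref.fpkm_plus >= 0.983129
        assert not ref.fpkm_plus >= 0.983130  # one ulp of the cutoff grid fails

    def test_shared_noise_and_unit_fold_equalizes_samples(self, tiny_cfg, tiny_dataset):
        _, truth, genes = tiny_dataset
        expr = ec.gen_expression(tiny_cfg, genes, truth, enrichment_fold=1.0,
                                 shared_noise=True)
        other = expr[expr.transcript_id != truth.reference_transcript_id]
        assert np.allclose(other.fpkm_plus, other.fpkm_minus)

    def test_same_seed_identical_table(self, tiny_cfg, tiny_dataset):
        _, truth, genes = tiny_dataset
        e1 = ec.gen_expression(tiny_cfg, genes, truth)
        e2 = ec.gen_expression(tiny_cfg, genes, truth)
        assert e1.equals(e2)

    def test_enriched_transcripts_boosted(self, tiny_cfg, tiny_dataset):
        _, truth, genes = tiny_dataset
        base = ec.gen_expression(tiny_cfg, genes, truth, enrichment_fold=1.0)
        boosted = ec.gen_expression(tiny_cfg, genes, truth, enrichment_fold=4.0)
        m = base.transcript_id.isin(truth.enriched_transcript_ids - {truth.reference_transcript_id})
        assert np.allclose(boosted.fpkm_plus[m], 4.0 * base.fpkm_plus[m], rtol=1e-5)


class TestConservation:
    def test_scores_within_unit_interval(self, tiny_cfg, tiny_dataset):
        genome, truth, _ = tiny_dataset
        cons = ec.gen_conservation(tiny_cfg, genome, truth)
        for arr in cons.values():
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_full_elevation_zero_background_gives_ones(self, tiny_dataset):
        genome, truth, _ = tiny_dataset
        cfg = ec.SyntheticConfig(seed=11, chrom_lengths={"chrA": 140_000},
                                 n_genes=10, n_planted_peaks=4, n_bound_sites=12,
                                 n_unbound_sites=40, conservation_elevation=1.0,
                                 conservation_bg_scale=0.0)
        cons = ec.gen_conservation(cfg, genome, truth)
        for chrom, pos, core in truth.bound_sites:
            assert np.all(cons[chrom][pos: pos + 6] == 1.0)
        # background stays exactly zero: coverage equals the union of windows
        covered = set()
        for c, p, _ in truth.bound_sites:
            covered.update(range(max(0, p - cfg.conservation_flank),
                                 min(len(cons[c]), p + 6 + cfg.conservation_flank)))
        assert cons["chrA"].sum() == pytest.approx(len(covered), abs=1e-6)

    def test_zero_elevation_leaves_background_untouched(self, tiny_dataset):
        genome, truth, _ = tiny_dataset
        cfg0 = ec.SyntheticConfig(seed=11, chrom_lengths={"chrA": 140_000},
                                  n_genes=10, n_planted_peaks=4, n_bound_sites=12,
                                  n_unbound_sites=40, conservation_elevation=0.0)
        cons = ec.gen_conservation(cfg0, genome, truth)
        rng = cfg0.rng(7)
        bg = np.clip(rng.beta(1.0, 9.0, size=len(genome["chrA"])), 0, 1)
        assert np.allclose(cons["chrA"], np.round(bg, 4))


class TestSiteSets:
    def test_identical_core_at_center_and_label_counts(self, shape_table):
        cfg = ec.SyntheticConfig(seed=5, n_bound_sites=40, n_unbound_sites=30)
        sites = ec.gen_site_sets(cfg, shape_table)
        sites.check_alignment()
        assert sites.labels.sum() == 40 and (sites.labels == 0).sum() == 30
        a = PAD + sites.core_offset
        assert all(s[a: a + 6] == cfg.site_core for s in sites.sequences)

    def test_zero_delta_flank_mgw_difference_within_three_se(self, shape_table):
        cfg = ec.SyntheticConfig(seed=6, n_bound_sites=500, n_unbound_sites=500,
                                 shape_effect_delta=0.0)
        sites = ec.gen_site_sets(cfg, shape_table)
        mgw = np.array([np.nanmean(predict_shape(s, shape_table)[2:-2, 0])
                        for s in sites.sequences])
        b, u = mgw[sites.labels == 1], mgw[sites.labels == 0]
        se = np.sqrt(b.var(ddof=1) / b.size + u.var(ddof=1) / u.size)
        assert abs(b.mean() - u.mean()) < 3 * se

    def test_positive_delta_shifts_bound_mgw(self, shape_table):
        cfg = ec.SyntheticConfig(seed=6, n_bound_sites=200, n_unbound_sites=200,
                                 shape_effect_delta=0.4)
        sites = ec.gen_site_sets(cfg, shape_table)
        mgw = np.array([np.nanmean(predict_shape(s, shape_table)[2:-2, 0])
                        for s in sites.sequences])
        b, u = mgw[sites.labels == 1], mgw[sites.labels == 0]
        assert b.mean() - u.mean() > 0.2

    def test_window_too_small_raises(self):
        with pytest.raises(ValueError, match="site_window"):
            ec.SyntheticConfig(site_window=12)

    def test_same_seed_identical_sites(self, shape_table):
        cfg = ec.SyntheticConfig(seed=7, n_bound_sites=20, n_unbound_sites=20)
        s1 = ec.gen_site_sets(cfg, shape_table)
        s2 = ec.gen_site_sets(cfg, shape_table)
        assert s1.sequences == s2.sequences
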