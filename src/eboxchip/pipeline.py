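"""End-to-end pipeline: signal -> peaks -> annotation -> motifs -> shape -> integration.

`simulate_inputs` materialises a complete synthetic input set on disk;
`run_pipeline` executes the analysis stages over input files and writes
peaks (BED6+4), profile/occurrence tables (TSV) and a JSON summary whose
content is a pure function of inputs + config (reruns are byte-identical).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .annotate import (anchored_profile, assign_peaks_to_genes, intron_preference,
                       metagene_profile)
from .classify import PAD, FEATURE_SETS, SiteSet, compare_models
from .integrate import (HypergeomParams, IntegrationParams, chip_transcript_set,
                        filter_expressed, hypergeom_tail, intersect_and_collapse)
from .motifs import (attach_peak_offsets, conservation_profile, gc_profile,
                     peak_ebox_counts, positional_profile, prefix_variant_profile,
                     sample_random_intronic_eboxes, scan_eboxes)
from .shape import synthetic_shape_table
from .signal import CallerParams, call_peaks, normalize_tracks, smooth_score
from .simulate import (SyntheticConfig, gen_annotation, gen_conservation,
                       gen_expression, gen_genome, gen_probe_tracks)

__all__ = ["PipelineConfig", "simulate_inputs", "run_pipeline", "STAGES"]

STAGES = ("callpeaks", "annotate", "motifs", "shape", "integrate")


@dataclass
class PipelineConfig:
    genome_fasta: str
    annotation_gtf: str
    chip_exp: str
    input_exp: str
    chip_ctl: str
    input_ctl: str
    conservation: str | None = None
    expression: str | None = None
    shape_table: str | None = None  # None -> packaged synthetic table
    outdir: str = "eboxchip_out"
    seed: int = 0
    caller: CallerParams = field(default_factory=CallerParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    site_core: str = "CATATG"
    site_window: int = 26
    ridge_lambda: float | None = None
    n_folds: int = 10
    n_random_intronic: int = 800
    conservation_flank: int = 20

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_inputs(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, str]:
    """Generate and write the full synthetic input set; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = io.provenance_lines(cfg.seed, io.config_hash(cfg.to_dict()))
    genome, truth = gen_genome(cfg)
    genes = gen_annotation(cfg, genome)
    tracks = gen_probe_tracks(cfg, genome, truth)
    cons = gen_conservation(cfg, genome, truth)
    expr = gen_expression(cfg, genes, truth)
    paths = {
        "genome_fasta": str(outdir / "genome.fa"),
        "annotation_gtf": str(outdir / "annotation.gtf"),
        "chip_exp": str(outdir / "chip_exp.bedgraph"),
        "input_exp": str(outdir / "input_exp.bedgraph"),
        "chip_ctl": str(outdir / "chip_ctl.bedgraph"),
        "input_ctl": str(outdir / "input_ctl.bedgraph"),
        "conservation": str(outdir / "conservation.bedgraph"),
        "expression": str(outdir / "expression.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    io.write_fasta(genome, paths["genome_fasta"])
    io.write_gtf(genes, paths["annotation_gtf"], header=head)
    for key, sample in zip(("chip_exp", "input_exp", "chip_ctl", "input_ctl"), tracks):
        io.write_bedgraph(sample, paths[key], span=cfg.probe_length, header=head)
    io.write_conservation(cons, paths["conservation"], header=head)
    io.write_expression(expr, paths["expression"], header=head)
    io.write_truth(truth, paths["truth"])
    return paths


def _profile_frame(profile, what: str) -> pd.DataFrame:
    edges = profile.bin_edges
    return pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:],
        what: profile.mean_signal,
    })


def _extract_site_windows(genome, occurrences, window, core, label):
    half = (window - len(core)) // 2
    seqs, labels = [], []
    for o in occurrences:
        seq = genome[o.chrom]
        a = o.position - half - PAD
        b = o.position + len(core) + half + PAD
        if a < 0 or b > len(seq):
            continue
        win = seq[a:b].upper()
        if any(ch not in "ACGT" for ch in win):
            warnings.warn(f"ambiguous base near {o.chrom}:{o.position}; site dropped")
            continue
        seqs.append(win)
        labels.append(label)
    return seqs, labels


def run_pipeline(config: PipelineConfig, upto: str = "integrate") -> dict:
    """Run analysis stages up to ``upto`` and write artifacts + summary JSON."""
    if upto not in STAGES:
        raise ValueError(f"upto must be one of {STAGES}")
    last = STAGES.index(upto)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = io.provenance_lines(config.seed, io.config_hash(config.to_dict()))
    summary: dict = {"seed": config.seed, "config_hash": io.config_hash(config.to_dict()),
                     "stages_run": list(STAGES[: last + 1])}

    def _fail(stage, exc):
        raise RuntimeError(f"pipeline stage '{stage}' failed on inputs of {config.outdir}: {exc}") from exc

    genome = io.read_fasta(config.genome_fasta)
    genes = io.read_annotation(config.annotation_gtf)

    # --- callpeaks
    try:
        samples = io.read_tracks([config.chip_exp, config.input_exp,
                                  config.chip_ctl, config.input_ctl])
        combined = normalize_tracks(*samples, quantile_norm=config.caller.quantile_norm)
        scored = smooth_score(combined, config.caller)
        peaks = call_peaks(scored, config.caller)
    except Exception as exc:  # noqa: BLE001
        _fail("callpeaks", exc)
    io.write_peaks_bed(peaks, outdir / "peaks.bed", header=head)
    summary["n_peaks"] = len(peaks)

    if last >= STAGES.index("annotate"):
        try:
            assoc = assign_peaks_to_genes(peaks, genes, config.integration.max_dist)
            tss = [(g.chrom, t.tss, g.strand) for g in genes for t in g.transcripts.values()]
            tts = [(g.chrom, t.tts, g.strand) for g in genes for t in g.transcripts.values()]
            prof_tss = anchored_profile(combined, tss)
            prof_tts = anchored_profile(combined, tts)
            meta = metagene_profile(combined, genes)
            pref = intron_preference(genes, track=combined)
        except Exception as exc:  # noqa: BLE001
            _fail("annotate", exc)
        _profile_frame(prof_tss, "mean_signal").to_csv(outdir / "profile_tss.tsv", sep="\t", index=False)
        _profile_frame(prof_tts, "mean_signal").to_csv(outdir / "profile_tts.tsv", sep="\t", index=False)
        _profile_frame(meta, "mean_signal").to_csv(outdir / "profile_metagene.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(a.peak_index, a.gene_id, a.distance) for a in assoc],
            columns=["peak_index", "gene_id", "distance"],
        ).to_csv(outdir / "peak_gene_associations.tsv", sep="\t", index=False)
        summary["n_associated_genes"] = len({a.gene_id for a in assoc})
        summary["intron_preference"] = {k: (None if np.isnan(v) else round(float(v), 6))
                                        if not np.isinf(v) else "inf"
                                        for k, v in pref.items()}

    occurrences = rand_occ = None
    if last >= STAGES.index("motifs"):
        try:
            regions = [(p.chrom, p.start, p.end) for p in peaks]
            occurrences = scan_eboxes(genome, regions)
            occurrences = attach_peak_offsets(occurrences, peaks)
            counts, tallies = peak_ebox_counts(occurrences, peaks)
            cons = (io.read_conservation(config.conservation,
                                         {c: len(s) for c, s in genome.items()})
                    if config.conservation else None)
            rand_occ = sample_random_intronic_eboxes(
                genome, genes, config.site_core, n=config.n_random_intronic,
                seed=config.seed, exclude_peaks=peaks)
        except Exception as exc:  # noqa: BLE001
            _fail("motifs", exc)
        pd.DataFrame(
            [(o.chrom, o.position, o.core, o.core_class, o.prefix_base, o.peak_offset)
             for o in occurrences],
            columns=["chrom", "position", "core", "core_class", "prefix_base", "peak_offset"],
        ).to_csv(outdir / "ebox_occurrences.tsv", sep="\t", index=False)
        summary["ebox"] = {**tallies, "n_occurrences": len(occurrences)}
        if peaks:
            edges, density = positional_profile(occurrences, peaks)
            pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "density": density}
                         ).to_csv(outdir / "ebox_positional_profile.tsv", sep="\t", index=False)
            gedges, gc = gc_profile(genome, peaks)
            pd.DataFrame({"bin_start": gedges[:-1], "bin_end": gedges[1:], "gc_fraction": gc}
                         ).to_csv(outdir / "gc_profile.tsv", sep="\t", index=False)
        if cons is not None:
            bound_core = [o for o in occurrences if o.peak_offset is not None
                          and o.core == config.site_core.upper()]
            if bound_core and rand_occ:
                prof_b = conservation_profile(bound_core, cons, config.conservation_flank)
                prof_r = conservation_profile(rand_occ, cons, config.conservation_flank)
                pd.DataFrame({"offset": prof_b.offsets, "bound_mean": prof_b.mean_score,
                              "random_mean": prof_r.mean_score}
                             ).to_csv(outdir / "conservation_profile.tsv", sep="\t", index=False)
                summary["conservation"] = {
                    "bound_core_mean": round(float(np.nanmean(
                        prof_b.mean_score[config.conservation_flank:
                                          config.conservation_flank + 6])), 6),
                    "random_core_mean": round(float(np.nanmean(
                        prof_r.mean_score[config.conservation_flank:
                                          config.conservation_flank + 6])), 6),
                    "n_bound": prof_b.n_sites, "n_random": prof_r.n_sites,
                }

    if last >= STAGES.index("shape"):
        try:
            core = config.site_core.upper()
            bound_core = [o for o in occurrences if o.peak_offset is not None and o.core == core]
            table = (io.read_shape_table(config.shape_table) if config.shape_table
                     else synthetic_shape_table())
            seqs_b, lab_b = _extract_site_windows(genome, bound_core, config.site_window, core, 1)
            seqs_u, lab_u = _extract_site_windows(genome, rand_occ, config.site_window, core, 0)
            if min(len(seqs_b), len(seqs_u)) >= config.n_folds:
                sites = SiteSet(seqs_b + seqs_u, np.array(lab_b + lab_u),
                                config.site_window, core)
                results = compare_models(sites, table, config.ridge_lambda,
                                         seed=config.seed, n_folds=config.n_folds)
                summary["auc"] = {fs: round(results[fs].auc, 4) for fs in FEATURE_SETS}
                summary["n_sites"] = {"bound": len(seqs_b), "unbound": len(seqs_u)}
            else:
                summary["auc"] = None
                summary["n_sites"] = {"bound": len(seqs_b), "unbound": len(seqs_u)}
        except Exception as exc:  # noqa: BLE001
            _fail("shape", exc)

    if last >= STAGES.index("integrate"):
        if not config.expression:
            raise RuntimeError("pipeline stage 'integrate' requires an expression table")
        try:
            expr = io.read_expression(config.expression)
            records = io.expression_records(expr)
            passing = filter_expressed(records, config.integration)
            assoc = assign_peaks_to_genes(peaks, genes, config.integration.max_dist)
            chip = chip_transcript_set(assoc, genes)
            overlap, target_genes = intersect_and_collapse(passing, chip, records)
            hp = HypergeomParams(N=len(records), K=len(passing), n=len(chip),
                                 k=len(overlap))
            pval = hypergeom_tail(hp)
        except Exception as exc:  # noqa: BLE001
            _fail("integrate", exc)
        pd.DataFrame({"transcript_id": sorted(overlap)}).to_csv(
            outdir / "target_transcripts.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": target_genes}).to_csv(
            outdir / "target_genes.tsv", sep="\t", index=False)
        summary["integration"] = {
            "N_transcripts": hp.N, "K_expressed_enriched": hp.K,
            "n_chip_transcripts": hp.n, "k_overlap": hp.k,
            "n_target_genes": len(target_genes),
            "p_value": pval,
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
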