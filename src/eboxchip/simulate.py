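"""Synthetic data with the statistical structure the analysis assumes.

One configuration object drives coherent generation of: a random genome
with E-box cores planted inside future peak intervals (bound) and inside
introns (unbound); multi-exon gene models; four tiling-array probe
tracks in which only the experimental ChIP sample carries log2 enrichment
over the planted peaks; a per-base conservation track elevated around
bound sites; a transcript FPKM table with planted enriched isoforms and a
reference transcript pinned exactly at the expression cutoff; and aligned
bound/unbound site windows whose flank composition shifts the mean minor
groove width of bound sites by a configurable amount.

Every generator is a pure function of (config.seed, arguments); each uses
its own seeded stream, so generators may be called in any order.  Every
planted feature is registered in :class:`PlantedTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .classify import PAD, SiteSet
from .genes import GeneModel, Transcript
from .shape import ShapeTable
from .signal import ProbeTrack

__all__ = ["SyntheticConfig", "PlantedTruth", "gen_genome", "gen_annotation",
           "gen_probe_tracks", "gen_expression", "gen_conservation", "gen_site_sets"]

_BASES = np.array(list("ACGT"))
TA_CORE, GC_CORE = "CATATG", "CAGCTG"
REFERENCE_FPKM_PLUS = 0.983129  # expression cutoff calibrator
REFERENCE_FPKM_MINUS = 0.26


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr2L": 350_000, "chr2R": 250_000}
    )
    gc_fraction: float = 0.45
    n_genes: int = 50
    n_planted_peaks: int = 10
    intergenic_gap: tuple[int, int] = (3500, 6500)
    peak_width: int = 600
    enrichment_fold: float = 4.0
    probe_spacing: int = 35
    probe_length: int = 25
    baseline_log2: float = 8.0
    noise_sd: float = 0.25
    n_bound_sites: int = 60
    n_unbound_sites: int = 200
    site_window: int = 26
    site_core: str = TA_CORE
    shape_effect_delta: float = 0.2
    bound_prefix_c_prob: float = 0.6
    frac_enriched_transcripts: float = 0.15
    expr_enrichment_fold: float = 4.0
    conservation_elevation: float = 0.6
    conservation_flank: int = 20
    conservation_bg_a: float = 1.0
    conservation_bg_b: float = 9.0
    conservation_bg_scale: float = 1.0

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_planted_peaks, self.n_bound_sites,
                  self.n_unbound_sites)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if not 0.0 <= self.frac_enriched_transcripts <= 1.0:
            raise ValueError("frac_enriched_transcripts must lie in [0, 1]")
        if self.enrichment_fold < 1 or self.expr_enrichment_fold < 1:
            raise ValueError("enrichment folds must be >= 1")
        if self.site_window < 16 or (self.site_window - len(self.site_core)) % 2:
            raise ValueError("site_window must be >= 16 and leave equal flanks around the core")
        if self.n_planted_peaks > self.n_genes:
            raise ValueError("cannot plant more peaks than genes (peaks live in first introns)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedTruth:
    """Registry of every planted feature; inputs to recovery checks."""

    peak_intervals: list[tuple[str, int, int]]
    bound_sites: list[tuple[str, int, str]]    # (chrom, core start, core)
    unbound_sites: list[tuple[str, int, str]]
    enriched_transcript_ids: set[str]
    reference_transcript_id: str

    @property
    def bound_site_positions(self) -> list[tuple[str, int]]:
        return [(c, p) for c, p, _ in self.bound_sites]


@dataclass
class _Layout:
    genes: list[GeneModel]
    truth: PlantedTruth


def _plan_gene(rng: np.random.Generator, cursor: int, peak_width: int,
               gene_id: str, chrom: str) -> GeneModel:
    """One non-overlapping multi-exon gene starting at/after ``cursor``."""
    n_exons = int(rng.integers(2, 6))
    exon_lens = rng.integers(150, 500, size=n_exons)
    # transcription-order intron lengths; the first is wide enough for a peak
    intron_lens = [peak_width + int(rng.integers(300, 800))]
    intron_lens += [int(rng.integers(300, 1200)) for _ in range(n_exons - 2)]
    strand = "+" if rng.random() < 0.5 else "-"
    lens = []
    for i, el in enumerate(exon_lens):
        lens.append(int(el))
        if i < n_exons - 1:
            lens.append(intron_lens[i])
    if strand == "-":
        lens = lens[::-1]
    pieces, at = [], cursor
    for L in lens:
        pieces.append((at, at + L))
        at += L
    exons = pieces[0::2]
    gene = GeneModel(gene_id, chrom, strand)
    gene.add(Transcript(f"{gene_id}.t1", exons, strand))
    if n_exons >= 3 and rng.random() < 0.3:
        skip = int(rng.integers(1, n_exons - 1))  # internal exon, genomic index
        iso = [e for i, e in enumerate(exons) if i != skip]
        gene.add(Transcript(f"{gene_id}.t2", iso, strand))
    return gene


def _layout(cfg: SyntheticConfig) -> _Layout:
    rng = cfg.rng(0)
    chroms = list(cfg.chrom_lengths)
    total_len = sum(cfg.chrom_lengths.values())
    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        quota = round(cfg.n_genes * cfg.chrom_lengths[chrom] / total_len)
        if ci == len(chroms) - 1:
            quota = cfg.n_genes - gi
        cursor = 500
        for _ in range(quota):
            cursor += int(rng.integers(*cfg.intergenic_gap))
            gene = _plan_gene(rng, cursor, cfg.peak_width, f"g{gi:04d}", chrom)
            span = gene.span
            if span[1] > cfg.chrom_lengths[chrom] - 500:
                raise ValueError(
                    f"cannot place {cfg.n_genes} genes: {chrom} "
                    f"(length {cfg.chrom_lengths[chrom]}) is too short"
                )
            genes.append(gene)
            cursor = span[1]
            gi += 1

    # peaks centered in first introns of randomly chosen target genes
    order = rng.permutation(len(genes))
    target_idx = sorted(order[: cfg.n_planted_peaks].tolist())
    peak_intervals: list[tuple[str, int, int]] = []
    for i in target_idx:
        g = genes[i]
        fi = g.transcripts[f"{g.gene_id}.t1"].first_intron
        a, b = fi
        mid = (a + b) // 2
        start = max(a, mid - cfg.peak_width // 2)
        end = min(b, start + cfg.peak_width)
        peak_intervals.append((g.chrom, start, end))

    # bound E-box cores inside peak intervals, spaced apart
    bound: list[tuple[str, int, str]] = []
    margin, min_space = 30, 14
    slots = []
    for chrom, a, b in peak_intervals:
        pos = a + margin
        while pos + 6 + margin <= b:
            slots.append((chrom, pos))
            pos += min_space + int(rng.integers(0, 20))
    if len(slots) < cfg.n_bound_sites:
        raise ValueError(
            f"planted peaks can host at most {len(slots)} bound sites "
            f"(requested {cfg.n_bound_sites}); widen peaks or add peaks"
        )
    pick = sorted(rng.choice(len(slots), size=cfg.n_bound_sites, replace=False).tolist())
    for j in pick:
        chrom, pos = slots[j]
        core = TA_CORE if rng.random() < 2 / 3 else GC_CORE
        bound.append((chrom, pos, core))

    # unbound cores inside introns, away from peaks
    peak_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, a, b in peak_intervals:
        peak_by_chrom.setdefault(chrom, []).append((a, b))
    unbound: list[tuple[str, int, str]] = []
    islots = []
    for g in genes:
        for t in g.transcripts.values():
            for (a, b) in t.introns:
                pos = a + margin
                while pos + 6 + margin <= b:
                    in_peak = any(pa - 8 < pos < pb + 8 for pa, pb in peak_by_chrom.get(g.chrom, []))
                    if not in_peak:
                        islots.append((g.chrom, pos))
                    pos += min_space + int(rng.integers(0, 30))
    # dedupe shared introns across isoforms
    islots = sorted(set(islots))
    if len(islots) < cfg.n_unbound_sites:
        raise ValueError(
            f"introns can host at most {len(islots)} unbound sites "
            f"(requested {cfg.n_unbound_sites})"
        )
    pick = sorted(rng.choice(len(islots), size=cfg.n_unbound_sites, replace=False).tolist())
    for j in pick:
        chrom, pos = islots[j]
        core = TA_CORE if rng.random() < 2 / 3 else GC_CORE
        unbound.append((chrom, pos, core))

    all_tids = [tid for g in genes for tid in g.transcript_ids]
    enriched = {tid for i in target_idx for tid in genes[i].transcript_ids}
    want = math.ceil(cfg.frac_enriched_transcripts * len(all_tids))
    extra_pool = [t for t in all_tids if t not in enriched]
    if want > len(enriched) and extra_pool:
        k = min(want - len(enriched), len(extra_pool))
        enriched.update(rng.choice(extra_pool, size=k, replace=False).tolist())
    ref_pool = sorted(set(all_tids) - enriched) or all_tids
    reference = str(ref_pool[int(rng.integers(0, len(ref_pool)))])

    truth = PlantedTruth(peak_intervals, bound, unbound, enriched, reference)
    return _Layout(genes, truth)


def gen_genome(cfg: SyntheticConfig) -> tuple[dict[str, str], PlantedTruth]:
    """Random genome with registered bound/unbound E-box cores planted.

    Bases are i.i.d. at ``cfg.gc_fraction``; bound cores sit inside the
    future peak intervals (with a 5' C planted at ``bound_prefix_c_prob``),
    unbound cores inside introns.  Deterministic given the seed.
    """
    layout = _layout(cfg)
    rng = cfg.rng(1)
    gc = cfg.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chrom_lengths.items():
        genome[chrom] = _BASES[rng.choice(4, size=length, p=p)]
    for chrom, pos, core in layout.truth.unbound_sites:
        genome[chrom][pos: pos + 6] = list(core)
    for chrom, pos, core in layout.truth.bound_sites:
        genome[chrom][pos: pos + 6] = list(core)
        if pos > 0 and rng.random() < cfg.bound_prefix_c_prob:
            genome[chrom][pos - 1] = "C"
    return {c: "".join(a) for c, a in genome.items()}, layout.truth


def gen_annotation(cfg: SyntheticConfig, genome: dict[str, str]) -> list[GeneModel]:
    """Non-overlapping multi-exon gene models matching the planted layout."""
    layout = _layout(cfg)
    for g in layout.genes:
        if g.span[1] > len(genome[g.chrom]):
            raise ValueError(f"gene {g.gene_id} extends beyond {g.chrom}")
    return layout.genes


def gen_probe_tracks(
    cfg: SyntheticConfig, genome: dict[str, str], truth: PlantedTruth
) -> tuple[dict[str, ProbeTrack], ...]:
    """Four probe samples on a shared grid: exp ChIP, exp input, ctl ChIP, ctl input.

    log2 intensity = baseline + N(0, noise_sd); the experimental ChIP sample
    additionally gains log2(enrichment_fold) over planted peak intervals.
    Values are quantized to 6 decimals so emitted bedGraph round-trips exactly.
    """
    peak_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, a, b in truth.peak_intervals:
        peak_by_chrom.setdefault(chrom, []).append((a, b))
    samples = []
    for s in range(4):
        rng = cfg.rng(2 + s)
        sample: dict[str, ProbeTrack] = {}
        for chrom, seq in genome.items():
            positions = np.arange(0, len(seq) - cfg.probe_length + 1, cfg.probe_spacing)
            values = cfg.baseline_log2 + rng.normal(0.0, cfg.noise_sd, size=positions.size)
            if s == 0:
                boost = math.log2(cfg.enrichment_fold)
                for a, b in peak_by_chrom.get(chrom, []):
                    values[(positions >= a) & (positions < b)] += boost
            sample[chrom] = ProbeTrack(chrom, positions, np.round(values, 6))
        samples.append(sample)
    return tuple(samples)


def gen_expression(
    cfg: SyntheticConfig,
    annotation: list[GeneModel],
    truth: PlantedTruth,
    enrichment_fold: float | None = None,
    shared_noise: bool = False,
) -> pd.DataFrame:
    """Per-transcript FPKM table (columns transcript_id, gene_id, fpkm_plus, fpkm_minus).

    FPKMs are log-normal; planted enriched transcripts have fpkm_plus
    multiplied by ``enrichment_fold`` (default from config, >= 1.5 expected);
    the registered reference transcript is pinned at exactly
    fpkm_plus = 0.983129 / fpkm_minus = 0.26 to exercise the cutoff.
    ``shared_noise`` reuses one noise draw for both samples (diagnostics).
    """
    if not annotation:
        raise ValueError("annotation is empty")
    fold = cfg.expr_enrichment_fold if enrichment_fold is None else enrichment_fold
    rng = cfg.rng(6)
    rows = []
    for g in annotation:
        for tid in g.transcript_ids:
            base = float(rng.lognormal(math.log(8.0), 1.2))
            eps_p = float(rng.lognormal(0.0, 0.3))
            eps_m = eps_p if shared_noise else float(rng.lognormal(0.0, 0.3))
            plus, minus = base * eps_p, base * eps_m
            if tid in truth.enriched_transcript_ids:
                plus *= fold
            if tid == truth.reference_transcript_id:
                plus, minus = REFERENCE_FPKM_PLUS, REFERENCE_FPKM_MINUS
            rows.append((tid, g.gene_id, round(plus, 6), round(minus, 6)))
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "fpkm_plus", "fpkm_minus"])


def gen_conservation(
    cfg: SyntheticConfig, genome: dict[str, str], truth: PlantedTruth
) -> dict[str, np.ndarray]:
    """Per-base scores in [0, 1]: Beta background, elevated around bound sites.

    Positions within +-conservation_flank of each bound core move toward 1
    by the configured elevation: s -> s + elevation * (1 - s).  Scores are
    quantized to 4 decimals for exact bedGraph round-trips.
    """
    rng = cfg.rng(7)
    cons: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        bg = rng.beta(cfg.conservation_bg_a, cfg.conservation_bg_b, size=len(seq))
        cons[chrom] = np.clip(bg * cfg.conservation_bg_scale, 0.0, 1.0)
    e = cfg.conservation_elevation
    for chrom, pos, core in truth.bound_sites:
        a = max(0, pos - cfg.conservation_flank)
        b = min(len(cons[chrom]), pos + len(core) + cfg.conservation_flank)
        cons[chrom][a:b] += e * (1.0 - cons[chrom][a:b])
    return {c: np.round(np.clip(v, 0.0, 1.0), 4) for c, v in cons.items()}


def _window_mean_mgw(seq_codes: np.ndarray, table: ShapeTable, width: int) -> np.ndarray:
    """Mean MGW over the window positions of padded site sequences (rows)."""
    kernel = np.array([256, 64, 16, 4, 1])
    mgw = table.as_array()[:, 0]
    wins = np.lib.stride_tricks.sliding_window_view(seq_codes, 5, axis=1)
    idx = wins @ kernel  # (n, width) pentamer indices for the window positions
    return mgw[idx].mean(axis=1)


def gen_site_sets(cfg: SyntheticConfig, table: ShapeTable) -> SiteSet:
    """Aligned bound/unbound site windows with a planted shape effect.

    All windows share the identical central core; flanks are i.i.d. at
    ``gc_fraction``.  For bound sites and shape_effect_delta > 0, each flank
    pair is chosen from 50 candidate draws as the one whose window-mean
    minor groove width is closest to (background mean + delta) -- a
    rejection-style bias of flank composition, leaving the core untouched.
    delta = 0 draws flanks exactly from the background.  Labels: bound = 1
    first, then unbound = 0.
    """
    w, core = cfg.site_window, cfg.site_core.upper()
    total = w + 2 * PAD
    core_at = PAD + (w - len(core)) // 2
    rng = cfg.rng(8)
    gc = cfg.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    core_codes = np.array(["ACGT".index(b) for b in core])

    def draw(n: int) -> np.ndarray:
        codes = rng.choice(4, size=(n, total), p=p)
        codes[:, core_at: core_at + len(core)] = core_codes
        return codes

    n_cand = 50
    bg_mean = float(_window_mean_mgw(draw(512), table, w).mean())
    target = bg_mean + cfg.shape_effect_delta
    if cfg.shape_effect_delta == 0:
        bound_codes = draw(cfg.n_bound_sites)
    else:
        chosen = []
        for _ in range(cfg.n_bound_sites):
            cands = draw(n_cand)
            means = _window_mean_mgw(cands, table, w)
            chosen.append(cands[int(np.argmin(np.abs(means - target)))])
        bound_codes = np.array(chosen)
    unbound_codes = draw(cfg.n_unbound_sites)
    all_codes = np.vstack([bound_codes, unbound_codes]) if cfg.n_bound_sites else unbound_codes
    seqs = ["".join(_BASES[row]) for row in all_codes]
    labels = np.r_[np.ones(cfg.n_bound_sites, int), np.zeros(cfg.n_unbound_sites, int)]
    return SiteSet(seqs, labels, window_width=w, core=core)
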