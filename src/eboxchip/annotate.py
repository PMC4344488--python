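"""Relating peaks and combined signal to gene models.

Peak-to-gene assignment uses the gap between the peak interval and the
gene span (overlap counts as distance 0); TSS/TTS-anchored and metagene
profiles are strand-oriented so that "downstream" always means
transcription-downstream; the intron-preference summary contrasts mean
signal over TSS regions, first introns and remaining introns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genes import GeneModel
from .signal import Peak, ProbeTrack

__all__ = [
    "Association",
    "AnchoredProfile",
    "assign_peaks_to_genes",
    "anchored_profile",
    "metagene_profile",
    "intron_preference",
    "peak_set_overlap",
]


@dataclass
class Association:
    peak_index: int
    gene_id: str
    distance: int  # bp gap between peak interval and gene span; 0 on overlap


@dataclass
class AnchoredProfile:
    bin_edges: np.ndarray   # bp offsets (or metagene bin index edges)
    mean_signal: np.ndarray  # per bin; NaN where no probe contributed
    n_anchors: int


def _interval_gap(a0: int, a1: int, b0: int, b1: int) -> int:
    """Gap in bp between half-open intervals; 0 if they overlap or touch."""
    return max(b0 - a1, a0 - b1, 0)


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Iterable[GeneModel],
    max_dist: int = 3000,
) -> list[Association]:
    """Associate each peak with every gene whose span lies within max_dist.

    A gene is associated when the gap between the peak interval and the gene
    span is strictly less than ``max_dist`` (an overlapping peak has distance
    0).  One peak may map to several genes and vice versa.  Peaks on
    chromosomes absent from the annotation are skipped with a warning.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[Association] = []
    for i, pk in enumerate(peaks):
        if pk.chrom not in by_chrom:
            warnings.warn(f"peak {i} on unannotated chromosome {pk.chrom}; skipped")
            continue
        for g in by_chrom[pk.chrom]:
            g0, g1 = g.span
            gap = _interval_gap(pk.start, pk.end, g0, g1)
            if gap < max_dist:
                out.append(Association(i, g.gene_id, gap))
    return out


def anchored_profile(
    track: Mapping[str, ProbeTrack],
    anchors: Sequence[tuple[str, int, str]],
    window: int = 3000,
    bins: int = 120,
) -> AnchoredProfile:
    """Mean signal in strand-oriented bins of +-window around each anchor.

    ``anchors`` are (chromosome, position, strand) triples; minus-strand
    anchors are mirrored so positive offsets are transcription-downstream.
    Bin means pool all probes from all anchors; empty bins are NaN.
    """
    if window <= 0 or bins < 1:
        raise ValueError("window must be positive and bins >= 1")
    edges = np.linspace(-window, window, bins + 1)
    sums = np.zeros(bins)
    counts = np.zeros(bins)
    n_used = 0
    for chrom, pos, strand in anchors:
        if chrom not in track:
            continue
        t = track[chrom]
        lo = np.searchsorted(t.positions, pos - window, side="left")
        hi = np.searchsorted(t.positions, pos + window, side="right")
        if hi <= lo:
            continue
        rel = t.positions[lo:hi] - pos
        if strand == "-":
            rel = -rel
        idx = np.clip(np.digitize(rel, edges) - 1, 0, bins - 1)
        np.add.at(sums, idx, t.values[lo:hi])
        np.add.at(counts, idx, 1)
        n_used += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    return AnchoredProfile(edges, mean, n_used)


def metagene_profile(
    track: Mapping[str, ProbeTrack],
    genes: Iterable[GeneModel],
    body_bins: int = 100,
    flank_bp: int = 1000,
    flank_bins: int = 20,
) -> AnchoredProfile:
    """Average signal over gene bodies rescaled to a common length.

    Each gene span is divided into ``body_bins`` equal-fraction bins
    (transcription-oriented); fixed-width flanks are prepended/appended.
    Returns bin index edges 0..total_bins with the upstream flank first.
    """
    total = body_bins + 2 * flank_bins
    sums = np.zeros(total)
    counts = np.zeros(total)
    n_used = 0
    for g in genes:
        if g.chrom not in track:
            continue
        t = track[g.chrom]
        g0, g1 = g.span
        lo = np.searchsorted(t.positions, g0 - flank_bp, side="left")
        hi = np.searchsorted(t.positions, g1 + flank_bp, side="right")
        if hi <= lo:
            continue
        pos = t.positions[lo:hi].astype(float)
        # transcription-oriented coordinate over the whole window
        u = pos - (g0 - flank_bp) if g.strand == "+" else (g1 + flank_bp - 1) - pos
        body_len = float(g1 - g0)
        idx = np.empty(pos.size, dtype=int)
        up = u < flank_bp
        body = (u >= flank_bp) & (u < flank_bp + body_len)
        dn = u >= flank_bp + body_len
        idx[up] = np.clip((u[up] / flank_bp * flank_bins).astype(int), 0, flank_bins - 1)
        frac = (u[body] - flank_bp) / body_len
        idx[body] = flank_bins + np.clip((frac * body_bins).astype(int), 0, body_bins - 1)
        idx[dn] = flank_bins + body_bins + np.clip(
            ((u[dn] - flank_bp - body_len) / flank_bp * flank_bins).astype(int),
            0, flank_bins - 1,
        )
        np.add.at(sums, idx, t.values[lo:hi])
        np.add.at(counts, idx, 1)
        n_used += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    return AnchoredProfile(np.arange(total + 1, dtype=float), mean, n_used)


def _category_intervals(
    genes: Iterable[GeneModel], tss_halfwidth: int
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Per-chromosome interval lists for TSS regions, first and other introns."""
    cats: dict[str, dict[str, list[tuple[int, int]]]] = {
        "tss": {}, "first_intron": {}, "other_intron": {}
    }
    for g in genes:
        for t in g.transcripts.values():
            cats["tss"].setdefault(g.chrom, []).append(
                (max(0, t.tss - tss_halfwidth), t.tss + tss_halfwidth + 1)
            )
            fi = t.first_intron
            if fi is not None:
                cats["first_intron"].setdefault(g.chrom, []).append(fi)
            for iv in t.other_introns:
                cats["other_intron"].setdefault(g.chrom, []).append(iv)
    return cats


def _in_any(positions: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(positions.size, dtype=bool)
    for a, b in intervals:
        mask |= (positions >= a) & (positions < b)
    return mask


def intron_preference(
    genes: Iterable[GeneModel],
    track: Mapping[str, ProbeTrack] | None = None,
    peaks: Sequence[Peak] | None = None,
    tss_halfwidth: int = 500,
) -> dict[str, float]:
    """Mean signal (or peak coverage) for TSS vs first-intron vs other-intron.

    Categories are defined per isoform; a probe falling in more than one
    category is counted once with priority TSS > first_intron > other_intron.
    Returns per-category means plus ``ratio_first_other`` (inf when the
    other-intron mean is zero and the first-intron mean is not).
    """
    if (track is None) == (peaks is None):
        raise ValueError("provide exactly one of track or peaks")
    genes = list(genes)
    cats = _category_intervals(genes, tss_halfwidth)
    sums = {c: 0.0 for c in cats}
    counts = {c: 0 for c in cats}
    if track is not None:
        for chrom, t in track.items():
            masks = {c: _in_any(t.positions, cats[c].get(chrom, [])) for c in cats}
            masks["first_intron"] &= ~masks["tss"]
            masks["other_intron"] &= ~masks["tss"] & ~masks["first_intron"]
            for c in cats:
                sums[c] += float(t.values[masks[c]].sum())
                counts[c] += int(masks[c].sum())
    else:
        # peak mode: fraction of category base pairs covered by any peak
        peak_ivs: dict[str, list[tuple[int, int]]] = {}
        for pk in peaks:  # type: ignore[union-attr]
            peak_ivs.setdefault(pk.chrom, []).append((pk.start, pk.end))
        for c in cats:
            for chrom, ivs in cats[c].items():
                for a, b in ivs:
                    grid = np.arange(a, b)
                    covered = _in_any(grid, peak_ivs.get(chrom, []))
                    sums[c] += float(covered.sum())
                    counts[c] += grid.size
    out = {c: (sums[c] / counts[c] if counts[c] else float("nan")) for c in cats}
    first, other = out["first_intron"], out["other_intron"]
    if other != 0:
        out["ratio_first_other"] = first / other
    else:
        out["ratio_first_other"] = float("inf") if first != 0 else float("nan")
    return out


def peak_set_overlap(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> float:
    """Fraction of peaks_a sharing >= 1 bp with any peak in peaks_b."""
    if not peaks_a:
        return 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for pk in peaks_b:
        by_chrom.setdefault(pk.chrom, []).append((pk.start, pk.end))
    hits = 0
    for pk in peaks_a:
        for a, b in by_chrom.get(pk.chrom, []):
            if pk.start < b and a < pk.end:
                hits += 1
                break
    return hits / len(peaks_a)
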