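"""E-box scanning and characterization within peaks.

The canonical E-box is CANNTG; the "TA" and "GC" classes name the two
central bases (CATATG / CAGCTG).  Both of those hexamers are their own
reverse complements, so an exhaustive plus-strand scan finds every
genomic occurrence; occurrences are therefore recorded in plus-strand
orientation throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genes import GeneModel
from .signal import Peak

__all__ = [
    "EboxOccurrence",
    "ConservationProfile",
    "TA_CORE",
    "GC_CORE",
    "expand_core",
    "scan_eboxes",
    "peak_ebox_counts",
    "positional_profile",
    "prefix_variant_profile",
    "gc_profile",
    "sample_random_intronic_eboxes",
    "conservation_profile",
]

TA_CORE = "CATATG"
GC_CORE = "CAGCTG"
_BASES = "ACGT"


def core_class(core: str) -> str:
    mid = core[2:4]
    return {"TA": "TA", "GC": "GC"}.get(mid, "other")


@dataclass
class EboxOccurrence:
    chrom: str
    position: int          # 0-based coordinate of the first core base
    core: str
    core_class: str
    prefix_base: str       # base immediately 5' of the core on the plus strand
    peak_offset: int | None = None  # bp from peak center, if inside a peak


@dataclass
class ConservationProfile:
    offsets: np.ndarray     # bp relative to core start (negative = 5' flank)
    mean_score: np.ndarray
    n_sites: int


def expand_core(pattern: str) -> list[str]:
    """Expand an IUPAC-N pattern like CANNTG into concrete 6-mers."""
    seqs = [""]
    for ch in pattern.upper():
        choices = _BASES if ch == "N" else ch
        seqs = [s + c for s in seqs for c in choices]
    return seqs


def scan_eboxes(
    genome: Mapping[str, str],
    regions: Sequence[tuple[str, int, int]] | None,
    cores: Iterable[str] = (TA_CORE, GC_CORE),
) -> list[EboxOccurrence]:
    """Report every plus-strand occurrence of the given 6-mer cores.

    ``regions`` restricts the scan to (chrom, start, end) intervals; None
    scans whole chromosomes.  Overlapping matches are all reported, sorted
    by (chromosome, position).
    """
    concrete: set[str] = set()
    for c in cores:
        c = c.upper()
        if len(c) != 6 or any(ch not in _BASES + "N" for ch in c):
            raise ValueError(f"invalid core {c!r}: must be a 6-mer over ACGTN")
        concrete.update(expand_core(c))
    if regions is None:
        regions = [(chrom, 0, len(seq)) for chrom, seq in genome.items()]
    out: list[EboxOccurrence] = []
    for chrom, start, end in regions:
        seq = genome[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(f"region {chrom}:{start}-{end} beyond chromosome end ({len(seq)})")
        sub = seq[start:end].upper()
        for i in range(len(sub) - 5):
            hexamer = sub[i: i + 6]
            if hexamer in concrete:
                pos = start + i
                prefix = seq[pos - 1].upper() if pos > 0 else "N"
                out.append(EboxOccurrence(chrom, pos, hexamer, core_class(hexamer), prefix))
    out.sort(key=lambda o: (o.chrom, o.position))
    return out


def attach_peak_offsets(
    occurrences: Sequence[EboxOccurrence], peaks: Sequence[Peak], use_summit: bool = False
) -> list[EboxOccurrence]:
    """Annotate occurrences inside peaks with their offset from the peak center.

    Center = interval midpoint by default; ``use_summit`` switches to the
    score summit.  Occurrences outside all peaks keep peak_offset None.
    """
    out = []
    for occ in occurrences:
        offset = None
        for pk in peaks:
            if pk.chrom == occ.chrom and pk.start <= occ.position < pk.end:
                center = pk.summit if use_summit else pk.center
                offset = occ.position - center
                break
        out.append(EboxOccurrence(occ.chrom, occ.position, occ.core, occ.core_class,
                                  occ.prefix_base, offset))
    return out


def peak_ebox_counts(
    occurrences: Sequence[EboxOccurrence], peaks: Sequence[Peak]
) -> tuple[list[int], dict[str, int]]:
    """Per-peak counts of TA/GC-class occurrences and the >=1 / >1 tallies."""
    counts = []
    for pk in peaks:
        n = sum(
            1
            for o in occurrences
            if o.chrom == pk.chrom and pk.start <= o.position < pk.end
            and o.core_class in ("TA", "GC")
        )
        counts.append(n)
    summary = {
        "n_peaks_with_ebox": sum(1 for n in counts if n >= 1),
        "n_peaks_with_multiple": sum(1 for n in counts if n > 1),
    }
    return counts, summary


def _center_bins(peaks: Sequence[Peak], bin_width: int) -> np.ndarray:
    half = max((pk.width + 1) // 2 for pk in peaks)
    nbins = int(np.ceil(half / bin_width))
    return np.arange(-nbins, nbins + 1) * bin_width  # bin edges


def positional_profile(
    occurrences: Sequence[EboxOccurrence],
    peaks: Sequence[Peak],
    bin_width: int = 50,
    use_summit: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence density versus distance from peak center.

    Counts per bin are normalised by the number of peaks wide enough to
    contribute that bin (peaks have unequal widths).  Returns (bin_edges,
    density); all-zero density when no occurrences are given.
    """
    if not peaks:
        raise ValueError("positional_profile requires at least one peak")
    occurrences = attach_peak_offsets(occurrences, peaks, use_summit)
    edges = _center_bins(peaks, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    contributing = np.array(
        [sum(1 for pk in peaks if abs(c) <= pk.width / 2) for c in centers], dtype=float
    )
    counts = np.zeros(centers.size)
    offs = [o.peak_offset for o in occurrences if o.peak_offset is not None]
    if offs:
        idx = np.clip(np.digitize(offs, edges) - 1, 0, centers.size - 1)
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(contributing > 0, counts / contributing, 0.0)
    return edges, density


def prefix_variant_profile(
    occurrences: Sequence[EboxOccurrence], bin_width: int = 100
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Frequency of each 5'-prefix base by distance-from-center bin.

    Uses occurrences that carry a peak_offset.  Per-bin frequencies sum to 1
    where data exist; empty bins are NaN (missing, not zero).
    """
    offs = np.array([o.peak_offset for o in occurrences if o.peak_offset is not None])
    if offs.size == 0:
        raise ValueError("no occurrences carry peak offsets")
    half = int(np.ceil(max(abs(offs.min()), abs(offs.max())) / bin_width)) or 1
    edges = np.arange(-half, half + 1) * bin_width
    nb = edges.size - 1
    tallies = {b: np.zeros(nb) for b in _BASES}
    for o in occurrences:
        if o.peak_offset is None or o.prefix_base not in _BASES:
            continue
        i = int(np.clip(np.digitize(o.peak_offset, edges) - 1, 0, nb - 1))
        tallies[o.prefix_base][i] += 1
    totals = sum(tallies.values())
    freqs = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in _BASES:
            freqs[b] = np.where(totals > 0, tallies[b] / totals, np.nan)
    return edges, freqs


def gc_profile(
    genome: Mapping[str, str], peaks: Sequence[Peak], bin_width: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Mean GC fraction versus distance from peak center, averaged over peaks."""
    if not peaks:
        raise ValueError("gc_profile requires at least one peak")
    edges = _center_bins(peaks, bin_width)
    nb = edges.size - 1
    gc_sum = np.zeros(nb)
    n_seen = np.zeros(nb)
    for pk in peaks:
        seq = genome[pk.chrom].upper()
        for i in range(nb):
            a = max(pk.start, pk.center + int(edges[i]))
            b = min(pk.end, pk.center + int(edges[i + 1]))
            if b <= a:
                continue
            window = seq[a:b]
            gc_sum[i] += (window.count("G") + window.count("C")) / len(window)
            n_seen[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return edges, np.where(n_seen > 0, gc_sum / n_seen, np.nan)


def sample_random_intronic_eboxes(
    genome: Mapping[str, str],
    genes: Iterable[GeneModel],
    core: str = TA_CORE,
    n: int = 800,
    seed: int = 0,
    exclude_peaks: Sequence[Peak] = (),
    first_intron_only: bool = True,
) -> list[EboxOccurrence]:
    """Uniform sample (without replacement) of intronic occurrences of a core.

    Occurrences overlapping any supplied peak are excluded so the sample
    represents genuinely unbound sites.  If fewer than ``n`` occurrences
    exist, all are returned with a warning.
    """
    regions: list[tuple[str, int, int]] = []
    for g in genes:
        for t in g.transcripts.values():
            ivs = [t.first_intron] if first_intron_only and t.first_intron else (
                [] if first_intron_only else t.introns)
            for iv in ivs:
                if iv is not None:
                    regions.append((g.chrom, iv[0], iv[1]))
    occs = scan_eboxes(genome, regions, cores=[core])
    # dedupe (isoforms share introns) and drop peak overlaps
    seen: set[tuple[str, int]] = set()
    pool: list[EboxOccurrence] = []
    for o in occs:
        key = (o.chrom, o.position)
        if key in seen:
            continue
        seen.add(key)
        in_peak = any(
            pk.chrom == o.chrom and pk.start < o.position + 6 and o.position < pk.end
            for pk in exclude_peaks
        )
        if not in_peak:
            pool.append(o)
    if len(pool) <= n:
        if len(pool) < n:
            warnings.warn(f"only {len(pool)} intronic {core} occurrences available (< {n})")
        return pool
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def conservation_profile(
    occurrences: Sequence[EboxOccurrence],
    conservation: Mapping[str, np.ndarray],
    flank: int = 20,
) -> ConservationProfile:
    """Mean per-base conservation over core +- flank, aligned on core start.

    Sites are stacked in plus-strand orientation; offsets run from -flank to
    5 + flank.  A site missing scores at an offset (chromosome edge or NaN)
    is dropped from that offset's mean.
    """
    offsets = np.arange(-flank, 6 + flank)
    rows = []
    for o in occurrences:
        scores = conservation.get(o.chrom)
        if scores is None:
            continue
        row = np.full(offsets.size, np.nan)
        lo, hi = o.position - flank, o.position + 6 + flank
        a, b = max(lo, 0), min(hi, len(scores))
        row[a - lo: b - lo] = np.asarray(scores[a:b], dtype=float)
        rows.append(row)
    if not rows:
        raise ValueError("no occurrences with conservation data")
    mat = np.vstack(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(mat, axis=0)
    return ConservationProfile(offsets, mean, len(rows))
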