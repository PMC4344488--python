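"""Readers and writers for the standard formats the pipeline touches.

Conventions: internal coordinates are 0-based half-open; emitted GTF is
1-based inclusive; BED/bedGraph are 0-based half-open.  Tabular outputs
carry '#' provenance header lines (tool version, seed, config hash),
which every reader here skips.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyfaidx
import pyranges

from . import __version__
from .genes import GeneModel, Transcript
from .integrate import ExpressionRecord
from .shape import SHAPE_FEATURES, ShapeTable
from .signal import Peak, ProbeTrack
from .simulate import PlantedTruth

__all__ = [
    "provenance_lines", "config_hash",
    "write_fasta", "read_fasta",
    "write_gtf", "read_annotation",
    "write_bedgraph", "read_track", "read_tracks",
    "write_conservation", "read_conservation",
    "write_peaks_bed", "read_peaks_bed",
    "write_expression", "read_expression", "expression_records",
    "write_shape_table", "read_shape_table",
    "write_truth", "read_truth",
]


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: int | None = None, cfg_hash: str | None = None) -> list[str]:
    lines = [f"# eboxchip v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if cfg_hash is not None:
        lines.append(f"# config={cfg_hash}")
    return lines


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ------------------------------------------------------------------ GTF

def write_gtf(genes: Iterable[GeneModel], path: str | Path,
              header: Sequence[str] = (), source: str = "eboxchip") -> None:
    """Exon-level GTF, 1-based inclusive coordinates."""
    rows = []
    for g in genes:
        for tid in g.transcript_ids:
            t = g.transcripts[tid]
            for a, b in t.exons:
                rows.append((g.chrom, a, f"{g.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t"
                             f"{g.strand}\t.\tgene_id \"{g.gene_id}\"; transcript_id \"{tid}\";"))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        for _, _, line in rows:
            fh.write(line + "\n")


def read_annotation(path: str | Path) -> list[GeneModel]:
    """GTF -> gene models (internal 0-based half-open), exon features only."""
    df = pyranges.read_gtf(str(path)).df
    df = df[df.Feature == "exon"]
    genes: dict[str, GeneModel] = {}
    for (gid, tid), sub in df.groupby(["gene_id", "transcript_id"], sort=True):
        chrom = str(sub.Chromosome.iloc[0])
        strand = str(sub.Strand.iloc[0])
        exons = list(zip(sub.Start.astype(int), sub.End.astype(int)))
        if gid not in genes:
            genes[gid] = GeneModel(str(gid), chrom, strand)
        genes[gid].add(Transcript(str(tid), exons, strand))
    return [genes[k] for k in sorted(genes)]


# ------------------------------------------------------- bedGraph / WIG

def write_bedgraph(sample: Mapping[str, ProbeTrack], path: str | Path,
                   span: int = 25, header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("track type=bedGraph\n")
        for chrom in sorted(sample):
            t = sample[chrom]
            for pos, val in zip(t.positions, t.values):
                fh.write(f"{chrom}\t{pos}\t{pos + span}\t{val:.6f}\n")


def _finish_chrom(records: dict, chrom: str, rows: list, path, cls=ProbeTrack) -> None:
    if not rows:
        return
    rows_sorted = sorted(rows)
    if rows_sorted != rows:
        warnings.warn(f"{path}: {chrom} records were unsorted; sorting")
    starts = [r[0] for r in rows_sorted]
    ends = [r[1] for r in rows_sorted]
    for i in range(1, len(rows_sorted)):
        if starts[i] < ends[i - 1]:
            raise ValueError(f"{path}: overlapping probe records on {chrom} near {starts[i]}")
    records[chrom] = cls(chrom, np.array(starts), np.array([r[2] for r in rows_sorted]))


def read_track(path: str | Path) -> dict[str, ProbeTrack]:
    """Parse a bedGraph or fixed/variable-step WIG file into probe tracks.

    Half-open intervals collapse to probe start positions.  Unsorted input
    is sorted with a warning; overlapping records raise; malformed lines
    raise with their line number.
    """
    rows_by_chrom: dict[str, list] = {}
    mode, chrom, step, span, at = "bedgraph", None, 1, 1, 0
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode = line.split()[0]
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                if mode == "fixedStep":
                    at = int(kv["start"]) - 1
                    step = int(kv.get("step", 1))
                continue
            parts = line.split()
            try:
                if mode == "bedgraph":
                    if len(parts) != 4:
                        raise ValueError("expected 4 columns")
                    c, a, b, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                    rows_by_chrom.setdefault(c, []).append((a, b, v))
                elif mode == "fixedStep":
                    v = float(parts[0])
                    rows_by_chrom.setdefault(chrom, []).append((at, at + span, v))
                    at += step
                else:  # variableStep
                    a, v = int(parts[0]) - 1, float(parts[1])
                    rows_by_chrom.setdefault(chrom, []).append((a, a + span, v))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {ln}: {raw.rstrip()!r}") from exc
    out: dict[str, ProbeTrack] = {}
    for c, rows in rows_by_chrom.items():
        _finish_chrom(out, c, rows, path)
    return out


def read_tracks(paths: Sequence[str | Path]) -> list[dict[str, ProbeTrack]]:
    """Read several track files and verify they share one probe grid."""
    samples = [read_track(p) for p in paths]
    first = samples[0]
    for s, p in zip(samples[1:], paths[1:]):
        if set(s) != set(first):
            raise ValueError(f"{p}: chromosome names differ from {paths[0]}")
        for chrom in first:
            if not np.array_equal(s[chrom].positions, first[chrom].positions):
                raise ValueError(f"{p}: probe grid differs from {paths[0]} on {chrom}")
    return samples


# ---------------------------------------------------------- conservation

def write_conservation(cons: Mapping[str, np.ndarray], path: str | Path,
                       header: Sequence[str] = ()) -> None:
    """Per-base scores as bedGraph, run-length merging equal neighbours."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("track type=bedGraph\n")
        for chrom in sorted(cons):
            v = np.asarray(cons[chrom])
            breaks = np.r_[0, np.flatnonzero(np.diff(v) != 0) + 1, v.size]
            for a, b in zip(breaks[:-1], breaks[1:]):
                fh.write(f"{chrom}\t{a}\t{b}\t{v[a]:.4f}\n")


def read_conservation(path: str | Path,
                      chrom_lengths: Mapping[str, int] | None = None) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "score"], skiprows=_count_track_lines(path))
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        length = chrom_lengths[chrom] if chrom_lengths else int(sub.end.max())
        arr = np.zeros(length)
        for a, b, s in zip(sub.start, sub.end, sub.score):
            arr[a:b] = s
        out[str(chrom)] = arr
    return out


def _count_track_lines(path: str | Path) -> list[int]:
    skip = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith(("track", "browser")):
                skip.append(i)
            elif not line.startswith("#"):
                break
    return skip


# ------------------------------------------------------------- peaks BED

def write_peaks_bed(peaks: Sequence[Peak], path: str | Path,
                    header: Sequence[str] = ()) -> None:
    """narrowPeak-style BED6+4: score scaled to 0-1000, summit as peak offset."""
    smax = max((p.score for p in peaks), default=1.0) or 1.0
    with open(path, "w") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        for i, p in enumerate(peaks):
            scaled = int(round(1000 * max(p.score, 0.0) / smax))
            logp = -np.log10(p.p_value) if p.p_value > 0 else 999.0
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i + 1}\t{scaled}\t.\t"
                     f"{p.score:.4f}\t{logp:.4f}\t{p.n_probes}\t{p.summit - p.start}\n")


def read_peaks_bed(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if raw.startswith(("#", "track", "browser")) or not raw.strip():
                continue
            f = raw.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: malformed BED line {ln}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            score = float(f[6]) if len(f) > 6 else 0.0
            logp = float(f[7]) if len(f) > 7 else 0.0
            n_probes = int(f[8]) if len(f) > 8 else 0
            summit = start + int(f[9]) if len(f) > 9 else (start + end) // 2
            peaks.append(Peak(chrom, start, end, summit, score, 10 ** (-logp), n_probes))
    return peaks


# ----------------------------------------------------------- expression

def write_expression(df: pd.DataFrame, path: str | Path, header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    want = {"transcript_id", "gene_id", "fpkm_plus", "fpkm_minus"}
    if not want <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(want)}")
    return df


def expression_records(df: pd.DataFrame) -> list[ExpressionRecord]:
    return [ExpressionRecord(r.transcript_id, r.gene_id, float(r.fpkm_plus),
                             float(r.fpkm_minus)) for r in df.itertuples()]


# ----------------------------------------------------------- shape table

def write_shape_table(table: ShapeTable, path: str | Path, header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        table.to_frame().to_csv(fh, sep="\t", index=False)


def read_shape_table(path: str | Path) -> ShapeTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    want = {"pentamer", *SHAPE_FEATURES}
    if not want <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(want)}")
    return ShapeTable.from_frame(df)


# ----------------------------------------------------------------- truth

def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "peak_intervals": [list(x) for x in truth.peak_intervals],
        "bound_sites": [list(x) for x in truth.bound_sites],
        "unbound_sites": [list(x) for x in truth.unbound_sites],
        "enriched_transcript_ids": sorted(truth.enriched_transcript_ids),
        "reference_transcript_id": truth.reference_transcript_id,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> PlantedTruth:
    d = json.loads(Path(path).read_text())
    return PlantedTruth(
        [tuple(x) for x in d["peak_intervals"]],
        [tuple(x) for x in d["bound_sites"]],
        [tuple(x) for x in d["unbound_sites"]],
        set(d["enriched_transcript_ids"]),
        d["reference_transcript_id"],
    )
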