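"""Gene models: multi-exon, multi-isoform, strand-aware.

Coordinates are 0-based half-open throughout.  The transcription start
site (TSS) of a minus-strand isoform is the larger genomic coordinate of
its span; the "first intron" is the intron adjacent to the TSS-proximal
exon in transcription orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Transcript", "GeneModel"]

Interval = tuple[int, int]


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval]
    strand: str

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a >= b:
                raise ValueError(f"{self.transcript_id}: empty exon {a}-{b}")
        for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """0-based coordinate of the first transcribed base."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def tts(self) -> int:
        return self.exons[-1][1] - 1 if self.strand == "+" else self.exons[0][0]

    @property
    def introns(self) -> list[Interval]:
        """Genomically sorted inter-exon gaps (may be empty)."""
        return [(b0, a1) for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]) if a1 > b0]

    @property
    def first_intron(self) -> Interval | None:
        ivs = self.introns
        if not ivs:
            return None
        return ivs[0] if self.strand == "+" else ivs[-1]

    @property
    def other_introns(self) -> list[Interval]:
        first = self.first_intron
        return [iv for iv in self.introns if iv != first]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> Interval:
        starts, ends = zip(*(t.span for t in self.transcripts.values()))
        return min(starts), max(ends)

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(self.transcripts)

    def add(self, transcript: Transcript) -> None:
        self.transcripts[transcript.transcript_id] = transcript
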