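"""ChIP x transcriptome target integration.

ChIP-associated transcripts (all isoforms of every peak-proximal gene)
are intersected with transcripts passing an absolute-expression and
fold-enrichment filter in the sorted-cell-positive sample; the overlap
is collapsed to distinct genes and scored with a cumulative
hypergeometric tail computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .annotate import Association
from .genes import GeneModel

__all__ = [
    "ExpressionRecord",
    "IntegrationParams",
    "HypergeomParams",
    "filter_expressed",
    "chip_transcript_set",
    "intersect_and_collapse",
    "hypergeom_tail",
]


@dataclass
class ExpressionRecord:
    transcript_id: str
    gene_id: str
    fpkm_plus: float   # FPKM in the marker-positive (sorted) sample
    fpkm_minus: float  # FPKM in the marker-negative sample

    def __post_init__(self) -> None:
        if self.fpkm_plus < 0 or self.fpkm_minus < 0:
            raise ValueError("FPKM values must be >= 0")


@dataclass
class IntegrationParams:
    """Defaults mirror a reference-transcript-derived cutoff of 0.983129 FPKM
    and a 1.5-fold enrichment requirement; peak-to-gene distance 3 kb."""

    fpkm_cutoff: float = 0.983129
    fold_cutoff: float = 1.5
    max_dist: int = 3000
    pseudocount: float = 0.0  # optional epsilon added to both FPKMs for the fold

    def __post_init__(self) -> None:
        if min(self.fpkm_cutoff, self.fold_cutoff, self.max_dist, self.pseudocount) < 0:
            raise ValueError("integration parameters must be >= 0")


@dataclass
class HypergeomParams:
    N: int  # population size (transcripts)
    K: int  # successes in population
    n: int  # sample size
    k: int  # successes in sample

    def __post_init__(self) -> None:
        ok = 0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N
        if not ok:
            raise ValueError(f"invalid hypergeometric parameters {self}")


def filter_expressed(
    records: Sequence[ExpressionRecord], params: IntegrationParams | None = None
) -> set[str]:
    """Transcripts passing fpkm_plus >= cutoff AND fold-enrichment >= cutoff.

    Fold = fpkm_plus / fpkm_minus; a zero denominator counts as infinite
    enrichment (passes the fold test) unless a pseudocount is configured.
    Duplicate transcript ids are an input error.
    """
    params = params or IntegrationParams()
    ids = [r.transcript_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript_id in expression records")
    passing: set[str] = set()
    for r in records:
        if r.fpkm_plus < params.fpkm_cutoff:
            continue
        num = r.fpkm_plus + params.pseudocount
        den = r.fpkm_minus + params.pseudocount
        fold = num / den if den > 0 else float("inf")
        if fold >= params.fold_cutoff:
            passing.add(r.transcript_id)
    return passing


def chip_transcript_set(
    associations: Sequence[Association], genes: Iterable[GeneModel] | Mapping[str, GeneModel]
) -> set[str]:
    """All transcript isoforms of every peak-associated gene (set semantics)."""
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    out: set[str] = set()
    for a in associations:
        out.update(genes[a.gene_id].transcript_ids)
    return out


def intersect_and_collapse(
    passing: set[str], chip_set: set[str], records: Sequence[ExpressionRecord]
) -> tuple[set[str], list[str]]:
    """Overlap transcripts and the sorted list of their distinct genes."""
    overlap = passing & chip_set
    gene_of = {r.transcript_id: r.gene_id for r in records}
    genes = sorted({gene_of[t] for t in overlap if t in gene_of})
    return overlap, genes


def hypergeom_tail(p: HypergeomParams, strict: bool = False) -> float:
    """Cumulative upper tail of the hypergeometric distribution, in log space.

    Returns P(X >= k) by default: sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n).
    ``strict=True`` gives P(X > k), the convention some spreadsheet-era
    published P-values turn out to follow.  Accurate to well over six
    significant digits.
    """
    lo = p.k + 1 if strict else p.k
    hi = min(p.K, p.n)
    if lo > hi:
        return 0.0
    if lo <= max(0, p.n + p.K - p.N):
        return 1.0

    def log_comb(n: np.ndarray | int, r: np.ndarray | int) -> np.ndarray:
        return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(r) + 1) - gammaln(
            np.asarray(n) - np.asarray(r) + 1
        )

    i = np.arange(lo, hi + 1)
    log_pmf = log_comb(p.K, i) + log_comb(p.N - p.K, p.n - i) - log_comb(p.N, p.n)
    return float(np.exp(logsumexp(log_pmf)))
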