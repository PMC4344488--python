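"""Tiling-array signal combination, smoothing and peak calling.

The four array samples of a tagged-ChIP design are combined per probe as

    C = [(chip_exp - input_exp) - (chip_ctl - input_ctl)] + (chip_exp - chip_ctl)

on log2 intensities, i.e. the control-normalised enrichment of the
experimental ChIP, reinforced by the direct experimental-vs-control ChIP
contrast.  The combined track is smoothed with a MAT-like windowed
statistic (trimmed mean times sqrt(window size)) and peaks are called on
per-probe upper-tail p-values under a robust (median/MAD) Gaussian null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "ProbeTrack",
    "CombinedTrack",
    "ScoredTrack",
    "CallerParams",
    "Peak",
    "quantile_normalize",
    "normalize_tracks",
    "smooth_score",
    "call_peaks",
]


@dataclass
class ProbeTrack:
    """Per-chromosome probe positions (0-based starts) with one value each."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError(f"{self.chrom}: probe positions must be strictly increasing")

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def spacing(self) -> int:
        """Median inter-probe distance (bp); 1 for single-probe tracks."""
        if len(self) < 2:
            return 1
        return int(np.median(np.diff(self.positions)))


# a "sample" is one array's tracks keyed by chromosome
Sample = Mapping[str, ProbeTrack]


@dataclass
class CombinedTrack(ProbeTrack):
    pass


@dataclass
class ScoredTrack(ProbeTrack):
    """Smoothed score and per-probe upper-tail p-value on the probe grid."""

    pvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.pvalues is None:
            raise ValueError("ScoredTrack requires pvalues")
        self.pvalues = np.asarray(self.pvalues, dtype=np.float64)


@dataclass
class CallerParams:
    """Peak-caller settings: 300 bp bandwidth/gap, >=8 probes, p <= 1e-4."""

    bandwidth: int = 300
    max_gap: int = 300
    min_probe: int = 8
    p_threshold: float = 1e-4
    trim: float = 0.1
    quantile_norm: bool = True

    def __post_init__(self) -> None:
        if min(self.bandwidth, self.max_gap, self.min_probe) <= 0 or self.p_threshold <= 0:
            raise ValueError("caller parameters must be positive")
        if not 0 <= self.trim < 0.5:
            raise ValueError("trim fraction must lie in [0, 0.5)")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    score: float
    p_value: float
    n_probes: int

    def __post_init__(self) -> None:
        if not (self.start < self.end and self.start <= self.summit < self.end):
            raise ValueError("peak coordinates violate start <= summit < end")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


def _check_grids(samples: list[Sample]) -> None:
    chroms = set(samples[0])
    for s in samples[1:]:
        if set(s) != chroms:
            raise ValueError("tracks do not share chromosome names")
    for chrom in chroms:
        ref = samples[0][chrom].positions
        for i, s in enumerate(samples[1:], start=2):
            pos = s[chrom].positions
            if pos.shape != ref.shape or not np.array_equal(pos, ref):
                bad = int(np.argmax(pos[: ref.size] != ref[: pos.size])) if pos.size and ref.size else 0
                raise ValueError(
                    f"probe grid mismatch on {chrom}: track 1 vs track {i} "
                    f"differ first at probe index {bad}"
                )


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Classic quantile normalization across columns (samples)."""
    order = np.argsort(matrix, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(matrix.shape[0])
    for j in range(matrix.shape[1]):
        ranks[order[:, j], j] = rows
    mean_by_rank = np.mean(np.take_along_axis(matrix, order, axis=0), axis=1)
    return mean_by_rank[ranks]


def normalize_tracks(
    t1: Sample | ProbeTrack,
    t2: Sample | ProbeTrack,
    t3: Sample | ProbeTrack,
    t4: Sample | ProbeTrack,
    quantile_norm: bool = True,
) -> dict[str, CombinedTrack] | CombinedTrack:
    """Combine the four array samples into the doubly-normalised track C.

    ``t1`` experimental ChIP, ``t2`` its input, ``t3`` control ChIP,
    ``t4`` control input.  All four must share an identical probe grid.
    Returns a single CombinedTrack when given bare ProbeTracks.
    """
    single = isinstance(t1, ProbeTrack)
    samples = [({t.chrom: t} if isinstance(t, ProbeTrack) else dict(t)) for t in (t1, t2, t3, t4)]
    _check_grids(samples)
    out: dict[str, CombinedTrack] = {}
    for chrom in samples[0]:
        vals = np.column_stack([s[chrom].values for s in samples])
        if quantile_norm and vals.shape[0] > 1:
            vals = quantile_normalize(vals)
        v1, v2, v3, v4 = vals.T
        combined = ((v1 - v2) - (v3 - v4)) + (v1 - v3)
        out[chrom] = CombinedTrack(chrom, samples[0][chrom].positions.copy(), combined)
    return out[next(iter(out))] if single else out


def _window_scores(track: ProbeTrack, bandwidth: int, min_probe: int, trim: float) -> tuple[np.ndarray, np.ndarray]:
    pos, val = track.positions, track.values
    lo = np.searchsorted(pos, pos - bandwidth, side="left")
    hi = np.searchsorted(pos, pos + bandwidth, side="right")
    n = hi - lo
    scores = np.zeros(len(pos))
    for i in range(len(pos)):
        w = val[lo[i]: hi[i]]
        scores[i] = stats.trim_mean(w, trim) * np.sqrt(w.size)
    return scores, n


def smooth_score(
    combined: Mapping[str, CombinedTrack] | CombinedTrack,
    params: CallerParams | None = None,
) -> dict[str, ScoredTrack] | ScoredTrack:
    """MAT-like smoothed score with per-probe p-values.

    Score ``s_i`` is the 10%-trimmed mean of the combined signal over probes
    within +-bandwidth of probe i, scaled by sqrt(window size).  P-values are
    upper-tail probabilities under a Gaussian null located at the genome-wide
    median of s with scale 1.4826 * MAD (robust to true peaks in the tail).
    Windows narrower than ``min_probe`` probes are assigned p = 1.
    """
    params = params or CallerParams()
    single = isinstance(combined, CombinedTrack)
    sample = {combined.chrom: combined} if single else dict(combined)

    all_scores, all_n = {}, {}
    for chrom, track in sample.items():
        all_scores[chrom], all_n[chrom] = _window_scores(
            track, params.bandwidth, params.min_probe, params.trim
        )
    pooled = np.concatenate(list(all_scores.values())) if all_scores else np.array([])
    if pooled.size == 0:
        return {} if not single else None  # empty track -> empty output
    mu = float(np.median(pooled))
    mad = float(stats.median_abs_deviation(pooled, scale=1.0))
    sigma = 1.4826 * mad
    out: dict[str, ScoredTrack] = {}
    for chrom, track in sample.items():
        s = all_scores[chrom]
        if sigma > 0:
            p = stats.norm.sf(s, loc=mu, scale=sigma)
        else:
            # degenerate null (constant score genome-wide): nothing deviates
            p = np.full(s.shape, 0.5)
        p[all_n[chrom] < params.min_probe] = 1.0
        out[chrom] = ScoredTrack(chrom, track.positions.copy(), s, pvalues=p)
    return out[next(iter(out))] if single else out


def call_peaks(
    scored: Mapping[str, ScoredTrack] | ScoredTrack,
    params: CallerParams | None = None,
) -> list[Peak]:
    """Naive peak caller on per-probe p-values.

    Probes with p <= p_threshold are significant; runs of significant probes
    whose consecutive gaps are <= max_gap merge; merged runs with at least
    min_probe significant probes become peaks.  A peak spans from the first
    to the last significant probe plus one probe spacing; the summit is the
    leftmost score maximum among its significant probes.
    """
    params = params or CallerParams()
    sample = {scored.chrom: scored} if isinstance(scored, ScoredTrack) else dict(scored)
    peaks: list[Peak] = []
    for chrom in sorted(sample):
        track = sample[chrom]
        sig = np.flatnonzero(track.pvalues <= params.p_threshold)
        if sig.size == 0:
            continue
        spacing = track.spacing
        pos = track.positions[sig]
        breaks = np.flatnonzero(np.diff(pos) > params.max_gap)
        runs = np.split(sig, breaks + 1)
        for run in runs:
            if run.size < params.min_probe:
                continue
            run_pos = track.positions[run]
            run_scores = track.values[run]
            summit = int(run_pos[int(np.argmax(run_scores))])
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(run_pos[0]),
                    end=int(run_pos[-1]) + spacing,
                    summit=summit,
                    score=float(np.max(run_scores)),
                    p_value=float(np.min(track.pvalues[run])),
                    n_probes=int(run.size),
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks
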