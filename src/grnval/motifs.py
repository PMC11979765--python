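"""Degenerate TF-binding-site scanning with exact p-value calibration.

A FIMO-style scanner: an IUPAC consensus (e.g. the generic HSF site
NGAANNTTCN) becomes a position probability matrix with N positions weighted
by genomic GC content; per-window log-odds scores are discretized onto an
integer lattice and the exact null score distribution under a 0-order
GC-derived background is computed by dynamic-programming convolution, giving
every window an exact (up to lattice resolution) p-value. Hits at p <= 0.01
are intersected with Y1H cloned-promoter regions (BED half-open semantics).

The background is the same GC-derived composition as the N weighting — not
re-estimated from the scanned sequences — so a scan is a pure function of
(consensus, gc, threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "MotifModel",
    "MotifHit",
    "ScoreDistribution",
    "consensus_to_pwm",
    "score_distribution",
    "scan_sequence",
    "intersect_hits",
    "reverse_complement",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    name: str
    probs: np.ndarray  # length x 4, columns ordered A, C, G, T
    background: np.ndarray  # length-4

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or not len(self.probs):
            raise ValueError("probs must be a (length x 4) matrix, length >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("each motif position must sum to 1")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")

    def __len__(self) -> int:
        return len(self.probs)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 0-based, forward strand
    end: int  # half-open
    strand: str  # "+" or "-"
    score: float  # log2-odds (lattice value)
    pvalue: float


def gc_background(gc_content: float) -> np.ndarray:
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content must be in (0, 1), got {gc_content}")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return np.array([at, gc, gc, at])


def consensus_to_pwm(
    consensus: str, gc_content: float, epsilon: float = 0.001, name: str | None = None
) -> MotifModel:
    """IUPAC consensus -> position probability matrix.

    Fixed letters carry mass 1 - 3*epsilon (epsilon on each other base, so
    log-odds never degenerate); degenerate codes split the non-epsilon mass
    uniformly over their allowed bases — except N, which takes the genomic
    composition: p(G) = p(C) = gc/2, p(A) = p(T) = (1-gc)/2. The background
    is that same composition.
    """
    bg = gc_background(gc_content)
    rows = []
    for i, ch in enumerate(consensus.upper()):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} at position {i}")
        if ch == "N":
            rows.append(bg.copy())
            continue
        allowed = IUPAC[ch]
        row = np.full(4, epsilon)
        row[[BASES.index(b) for b in allowed]] = (
            1.0 - (4 - len(allowed)) * epsilon
        ) / len(allowed)
        rows.append(row)
    return MotifModel(
        name=name or consensus.upper(), probs=np.array(rows), background=bg
    )


@dataclass
class ScoreDistribution:
    """Exact null distribution of the lattice log-odds score.

    ``int_scores[i, b]`` is the integer lattice score of base b at position
    i (real log2-odds / delta, rounded); ``tail[v - offset]`` is
    P(total >= v) under the background, computed by exact convolution.
    """

    int_scores: np.ndarray
    delta: float
    offset: int
    tail: np.ndarray

    def pvalue(self, total: int | np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(total) - self.offset, 0, len(self.tail) - 1)
        p = self.tail[idx]
        return np.where(np.asarray(total) > self.offset + len(self.tail) - 1, 0.0, p)

    @property
    def max_total(self) -> int:
        return self.offset + len(self.tail) - 1


def score_distribution(model: MotifModel, bins: int = 1000) -> ScoreDistribution:
    """Exact null score distribution by dynamic-programming convolution.

    Per-position log2-odds are rounded to an integer lattice of width
    delta = range/bins; the distribution of the lattice total under the
    background model is exact, so reported p-values are exact tail
    probabilities of the scores the scanner actually assigns.
    """
    if bins < 100:
        raise ValueError("bins must be >= 100")
    if ((model.background == 0) & (model.probs > 0).any(axis=0)).any():
        raise ValueError(
            "background probability 0 for a base the motif can emit "
            "(infinite log-odds)"
        )
    lods = np.log2(np.maximum(model.probs, 1e-300) / model.background)
    span = float(lods.max() - lods.min())
    delta = span / bins if span > 0 else 1.0
    ints = np.round(lods / delta).astype(np.int64)
    mins = ints.min(axis=1)
    maxs = ints.max(axis=1)
    offset = int(mins.sum())
    size = int((maxs - mins).sum()) + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    width = 1  # occupied prefix of dist, relative support so far
    for i in range(len(model)):
        new = np.zeros(size)
        for b in range(4):
            shift = int(ints[i, b] - mins[i])
            new[shift : shift + width] += model.background[b] * dist[:width]
        width += int(maxs[i] - mins[i])
        dist = new
    tail = dist[::-1].cumsum()[::-1]
    return ScoreDistribution(int_scores=ints, delta=delta, offset=offset, tail=tail)


def _encode(sequence: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_totals(codes: np.ndarray, ints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lattice totals for every window plus a validity mask (no non-ACGT)."""
    L = ints.shape[0]
    n_win = len(codes) - L + 1
    totals = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    for j in range(L):
        c = safe[j : j + n_win]
        totals += ints[j, c]
        valid &= codes[j : j + n_win] >= 0
    return totals, valid


def scan_sequence(
    model: MotifModel,
    sequence: str,
    sequence_id: str = "seq",
    p_threshold: float = 0.01,
    both_strands: bool = True,
    dist: ScoreDistribution | None = None,
    bins: int = 1000,
) -> list[MotifHit]:
    """Report every window matching the motif at p <= p_threshold.

    Windows containing any non-ACGT letter are skipped. The minus strand is
    scored on the reverse complement; coordinates are always reported on the
    forward strand (0-based half-open). Sequences shorter than the motif
    yield an empty list.
    """
    if dist is None:
        dist = score_distribution(model, bins=bins)
    L = len(model)
    if len(sequence) < L:
        return []
    codes = _encode(sequence)
    hits: list[MotifHit] = []
    strand_matrices = [("+", dist.int_scores)]
    if both_strands:
        # minus-strand window score == plus-strand score of its revcomp:
        # reverse positions, complement bases
        strand_matrices.append(("-", dist.int_scores[::-1, ::-1]))
    for strand, ints in strand_matrices:
        totals, valid = _window_totals(codes, ints)
        pvals = dist.pvalue(totals)
        keep = valid & (pvals <= p_threshold)
        for i in np.flatnonzero(keep):
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=int(i),
                    end=int(i) + L,
                    strand=strand,
                    score=float(totals[i] * dist.delta),
                    pvalue=float(pvals[i]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def intersect_hits(
    hits: Iterable[MotifHit],
    regions: Sequence[tuple[str, int, int]],
) -> list[MotifHit]:
    """Hits overlapping >= 1 bp with any region on the same sequence.

    Regions are 0-based half-open (BED); default BEDTools-intersect
    semantics, so a hit abutting a region boundary does not overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for seq_id, start, end in regions:
        if start >= end:
            raise ValueError(f"malformed region {seq_id}:{start}-{end} (start >= end)")
        trees.setdefault(seq_id, IntervalTree()).addi(start, end)
    return [
        h
        for h in hits
        if h.sequence_id in trees and trees[h.sequence_id].overlap(h.start, h.end)
    ]
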