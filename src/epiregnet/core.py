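"""Core domain types shared by every pipeline stage.

All internal computation uses 0-based half-open coordinates (the BED
convention).  VCF-style 1-based positions are converted at the I/O
boundary and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

DNA_ALPHABET = frozenset("ACGT")
STRANDS = frozenset({"+", "-", "."})

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A located feature: ``[start, end)`` on ``seq_id``, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, seq_id: str, pos: int) -> bool:
        return self.seq_id == seq_id and self.start <= pos < self.end


@dataclass(frozen=True)
class Variant:
    """A sequence variant with a VCF-style 1-based position."""

    seq_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or not set(allele) <= DNA_ALPHABET:
                raise ValueError(
                    f"allele {allele!r} of {self.id} is not uppercase A/C/G/T"
                )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) for {self.id}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def to_interval(self) -> GenomicInterval:
        """0-based half-open footprint of the reference allele."""
        start = self.pos - 1
        return GenomicInterval(self.seq_id, start, start + len(self.ref_allele),
                               name=self.id)

    @classmethod
    def from_interval(cls, iv: GenomicInterval, ref: str, alt: str,
                      id: str = ".") -> "Variant":
        return cls(iv.seq_id, iv.start + 1, ref, alt, id)


def _canonical_order(a: GenomicInterval, b: GenomicInterval) -> bool:
    return (a.seq_id, a.start, a.end) <= (b.seq_id, b.start, b.end)


@dataclass(frozen=True)
class ContactPair:
    """A chromatin contact between two anchors, with a read/ligation count.

    Anchors are stored in canonical order (lexicographic seq_id, then
    coordinates) so that equal contacts compare equal regardless of the
    order they were supplied in.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"contact count must be >= 1, got {self.count}")
        if not _canonical_order(self.anchor1, self.anchor2):
            a1, a2 = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)

    @classmethod
    def make(cls, a: GenomicInterval, b: GenomicInterval, count: int = 1
             ) -> "ContactPair":
        if _canonical_order(a, b):
            return cls(a, b, count)
        return cls(b, a, count)


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's differential-expression measurement (treated vs vehicle)."""

    gene: str
    log2fc: float
    pvalue: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"non-finite log2fc for {self.gene}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value for {self.gene} outside (0, 1]")


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities (A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray          # L x 4, rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "background", background)
        if matrix.ndim != 2 or matrix.shape[1] != 4 or matrix.shape[0] < 1:
            raise ValueError(f"PWM {self.motif_id}: matrix must be L x 4")
        if np.any(matrix <= 0):
            raise ValueError(f"PWM {self.motif_id}: zero/negative probability "
                             "(apply a pseudocount)")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")
        if not np.isclose(background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray,
                    background: Optional[np.ndarray] = None,
                    pseudocount: float = 0.5) -> "PWM":
        """Normalise a count matrix, adding ``pseudocount`` to every cell."""
        counts = np.asarray(counts, dtype=float) + pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(motif_id, matrix, background)

    def log_odds(self, seq: str) -> float:
        """log2-odds score of a sequence of length L against the background."""
        if len(seq) != len(self):
            raise ValueError(f"sequence length {len(seq)} != motif length "
                             f"{len(self)}")
        score = 0.0
        for i, base in enumerate(seq):
            j = _BASE_INDEX[base]
            score += math.log2(self.matrix[i, j] / self.background[j])
        return score


@dataclass(frozen=True)
class GeneModel:
    """A gene body with exon blocks; TSS/TES are strand-aware."""

    seq_id: str
    start: int
    end: int
    strand: str
    name: str
    exons: tuple = ()           # tuple of (start, end), 0-based half-open

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.name}: invalid body coordinates")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.name}: exon ({s},{e}) outside "
                                 "the gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end,
                               self.strand, self.name)

    def tss_flank(self, flank_bp: int) -> GenomicInterval:
        """Symmetric window of ±flank_bp around the TSS (clipped at 0)."""
        start = max(0, self.tss - flank_bp)
        return GenomicInterval(self.seq_id, start, self.tss + flank_bp + 1,
                               self.strand, self.name)


class IntervalSet:
    """Indexed collection of intervals with optional payloads.

    Backed by one interval tree per sequence; supports membership and
    minimum-overlap queries, which is all the annotation logic needs.
    """

    def __init__(self, intervals: Iterable = (),
                 payloads: Optional[Iterable] = None) -> None:
        from intervaltree import IntervalTree

        self._trees: dict = {}
        self._items: list = []
        self._IntervalTree = IntervalTree
        if payloads is None:
            for iv in intervals:
                self.add(iv)
        else:
            for iv, payload in zip(intervals, payloads):
                self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload=None) -> None:
        idx = len(self._items)
        self._items.append((iv, payload))
        tree = self._trees.get(iv.seq_id)
        if tree is None:
            tree = self._trees[iv.seq_id] = self._IntervalTree()
        tree.addi(iv.start, iv.end, idx)

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator:
        return (iv for iv, _ in self._items)

    def items(self) -> Iterator:
        return iter(self._items)

    def query(self, iv: GenomicInterval, min_overlap_bp: int = 1) -> list:
        """All (interval, payload, overlap_bp) overlapping by >= min_overlap_bp."""
        tree = self._trees.get(iv.seq_id)
        if tree is None:
            return []
        hits = []
        for hit in tree.overlap(iv.start, iv.end):
            stored, payload = self._items[hit.data]
            ov = stored.overlap_bp(iv)
            if ov >= min_overlap_bp:
                hits.append((stored, payload, ov))
        hits.sort(key=lambda t: (t[0].start, t[0].end, t[0].name))
        return hits

    def overlaps(self, iv: GenomicInterval, min_overlap_bp: int = 1) -> bool:
        return bool(self.query(iv, min_overlap_bp))

    def contains_point(self, seq_id: str, pos: int) -> bool:
        tree = self._trees.get(seq_id)
        return bool(tree is not None and tree.at(pos))
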