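"""Transcriptional-hub extraction from chromatin-contact lists.

A hub is the set of genes whose loci are in spatial contact with one
anchor regulatory element, split into cis (same chromosome) and trans
(different chromosome) partners.  A permutation null on the far-end
anchors supports an empirical significance for the observed hub size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import ContactPair, GeneModel, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)


@dataclass
class ContactHub:
    """Genes contacted by one anchor element.

    ``cis_genes``/``trans_genes`` are ordered by descending summed
    contact count, then name, so output is deterministic.
    ``total_degree`` counts distinct contacted elements, mapped to a
    gene or not.
    """

    anchor: GenomicInterval
    cis_genes: Tuple[str, ...] = ()
    trans_genes: Tuple[str, ...] = ()
    contact_counts: Dict[str, int] = field(default_factory=dict)
    total_degree: int = 0

    @property
    def genes(self) -> Tuple[str, ...]:
        return self.cis_genes + self.trans_genes

    @property
    def size(self) -> int:
        return len(self.cis_genes) + len(self.trans_genes)


def _gene_index(genes: Sequence[GeneModel], promoter_flank_bp: int
                ) -> IntervalSet:
    """Index of gene body union TSS flank, payload = gene name."""
    index = IntervalSet()
    for g in genes:
        start = min(g.start, max(0, g.tss - promoter_flank_bp))
        end = max(g.end, g.tss + promoter_flank_bp + 1)
        index.add(GenomicInterval(g.seq_id, start, end, g.strand, g.name),
                  g.name)
    return index


def _far_ends(anchor: GenomicInterval, contacts: Sequence[ContactPair],
              min_count: int) -> List[Tuple[GenomicInterval, int]]:
    """Far-end anchors of pairs touching the anchor; self-loops skipped."""
    out = []
    for pair in contacts:
        if pair.count < min_count:
            continue
        hit1 = anchor.overlap_bp(pair.anchor1) > 0
        hit2 = anchor.overlap_bp(pair.anchor2) > 0
        if hit1 and hit2:
            logger.warning("contact %s-%s is a self-loop on the anchor; "
                           "skipped", pair.anchor1, pair.anchor2)
            continue
        if hit1:
            out.append((pair.anchor2, pair.count))
        elif hit2:
            out.append((pair.anchor1, pair.count))
    return out


def _assemble(anchor: GenomicInterval,
              far_ends: Sequence[Tuple[GenomicInterval, int]],
              gene_index: IntervalSet) -> ContactHub:
    counts: Dict[str, int] = {}
    cis: set = set()
    trans: set = set()
    distinct = set()
    for far, count in far_ends:
        distinct.add((far.seq_id, far.start, far.end))
        for _, gene_name, _ in gene_index.query(far):
            counts[gene_name] = counts.get(gene_name, 0) + count
            (cis if far.seq_id == anchor.seq_id else trans).add(gene_name)
    # a gene touched both in cis and trans counts once, as cis
    trans -= cis
    order = lambda names: tuple(sorted(names, key=lambda n: (-counts[n], n)))
    return ContactHub(anchor=anchor, cis_genes=order(cis),
                      trans_genes=order(trans), contact_counts=counts,
                      total_degree=len(distinct))


def extract_hub(anchor: GenomicInterval, contacts: Sequence[ContactPair],
                genes: Sequence[GeneModel], min_count: int = 1,
                promoter_flank_bp: int = 2000) -> ContactHub:
    """Genes contacted by ``anchor`` through pairs with count >= min_count.

    A far end maps to every gene whose body or TSS flank
    (± promoter_flank_bp) it overlaps.  Output ordering is deterministic
    and independent of input order.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    index = _gene_index(genes, promoter_flank_bp)
    return _assemble(anchor, _far_ends(anchor, contacts, min_count), index)


def hub_null_distribution(anchor: GenomicInterval,
                          contacts: Sequence[ContactPair],
                          genes: Sequence[GeneModel],
                          n_perm: int = 999,
                          seed: int = 0,
                          min_count: int = 1,
                          promoter_flank_bp: int = 2000
                          ) -> Tuple[float, np.ndarray]:
    """Empirical p-value for the observed hub size.

    Keeps the number of anchor-touching contacts fixed and redraws their
    far ends uniformly (without replacement) from the far ends of the
    whole contact list, recomputing the hub size each time.
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable p-value")
    index = _gene_index(genes, promoter_flank_bp)
    observed_fars = _far_ends(anchor, contacts, min_count)
    observed = _assemble(anchor, observed_fars, index).size

    pool = []
    for pair in contacts:
        if pair.count >= min_count:
            pool.append((pair.anchor1, pair.count))
            pool.append((pair.anchor2, pair.count))
    m = len(observed_fars)
    rng = np.random.default_rng(seed)
    null_sizes = np.zeros(n_perm, dtype=int)
    if m and pool:
        replace = m > len(pool)
        for i in range(n_perm):
            idx = rng.choice(len(pool), size=m, replace=replace)
            null_sizes[i] = _assemble(anchor, [pool[j] for j in idx],
                                      index).size
    p = (1 + int(np.sum(null_sizes >= observed))) / (n_perm + 1)
    return p, null_sizes


def hub_to_frame(hub: ContactHub):
    """Arc summary (seq_id, start, end, gene, count, cis) for plotting/export."""
    import pandas as pd

    rows = []
    for gene in hub.genes:
        rows.append({
            "anchor_seq_id": hub.anchor.seq_id,
            "anchor_start": hub.anchor.start,
            "anchor_end": hub.anchor.end,
            "gene": gene,
            "count": hub.contact_counts[gene],
            "compartment": "cis" if gene in hub.cis_genes else "trans",
        })
    return pd.DataFrame(
        rows, columns=["anchor_seq_id", "anchor_start", "anchor_end",
                       "gene", "count", "compartment"])
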