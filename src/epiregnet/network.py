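"""TF-centric regulatory-network reconstruction and enrichment statistics.

Builds the drug-responsive TF->target network from a two-condition
differential-expression table and an interaction edge list, and computes
the summary statistics used to interpret it: regulon coverage of the
differentially expressed (DE) set, Fisher's exact enrichment with
Benjamini-Hochberg correction, direction bias of TF functional classes,
super-enhancer-based master-TF assignment, closure overlap with regional
TF catalogues and HOT-region (high-occupancy target) overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionRecord, GeneModel, IntervalSet

logger = logging.getLogger(__name__)

Edge = Tuple[str, str, str]          # (tf, target, sign)


@dataclass(frozen=True)
class DifferentialSet:
    """Up/down-regulated gene sets plus the measured universe."""

    up: frozenset
    down: frozenset
    universe: frozenset
    thresholds: Tuple[float, float] = (1.0, 0.05)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")
        if not (self.up | self.down) <= self.universe:
            raise ValueError("DE genes outside the measured universe")

    @property
    def de(self) -> frozenset:
        return self.up | self.down


@dataclass
class EnrichmentResult:
    """A 2x2 contingency test: counts, odds ratio, Fisher p, BH q."""

    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float
    q_bh: float = float("nan")

    @property
    def table(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def select_differential(records: Sequence[ExpressionRecord],
                        min_abs_log2fc: float = 1.0,
                        max_p: float = 0.05) -> DifferentialSet:
    """Threshold an expression table into up/down/universe sets.

    Duplicate gene symbols keep the record with the smallest p-value.
    """
    if min_abs_log2fc < 0 or not math.isfinite(min_abs_log2fc):
        raise ValueError("min_abs_log2fc must be finite and >= 0")
    best: Dict[str, ExpressionRecord] = {}
    for rec in records:
        prev = best.get(rec.gene)
        if prev is None:
            best[rec.gene] = rec
        elif rec.pvalue < prev.pvalue:
            logger.warning("duplicate gene %s: keeping record with smaller p",
                           rec.gene)
            best[rec.gene] = rec
        else:
            logger.warning("duplicate gene %s: discarding larger-p record",
                           rec.gene)
    up, down = set(), set()
    for rec in best.values():
        if rec.pvalue <= max_p:
            if rec.log2fc >= min_abs_log2fc:
                up.add(rec.gene)
            elif rec.log2fc <= -min_abs_log2fc:
                down.add(rec.gene)
    return DifferentialSet(frozenset(up), frozenset(down),
                           frozenset(best), (min_abs_log2fc, max_p))


# ---------------------------------------------------------------------------
# Fisher's exact test

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Two-sided Fisher's exact test by the minimum-likelihood rule.

    The p-value is the sum of hypergeometric probabilities of every
    table with the same margins whose probability does not exceed that
    of the observed table (within a small relative tolerance on the
    comparison, to absorb float ties).  The summation itself is
    delegated to ``scipy.stats.fisher_exact``, which implements exactly
    this rule; input validation and the sample odds ratio (ad/bc,
    infinite when bc = 0) are handled here.  Returns (odds_ratio, p).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError(f"counts must be non-negative integers, got {x}")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty contingency table")
    p = float(scipy.stats.fisher_exact([[a, b], [c, d]],
                                       alternative="two-sided")[1])
    p = min(1.0, p)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return odds, p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values for a batch of raw p-values."""
    if len(pvalues) == 0:
        return np.array([])
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


def adjust_batch(results: Sequence[EnrichmentResult]
                 ) -> List[EnrichmentResult]:
    """Attach BH q-values across one analysis batch."""
    qs = bh_adjust([r.p_two_sided for r in results])
    return [replace(r, q_bh=float(q)) for r, q in zip(results, qs)]


# ---------------------------------------------------------------------------
# Regulon statistics

def targets_of(tf: str, edges: Iterable[Edge]) -> Set[str]:
    return {target for source, target, _ in edges if source == tf}


def regulon_coverage(tf: str, edges: Sequence[Edge], de: DifferentialSet
                     ) -> Tuple[float, EnrichmentResult]:
    """Fraction of the DE set that are known targets of ``tf``.

    Also tests target membership against DE membership over the measured
    universe with Fisher's exact test.
    """
    targets = targets_of(tf, edges)
    if not targets:
        raise ValueError(f"{tf} has no targets in the edge list")
    de_genes = de.de
    if not de_genes:
        raise ValueError("empty differential set: coverage undefined")
    targets_in_universe = targets & de.universe
    a = len(targets_in_universe & de_genes)
    b = len(targets_in_universe - de_genes)
    c = len(de_genes - targets_in_universe)
    d = len(de.universe) - a - b - c
    odds, p = fisher_exact_2x2(a, b, c, d)
    fraction = a / len(de_genes)
    return fraction, EnrichmentResult(tf, a, b, c, d, odds, p)


def classify_tf_direction_bias(tf_class_sets: Mapping[str, Set[str]],
                               de: DifferentialSet
                               ) -> Dict[str, EnrichmentResult]:
    """Is a functional class of TFs biased toward down-regulation?

    For each class, a 2x2 of (class membership) x (down-regulated) over
    the measured TFs (the union of the supplied class sets restricted to
    the universe), tested with Fisher's exact test.
    """
    measured: Set[str] = set()
    for label, tfs in tf_class_sets.items():
        measured |= tfs
    measured &= set(de.universe)
    results: Dict[str, EnrichmentResult] = {}
    for label, tfs in tf_class_sets.items():
        members = tfs & measured
        if not members:
            raise ValueError(f"TF class {label!r} empty within the universe")
        others = measured - members
        a = len(members & de.down)
        b = len(members) - a
        c = len(others & de.down)
        d = len(others) - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        results[label] = EnrichmentResult(label, a, b, c, d, odds, p)
    return results


def identify_master_tfs(tfs: Iterable[str],
                        super_enhancers: IntervalSet,
                        gene_models: Mapping[str, GeneModel],
                        tss_flank_bp: int = 2000) -> Set[str]:
    """TFs whose gene body or TSS flank overlaps a super-enhancer."""
    masters: Set[str] = set()
    for tf in tfs:
        model = gene_models.get(tf)
        if model is None:
            logger.warning("TF %s absent from gene models; excluded from "
                           "master-TF assignment", tf)
            continue
        if (super_enhancers.overlaps(model.body)
                or super_enhancers.overlaps(model.tss_flank(tss_flank_bp))):
            masters.add(tf)
    return masters


def direct_tf_closure(seed_tfs: Set[str], edges: Sequence[Edge],
                      all_tfs: Set[str]) -> Set[str]:
    """Seed TFs plus their direct targets that are themselves TFs."""
    closure = set(seed_tfs)
    for tf, target, _ in edges:
        if tf in seed_tfs and target in all_tfs:
            closure.add(target)
    return closure


def tf_overlap_fraction(tf_closure: Set[str], region_tfs: Set[str]) -> float:
    """Percentage of a region's TF catalogue covered by the closure."""
    if not region_tfs:
        raise ValueError("region TF set is empty")
    return 100.0 * len(tf_closure & region_tfs) / len(region_tfs)


def hot_overlap(genes: Iterable[str],
                gene_models: Mapping[str, GeneModel],
                hot_regions: IntervalSet) -> float:
    """Fraction of genes whose body overlaps a HOT region."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    hits = 0
    considered = 0
    for gene in genes:
        model = gene_models.get(gene)
        if model is None:
            logger.warning("gene %s absent from gene models; excluded from "
                           "HOT overlap", gene)
            continue
        considered += 1
        if hot_regions.overlaps(model.body):
            hits += 1
    if considered == 0:
        raise ValueError("no listed gene has a gene model")
    return hits / considered


# ---------------------------------------------------------------------------
# Network assembly

def build_network(de: DifferentialSet, edges: Sequence[Edge],
                  seeds: Iterable[str] = ()) -> nx.DiGraph:
    """Induced TF->target subgraph over DE genes, seeds and their
    one-hop interactors.

    One-hop expansion over the supplied edge list stands in for
    proprietary network-growing tools: a node enters the network when it
    is differentially expressed, a seed, or directly interacts with one
    that is.  Node attributes: ``is_tf``, ``direction``
    (up/down/unmeasured) and ``is_master_tf`` (False until assigned).
    """
    core = set(de.de) | set(seeds)
    members = set(core)
    for tf, target, _ in edges:
        if tf in core or target in core:
            members.add(tf)
            members.add(target)
    graph = nx.DiGraph()
    tf_names = {tf for tf, _, _ in edges}
    for gene in members:
        if gene in de.up:
            direction = "up"
        elif gene in de.down:
            direction = "down"
        else:
            direction = "unmeasured"
        graph.add_node(gene, is_tf=gene in tf_names, direction=direction,
                       is_master_tf=False)
    for tf, target, sign in edges:
        if tf in members and target in members:
            graph.add_edge(tf, target, sign=sign)
    return graph


def node_degree(network: nx.DiGraph, gene: str) -> int:
    """Count of distinct direct-interaction partners of a gene."""
    if gene not in network:
        return 0
    neighbors = set(network.predecessors(gene)) | set(network.successors(gene))
    return len(neighbors - {gene})


def network_to_frames(network: nx.DiGraph):
    """(nodes, edges) DataFrames with GraphML-compatible attribute names."""
    import pandas as pd

    nodes = pd.DataFrame(
        [{"name": n, **attrs} for n, attrs in network.nodes(data=True)]
    ).sort_values("name").reset_index(drop=True)
    edge_rows = [{"source": u, "target": v, "sign": d.get("sign", ".")}
                 for u, v, d in network.edges(data=True)]
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "sign"])
    if len(edges):
        edges = edges.sort_values(["source", "target"]).reset_index(drop=True)
    return nodes, edges


def enrichment_to_frame(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame([{
        "label": r.label, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "odds_ratio": r.odds_ratio, "p": r.p_two_sided, "q": r.q_bh,
    } for r in results])
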