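"""Functional annotation of noncoding variants.

A noncoding variant is judged to mark a functional regulatory element by
a checklist of independent evidence criteria: location in open chromatin
(DNase I hypersensitivity), low-to-moderate CpG methylation, a
combinatorial histone-mark state (H3K27ac with H3K4me1 = enhancer, with
H3K4me3 = promoter), genic context, molecular-QTL annotation, ChIP-seq
protein occupancy, transcription-factor motif disruption (PWM log-odds
delta), consistency with the expected RNA species (bidirectional eRNA
for enhancers, promoter-proximal mRNA), Hi-C connectivity of the element
and a k-mer-based allele-bias score in the style of deltaSVM.  Every
criterion records its evidence independently; the final causal call is a
transparent, configurable conjunction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

from .core import (PWM, ContactPair, GeneModel, GenomicInterval, IntervalSet,
                   Variant, reverse_complement)

logger = logging.getLogger(__name__)


class ElementClass(str, Enum):
    ENHANCER = "enhancer"
    PROMOTER = "promoter"
    UNCLASSIFIED = "unclassified"


class GenicContext(str, Enum):
    EXONIC = "exonic"
    INTRONIC = "intronic"
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    INTERGENIC = "intergenic"


@dataclass
class ChromatinTrackSet:
    """All chromatin evidence tracks used by the annotation checklist."""

    dnase: IntervalSet = field(default_factory=IntervalSet)
    h3k27ac: IntervalSet = field(default_factory=IntervalSet)
    h3k4me1: IntervalSet = field(default_factory=IntervalSet)
    h3k4me3: IntervalSet = field(default_factory=IntervalSet)
    methylation: IntervalSet = field(default_factory=IntervalSet)  # payload: level
    qtl: IntervalSet = field(default_factory=IntervalSet)          # payload: label
    chip_bound: IntervalSet = field(default_factory=IntervalSet)   # payload: proteins
    ernas: IntervalSet = field(default_factory=IntervalSet)
    super_enhancers: IntervalSet = field(default_factory=IntervalSet)
    hot_regions: IntervalSet = field(default_factory=IntervalSet)

    def known_sequences(self) -> set:
        seqs: set = set()
        for track in (self.dnase, self.h3k27ac, self.h3k4me1, self.h3k4me3,
                      self.methylation, self.qtl, self.chip_bound, self.ernas,
                      self.super_enhancers, self.hot_regions):
            seqs.update(iv.seq_id for iv in track)
        return seqs


@dataclass
class AnnotationConfig:
    """Thresholds of the causal-call rule; all are deliberately explicit.

    methylation_max: highest methylation level still counted as
        "low to moderate" (fraction methylated, default 0.6).
    min_overlap_bp: minimum peak overlap for the histone-mark rules.
    bias_threshold: |allele bias| at or above which the variant is
        considered allele-selective.
    min_hic_degree: contact partners required before the element is
        reported as spatially connected (informational only).
    tss_flank_bp: promoter flank used for genic context and
        promoter-RNA consistency.
    kmer_k: k-mer length of the allele-bias scorer.
    """

    methylation_max: float = 0.6
    min_overlap_bp: int = 1
    bias_threshold: float = 2.0
    min_hic_degree: int = 1
    tss_flank_bp: int = 5000
    kmer_k: int = 8


class PwmHit(NamedTuple):
    position: int      # genomic 0-based start of the best-scoring window
    strand: str
    delta: float       # best alt-allele score minus best ref-allele score


@dataclass
class AnnotationReport:
    """Checklist verdict for one variant; one field per evidence criterion."""

    variant: Variant
    open_chromatin: bool = False
    methylation_ok: bool = True
    element_class: ElementClass = ElementClass.UNCLASSIFIED
    genic_context: GenicContext = GenicContext.INTERGENIC
    qtl_labels: frozenset = frozenset()
    bound_proteins: frozenset = frozenset()
    pwm_disruptions: Tuple[Tuple[str, float], ...] = ()
    rna_consistent: bool = False
    hic_degree: int = 0
    allele_bias_score: float = 0.0
    causal_call: bool = False

    def to_row(self) -> Dict[str, object]:
        return {
            "variant_id": self.variant.id,
            "seq_id": self.variant.seq_id,
            "pos": self.variant.pos,
            "ref": self.variant.ref_allele,
            "alt": self.variant.alt_allele,
            "open_chromatin": self.open_chromatin,
            "methylation_ok": self.methylation_ok,
            "element_class": self.element_class.value,
            "genic_context": self.genic_context.value,
            "qtl_labels": ",".join(sorted(self.qtl_labels)) or ".",
            "bound_proteins": ",".join(sorted(self.bound_proteins)) or ".",
            "pwm_disruptions": ";".join(
                f"{m}:{d:.6g}" for m, d in self.pwm_disruptions) or ".",
            "rna_consistent": self.rna_consistent,
            "hic_degree": self.hic_degree,
            "allele_bias_score": self.allele_bias_score,
            "causal_call": self.causal_call,
        }


# ---------------------------------------------------------------------------
# Individual criteria

def classify_element(iv: GenomicInterval, tracks: ChromatinTrackSet,
                     min_overlap_bp: int = 1) -> ElementClass:
    """Combinatorial histone-mark state of an interval.

    H3K27ac together with H3K4me3 calls a promoter; H3K27ac with H3K4me1
    calls an enhancer.  When both co-occur the promoter call wins, since
    TSS-proximal H3K4me3 is the more specific mark.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if not tracks.h3k27ac.overlaps(iv, min_overlap_bp):
        return ElementClass.UNCLASSIFIED
    if tracks.h3k4me3.overlaps(iv, min_overlap_bp):
        return ElementClass.PROMOTER
    if tracks.h3k4me1.overlaps(iv, min_overlap_bp):
        return ElementClass.ENHANCER
    return ElementClass.UNCLASSIFIED


def genic_context(v: Variant, genes: Sequence[GeneModel],
                  tss_flank_bp: int = 5000) -> GenicContext:
    """Genic context with precedence exonic > intronic > 5' > 3' > intergenic.

    5'/3' flanks are strand-aware windows of ``tss_flank_bp`` upstream of
    the TSS and downstream of the TES respectively.
    """
    pos = v.pos - 1
    in_intron = in_five = in_three = False
    for g in genes:
        if g.seq_id != v.seq_id:
            continue
        if g.start <= pos < g.end:
            if any(s <= pos < e for s, e in g.exons):
                return GenicContext.EXONIC
            in_intron = True
            continue
        if g.strand == "+":
            if g.start - tss_flank_bp <= pos < g.start:
                in_five = True
            if g.end <= pos < g.end + tss_flank_bp:
                in_three = True
        else:
            if g.end <= pos < g.end + tss_flank_bp:
                in_five = True
            if g.start - tss_flank_bp <= pos < g.start:
                in_three = True
    if in_intron:
        return GenicContext.INTRONIC
    if in_five:
        return GenicContext.FIVE_PRIME
    if in_three:
        return GenicContext.THREE_PRIME
    return GenicContext.INTERGENIC


def pwm_delta(v: Variant, seq: str, pwm: PWM,
              var_offset: Optional[int] = None) -> PwmHit:
    """Best motif-score change caused by substituting the alternate allele.

    Scans every window overlapping the variant on both strands, scores
    log2-odds against the motif background, and returns
    ``max(alt) - max(ref)`` together with the window and strand of the
    overall best-scoring configuration.  SNVs only.
    """
    if not v.is_snv:
        raise ValueError(f"pwm_delta supports SNVs only; {v.id} is an indel")
    if var_offset is None:
        var_offset = len(seq) // 2
    if not (0 <= var_offset < len(seq)):
        raise ValueError("variant offset outside the supplied sequence")
    L = len(pwm)
    genome_start = (v.pos - 1) - var_offset

    def best(allele: str) -> Tuple[float, int, str]:
        subst = seq[:var_offset] + allele + seq[var_offset + 1:]
        top = (float("-inf"), -1, ".")
        for s in range(max(0, var_offset - L + 1),
                       min(len(seq) - L, var_offset) + 1):
            window = subst[s:s + L]
            for strand, oriented in (("+", window),
                                     ("-", reverse_complement(window))):
                score = pwm.log_odds(oriented)
                if score > top[0]:
                    top = (score, s, strand)
        return top

    ref_best = best(v.ref_allele)
    alt_best = best(v.alt_allele)
    if ref_best[1] < 0:                     # no window fits the sequence
        return PwmHit(v.pos - 1, ".", 0.0)
    winner = alt_best if alt_best[0] >= ref_best[0] else ref_best
    return PwmHit(genome_start + winner[1], winner[2],
                  alt_best[0] - ref_best[0])


def allele_bias(v: Variant, seq: str, weights: Dict[str, float], k: int,
                var_offset: Optional[int] = None) -> float:
    """k-mer weight-table allele-bias score (the deltaSVM scoring rule).

    Sums the supplied weights over all k-mers of the (2k-1)-bp window
    centred on the variant with the alternate allele substituted, minus
    the same sum with the reference allele.  Missing k-mers weigh 0.
    Training of the weight table is out of scope; any table (e.g. from a
    published gkm-SVM model) can be supplied.
    """
    if not v.is_snv:
        raise ValueError(f"allele_bias supports SNVs only; {v.id} is an indel")
    if not (1 <= k <= 12):
        raise ValueError("k must be in [1, 12]")
    if var_offset is None:
        var_offset = len(seq) // 2
    lo, hi = var_offset - (k - 1), var_offset + k
    if lo < 0 or hi > len(seq):
        warnings.warn(f"allele-bias window for {v.id} truncated at a "
                      "sequence end", stacklevel=2)
        lo, hi = max(0, lo), min(len(seq), hi)
    center = var_offset - lo

    def window_sum(allele: str) -> float:
        window = seq[lo:var_offset] + allele + seq[var_offset + 1:hi]
        return sum(weights.get(window[i:i + k], 0.0)
                   for i in range(len(window) - k + 1))

    return window_sum(v.alt_allele) - window_sum(v.ref_allele)


# ---------------------------------------------------------------------------
# Hi-C connectivity of the containing element

def _containing_element(v: Variant, tracks: ChromatinTrackSet
                        ) -> GenomicInterval:
    """The DNase element containing the variant, else its own footprint."""
    hits = tracks.dnase.query(v.to_interval())
    if hits:
        return max(hits, key=lambda h: h[2])[0]
    return v.to_interval()


def element_contact_degree(element: GenomicInterval,
                           contacts: Sequence[ContactPair]) -> int:
    """Number of distinct elements the given element touches in Hi-C."""
    partners = set()
    for pair in contacts:
        hit1 = element.overlap_bp(pair.anchor1) > 0
        hit2 = element.overlap_bp(pair.anchor2) > 0
        if hit1 and hit2:
            continue                       # self-loop; uninformative
        if hit1:
            far = pair.anchor2
        elif hit2:
            far = pair.anchor1
        else:
            continue
        partners.add((far.seq_id, far.start, far.end))
    return len(partners)


# ---------------------------------------------------------------------------
# The full checklist

def annotate(v: Variant,
             tracks: ChromatinTrackSet,
             genes: Sequence[GeneModel],
             pwms: Sequence[PWM] = (),
             weights: Optional[Dict[str, float]] = None,
             contacts: Sequence[ContactPair] = (),
             config: Optional[AnnotationConfig] = None,
             sequences: Optional[Dict[str, str]] = None) -> AnnotationReport:
    """Run every annotation criterion for one variant and combine them.

    The causal call is the conjunction: open chromatin AND acceptable
    methylation AND a classified element state AND an allele-bias score
    of magnitude >= ``config.bias_threshold``.  All other criteria are
    recorded as independent evidence.
    """
    config = config or AnnotationConfig()

    if v.seq_id not in tracks.known_sequences():
        logger.warning("variant %s on sequence %s absent from all tracks; "
                       "reporting empty evidence", v.id, v.seq_id)
        return AnnotationReport(variant=v, methylation_ok=False)

    iv = v.to_interval()

    # (1) open chromatin
    open_chromatin = tracks.dnase.overlaps(iv)

    # (2) low-to-moderate methylation of overlapping cytosine records
    methylation_ok = all(level <= config.methylation_max
                         for _, level, _ in tracks.methylation.query(iv))

    # (3) combinatorial histone-mark state
    element_class = classify_element(iv, tracks, config.min_overlap_bp)

    # (3b) genic context
    context = genic_context(v, genes, config.tss_flank_bp)

    # (4) molecular-QTL annotation
    qtl_labels = frozenset(label for _, label, _ in tracks.qtl.query(iv)
                           if label)

    # (4b) ChIP-seq-bound proteins
    bound: set = set()
    for _, proteins, _ in tracks.chip_bound.query(iv):
        if proteins:
            bound.update(proteins)

    # (5) PWM disruption and (9) allele bias need local sequence
    pwm_disruptions: List[Tuple[str, float]] = []
    bias = 0.0
    if sequences is not None and v.seq_id in sequences and v.is_snv:
        seq = sequences[v.seq_id]
        flank = max(config.kmer_k - 1,
                    max((len(p) - 1 for p in pwms), default=0))
        lo = max(0, (v.pos - 1) - flank)
        hi = min(len(seq), v.pos + flank)
        local = seq[lo:hi]
        offset = (v.pos - 1) - lo
        for pwm in pwms:
            hit = pwm_delta(v, local, pwm, var_offset=offset)
            pwm_disruptions.append((pwm.motif_id, hit.delta))
        if weights:
            bias = allele_bias(v, local, weights, config.kmer_k,
                               var_offset=offset)
    elif sequences is None:
        logger.warning("no sequence supplied for %s; PWM and allele-bias "
                       "criteria skipped", v.id)

    # (6) requisite RNA species
    if element_class is ElementClass.ENHANCER:
        rna_consistent = tracks.ernas.overlaps(iv)
    elif element_class is ElementClass.PROMOTER:
        pos = v.pos - 1
        rna_consistent = any(
            g.seq_id == v.seq_id and abs(pos - g.tss) <= config.tss_flank_bp
            for g in genes)
    else:
        rna_consistent = False

    # (7) Hi-C connectivity of the containing element
    hic_degree = (element_contact_degree(_containing_element(v, tracks),
                                         contacts) if contacts else 0)

    causal = (open_chromatin and methylation_ok
              and element_class is not ElementClass.UNCLASSIFIED
              and abs(bias) >= config.bias_threshold)

    return AnnotationReport(
        variant=v,
        open_chromatin=open_chromatin,
        methylation_ok=methylation_ok,
        element_class=element_class,
        genic_context=context,
        qtl_labels=qtl_labels,
        bound_proteins=frozenset(bound),
        pwm_disruptions=tuple(pwm_disruptions),
        rna_consistent=rna_consistent,
        hic_degree=hic_degree,
        allele_bias_score=bias,
        causal_call=causal,
    )


def annotate_all(variants: Sequence[Variant], *args, **kwargs
                 ) -> List[AnnotationReport]:
    return [annotate(v, *args, **kwargs) for v in variants]


def reports_to_frame(reports: Sequence[AnnotationReport]):
    import pandas as pd

    return pd.DataFrame([r.to_row() for r in reports])


def write_reports(reports: Sequence[AnnotationReport], tsv_path: str,
                  json_path: Optional[str] = None) -> None:
    frame = reports_to_frame(reports)
    frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        frame.to_json(json_path, orient="records", indent=2)
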