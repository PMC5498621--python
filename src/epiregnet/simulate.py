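"""Synthetic data with planted, recorded ground truth.

Every input the pipeline consumes can be generated here: a toy genome,
gene models, chromatin feature tracks (DNase, H3K27ac, H3K4me1/3,
super-enhancers, HOT regions, eRNAs), a methylation bedGraph, a variant
set with planted causal variants (motif disruptions plus k-mer allele
bias), a chromatin-contact list with one planted transcriptional hub, a
two-condition expression table with planted differential regulons, a
TF->target edge list, a k-mer weight table, PWMs and GMT gene sets.

The generator emulates the statistical structure the analysis assumes -
co-occurring histone marks at regulatory elements, low methylation in
open chromatin, allele-selective causal variants, a multi-gene contact
hub over background ligation noise, and TF regulons covering a stated
fraction of the differentially expressed genes - not sequence
composition, Hi-C distance decay or microarray probe behaviour.  All
randomness flows from a single seeded generator, so identical configs
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import norm

from . import io as gio
from .annotation import ChromatinTrackSet
from .core import (PWM, ContactPair, ExpressionRecord, GeneModel,
                   GenomicInterval, IntervalSet, Variant)

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Structural defaults mirror the scale of the system the pipeline is
    aimed at: a 12-gene contact hub, HOT regions spanning 19% of the
    genome, 8 super-enhancer-driven master TFs, 3 causal variants among
    100 candidate SNPs, and a planted regulon covering 60% of a
    120-gene differential set within a 2,000-gene universe.
    """

    seed: int = 0
    # genome layout
    n_chromosomes: int = 4
    chrom_length_bp: int = 10_000_000
    # regulatory elements
    n_enhancers: int = 100
    n_promoters: int = 100
    peak_width_bp: int = 1000
    peak_dropout_rate: float = 0.0
    # variants
    n_variants: int = 100
    n_causal_variants: int = 3
    bias_effect_size: float = 4.0
    # contacts
    hub_anchor: Optional[GenomicInterval] = None
    hub_size: int = 12
    n_noise_contacts: int = 1000
    # genes / network
    n_genes: int = 2000
    n_tfs: int = 60
    n_master_tfs: int = 8
    regulon_size_distribution: Tuple = ("uniform", 10, 60)
    de_fraction: float = 0.06
    planted_coverage_fraction: float = 0.6
    log2fc_effect_mean: float = 2.0
    log2fc_effect_sd: float = 0.35
    noise_sd: float = 0.25
    # tracks
    hot_genome_fraction: float = 0.19
    methylation_beta_params: Tuple = ((1.0, 19.0), (2.0, 2.0))
    n_background_methylation_tiles: int = 5000
    methylation_tile_bp: int = 200
    # scoring
    kmer_k: int = 8
    pwm_length: int = 8

    def __post_init__(self) -> None:
        counts = dict(n_chromosomes=self.n_chromosomes,
                      chrom_length_bp=self.chrom_length_bp,
                      n_enhancers=self.n_enhancers,
                      n_promoters=self.n_promoters,
                      peak_width_bp=self.peak_width_bp,
                      n_variants=self.n_variants,
                      hub_size=self.hub_size,
                      n_genes=self.n_genes, n_tfs=self.n_tfs)
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        for name, value in (("peak_dropout_rate", self.peak_dropout_rate),
                            ("de_fraction", self.de_fraction),
                            ("planted_coverage_fraction",
                             self.planted_coverage_fraction),
                            ("hot_genome_fraction", self.hot_genome_fraction)):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_causal_variants > self.n_variants:
            raise ValueError("n_causal_variants exceeds n_variants")
        if self.n_causal_variants > self.n_enhancers + self.n_promoters:
            raise ValueError("n_causal_variants exceeds the number of "
                             "planted elements")
        if self.n_master_tfs > self.n_tfs:
            raise ValueError("n_master_tfs exceeds n_tfs")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs exceeds n_genes")
        if not (1 <= self.kmer_k <= 12):
            raise ValueError("kmer_k must be in [1, 12]")
        slot = self.chrom_length_bp * self.n_chromosomes / self.n_genes
        if slot < 10_000:
            raise ValueError("genome too small for the requested gene count: "
                             "need >= 10 kb per gene slot")

    @property
    def chromosomes(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def genome_bp(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp


@dataclass
class GroundTruth:
    """Planted structure, recorded so every stage can be scored."""

    elements: List[Tuple[GenomicInterval, str]] = field(default_factory=list)
    causal_variant_ids: List[str] = field(default_factory=list)
    hub_anchor: Optional[GenomicInterval] = None
    hub_genes_cis: List[str] = field(default_factory=list)
    hub_genes_trans: List[str] = field(default_factory=list)
    master_tfs: List[str] = field(default_factory=list)
    tf_names: List[str] = field(default_factory=list)
    planted_tf: str = ""
    planted_regulon: List[str] = field(default_factory=list)
    planted_coverage_fraction: float = 0.0
    de_up: List[str] = field(default_factory=list)
    de_down: List[str] = field(default_factory=list)
    hot_fraction_realized: float = 0.0

    @property
    def hub_genes(self) -> List[str]:
        return self.hub_genes_cis + self.hub_genes_trans

    def to_json(self, path: str) -> None:
        def iv(x: Optional[GenomicInterval]):
            if x is None:
                return None
            return {"seq_id": x.seq_id, "start": x.start, "end": x.end,
                    "name": x.name}

        payload = {
            "elements": [{"interval": iv(e), "label": label}
                         for e, label in self.elements],
            "causal_variant_ids": self.causal_variant_ids,
            "hub_anchor": iv(self.hub_anchor),
            "hub_genes_cis": self.hub_genes_cis,
            "hub_genes_trans": self.hub_genes_trans,
            "master_tfs": self.master_tfs,
            "tf_names": self.tf_names,
            "planted_tf": self.planted_tf,
            "planted_regulon": self.planted_regulon,
            "planted_coverage_fraction": self.planted_coverage_fraction,
            "de_up": self.de_up,
            "de_down": self.de_down,
            "hot_fraction_realized": self.hot_fraction_realized,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Sub-generators (each usable on its own; all draw from the passed rng)

def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator) -> Dict[str, str]:
    """Uniform-composition random genome as uppercase strings."""
    genome = {}
    for chrom in config.chromosomes:
        idx = rng.integers(0, 4, size=config.chrom_length_bp)
        genome[chrom] = _BASE_BYTES[idx].tobytes().decode("ascii")
    return genome


def simulate_gene_models(config: SimulationConfig,
                         rng: np.random.Generator) -> List[GeneModel]:
    """Non-overlapping gene models on an even grid with >= 5 kb spacing.

    TF-style names (TF001...) are assigned to a random subset of gene
    slots so TF genes are spread across chromosomes.
    """
    per_chrom = [config.n_genes // config.n_chromosomes]
    per_chrom *= config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    tf_slots = set(rng.choice(config.n_genes, size=config.n_tfs,
                              replace=False).tolist())
    genes: List[GeneModel] = []
    slot_index = 0
    tf_counter = 0
    gene_counter = 0
    for chrom, count in zip(config.chromosomes, per_chrom):
        slot_w = config.chrom_length_bp // count
        for j in range(count):
            length = int(rng.integers(1500, 3001))
            margin_lo = 2500
            margin_hi = slot_w - length - 2500
            start = j * slot_w + int(rng.integers(margin_lo, margin_hi))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            edges = np.linspace(start, end, n_exons + 1).astype(int)
            exons = []
            for k in range(n_exons):
                seg_lo, seg_hi = int(edges[k]), int(edges[k + 1])
                ex_start = seg_lo if k == 0 else int(
                    rng.integers(seg_lo, seg_hi - 100))
                ex_end = seg_hi if k == n_exons - 1 else int(
                    rng.integers(ex_start + 50, seg_hi))
                exons.append((ex_start, ex_end))
            if slot_index in tf_slots:
                tf_counter += 1
                name = f"TF{tf_counter:03d}"
            else:
                gene_counter += 1
                name = f"G{gene_counter:05d}"
            genes.append(GeneModel(chrom, start, end, strand, name,
                                   tuple(exons)))
            slot_index += 1
    return genes


def _jitter(rng: np.random.Generator, span: int = 50) -> int:
    return int(rng.integers(-span, span + 1))


def simulate_chromatin(config: SimulationConfig,
                       genes: Sequence[GeneModel],
                       master_tfs: Sequence[str],
                       rng: np.random.Generator):
    """Chromatin tracks with planted enhancer/promoter elements.

    Each element carries a DNase peak, low methylation tiles, and the
    defining histone-mark pair; each histone mark is dropped
    independently with ``peak_dropout_rate`` (DNase and methylation stay
    noise-free so dropout acts only on the combinatorial state calls).
    Super-enhancers are placed over the master-TF gene bodies; HOT
    regions tile a fixed fraction of the genome exactly.

    Returns (track lists dict, elements ground truth, realized hot fraction).
    """
    w = config.peak_width_bp
    elements: List[Tuple[GenomicInterval, str]] = []
    placed = IntervalSet()

    # promoters sit at TSSs of randomly chosen genes
    promoter_genes = rng.choice(len(genes), size=config.n_promoters,
                                replace=False)
    for i in sorted(promoter_genes.tolist()):
        g = genes[i]
        start = max(0, g.tss - w // 2)
        iv = GenomicInterval(g.seq_id, start, start + w,
                             name=f"prom_{g.name}")
        elements.append((iv, "promoter"))
        placed.add(iv)

    # enhancers land anywhere that does not collide with another element
    n_placed = 0
    while n_placed < config.n_enhancers:
        chrom = config.chromosomes[int(rng.integers(config.n_chromosomes))]
        start = int(rng.integers(w, config.chrom_length_bp - 2 * w))
        iv = GenomicInterval(chrom, start, start + w,
                             name=f"enh_{n_placed + 1:04d}")
        if placed.overlaps(GenomicInterval(chrom, start - w, start + 2 * w)):
            continue
        elements.append((iv, "enhancer"))
        placed.add(iv)
        n_placed += 1

    tracks: Dict[str, list] = {
        "dnase": [], "h3k27ac": [], "h3k4me1": [], "h3k4me3": [],
        "ernas": [], "super_enhancers": [], "hot_regions": [],
        "methylation": [], "qtl": [], "chip_bound": [],
    }
    d = config.peak_dropout_rate
    el_beta, bg_beta = config.methylation_beta_params
    tile = config.methylation_tile_bp
    chip_proteins = np.array(["CTCF", "EP300", "POLR2A", "REST", "RAD21"])

    for iv, label in elements:
        tracks["dnase"].append(iv)
        if rng.random() >= d:
            tracks["h3k27ac"].append(
                GenomicInterval(iv.seq_id, max(0, iv.start + _jitter(rng)),
                                iv.end + _jitter(rng) + 1,
                                name=f"k27ac_{iv.name}"))
        second = "h3k4me1" if label == "enhancer" else "h3k4me3"
        if rng.random() >= d:
            tracks[second].append(
                GenomicInterval(iv.seq_id, max(0, iv.start + _jitter(rng)),
                                iv.end + _jitter(rng) + 1,
                                name=f"{second}_{iv.name}"))
        if label == "enhancer":
            tracks["ernas"].append(
                GenomicInterval(iv.seq_id, iv.start, iv.end,
                                name=f"eRNA_{iv.name}"))
        for tstart in range(iv.start, iv.end, tile):
            level = float(rng.beta(*el_beta))
            tracks["methylation"].append(
                (GenomicInterval(iv.seq_id, tstart,
                                 min(iv.end, tstart + tile)), level))
        if rng.random() < 0.3:
            tracks["qtl"].append((iv, "eQTL" if rng.random() < 0.7
                                  else "hQTL"))
        if rng.random() < 0.4:
            picks = rng.choice(len(chip_proteins),
                               size=int(rng.integers(1, 4)), replace=False)
            tracks["chip_bound"].append(
                (iv, frozenset(chip_proteins[picks].tolist())))

    # background methylation tiles away from elements
    n_bg = 0
    while n_bg < config.n_background_methylation_tiles:
        chrom = config.chromosomes[int(rng.integers(config.n_chromosomes))]
        start = int(rng.integers(0, config.chrom_length_bp - tile))
        iv = GenomicInterval(chrom, start, start + tile)
        if placed.overlaps(iv):
            continue
        tracks["methylation"].append((iv, float(rng.beta(*bg_beta))))
        n_bg += 1

    # super-enhancers over master-TF gene bodies
    by_name = {g.name: g for g in genes}
    for tf in master_tfs:
        g = by_name[tf]
        tracks["super_enhancers"].append(
            GenomicInterval(g.seq_id, max(0, g.start - 1000), g.end + 1000,
                            name=f"SE_{tf}"))

    # HOT regions: non-overlapping blocks covering the target fraction
    block = 100_000
    needed = int(round(config.hot_genome_fraction * config.genome_bp))
    n_blocks = max(0, needed // block)
    tiles_per_chrom = config.chrom_length_bp // block
    all_tiles = [(c, t) for c in config.chromosomes
                 for t in range(tiles_per_chrom)]
    chosen = rng.choice(len(all_tiles), size=min(n_blocks, len(all_tiles)),
                        replace=False)
    covered = 0
    for idx in sorted(chosen.tolist()):
        chrom, t = all_tiles[idx]
        tracks["hot_regions"].append(
            GenomicInterval(chrom, t * block, (t + 1) * block,
                            name=f"HOT_{chrom}_{t}"))
        covered += block
    remainder = needed - covered
    if remainder > 0:
        free = sorted(set(range(tiles_per_chrom))
                      - {t for c, t in (all_tiles[i] for i in chosen.tolist())
                         if c == config.chromosomes[0]})
        if free:
            t = free[0]
            tracks["hot_regions"].append(
                GenomicInterval(config.chromosomes[0], t * block,
                                t * block + remainder, name="HOT_remainder"))
            covered += remainder
    realized = covered / config.genome_bp
    return tracks, elements, realized


def build_trackset(tracks: Dict[str, list]) -> ChromatinTrackSet:
    """Assemble generator track lists into an indexed ChromatinTrackSet."""
    ts = ChromatinTrackSet()
    for name in ("dnase", "h3k27ac", "h3k4me1", "h3k4me3", "ernas",
                 "super_enhancers", "hot_regions"):
        for iv in tracks.get(name, []):
            getattr(ts, name).add(iv)
    for iv, level in tracks.get("methylation", []):
        ts.methylation.add(iv, level)
    for iv, label in tracks.get("qtl", []):
        ts.qtl.add(iv, label)
    for iv, proteins in tracks.get("chip_bound", []):
        ts.chip_bound.add(iv, proteins)
    return ts


def _window_kmers(seq: str, center: int, allele: str, k: int) -> List[str]:
    lo, hi = center - (k - 1), center + k
    window = seq[lo:center] + allele + seq[center + 1:hi]
    return [window[i:i + k] for i in range(len(window) - k + 1)]


def simulate_variants(config: SimulationConfig,
                      genome: Dict[str, str],
                      elements: Sequence[Tuple[GenomicInterval, str]],
                      rng: np.random.Generator):
    """Candidate variants: causal ones inside planted elements, decoys outside.

    Causal variants receive a planted allele bias: weights are assigned
    to the k-mers introduced by the alternate allele (restricted to
    k-mers absent from every reference window, so the planted bias is
    exact), summing to ±``bias_effect_size``.  A consensus PWM over each
    causal reference window plants a motif disruption.  Decoy variants
    avoid every element.

    Returns (variants, weights, pwms, causal_ids).
    """
    k = config.kmer_k
    element_index = IntervalSet(iv for iv, _ in elements)
    n_causal = config.n_causal_variants

    chosen = rng.choice(len(elements), size=n_causal, replace=False)
    positions: List[Tuple[str, int]] = []
    for idx in chosen.tolist():
        iv, _ = elements[idx]
        positions.append((iv.seq_id, (iv.start + iv.end) // 2))

    n_decoys = config.n_variants - n_causal
    placed = 0
    while placed < n_decoys:
        chrom = config.chromosomes[int(rng.integers(config.n_chromosomes))]
        pos = int(rng.integers(k, config.chrom_length_bp - k))
        if element_index.contains_point(chrom, pos):
            continue
        positions.append((chrom, pos))
        placed += 1

    variants: List[Variant] = []
    for i, (chrom, pos) in enumerate(positions):
        ref = genome[chrom][pos]
        alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        variants.append(Variant(chrom, pos + 1, ref, alt,
                                id=f"rs{900000 + i:07d}"))
    causal_ids = [v.id for v in variants[:n_causal]]

    # every reference-window k-mer, over all variants, is off limits for
    # planted weights, so reference windows always sum to zero
    ref_kmers: Set[str] = set()
    for v in variants:
        ref_kmers.update(_window_kmers(genome[v.seq_id], v.pos - 1,
                                       v.ref_allele, k))

    weights: Dict[str, float] = {}
    for v in variants[:n_causal]:
        alt_kmers = [m for m in _window_kmers(genome[v.seq_id], v.pos - 1,
                                              v.alt_allele, k)
                     if m not in ref_kmers]
        if not alt_kmers:          # pathological repeat context
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        w = sign * config.bias_effect_size / len(alt_kmers)
        for m in alt_kmers:
            weights[m] = weights.get(m, 0.0) + w

    # small random background weights on k-mers outside all variant windows
    all_variant_kmers = set(ref_kmers)
    for v in variants:
        all_variant_kmers.update(_window_kmers(genome[v.seq_id], v.pos - 1,
                                               v.alt_allele, k))
    n_noise = 0
    while n_noise < 200:
        m = "".join(_BASES[j] for j in rng.integers(0, 4, size=k))
        if m in all_variant_kmers or m in weights:
            continue
        weights[m] = float(rng.normal(0.0, 0.05))
        n_noise += 1

    # planted motif disruptions: consensus PWM over each causal ref window
    pwms: List[PWM] = []
    L = config.pwm_length
    for i, v in enumerate(variants[:n_causal]):
        offset = int(rng.integers(0, L))
        start = (v.pos - 1) - offset
        window = genome[v.seq_id][start:start + L]
        counts = np.ones((L, 4))
        for j, base in enumerate(window):
            counts[j, _BASES.index(base)] = 17.0
        pwms.append(PWM.from_counts(f"planted_motif_{i + 1}", counts))
    for i in range(2):
        counts = rng.integers(0, 20, size=(L, 4)).astype(float)
        pwms.append(PWM.from_counts(f"background_motif_{i + 1}", counts))

    return variants, weights, pwms, causal_ids


def simulate_contacts(config: SimulationConfig,
                      genes: Sequence[GeneModel],
                      elements: Sequence[Tuple[GenomicInterval, str]],
                      rng: np.random.Generator):
    """Planted contact hub plus uniform background ligation noise.

    The anchor is a planted promoter element (or ``config.hub_anchor``).
    Hub contacts link the anchor to windows inside the bodies of
    ``hub_size`` genes drawn genome-wide (a cis/trans mixture follows
    from chromosome assignment).  Noise pairs avoid the anchor, so the
    planted hub is exactly recoverable by construction.

    Returns (contacts, anchor, cis gene names, trans gene names).
    """
    anchor = config.hub_anchor
    if anchor is None:
        promoters = [iv for iv, label in elements if label == "promoter"]
        if not promoters:
            raise ValueError("no promoter elements available for the hub "
                             "anchor; supply config.hub_anchor")
        anchor = promoters[int(rng.integers(len(promoters)))]

    eligible = [g for g in genes
                if g.seq_id != anchor.seq_id
                or min(abs(g.start - anchor.end),
                       abs(anchor.start - g.end)) > 50_000]
    picks = rng.choice(len(eligible), size=config.hub_size, replace=False)
    hub_genes = [eligible[i] for i in sorted(picks.tolist())]

    contacts: List[ContactPair] = []
    for g in hub_genes:
        w = min(1500, len(g.body) - 1)
        start = g.start + int(rng.integers(0, len(g.body) - w))
        far = GenomicInterval(g.seq_id, start, start + w)
        contacts.append(ContactPair.make(anchor, far,
                                         int(rng.integers(2, 11))))

    n_noise = 0
    while n_noise < config.n_noise_contacts:
        ends = []
        for _ in range(2):
            chrom = config.chromosomes[int(rng.integers(config.n_chromosomes))]
            start = int(rng.integers(0, config.chrom_length_bp - 2000))
            ends.append(GenomicInterval(chrom, start,
                                        start + int(rng.integers(500, 2000))))
        if (anchor.overlap_bp(ends[0]) or anchor.overlap_bp(ends[1])
                or ends[0].overlap_bp(ends[1])):
            continue
        contacts.append(ContactPair.make(ends[0], ends[1],
                                         int(rng.integers(1, 6))))
        n_noise += 1

    order = rng.permutation(len(contacts))
    contacts = [contacts[i] for i in order]
    cis = sorted(g.name for g in hub_genes if g.seq_id == anchor.seq_id)
    trans = sorted(g.name for g in hub_genes if g.seq_id != anchor.seq_id)
    return contacts, anchor, cis, trans


def simulate_expression(config: SimulationConfig,
                        genes: Sequence[GeneModel],
                        rng: np.random.Generator):
    """Two-condition expression table with planted DE genes.

    DE genes draw log2 fold-changes from ±Normal(effect_mean, effect_sd);
    all others from Normal(0, noise_sd).  P-values come from the same
    effect model (one-sample z against noise_sd), so thresholding acts
    consistently with the planted effects.

    Returns (records, up gene names, down gene names).
    """
    names = [g.name for g in genes]
    n_de = int(round(config.de_fraction * len(names)))
    de_idx = rng.choice(len(names), size=n_de, replace=False)
    de_set = {names[i] for i in de_idx.tolist()}
    up, down = set(), set()
    records: List[ExpressionRecord] = []
    for name in names:
        if name in de_set:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * rng.normal(config.log2fc_effect_mean,
                                    config.log2fc_effect_sd)
            (up if sign > 0 else down).add(name)
        else:
            lfc = rng.normal(0.0, config.noise_sd)
        p = 2.0 * float(norm.sf(abs(lfc) / config.noise_sd))
        p = min(1.0, max(p, 5e-324))
        records.append(ExpressionRecord(name, float(lfc), p))
    return records, sorted(up), sorted(down)


def simulate_regulons(config: SimulationConfig,
                      genes: Sequence[GeneModel],
                      de_up: Sequence[str],
                      de_down: Sequence[str],
                      rng: np.random.Generator):
    """TF->target edge list with one planted high-coverage regulon.

    The planted TF targets ``planted_coverage_fraction`` of the DE genes
    plus a smaller draw of non-DE genes; remaining TFs receive regulons
    of sizes from ``regulon_size_distribution`` drawn uniformly over all
    genes.

    Returns (edges, planted tf name, planted regulon gene list).
    """
    names = [g.name for g in genes]
    tf_names = sorted(n for n in names if n.startswith("TF"))
    planted_tf = tf_names[0]
    de_genes = sorted(set(de_up) | set(de_down))
    non_de = sorted(set(names) - set(de_genes) - {planted_tf})

    n_de_targets = int(round(config.planted_coverage_fraction * len(de_genes)))
    de_targets = [de_genes[i] for i in sorted(
        rng.choice(len(de_genes), size=n_de_targets, replace=False).tolist())]
    n_bg_targets = int(round(0.35 * max(1, n_de_targets)))
    bg_targets = [non_de[i] for i in sorted(
        rng.choice(len(non_de), size=min(n_bg_targets, len(non_de)),
                   replace=False).tolist())]
    regulon = [t for t in de_targets + bg_targets if t != planted_tf]

    edges: Dict[Tuple[str, str], str] = {}
    for target in regulon:
        edges[(planted_tf, target)] = "+" if rng.random() < 0.7 else "-"

    kind, lo, hi = config.regulon_size_distribution
    for tf in tf_names[1:]:
        if kind == "uniform":
            size = int(rng.integers(int(lo), int(hi) + 1))
        elif kind == "lognormal":
            size = max(1, int(rng.lognormal(float(lo), float(hi))))
        else:
            raise ValueError(f"unknown regulon size distribution {kind!r}")
        size = min(size, len(names) - 1)
        picks = rng.choice(len(names), size=size, replace=False)
        for i in picks.tolist():
            if names[i] == tf:
                continue
            edges.setdefault((tf, names[i]),
                             "+" if rng.random() < 0.5 else "-")
    edge_list = [(tf, target, sign)
                 for (tf, target), sign in sorted(edges.items())]
    return edge_list, planted_tf, regulon


# ---------------------------------------------------------------------------
# Bundles

@dataclass
class SimulatedData:
    """In-memory bundle of every generated input plus its ground truth."""

    config: SimulationConfig
    genome: Dict[str, str]
    genes: List[GeneModel]
    tracks: ChromatinTrackSet
    track_lists: Dict[str, list]
    variants: List[Variant]
    kmer_weights: Dict[str, float]
    pwms: List[PWM]
    contacts: List[ContactPair]
    expression: List[ExpressionRecord]
    edges: List[Tuple[str, str, str]]
    gene_sets: Dict[str, set]
    truth: GroundTruth

    @property
    def gene_models(self) -> Dict[str, GeneModel]:
        return {g.name: g for g in self.genes}


def simulate(config: SimulationConfig) -> SimulatedData:
    """Run every sub-generator under one seeded stream."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    genes = simulate_gene_models(config, rng)
    tf_names = sorted(g.name for g in genes if g.name.startswith("TF"))
    master_idx = rng.choice(len(tf_names), size=config.n_master_tfs,
                            replace=False)
    master_tfs = sorted(tf_names[i] for i in master_idx.tolist())

    track_lists, elements, hot_realized = simulate_chromatin(
        config, genes, master_tfs, rng)
    variants, weights, pwms, causal_ids = simulate_variants(
        config, genome, elements, rng)
    contacts, anchor, hub_cis, hub_trans = simulate_contacts(
        config, genes, elements, rng)
    expression, de_up, de_down = simulate_expression(config, genes, rng)
    edges, planted_tf, regulon = simulate_regulons(
        config, genes, de_up, de_down, rng)

    gene_sets = {
        "planted_regulon": set(regulon),
        "de_up": set(de_up),
        "de_down": set(de_down),
        "hub_genes": set(hub_cis) | set(hub_trans),
        "master_tfs": set(master_tfs),
    }
    truth = GroundTruth(
        elements=elements,
        causal_variant_ids=causal_ids,
        hub_anchor=anchor,
        hub_genes_cis=hub_cis,
        hub_genes_trans=hub_trans,
        master_tfs=master_tfs,
        tf_names=tf_names,
        planted_tf=planted_tf,
        planted_regulon=regulon,
        planted_coverage_fraction=config.planted_coverage_fraction,
        de_up=de_up,
        de_down=de_down,
        hot_fraction_realized=hot_realized,
    )
    return SimulatedData(
        config=config, genome=genome, genes=genes,
        tracks=build_trackset(track_lists), track_lists=track_lists,
        variants=variants, kmer_weights=weights, pwms=pwms,
        contacts=contacts, expression=expression, edges=edges,
        gene_sets=gene_sets, truth=truth)


def generate_all(config: SimulationConfig, outdir: str
                 ) -> Tuple[Dict[str, str], GroundTruth]:
    """Generate the full bundle and write every file format.

    Returns (manifest, ground truth); the manifest (also written as
    ``manifest.json``) maps logical input names to file paths.
    """
    data = simulate(config)
    os.makedirs(outdir, exist_ok=True)
    tag = f"epiregnet synthetic fixture seed={config.seed}"

    paths = {name: os.path.join(outdir, fname) for name, fname in {
        "genome": "genome.fa", "genes": "genes.bed",
        "dnase": "dnase.bed", "h3k27ac": "h3k27ac.bed",
        "h3k4me1": "h3k4me1.bed", "h3k4me3": "h3k4me3.bed",
        "ernas": "ernas.bed", "super_enhancers": "super_enhancers.bed",
        "hot_regions": "hot_regions.bed",
        "methylation": "methylation.bedgraph",
        "qtl": "qtl.bed", "chip_bound": "chip_bound.bed",
        "variants": "variants.vcf", "contacts": "contacts.bedpe",
        "expression": "expression.tsv", "edges": "edges.tsv",
        "kmer_weights": "kmer_weights.tsv", "pwms": "pwms.txt",
        "gene_sets": "gene_sets.gmt",
        "ground_truth": "ground_truth.json",
        "manifest": "manifest.json",
    }.items()}

    gio.write_fasta(paths["genome"], data.genome)
    gio.write_genes(paths["genes"], data.genes, header=tag)
    for name in ("dnase", "h3k27ac", "h3k4me1", "h3k4me3", "ernas",
                 "super_enhancers", "hot_regions"):
        gio.write_bed(paths[name], data.track_lists[name], header=tag)
    gio.write_bedgraph(paths["methylation"], data.track_lists["methylation"],
                       header=tag)
    gio.write_bed(paths["qtl"],
                  [GenomicInterval(iv.seq_id, iv.start, iv.end, iv.strand,
                                   label)
                   for iv, label in data.track_lists["qtl"]], header=tag)
    gio.write_bed(paths["chip_bound"],
                  [GenomicInterval(iv.seq_id, iv.start, iv.end, iv.strand,
                                   ",".join(sorted(proteins)))
                   for iv, proteins in data.track_lists["chip_bound"]],
                  header=tag)
    gio.write_variants(paths["variants"], data.variants, header=tag)
    gio.write_contacts(paths["contacts"], data.contacts, header=tag)
    gio.write_expression(paths["expression"], data.expression, header=tag)
    gio.write_edges(paths["edges"], data.edges, header=tag)
    gio.write_kmer_weights(paths["kmer_weights"], data.kmer_weights,
                           header=tag)
    gio.write_pwm(paths["pwms"], data.pwms, header=tag)
    gio.write_gene_sets(paths["gene_sets"], data.gene_sets, header=tag)
    data.truth.to_json(paths["ground_truth"])

    manifest = {"seed": config.seed,
                "config": dataclasses.asdict(
                    dataclasses.replace(config, hub_anchor=None)),
                "files": {k: os.path.abspath(v) for k, v in paths.items()
                          if k != "manifest"}}
    if config.hub_anchor is not None:
        manifest["hub_anchor"] = {
            "seq_id": config.hub_anchor.seq_id,
            "start": config.hub_anchor.start, "end": config.hub_anchor.end}
    with open(paths["manifest"], "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest, data.truth
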