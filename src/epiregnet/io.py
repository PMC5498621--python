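"""Readers and writers for the text formats the pipeline consumes.

Supported formats: BED3/BED6/BED12, sites-only VCF, BEDPE, bedGraph,
GMT, header-carrying TSV (expression tables and TF->target edge lists),
a minimal MEME-like PWM count-matrix text, k-mer weight tables and FASTA.

Coordinate conventions are enforced at this boundary: BED-family files
are 0-based half-open, VCF positions are 1-based.  Every reader raises
``FormatError`` naming the offending line; every writer emits files the
corresponding reader round-trips exactly (up to whitespace
normalisation).
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .core import (DNA_ALPHABET, PWM, ContactPair, ExpressionRecord,
                   GeneModel, GenomicInterval, Variant)


class FormatError(ValueError):
    """A malformed record; the message names the file and line number."""


def _records(path: str, comment_prefixes: Tuple[str, ...] = ("#",),
             skip_tokens: Tuple[str, ...] = ("track", "browser")):
    """Yield (line_number, fields) for data lines of a whitespace-delimited file."""
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if any(line.startswith(p) for p in comment_prefixes):
                continue
            first = line.split(None, 1)[0]
            if first in skip_tokens:
                continue
            yield lineno, line.split()


def _err(path: str, lineno: int, message: str) -> FormatError:
    return FormatError(f"{os.path.basename(path)}, line {lineno}: {message}")


def _parse_int(path: str, lineno: int, token: str, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise _err(path, lineno, f"non-integer {what}: {token!r}") from None


# ---------------------------------------------------------------------------
# BED family

def read_bed(path: str) -> List[GenomicInterval]:
    """Parse BED3/BED6 into intervals, preserving file order."""
    out = []
    for lineno, fields in _records(path):
        if len(fields) < 3:
            raise _err(path, lineno, f"expected >= 3 columns, got {len(fields)}")
        start = _parse_int(path, lineno, fields[1], "start")
        end = _parse_int(path, lineno, fields[2], "end")
        if start >= end or start < 0:
            raise _err(path, lineno,
                       f"invalid coordinates [{start}, {end}): require "
                       "0 <= start < end")
        name = fields[3] if len(fields) > 3 else ""
        strand = fields[5] if len(fields) > 5 else "."
        if strand not in ("+", "-", "."):
            raise _err(path, lineno, f"invalid strand {strand!r}")
        out.append(GenomicInterval(fields[0], start, end, strand, name))
    return out


def write_bed(path: str, intervals: Iterable[GenomicInterval],
              header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for iv in intervals:
            handle.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t"
                         f"{iv.name or '.'}\t0\t{iv.strand}\n")


def read_genes(path: str) -> List[GeneModel]:
    """Parse gene models from BED12 (exon blocks) or BED6 (single-exon)."""
    out = []
    for lineno, fields in _records(path):
        if len(fields) < 6:
            raise _err(path, lineno, "gene models need >= 6 BED columns")
        start = _parse_int(path, lineno, fields[1], "start")
        end = _parse_int(path, lineno, fields[2], "end")
        if start >= end or start < 0:
            raise _err(path, lineno, f"invalid coordinates [{start}, {end})")
        name, strand = fields[3], fields[5]
        if strand not in ("+", "-"):
            raise _err(path, lineno, f"gene strand must be +/-, got {strand!r}")
        if len(fields) >= 12:
            n_blocks = _parse_int(path, lineno, fields[9], "blockCount")
            sizes = [_parse_int(path, lineno, t, "blockSizes")
                     for t in fields[10].rstrip(",").split(",")]
            offsets = [_parse_int(path, lineno, t, "blockStarts")
                       for t in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise _err(path, lineno, "blockCount disagrees with block lists")
            exons = tuple((start + o, start + o + s)
                          for o, s in zip(offsets, sizes))
        else:
            exons = ((start, end),)
        try:
            out.append(GeneModel(fields[0], start, end, strand, name, exons))
        except ValueError as exc:
            raise _err(path, lineno, str(exc)) from None
    return out


def write_genes(path: str, genes: Iterable[GeneModel],
                header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, e in g.exons)
            handle.write(
                f"{g.seq_id}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n")


def read_bedgraph(path: str) -> List[Tuple[GenomicInterval, float]]:
    """bedGraph with the 4th column interpreted as a methylation level in [0, 1]."""
    out = []
    for lineno, fields in _records(path):
        if len(fields) < 4:
            raise _err(path, lineno, "bedGraph needs 4 columns")
        start = _parse_int(path, lineno, fields[1], "start")
        end = _parse_int(path, lineno, fields[2], "end")
        if start >= end or start < 0:
            raise _err(path, lineno, f"invalid coordinates [{start}, {end})")
        try:
            level = float(fields[3])
        except ValueError:
            raise _err(path, lineno, f"non-numeric level {fields[3]!r}") from None
        if not (0.0 <= level <= 1.0):
            raise _err(path, lineno, f"methylation level {level} outside [0, 1]")
        out.append((GenomicInterval(fields[0], start, end), level))
    return out


def write_bedgraph(path: str, records: Iterable[Tuple[GenomicInterval, float]],
                   header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for iv, level in records:
            handle.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{level:.6g}\n")


# ---------------------------------------------------------------------------
# Variants (sites-only VCF subset)

def read_variants(path: str) -> List[Variant]:
    """Sites-only VCF: CHROM POS ID REF ALT; multiallelic records expanded."""
    out = []
    for lineno, fields in _records(path, comment_prefixes=("#",),
                                   skip_tokens=()):
        if len(fields) < 5:
            raise _err(path, lineno,
                       "expected CHROM POS ID REF ALT (>= 5 columns), got "
                       f"{len(fields)}")
        pos = _parse_int(path, lineno, fields[1], "POS")
        ref = fields[3].upper()
        if not set(ref) <= DNA_ALPHABET:
            raise _err(path, lineno, f"REF allele {fields[3]!r} is not A/C/G/T")
        for alt in fields[4].split(","):
            alt = alt.upper()
            if not alt or not set(alt) <= DNA_ALPHABET:
                raise _err(path, lineno,
                           f"ALT allele {alt!r} is not A/C/G/T")
            try:
                out.append(Variant(fields[0], pos, ref, alt, fields[2]))
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from None
    return out


def write_variants(path: str, variants: Iterable[Variant],
                   header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        if header:
            handle.write(f"##source={header}\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            handle.write(f"{v.seq_id}\t{v.pos}\t{v.id}\t{v.ref_allele}\t"
                         f"{v.alt_allele}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Contacts (BEDPE)

def read_contacts(path: str) -> List[ContactPair]:
    """BEDPE with a 7th column holding the contact count."""
    out = []
    for lineno, fields in _records(path):
        if len(fields) < 7:
            raise _err(path, lineno, "BEDPE needs 6 coordinates + count")
        coords = [_parse_int(path, lineno, fields[i], f"column {i + 1}")
                  for i in (1, 2, 4, 5)]
        count = _parse_int(path, lineno, fields[6], "count")
        if count < 1:
            raise _err(path, lineno, f"count must be >= 1, got {count}")
        try:
            a = GenomicInterval(fields[0], coords[0], coords[1])
            b = GenomicInterval(fields[3], coords[2], coords[3])
        except ValueError as exc:
            raise _err(path, lineno, str(exc)) from None
        out.append(ContactPair.make(a, b, count))
    return out


def write_contacts(path: str, contacts: Iterable[ContactPair],
                   header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for c in contacts:
            handle.write(
                f"{c.anchor1.seq_id}\t{c.anchor1.start}\t{c.anchor1.end}\t"
                f"{c.anchor2.seq_id}\t{c.anchor2.start}\t{c.anchor2.end}\t"
                f"{c.count}\n")


# ---------------------------------------------------------------------------
# Expression and edge TSVs

def read_expression(path: str) -> List[ExpressionRecord]:
    """TSV with a header row containing gene, log2fc, pvalue columns."""
    out = []
    header = None
    for lineno, fields in _records(path):
        if header is None:
            header = [f.lower() for f in fields]
            for col in ("gene", "log2fc", "pvalue"):
                if col not in header:
                    raise _err(path, lineno, f"missing column {col!r} in header")
            idx = {c: header.index(c) for c in ("gene", "log2fc", "pvalue")}
            continue
        try:
            out.append(ExpressionRecord(fields[idx["gene"]],
                                        float(fields[idx["log2fc"]]),
                                        float(fields[idx["pvalue"]])))
        except (ValueError, IndexError) as exc:
            raise _err(path, lineno, str(exc)) from None
    if header is None:
        raise FormatError(f"{os.path.basename(path)}: empty expression table")
    return out


def write_expression(path: str, records: Iterable[ExpressionRecord],
                     header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        handle.write("gene\tlog2fc\tpvalue\n")
        for r in records:
            handle.write(f"{r.gene}\t{r.log2fc:.17g}\t{r.pvalue:.17g}\n")


def read_edges(path: str) -> List[Tuple[str, str, str]]:
    """TF->target edge list: TSV with tf, target, sign columns."""
    out = []
    header = None
    for lineno, fields in _records(path):
        if header is None:
            header = [f.lower() for f in fields]
            for col in ("tf", "target", "sign"):
                if col not in header:
                    raise _err(path, lineno, f"missing column {col!r} in header")
            idx = {c: header.index(c) for c in ("tf", "target", "sign")}
            continue
        try:
            tf, target, sign = (fields[idx["tf"]], fields[idx["target"]],
                                fields[idx["sign"]])
        except IndexError:
            raise _err(path, lineno, "short edge record") from None
        if sign not in ("+", "-", "."):
            raise _err(path, lineno, f"edge sign must be +/-/. , got {sign!r}")
        out.append((tf, target, sign))
    if header is None:
        raise FormatError(f"{os.path.basename(path)}: empty edge list")
    return out


def write_edges(path: str, edges: Iterable[Tuple[str, str, str]],
                header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        handle.write("tf\ttarget\tsign\n")
        for tf, target, sign in edges:
            handle.write(f"{tf}\t{target}\t{sign}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)

def read_gene_sets(path: str) -> Dict[str, set]:
    out: Dict[str, set] = {}
    for lineno, fields in _records(path):
        if len(fields) < 2:
            raise _err(path, lineno, "GMT line needs name, description, genes")
        out[fields[0]] = set(fields[2:])
    return out


def write_gene_sets(path: str, sets: Dict[str, Iterable[str]],
                    header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for name, genes in sets.items():
            genes = "\t".join(sorted(genes))
            handle.write(f"{name}\tna\t{genes}\n" if genes else f"{name}\tna\n")


# ---------------------------------------------------------------------------
# PWMs (minimal MEME-like count/probability matrices)

def read_pwm(path: str, pseudocount: float = 0.5) -> List[PWM]:
    """Parse motifs introduced by ``MOTIF <id>`` lines.

    Each motif holds L rows of 4 numbers (A C G T).  Integer rows are
    treated as counts and normalised with ``pseudocount``; rows already
    summing to ~1 are taken as probabilities verbatim.  An optional
    ``BACKGROUND a c g t`` line overrides the uniform background.
    """
    motifs: List[PWM] = []
    motif_id = None
    rows: List[List[float]] = []
    background = None

    def flush(lineno: int) -> None:
        nonlocal motif_id, rows, background
        if motif_id is None:
            return
        if not rows:
            raise _err(path, lineno, f"motif {motif_id} has no matrix rows")
        matrix = np.array(rows, dtype=float)
        bg = np.full(4, 0.25) if background is None else np.array(background)
        try:
            if np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
                motifs.append(PWM(motif_id, matrix, bg))
            else:
                motifs.append(PWM.from_counts(motif_id, matrix, bg,
                                              pseudocount=pseudocount))
        except ValueError as exc:
            raise _err(path, lineno, str(exc)) from None
        motif_id, rows, background = None, [], None

    last = 0
    for lineno, fields in _records(path):
        last = lineno
        if fields[0].upper() == "MOTIF":
            flush(lineno)
            if len(fields) < 2:
                raise _err(path, lineno, "MOTIF line lacks an identifier")
            motif_id = fields[1]
        elif fields[0].upper() in ("BACKGROUND", "BACKGROUND:"):
            background = [float(t) for t in fields[1:5]]
        else:
            if motif_id is None:
                raise _err(path, lineno, "matrix row before any MOTIF line")
            if len(fields) != 4:
                raise _err(path, lineno,
                           f"expected 4 columns (A C G T), got {len(fields)}")
            try:
                rows.append([float(t) for t in fields])
            except ValueError:
                raise _err(path, lineno, "non-numeric matrix entry") from None
    flush(last)
    return motifs


def write_pwm(path: str, pwms: Iterable[PWM],
              header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for pwm in pwms:
            handle.write(f"MOTIF {pwm.motif_id}\n")
            handle.write("BACKGROUND "
                         + " ".join(f"{b:.17g}" for b in pwm.background) + "\n")
            for row in pwm.matrix:
                handle.write(" ".join(f"{p:.17g}" for p in row) + "\n")


# ---------------------------------------------------------------------------
# k-mer weight tables

def read_kmer_weights(path: str) -> Dict[str, float]:
    """Two-column TSV (kmer, weight); absent k-mers default to weight 0."""
    out: Dict[str, float] = {}
    header = None
    for lineno, fields in _records(path):
        if header is None and fields[0].lower() == "kmer":
            header = fields
            continue
        header = header or ["kmer", "weight"]
        if len(fields) < 2:
            raise _err(path, lineno, "weight table needs kmer and weight")
        kmer = fields[0].upper()
        if not set(kmer) <= DNA_ALPHABET:
            raise _err(path, lineno, f"invalid k-mer {fields[0]!r}")
        try:
            out[kmer] = float(fields[1])
        except ValueError:
            raise _err(path, lineno, f"non-numeric weight {fields[1]!r}") from None
    return out


def write_kmer_weights(path: str, weights: Dict[str, float],
                       header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        handle.write("kmer\tweight\n")
        for kmer in sorted(weights):
            handle.write(f"{kmer}\t{weights[kmer]:.17g}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> Dict[str, str]:
    """Whole-genome FASTA into a dict of uppercase sequences."""
    seqs: Dict[str, List[str]] = {}
    name = None
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise FormatError(f"{os.path.basename(path)}: sequence "
                                      "data before the first header")
                seqs[name].append(line.upper())
    return {n: "".join(parts) for n, parts in seqs.items()}


def write_fasta(path: str, seqs: Dict[str, str], width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")
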