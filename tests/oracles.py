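"""Independent brute-force oracles used to check the fast implementations.

Everything here is written as plain enumeration over the definition of
the statistic, deliberately sharing no code with the package internals.
"""

from fractions import Fraction
from math import comb, inf, log2

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational full enumeration of the minimum-likelihood rule."""
    n = a + b + c + d
    row, col = a + b, a + c
    denom = comb(n, col)

    def prob(x: int) -> Fraction:
        return Fraction(comb(row, x) * comb(n - row, col - x), denom)

    threshold = prob(a) * (1 + Fraction(1, 10**7))
    lo, hi = max(0, row + col - n), min(row, col)
    total = sum((prob(x) for x in range(lo, hi + 1) if prob(x) <= threshold),
                Fraction(0))
    return float(total)


def pwm_best_score(seq: str, matrix, background) -> float:
    """Max log2-odds over all windows and both strands of a sequence."""
    L = len(matrix)
    best = -inf
    for s in range(0, len(seq) - L + 1):
        window = seq[s:s + L]
        for oriented in (window, revcomp(window)):
            score = sum(
                log2(matrix[i][_IDX[oriented[i]]] / background[_IDX[oriented[i]]])
                for i in range(L))
            best = max(best, score)
    return best


def pwm_delta_oracle(seq: str, var_offset: int, ref: str, alt: str,
                     matrix, background) -> float:
    """Exhaustive rescan: restrict to windows covering the variant."""
    L = len(matrix)

    def best(allele: str) -> float:
        substituted = seq[:var_offset] + allele + seq[var_offset + 1:]
        top = -inf
        for s in range(0, len(seq) - L + 1):
            if not (s <= var_offset < s + L):
                continue
            window = substituted[s:s + L]
            for oriented in (window, revcomp(window)):
                score = sum(
                    log2(matrix[i][_IDX[oriented[i]]]
                         / background[_IDX[oriented[i]]])
                    for i in range(L))
                top = max(top, score)
        return top

    ref_best, alt_best = best(ref), best(alt)
    if ref_best == -inf:
        return 0.0
    return alt_best - ref_best


def allele_bias_oracle(seq: str, var_offset: int, ref: str, alt: str,
                       weights, k: int) -> float:
    """Hand enumeration of the k-mers of the (2k-1)-bp centred window."""
    lo = max(0, var_offset - (k - 1))
    hi = min(len(seq), var_offset + k)

    def total(allele: str) -> float:
        window = seq[lo:var_offset] + allele + seq[var_offset + 1:hi]
        kmers = [window[i:i + k] for i in range(len(window) - k + 1)]
        return sum(weights.get(m, 0.0) for m in kmers)

    return total(alt) - total(ref)


def hub_oracle(anchor, contacts, genes, min_count, flank):
    """Double-loop overlap scan re-deriving the hub gene set."""

    def overlaps(iv, seq_id, start, end):
        return iv.seq_id == seq_id and min(iv.end, end) > max(iv.start, start)

    gene_windows = []
    for g in genes:
        tss = g.start if g.strand == "+" else g.end - 1
        lo = min(g.start, max(0, tss - flank))
        hi = max(g.end, tss + flank + 1)
        gene_windows.append((g.name, g.seq_id, lo, hi))

    found = set()
    for pair in contacts:
        if pair.count < min_count:
            continue
        hit1 = overlaps(anchor, pair.anchor1.seq_id, pair.anchor1.start,
                        pair.anchor1.end)
        hit2 = overlaps(anchor, pair.anchor2.seq_id, pair.anchor2.start,
                        pair.anchor2.end)
        if hit1 == hit2:
            continue
        far = pair.anchor2 if hit1 else pair.anchor1
        for name, seq_id, lo, hi in gene_windows:
            if overlaps(far, seq_id, lo, hi):
                found.add(name)
    return found
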