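"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (strings,
Counter, Fraction, exhaustive enumeration) and shares no code path with
the package internals it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from fractions import Fraction

# an independently written standard genetic code (DNA alphabet)
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SYNONYMS = {
    aa: sorted(c for c, a in _CODE.items() if a == aa)
    for aa in set(_CODE.values())
}


def translate(seq: str) -> str:
    return "".join(_CODE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def shannon_entropy_codons(codons: list[str]) -> float:
    n = len(codons)
    counts = Counter(codons)
    return -sum((k / n) * math.log2(k / n) for k in counts.values())


def sense_codons(seq: str) -> list[str]:
    return [
        seq[i : i + 3]
        for i in range(0, len(seq), 3)
        if _CODE.get(seq[i : i + 3], "*") != "*" and "N" not in seq[i : i + 3]
    ]


def exact_null_entropy(seq: str) -> float:
    """Exact mean Shannon entropy over ALL synonymous re-encodings,
    enumerated exhaustively (feasible for few degenerate positions)."""
    codons = sense_codons(seq)
    options = [SYNONYMS[_CODE[c]] for c in codons]
    total = 0.0
    count = 0
    for variant in itertools.product(*options):
        total += shannon_entropy_codons(list(variant))
        count += 1
    return total / count


def degenerate_positions(seq: str) -> int:
    return sum(1 for c in sense_codons(seq) if len(SYNONYMS[_CODE[c]]) > 1)


# ---------------------------------------------------------------------------
# ENC from first principles


_WRIGHT_CLASSES = {2: 9, 3: 1, 4: 5, 6: 3}


def brute_enc(seq: str) -> float | None:
    codons = sense_codons(seq)
    counts = Counter(codons)
    class_f: dict[int, list[float]] = {k: [] for k in _WRIGHT_CLASSES}
    for aa, syns in SYNONYMS.items():
        if aa == "*" or len(syns) == 1:
            continue
        family = [counts.get(c, 0) for c in syns]
        n = sum(family)
        if n < 2:
            continue
        s = sum((x / n) ** 2 for x in family)
        class_f[len(syns)].append((n * s - 1) / (n - 1))
    means = {k: (sum(v) / len(v) if v else None) for k, v in class_f.items()}
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2
    if any(means[k] is None for k in (2, 3, 4, 6)):
        return None
    if min(means[k] for k in (2, 3, 4, 6)) <= 0:
        return 61.0  # F -> 0 sends the estimator above the cap
    value = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(61.0, max(20.0, value))


# ---------------------------------------------------------------------------
# exact mHG by exhaustive permutation enumeration (tiny N only)


def hypergeom_tail_exact(b: int, N: int, B: int, n: int) -> Fraction:
    """P(X >= b), X ~ Hypergeometric(N, B, n), in exact rational arithmetic."""
    total = math.comb(N, n)
    acc = 0
    for k in range(b, min(n, B) + 1):
        acc += math.comb(B, k) * math.comb(N - B, n - k)
    return Fraction(acc, total)


def min_tail(membership: tuple[int, ...]) -> Fraction:
    N = len(membership)
    B = sum(membership)
    best = Fraction(1)
    b = 0
    for n in range(1, N + 1):
        b += membership[n - 1]
        if b > 0:
            best = min(best, hypergeom_tail_exact(b, N, B, n))
    return best


def brute_mhg_pvalue(N: int, B: int, score: Fraction) -> Fraction:
    """Exact P(min tail <= score) over all C(N,B) label placements."""
    hits = 0
    total = 0
    for positions in itertools.combinations(range(N), B):
        membership = tuple(1 if i in positions else 0 for i in range(N))
        total += 1
        if min_tail(membership) <= score:
            hits += 1
    return Fraction(hits, total)


# ---------------------------------------------------------------------------
# BH step-up by the textbook definition


def brute_bh(ps: list[float]) -> list[float]:
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    qs = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = min(prev, ps[i] * m / rank_from_top)
        qs[i] = q
        prev = q
    return qs
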