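"""Genetic-code bookkeeping, codon counting, usage tables and GC profiling.

The standard genetic code is loaded from Biopython's codon tables and
re-expressed as flat numpy lookup arrays so that downstream statistics
(entropy scoring, ENC) can operate on integer codon indices instead of
strings.  All sequences are handled in the DNA alphabet (A, C, G, T, with N
for ambiguity); RNA display (U for T) is a formatting concern only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

#: codon index 64 is the sentinel for codons containing non-ACGT characters
AMBIGUOUS_CODON = 64


def _build_codons() -> list[str]:
    return [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]


CODONS: list[str] = _build_codons()
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: amino acids in fixed order; '*' (stop) deliberately last
AMINO_ACIDS: list[str] = sorted({aa for aa in _STANDARD.forward_table.values()}) + ["*"]
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
STOP_AA = AA_INDEX["*"]


def _aa_of(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD.forward_table[codon]


#: amino-acid index per codon index; sentinel codon maps to -1
AA_OF_CODON: np.ndarray = np.array(
    [AA_INDEX[_aa_of(c)] for c in CODONS] + [-1], dtype=np.int64
)

#: synonym codon indices per amino acid, lexicographic within family
SYNONYMS: dict[str, list[str]] = {
    aa: sorted(c for c in CODONS if _aa_of(c) == aa) for aa in AMINO_ACIDS
}
DEGENERACY: np.ndarray = np.array(
    [len(SYNONYMS[aa]) for aa in AMINO_ACIDS], dtype=np.int64
)

_MAX_DEG = int(DEGENERACY.max())
#: (n_aa, 6) matrix of synonym codon indices, row-padded with the first synonym
SYN_MATRIX: np.ndarray = np.array(
    [
        [CODON_INDEX[c] for c in SYNONYMS[aa]]
        + [CODON_INDEX[SYNONYMS[aa][0]]] * (_MAX_DEG - len(SYNONYMS[aa]))
        for aa in AMINO_ACIDS
    ],
    dtype=np.int64,
)

_NT_CODE = np.full(256, -1, dtype=np.int64)
for _i, _nt in enumerate(NUCLEOTIDES):
    _NT_CODE[ord(_nt)] = _i
    _NT_CODE[ord(_nt.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_codons(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an array of codon indices (0..63).

    Trailing nucleotides beyond the last full codon are ignored; any codon
    containing a character outside ACGT becomes the sentinel index 64.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    vals = _NT_CODE[raw]
    n = 3 * (len(vals) // 3)
    vals = vals[:n].reshape(-1, 3)
    idx = vals[:, 0] * 16 + vals[:, 1] * 4 + vals[:, 2]
    idx[(vals < 0).any(axis=1)] = AMBIGUOUS_CODON
    return idx


def decode_codons(indices: Iterable[int]) -> str:
    return "".join(CODONS[i] if i < AMBIGUOUS_CODON else "NNN" for i in indices)


class GeneticCode:
    """The standard nuclear genetic code with Wright's degeneracy classes.

    61 sense codons partition into 2 one-fold (Met, Trp), 9 two-fold,
    1 three-fold (Ile), 5 four-fold and 3 six-fold (Leu, Ser, Arg) families:
    2*1 + 9*2 + 1*3 + 5*4 + 3*6 = 61.
    """

    stop_codons = STOP_CODONS
    codons = CODONS

    def __init__(self) -> None:
        self.synonyms = {aa: list(SYNONYMS[aa]) for aa in AMINO_ACIDS if aa != "*"}
        self.degeneracy = {aa: len(s) for aa, s in self.synonyms.items()}
        self.classes: dict[int, list[str]] = {}
        for aa, k in self.degeneracy.items():
            self.classes.setdefault(k, []).append(aa)
        for fams in self.classes.values():
            fams.sort()

    def aa_for(self, codon: str) -> str:
        return _aa_of(codon.upper())

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in STOP_CODONS

    def translate(self, seq: str) -> str:
        return "".join(self.aa_for(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3))


STANDARD_CODE = GeneticCode()


# ---------------------------------------------------------------------------
# codon usage tables


@dataclass
class CodonUsageTable:
    """Pooled codon counts with per-thousand frequencies.

    ``counts`` covers all 64 codons (zeros included).  Stop codons appear in
    the table whenever the input sequences retained their terminal stops;
    per-gene bias statistics never consume this table's stop rows.
    """

    counts: dict[str, int]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = int(sum(self.counts.values()))

    def per_thousand(self, codon: str) -> float:
        if self.total == 0:
            raise ValueError("empty usage table")
        return 1000.0 * self.counts[codon] / self.total

    def frequencies(self) -> np.ndarray:
        """Relative frequency per codon index (length 64)."""
        arr = np.array([self.counts[c] for c in CODONS], dtype=float)
        return arr / arr.sum()

    def to_frame(self, rna: bool = False) -> pd.DataFrame:
        rows = []
        for codon in CODONS:
            shown = codon.replace("T", "U") if rna else codon
            rows.append(
                {
                    "codon": shown,
                    "aa": _aa_of(codon),
                    "count": self.counts[codon],
                    "per_thousand": round(1000.0 * self.counts[codon] / self.total, 1),
                }
            )
        return pd.DataFrame(rows)


def count_codons(genes: Sequence) -> CodonUsageTable:
    """Pool codon counts over a collection of genes.

    ``genes`` may be nucleotide strings or objects with a ``seq`` attribute.
    Codons containing N are excluded.
    """
    if len(genes) == 0:
        raise ValueError("count_codons requires at least one gene")
    totals = np.zeros(AMBIGUOUS_CODON + 1, dtype=np.int64)
    for g in genes:
        seq = g if isinstance(g, str) else g.seq
        idx = encode_codons(seq)
        totals += np.bincount(idx, minlength=AMBIGUOUS_CODON + 1)
    if totals[AMBIGUOUS_CODON]:
        logger.info("excluded %d ambiguous (N-containing) codons", totals[AMBIGUOUS_CODON])
    counts = {c: int(totals[i]) for i, c in enumerate(CODONS)}
    if sum(counts.values()) == 0:
        raise ValueError("no unambiguous codons in input")
    return CodonUsageTable(counts)


@dataclass
class PreferredCodon:
    codon: str
    tied: bool = False


def preferred_codons(table: CodonUsageTable) -> dict[str, PreferredCodon]:
    """Call the preferred (most used) synonym for each amino acid.

    Ties are broken lexicographically and flagged.  Amino acids with zero
    total count are absent from the returned map (logged).  Stop codons are
    not assigned a preference.
    """
    result: dict[str, PreferredCodon] = {}
    for aa, syns in SYNONYMS.items():
        if aa == "*":
            continue
        counts = [table.counts[c] for c in syns]
        total = sum(counts)
        if total == 0:
            logger.warning("amino acid %s has zero codon count; no preferred codon", aa)
            continue
        best = max(counts)
        winners = [c for c, n in zip(syns, counts) if n == best]
        result[aa] = PreferredCodon(codon=winners[0], tied=len(winners) > 1)
    return result


# ---------------------------------------------------------------------------
# GC content


def gc_percent(seq: str) -> float:
    """GC percentage over unambiguous positions; N is excluded from both
    numerator and denominator."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous nucleotides")
    return 100.0 * gc / (gc + at)


@dataclass
class GCProfile:
    gene_id: str
    gc_gene: float
    gc_up: float | None
    gc_down: float | None
    flank_up_len: int
    flank_down_len: int
    strand: str = "+"


def flank_gc(locus, genome: Mapping[str, str], flank: int = 10_000) -> GCProfile:
    """GC content of a gene body and its up/downstream flanks.

    Flanks are taken relative to transcript orientation: for a minus-strand
    gene the upstream window lies at higher genomic coordinates and is
    reverse-complemented before GC (a no-op for GC itself, but keeps the
    emitted windows transcript-oriented).  Windows are clipped at contig
    boundaries and the achieved lengths reported.
    """
    if locus.contig not in genome:
        raise KeyError(f"contig {locus.contig!r} not in genome")
    contig = genome[locus.contig]
    n = len(contig)
    if not (0 <= locus.start < locus.end <= n):
        raise ValueError(
            f"locus {locus.gene_id} [{locus.start},{locus.end}) outside contig of length {n}"
        )
    gene = contig[locus.start : locus.end]
    left = contig[max(0, locus.start - flank) : locus.start]
    right = contig[locus.end : min(n, locus.end + flank)]
    if locus.strand == "+":
        up, down = left, right
    else:
        gene = reverse_complement(gene)
        up, down = reverse_complement(right), reverse_complement(left)

    def _gc(s: str) -> float | None:
        try:
            return gc_percent(s) if s else None
        except ValueError:
            return None

    return GCProfile(
        gene_id=locus.gene_id,
        gc_gene=gc_percent(gene),
        gc_up=_gc(up),
        gc_down=_gc(down),
        flank_up_len=len(up),
        flank_down_len=len(down),
        strand=locus.strand,
    )
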