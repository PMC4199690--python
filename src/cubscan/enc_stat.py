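"""Wright's effective number of codons (ENC).

ENC measures how far a gene's codon usage departs from equal use of
synonymous codons: 20 when one codon is used exclusively per amino acid,
61 when all synonyms are used equally.  The building block is the family
homozygosity

    F = (n * sum(p_i^2) - 1) / (n - 1)

over an amino acid's synonym counts (n = family total, p_i = count_i / n),
an unbiased estimator of the probability that two random codons of the
family are identical.  ENC combines class means over Wright's degeneracy
classes:

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

with a missing three-fold class (Ile absent or rare) imputed as the mean
of F2 and F4, and the result clamped to the theoretical [20, 61] range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import (
    AMBIGUOUS_CODON,
    AMINO_ACIDS,
    SYNONYMS,
    CODON_INDEX,
    encode_codons,
)
from .cub_entropy import CUBResult

ENC_MIN, ENC_MAX = 20.0, 61.0

#: Wright's degeneracy classes: (fold, number of families, weight in ENC)
_CLASS_FOLDS = (2, 3, 4, 6)
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}

_FAMILIES: dict[int, list[list[int]]] = {
    k: [
        [CODON_INDEX[c] for c in SYNONYMS[aa]]
        for aa in AMINO_ACIDS
        if aa != "*" and len(SYNONYMS[aa]) == k
    ]
    for k in _CLASS_FOLDS
}


class ENCUndefinedError(ValueError):
    """No degeneracy class has an eligible family (n >= 2)."""


@dataclass
class ENCResult:
    gene_id: str
    enc: float
    f2: float | None
    f3: float | None
    f4: float | None
    f6: float | None
    families_used: int


def family_homozygosity(counts: Sequence[int]) -> float | None:
    """F-hat for one synonym family; None (excluded) when n < 2."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative codon count")
    n = counts.sum()
    if n < 2:
        return None
    p = counts / n
    return float((n * (p**2).sum() - 1.0) / (n - 1.0))


def enc(seq_or_gene, gene_id: str | None = None) -> ENCResult:
    """Wright's ENC for one coding sequence (stops and N-codons ignored)."""
    if hasattr(seq_or_gene, "seq"):
        seq = seq_or_gene.seq
        gene_id = gene_id or seq_or_gene.gene_id
    else:
        seq = seq_or_gene
        gene_id = gene_id or "gene"
    idx = encode_codons(seq)
    counts = np.bincount(idx[idx < AMBIGUOUS_CODON], minlength=AMBIGUOUS_CODON)

    class_means: dict[int, float | None] = {}
    families_used = 0
    for k in _CLASS_FOLDS:
        fs = []
        for family in _FAMILIES[k]:
            f = family_homozygosity(counts[family])
            if f is not None:
                fs.append(f)
        if fs:
            class_means[k] = float(np.mean(fs))
            families_used += len(fs)
        else:
            class_means[k] = None

    f2, f3, f4, f6 = (class_means[k] for k in _CLASS_FOLDS)
    if f3 is None and f2 is not None and f4 is not None:
        f3 = (f2 + f4) / 2.0  # Wright's imputation for the lone Ile family
    if f2 is None or f4 is None or f6 is None or f3 is None:
        raise ENCUndefinedError(
            f"gene {gene_id!r}: a degeneracy class has no eligible family; ENC undefined"
        )
    # a class mean of zero (perfectly even usage at tiny n) sends ENC to
    # +inf; the range cap absorbs it
    if min(f2, f3, f4, f6) <= 0:
        value = float("inf")
    else:
        value = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    value = min(ENC_MAX, max(ENC_MIN, value))
    return ENCResult(
        gene_id=gene_id,
        enc=value,
        f2=class_means[2],
        f3=class_means[3],
        f4=class_means[4],
        f6=class_means[6],
        families_used=families_used,
    )


def enc_genes(genes) -> tuple[list[ENCResult], list[str]]:
    """ENC per gene; genes with no eligible family are returned separately."""
    results, flagged = [], []
    for g in genes:
        try:
            results.append(enc(g))
        except ENCUndefinedError:
            flagged.append(g.gene_id)
    return results, flagged


def enc_vs_entropy(
    enc_results: Sequence[ENCResult], cub_results: Sequence[CUBResult]
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of ENC with differential entropy over shared genes.

    Both statistics increase toward unbiased usage, so a genome with graded
    bias should show a positive correlation.  Returns (r, paired table) with
    the table suitable for scatter plotting.
    """
    enc_map = {r.gene_id: r.enc for r in enc_results}
    cub_map = {r.gene_id: r.d for r in cub_results}
    shared = sorted(set(enc_map) & set(cub_map))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    table = pd.DataFrame(
        {
            "gene_id": shared,
            "enc": [enc_map[g] for g in shared],
            "d": [cub_map[g] for g in shared],
        }
    )
    r, _p = stats.pearsonr(table["enc"], table["d"])
    return float(r), table
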