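"""Per-gene codon usage bias via differential entropy.

The statistic: compute an entropy (regularity) estimate for the observed
coding sequence, re-encode the same protein ``n_random`` times with codons
drawn at random from each amino acid's synonym set, and report

    D = H_obs - mean(H_null)

Negative D means the observed codon choice is more regular (more biased)
than random synonymous coding.  Because the null re-encodings share the
gene's length and amino-acid composition, D is comparable across genes of
different lengths and compositions.

Two estimators are provided: ``codon_shannon`` (Shannon entropy of the
gene's empirical codon distribution, in bits per codon; proportion-
sensitive and exactly checkable by enumeration) and ``lz76``
(Lempel-Ziv-76 normalized phrase complexity of the nucleotide string;
sensitive to order as well as proportion).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .codon_core import (
    AA_OF_CODON,
    AMBIGUOUS_CODON,
    DEGENERACY,
    STOP_AA,
    SYN_MATRIX,
    CodonUsageTable,
    decode_codons,
    encode_codons,
)
from .seq_io import CodingSequence

logger = logging.getLogger(__name__)

ESTIMATORS = ("codon_shannon", "lz76")
NULL_MODELS = ("uniform_synonymous", "genome_frequency")


@dataclass(frozen=True)
class CUBConfig:
    """Configuration of the differential-entropy score.

    ``n_random`` null re-encodings per gene (default 20); ``master_seed``
    combined with each gene_id gives a per-gene stream so results do not
    depend on gene order.
    """

    n_random: int = 20
    estimator: str = "codon_shannon"
    null_model: str = "uniform_synonymous"
    master_seed: int = 0
    genome_frequencies: np.ndarray | None = None  # length-64, for genome_frequency null

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.null_model not in NULL_MODELS:
            raise ValueError(f"unknown null model {self.null_model!r}")


@dataclass
class CUBResult:
    gene_id: str
    h_obs: float
    h_null_mean: float
    h_null_sd: float
    d: float
    n_codons: int
    estimator: str
    seed: int
    rank: int | None = None
    tied: bool = False


def gene_seed(master_seed: int, gene_id: str) -> int:
    """Stable per-gene seed below 2**31, independent of gene order."""
    h = hashlib.blake2b(f"{master_seed}:{gene_id}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") % (2**31)


# ---------------------------------------------------------------------------
# estimators


def _sense_codon_array(seq: str | np.ndarray) -> np.ndarray:
    """Codon index array with stop and N-containing codons removed."""
    idx = encode_codons(seq) if isinstance(seq, str) else np.asarray(seq)
    aa = AA_OF_CODON[idx]
    return idx[(aa >= 0) & (aa != STOP_AA)]


def codon_entropy(seq: str | np.ndarray) -> float:
    """Shannon entropy (bits/codon) of the empirical codon distribution."""
    idx = _sense_codon_array(seq)
    if idx.size == 0:
        raise ValueError("no usable codons (all stop or ambiguous)")
    counts = np.bincount(idx, minlength=AMBIGUOUS_CODON)
    return _entropy_from_counts(counts[None, :], idx.size)[0]


def _entropy_from_counts(counts: np.ndarray, n: int) -> np.ndarray:
    """Row-wise Shannon entropy of count matrices with shared total n."""
    p = counts / n
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=p > 0)
    return np.maximum(-(p * logp).sum(axis=1), 0.0)


def lz76_complexity(seq: str) -> float:
    """Lempel-Ziv-76 phrase count, normalized by n / log4(n).

    Returns c(n) * log4(n) / n: roughly 1 for incompressible i.i.d.
    nucleotide sequence, lower for regular sequence.
    """
    n = len(seq)
    if n < 4:
        raise ValueError("sequence too short for LZ76 (need >= 4 nt)")
    c = _lz76_phrases(seq)
    return c * (math.log(n, 4)) / n


def _lz76_phrases(s: str) -> int:
    # classic LZ76 exhaustive-history parsing
    n = len(s)
    i = 0
    c = 1
    u = 1  # length of current candidate extension
    v = 1
    vmax = 1
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            vmax = max(v, vmax)
            i += 1
            if i == u:  # no history match extends: new phrase
                c += 1
                u += vmax
                v = 1
                i = 0
                vmax = 1
            else:
                v = 1
    if v != 1:
        c += 1
    return c


# ---------------------------------------------------------------------------
# synonymous null


def _null_draws(
    aa: np.ndarray, n_draws: int, rng: np.random.Generator, config: CUBConfig
) -> np.ndarray:
    """(n_draws, len(aa)) codon indices encoding the same amino acids."""
    if config.null_model == "uniform_synonymous":
        u = rng.random((n_draws, aa.size))
        choice = np.minimum((u * DEGENERACY[aa]).astype(np.int64), DEGENERACY[aa] - 1)
        return SYN_MATRIX[aa, choice]
    # genome_frequency: codons drawn proportionally to genome-wide usage
    freqs = config.genome_frequencies
    if freqs is None:
        raise ValueError("genome_frequency null requires genome_frequencies")
    probs = np.asarray(freqs, dtype=float)[SYN_MATRIX]  # (n_aa, 6)
    # zero out padding columns, renormalize within each synonym family
    pad = np.arange(SYN_MATRIX.shape[1])[None, :] >= DEGENERACY[:, None]
    probs = np.where(pad, 0.0, probs)
    rowsum = probs.sum(axis=1, keepdims=True)
    uniform = np.where(pad, 0.0, 1.0 / DEGENERACY[:, None])
    probs = np.where(rowsum > 0, probs / np.where(rowsum == 0, 1, rowsum), uniform)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n_draws, aa.size, 1))
    choice = (u > cum[aa][None, :, :]).sum(axis=2)
    choice = np.minimum(choice, DEGENERACY[aa] - 1)
    return SYN_MATRIX[aa, choice]


def synonymous_randomize(
    seq: str,
    rng: np.random.Generator,
    null_model: str = "uniform_synonymous",
    genome_table: CodonUsageTable | None = None,
) -> str:
    """Re-encode a CDS with random synonymous codons.

    The translation of the output equals the translation of the input
    codon-for-codon; stop and N-containing codons are passed through
    unchanged.
    """
    idx = encode_codons(seq)
    aa = AA_OF_CODON[idx]
    sense = (aa >= 0) & (aa != STOP_AA)
    config = CUBConfig(
        null_model=null_model,
        genome_frequencies=genome_table.frequencies() if genome_table else None,
    )
    out = idx.copy()
    if sense.any():
        out[sense] = _null_draws(aa[sense], 1, rng, config)[0]
    pieces = []
    pos = 0
    for i, codon_idx in enumerate(out):
        if codon_idx == AMBIGUOUS_CODON:
            pieces.append(seq[3 * i : 3 * i + 3])  # preserve original ambiguous codon
        else:
            pieces.append(decode_codons([codon_idx]))
        pos += 3
    return "".join(pieces) + seq[3 * len(out) :]


# ---------------------------------------------------------------------------
# the score


def differential_entropy(gene: CodingSequence | str, config: CUBConfig) -> CUBResult:
    """Score one gene: H_obs minus the mean H over synonymous re-encodings."""
    if isinstance(gene, str):
        gene = CodingSequence(gene_id="gene", species="", seq=gene)
    seed = gene_seed(config.master_seed, gene.gene_id)
    rng = np.random.default_rng(seed)
    idx = _sense_codon_array(gene.seq)
    if idx.size == 0:
        raise ValueError(f"gene {gene.gene_id!r} has no usable codons")
    aa = AA_OF_CODON[idx]

    if config.estimator == "codon_shannon":
        counts = np.bincount(idx, minlength=AMBIGUOUS_CODON)
        h_obs = float(_entropy_from_counts(counts[None, :], idx.size)[0])
        draws = _null_draws(aa, config.n_random, rng, config)
        null_counts = np.zeros((config.n_random, AMBIGUOUS_CODON), dtype=np.int64)
        rows = np.repeat(np.arange(config.n_random), idx.size)
        np.add.at(null_counts, (rows, draws.ravel()), 1)
        h_null = _entropy_from_counts(null_counts, idx.size)
    else:  # lz76
        h_obs = lz76_complexity(decode_codons(idx))
        draws = _null_draws(aa, config.n_random, rng, config)
        h_null = np.array([lz76_complexity(decode_codons(row)) for row in draws])

    h_null_mean = float(h_null.mean())
    h_null_sd = float(h_null.std(ddof=1)) if config.n_random > 1 else 0.0
    return CUBResult(
        gene_id=gene.gene_id,
        h_obs=h_obs,
        h_null_mean=h_null_mean,
        h_null_sd=h_null_sd,
        d=h_obs - h_null_mean,
        n_codons=int(idx.size),
        estimator=config.estimator,
        seed=seed,
    )


def score_genes(
    genes: Sequence[CodingSequence], config: CUBConfig
) -> tuple[list[CUBResult], list[str]]:
    """Score every eligible gene; return (results, ineligible gene_ids).

    Ineligible genes (internal stops, excessive N content) are excluded and
    reported, mirroring their routing toward the pseudogene screen.
    """
    results: list[CUBResult] = []
    skipped: list[str] = []
    for g in genes:
        if not g.cub_eligible():
            skipped.append(g.gene_id)
            continue
        results.append(differential_entropy(g, config))
    if skipped:
        logger.info("excluded %d ineligible genes from CUB scoring", len(skipped))
    return results, skipped


def rank_genes(results: Sequence[CUBResult]) -> list[CUBResult]:
    """Rank ascending by D (most negative = most biased = rank 1).

    Ties are broken by gene_id and flagged.  Results are returned as copies
    with ``rank`` set.
    """
    ids = [r.gene_id for r in results]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene_id(s) in results: {dup}")
    ordered = sorted(results, key=lambda r: (r.d, r.gene_id))
    d_counts: dict[float, int] = {}
    for r in ordered:
        d_counts[r.d] = d_counts.get(r.d, 0) + 1
    out = []
    for i, r in enumerate(ordered, 1):
        out.append(replace(r, rank=i, tied=d_counts[r.d] > 1))
    return out
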