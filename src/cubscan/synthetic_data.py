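"""Truth-known synthetic genomes for exercising the analysis end-to-end.

The generator plants codon bias with a preferred-codon mixture: each codon
for an amino acid with k synonyms is the family's preferred codon with
probability beta + (1 - beta)/k and any specific other synonym with
probability (1 - beta)/k.  beta = 0 reproduces the uniform synonymous null
exactly (so scored bias calibrates at zero), beta = 1 uses the preferred
codon exclusively (driving ENC to its lower bound on full-coverage genes),
and every bias statistic is monotone in beta in between.

Gene lengths follow a log-normal over codon counts (median 250 codons,
log-sd 0.6, clipped to [50, 3000]), a crude but adequate stand-in for the
spread of mammalian CDS lengths.  Planted gene sets receive elevated beta
so that ranked-list enrichment has a known positive control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .codon_core import AMINO_ACIDS, CODONS, SYN_MATRIX, SYNONYMS, DEGENERACY
from .enrichment import GeneSetCollection
from .pseudogene_screen import GAP, AlignedPair
from .seq_io import CodingSequence

_N_AA = 20  # sense amino acids; AMINO_ACIDS[:20] (stop is last)

DEFAULT_PREFERRED: dict[str, str] = {
    aa: SYNONYMS[aa][0] for aa in AMINO_ACIDS if aa != "*"
}


@dataclass
class SimConfig:
    """Study design for a synthetic genome."""

    n_genes: int = 300
    length_median: int = 250
    length_log_sd: float = 0.6
    length_clip: tuple[int, int] = (50, 3000)
    aa_composition: np.ndarray | None = None  # length 20, sums to 1; uniform if None
    preferred: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PREFERRED))
    beta_background: float = 0.05
    beta_planted: float = 0.6
    n_terms: int = 15
    term_size: int = 20
    planted_term_size: int = 20
    include_start: bool = True
    include_stop: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for b in (self.beta_background, self.beta_planted):
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"beta {b} outside [0, 1]")
        if self.planted_term_size < 5:
            raise ValueError("planted term must have >= 5 genes")
        if self.planted_term_size > self.n_genes or self.term_size > self.n_genes:
            raise ValueError("term size exceeds n_genes")


@dataclass
class SimGenome:
    genes: list[CodingSequence]
    collection: GeneSetCollection
    truth: pd.DataFrame  # gene_id, beta, n_codons, planted, terms


def _preferred_indices(preferred: Mapping[str, str]) -> np.ndarray:
    arr = np.empty(_N_AA, dtype=np.int64)
    for i, aa in enumerate(AMINO_ACIDS[:_N_AA]):
        codon = preferred[aa]
        if codon not in SYNONYMS[aa]:
            raise ValueError(f"{codon} is not a synonym of {aa}")
        arr[i] = CODONS.index(codon)
    return arr


def _encode_protein(
    aa_idx: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    preferred_idx: np.ndarray,
) -> np.ndarray:
    """Codon indices for an amino-acid index sequence under the bias model."""
    n = aa_idx.size
    take_preferred = rng.random(n) < beta
    u = rng.random(n)
    deg = DEGENERACY[aa_idx]
    uniform_choice = np.minimum((u * deg).astype(np.int64), deg - 1)
    codons = SYN_MATRIX[aa_idx, uniform_choice]
    return np.where(take_preferred, preferred_idx[aa_idx], codons)


def simulate_gene(
    length: int,
    beta: float,
    rng: np.random.Generator,
    preferred: Mapping[str, str] | None = None,
    aa_composition: np.ndarray | None = None,
    include_start: bool = True,
    include_stop: bool = False,
    gene_id: str = "gene",
    species: str = "synthetic",
) -> CodingSequence:
    """One synthetic gene of ``length`` body codons with bias strength beta."""
    if length < 1:
        raise ValueError("length must be >= 1 codon")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta {beta} outside [0, 1]")
    if aa_composition is None:
        aa_idx = rng.integers(0, _N_AA, size=length)
    else:
        aa_idx = rng.choice(_N_AA, size=length, p=np.asarray(aa_composition, dtype=float))
    pref_idx = _preferred_indices(preferred or DEFAULT_PREFERRED)
    codons = _encode_protein(aa_idx, beta, rng, pref_idx)
    seq = "".join(CODONS[c] for c in codons)
    if include_start:
        seq = "ATG" + seq
    if include_stop:
        seq = seq + "TAA"
    return CodingSequence(gene_id=gene_id, species=species, seq=seq)


def _sample_lengths(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lengths = rng.lognormal(np.log(config.length_median), config.length_log_sd, config.n_genes)
    lo, hi = config.length_clip
    return np.clip(np.round(lengths), lo, hi).astype(int)


def simulate_genome(config: SimConfig) -> SimGenome:
    """A genome with one planted (high-beta) gene set and random decoy sets."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = len(str(n))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]
    lengths = _sample_lengths(config, rng)

    planted = rng.choice(n, size=config.planted_term_size, replace=False)
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted] = True

    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    sets["T000"] = frozenset(gene_ids[i] for i in planted)
    names["T000"] = "planted_biased_set"
    for t in range(1, config.n_terms):
        members = rng.choice(n, size=config.term_size, replace=False)
        sets[f"T{t:03d}"] = frozenset(gene_ids[i] for i in members)
        names[f"T{t:03d}"] = f"decoy_set_{t}"

    genes: list[CodingSequence] = []
    rows = []
    for i, gid in enumerate(gene_ids):
        beta = config.beta_planted if planted_mask[i] else config.beta_background
        genes.append(
            simulate_gene(
                int(lengths[i]),
                beta,
                rng,
                preferred=config.preferred,
                aa_composition=config.aa_composition,
                include_start=config.include_start,
                include_stop=config.include_stop,
                gene_id=gid,
            )
        )
        terms = sorted(t for t, members in sets.items() if gid in members)
        rows.append(
            {
                "gene_id": gid,
                "beta": beta,
                "n_codons": int(lengths[i]),
                "planted": bool(planted_mask[i]),
                "terms": ";".join(terms),
            }
        )
    return SimGenome(
        genes=genes,
        collection=GeneSetCollection(sets=sets, names=names),
        truth=pd.DataFrame(rows),
    )


@dataclass
class SimOrthologPair:
    genes_a: list[CodingSequence]
    genes_b: list[CodingSequence]
    ortholog_map: dict[str, str]
    truth: pd.DataFrame  # gene_id, beta_a, beta_b, shifted


def simulate_ortholog_pair(
    config: SimConfig,
    beta_shift: float = 0.0,
    n_shifted: int = 0,
) -> SimOrthologPair:
    """Two genomes encoding identical proteins with species-specific bias.

    ``n_shifted`` genes of species A receive beta_background + beta_shift
    (clipped to 1); everything else uses beta_background in both species.
    Only codon choices differ between species, so any delta in scored bias
    is attributable to the planted shift.
    """
    if beta_shift < 0:
        raise ValueError("beta_shift must be >= 0")
    if n_shifted > config.n_genes:
        raise ValueError("shifted subset exceeds n_genes")
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = len(str(n))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]
    lengths = _sample_lengths(config, rng)
    shifted = set(rng.choice(n, size=n_shifted, replace=False).tolist()) if n_shifted else set()
    pref_idx = _preferred_indices(config.preferred)

    genes_a, genes_b, rows = [], [], []
    for i, gid in enumerate(gene_ids):
        aa_idx = rng.integers(0, _N_AA, size=int(lengths[i]))
        beta_a = min(1.0, config.beta_background + beta_shift) if i in shifted else config.beta_background
        beta_b = config.beta_background
        for species, beta, bucket in (
            ("speciesA", beta_a, genes_a),
            ("speciesB", beta_b, genes_b),
        ):
            codons = _encode_protein(aa_idx, beta, rng, pref_idx)
            seq = "ATG" + "".join(CODONS[c] for c in codons) if config.include_start else "".join(
                CODONS[c] for c in codons
            )
            bucket.append(CodingSequence(gene_id=gid, species=species, seq=seq))
        rows.append(
            {"gene_id": gid, "beta_a": beta_a, "beta_b": beta_b, "shifted": i in shifted}
        )
    return SimOrthologPair(
        genes_a=genes_a,
        genes_b=genes_b,
        ortholog_map={g: g for g in gene_ids},
        truth=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# lesion simulation


@dataclass(frozen=True)
class LesionSpec:
    """kind in {deletion, insertion, stop_substitution}; ``position`` is a
    nucleotide offset for indels and a codon index for stop substitutions."""

    kind: str
    position: int
    length: int = 0

    def expected_lesion(self) -> str | None:
        if self.kind in ("deletion", "insertion"):
            return "frameshift" if self.length % 3 else None
        if self.kind == "stop_substitution":
            return "premature_stop"
        raise ValueError(f"unknown lesion kind {self.kind!r}")

    def expected_codon_index(self) -> int:
        if self.kind == "stop_substitution":
            return self.position
        return self.position // 3


def simulate_lesion_pair(
    gene: CodingSequence, spec: LesionSpec, rng: np.random.Generator
) -> tuple[AlignedPair, dict]:
    """Plant one lesion into a copy of ``gene`` and return the alignment
    plus a truth record (expected lesion type and codon index)."""
    seq = gene.seq
    n = len(seq)
    if spec.kind == "deletion":
        if not (0 <= spec.position and spec.position + spec.length <= n):
            raise ValueError("deletion out of range")
        ref = seq
        tgt = seq[: spec.position] + GAP * spec.length + seq[spec.position + spec.length :]
    elif spec.kind == "insertion":
        if not 0 <= spec.position <= n:
            raise ValueError("insertion point out of range")
        ins = "".join(rng.choice(list("ACGT"), size=spec.length))
        ref = seq[: spec.position] + GAP * spec.length + seq[spec.position :]
        tgt = seq[: spec.position] + ins + seq[spec.position :]
    elif spec.kind == "stop_substitution":
        n_codons = n // 3
        if not 0 <= spec.position < n_codons - (1 if seq[-3:] in ("TAA", "TAG", "TGA") else 0):
            raise ValueError("stop substitution position out of range")
        stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
        p = 3 * spec.position
        ref = seq
        tgt = seq[:p] + stop + seq[p + 3 :]
    else:
        raise ValueError(f"unknown lesion kind {spec.kind!r}")
    pair = AlignedPair(gene_id=gene.gene_id, ref_seq=ref, target_seq=tgt)
    truth = {
        "gene_id": gene.gene_id,
        "kind": spec.kind,
        "expected_lesion": spec.expected_lesion(),
        "expected_codon_index": spec.expected_codon_index(),
        "length": spec.length,
    }
    return pair, truth
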