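"""Reading, writing and validating coding sequences and gene coordinates.

FASTA I/O goes through Biopython.  A coding sequence record may carry a
species tag in its description (``species=<label>``); records without one
fall back to the species passed by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_core import AMBIGUOUS_CODON, STOP_CODONS, encode_codons

logger = logging.getLogger(__name__)

Policy = Literal["strict", "trim", "skip"]

_VALID_CHARS = frozenset("ACGTN")

#: genes whose fraction of N-containing codons exceeds this are flagged and
#: excluded from bias ranking (masked assembly gaps would otherwise mimic
#: low-entropy sequence)
MAX_N_CODON_FRACTION = 0.10


@dataclass
class CodingSequence:
    """One gene's coding sequence, the atomic unit of every statistic."""

    gene_id: str
    species: str
    seq: str
    trimmed_stop: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon_indices(self) -> np.ndarray:
        return encode_codons(self.seq)

    def n_codon_fraction(self) -> float:
        idx = self.codon_indices()
        if idx.size == 0:
            return 0.0
        return float((idx == AMBIGUOUS_CODON).mean())

    def has_internal_stop(self) -> bool:
        """True if any stop codon occurs before the final codon."""
        idx = self.codon_indices()
        stops = {c for c in range(64) if _is_stop_index(c)}
        return any(int(c) in stops for c in idx[:-1]) if idx.size > 1 else False

    def cub_eligible(self) -> bool:
        """Eligible for per-gene bias scoring: no internal stop, tolerable N
        content, at least one codon."""
        return (
            self.n_codons >= 1
            and not self.has_internal_stop()
            and self.n_codon_fraction() <= MAX_N_CODON_FRACTION
        )


def _is_stop_index(idx: int) -> bool:
    from .codon_core import CODONS

    return CODONS[idx] in STOP_CODONS


@dataclass
class GeneLocus:
    """0-based half-open genomic interval with strand."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) for {self.gene_id}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")


class FastaValidationError(ValueError):
    pass


def _validate_record(
    gene_id: str,
    seq: str,
    policy: Policy,
    remove_terminal_stop: bool,
) -> CodingSequence | None:
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise FastaValidationError(
            f"record {gene_id!r} contains non-nucleotide characters: {sorted(bad)}"
        )
    rem = len(seq) % 3
    if rem:
        if policy == "strict":
            raise FastaValidationError(
                f"record {gene_id!r} length {len(seq)} is not a multiple of 3"
            )
        if policy == "trim":
            logger.warning("trimming %d trailing nt from %s", rem, gene_id)
            seq = seq[: len(seq) - rem]
        elif policy == "skip":
            logger.warning("skipping %s: length %d not a multiple of 3", gene_id, len(seq))
            return None
        else:
            raise ValueError(f"unknown policy {policy!r}")
    trimmed = False
    if remove_terminal_stop and len(seq) >= 3 and seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
        trimmed = True
    return CodingSequence(gene_id=gene_id, species="", seq=seq, trimmed_stop=trimmed)


def read_cds_fasta(
    path: str | Path,
    policy: Policy = "strict",
    remove_terminal_stop: bool = True,
    species: str = "",
) -> list[CodingSequence]:
    """Read and validate a CDS FASTA.

    Parameters
    ----------
    policy
        What to do with records whose length is not a multiple of 3:
        ``strict`` raises, ``trim`` drops the trailing 1-2 nt, ``skip``
        drops the record (both with a logged warning).
    remove_terminal_stop
        Strip a terminal stop codon and record it via ``trimmed_stop``.
    species
        Default species label for records lacking a ``species=`` tag.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaValidationError(f"empty or non-FASTA file: {path}")
    out: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in records:
        gene_id = rec.id
        if gene_id in seen:
            raise FastaValidationError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        cds = _validate_record(gene_id, str(rec.seq).upper(), policy, remove_terminal_stop)
        if cds is None:
            continue
        tag = _species_tag(rec.description)
        cds.species = tag if tag else species
        out.append(cds)
    return out


def _species_tag(description: str) -> str:
    for token in description.split():
        if token.startswith("species="):
            return token[len("species=") :]
    return ""


def write_cds_fasta(genes: Iterable[CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(g.seq),
            id=g.gene_id,
            description=f"species={g.species}" if g.species else "",
        )
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[GeneLocus]:
    """Parse a 6-column BED file into gene loci (0-based half-open)."""
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED columns, got {len(fields)}")
            contig, start, end, name, _score, strand = fields[:6]
            loci.append(
                GeneLocus(
                    gene_id=name,
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    return loci


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA as a contig -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
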