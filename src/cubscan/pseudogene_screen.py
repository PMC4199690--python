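"""Pseudogene lesion detection from pairwise alignments.

A candidate pseudogene carries a disabling lesion relative to an intact
reference: a frameshift (indel whose length is not a multiple of 3) or a
premature stop codon (an in-frame stop, in the target's running reading
frame, upstream of the reference terminal stop).  The reading frame is
anchored at the alignment start and tracked cumulatively, so compensating
indels restore frame downstream while each non-triplet indel is still
recorded.

Three artifact filters can mark calls as suspect without deleting them:
lesions also present in the reference-to-self alignment (aligner flaws),
lesions adjacent to annotated splice boundaries (gene-model errors), and
lesions at low-coverage or heterozygous sites (assembly errors /
polymorphism).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .codon_core import STOP_CODONS

logger = logging.getLogger(__name__)

GAP = "-"

FILTER_SELF = "self_alignment"
FILTER_SPLICE = "splice_adjacent"
FILTER_LOW_COV = "low_coverage"
FILTER_HET = "heterozygous"


@dataclass
class AlignedPair:
    """A gapped pairwise alignment; reference frame anchored at column 0."""

    gene_id: str
    ref_seq: str
    target_seq: str

    def __post_init__(self) -> None:
        self.ref_seq = self.ref_seq.upper()
        self.target_seq = self.target_seq.upper()
        if len(self.ref_seq) != len(self.target_seq):
            raise ValueError(
                f"{self.gene_id}: gapped lengths differ "
                f"({len(self.ref_seq)} vs {len(self.target_seq)})"
            )
        ref_len = len(self.ref_seq.replace(GAP, ""))
        if ref_len % 3:
            raise ValueError(
                f"{self.gene_id}: ungapped reference length {ref_len} not a multiple of 3"
            )


@dataclass
class PseudogeneCall:
    gene_id: str
    lesion_type: str  # "frameshift" | "premature_stop"
    ref_codon_index: int
    ref_nt_pos: int
    detail: str  # signed indel length, or the stop codon identity
    filters_failed: set[str] = field(default_factory=set)

    @property
    def passes(self) -> bool:
        return not self.filters_failed


def read_aligned_pair(path: str | Path, gene_id: str | None = None) -> AlignedPair:
    """Read an aligned-FASTA file holding reference then target."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, got {len(records)}")
    return AlignedPair(
        gene_id=gene_id or records[1].id,
        ref_seq=str(records[0].seq),
        target_seq=str(records[1].seq),
    )


def detect_lesions(pair: AlignedPair) -> list[PseudogeneCall]:
    """Call frameshifts and premature stops in the target sequence."""
    ref, tgt = pair.ref_seq, pair.target_seq
    calls: list[PseudogeneCall] = []

    # pass 1: indels, tracked as runs of gap columns
    ref_pos = 0  # ungapped ref nts consumed
    i = 0
    n_cols = len(ref)
    target_nts: list[str] = []
    target_ref_pos: list[int] = []  # ref nt index mapped to each target nt
    while i < n_cols:
        r, t = ref[i], tgt[i]
        if r == GAP and t == GAP:
            raise ValueError(f"{pair.gene_id}: gap-vs-gap column at {i}")
        if t == GAP and r != GAP:  # deletion in target
            start_ref = ref_pos
            length = 0
            while i < n_cols and tgt[i] == GAP and ref[i] != GAP:
                length += 1
                ref_pos += 1
                i += 1
            if length % 3:
                calls.append(
                    PseudogeneCall(
                        gene_id=pair.gene_id,
                        lesion_type="frameshift",
                        ref_codon_index=start_ref // 3,
                        ref_nt_pos=start_ref,
                        detail=f"-{length}",
                    )
                )
            continue
        if r == GAP and t != GAP:  # insertion in target
            start_ref = ref_pos
            length = 0
            while i < n_cols and ref[i] == GAP and tgt[i] != GAP:
                target_nts.append(tgt[i])
                target_ref_pos.append(ref_pos)
                length += 1
                i += 1
            if length % 3:
                calls.append(
                    PseudogeneCall(
                        gene_id=pair.gene_id,
                        lesion_type="frameshift",
                        ref_codon_index=start_ref // 3,
                        ref_nt_pos=start_ref,
                        detail=f"+{length}",
                    )
                )
            continue
        target_nts.append(t)
        target_ref_pos.append(ref_pos)
        ref_pos += 1
        i += 1

    ref_len = ref_pos
    # the reference terminal stop, if present, is its last codon
    ref_ungapped = ref.replace(GAP, "")
    ref_has_stop = ref_ungapped[-3:] in STOP_CODONS
    # ref nt positions strictly before this are "before the terminal stop"
    terminal_boundary = ref_len - 3 if ref_has_stop else ref_len

    # pass 2: in-frame stops of the target's running frame (frame anchored
    # at alignment start => consecutive triplets of the ungapped target)
    target_str = "".join(target_nts)
    for ci in range(len(target_str) // 3):
        codon = target_str[3 * ci : 3 * ci + 3]
        if codon in STOP_CODONS:
            r = target_ref_pos[3 * ci]
            if r < terminal_boundary:
                calls.append(
                    PseudogeneCall(
                        gene_id=pair.gene_id,
                        lesion_type="premature_stop",
                        ref_codon_index=r // 3,
                        ref_nt_pos=r,
                        detail=codon,
                    )
                )

    calls.sort(key=lambda c: (c.ref_nt_pos, c.lesion_type))
    return calls


# ---------------------------------------------------------------------------
# artifact filters


def filter_self_alignment(
    calls: Sequence[PseudogeneCall], ref_self_calls: Sequence[PseudogeneCall]
) -> list[PseudogeneCall]:
    """Flag every call of a gene whose reference self-alignment also shows
    lesions (the lesion is then an alignment artifact, not biology)."""
    dirty_genes = {c.gene_id for c in ref_self_calls}
    out = []
    for c in calls:
        c = replace(c, filters_failed=set(c.filters_failed))
        if c.gene_id in dirty_genes:
            c.filters_failed.add(FILTER_SELF)
        out.append(c)
    return out


def filter_splice_adjacent(
    calls: Sequence[PseudogeneCall],
    boundaries: Sequence[int] | None,
    window: int = 10,
) -> list[PseudogeneCall]:
    """Flag lesions within ``window`` nt of an exon boundary.

    ``boundaries`` are exon boundary positions in reference CDS nucleotide
    coordinates.  With no boundaries supplied the filter is skipped.
    """
    if not boundaries:
        logger.warning("no exon boundaries supplied; splice-adjacency filter skipped")
        return [replace(c, filters_failed=set(c.filters_failed)) for c in calls]
    bs = list(boundaries)
    if bs != sorted(bs):
        raise ValueError("exon boundaries must be sorted")
    out = []
    for c in calls:
        c = replace(c, filters_failed=set(c.filters_failed))
        if any(abs(c.ref_nt_pos - b) <= window for b in bs):
            c.filters_failed.add(FILTER_SPLICE)
        out.append(c)
    return out


def filter_coverage(
    calls: Sequence[PseudogeneCall],
    coverage: Mapping[int, tuple[int, float]],
    min_cov: int = 5,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[PseudogeneCall]:
    """Flag lesions at poorly covered or heterozygous sites.

    ``coverage`` maps reference nt position -> (depth, alt_fraction).  A
    lesion site absent from the table is treated as low-coverage.
    """
    lo, hi = het_band
    out = []
    for c in calls:
        c = replace(c, filters_failed=set(c.filters_failed))
        rec = coverage.get(c.ref_nt_pos)
        if rec is None:
            logger.info("no coverage at %s:%d; treated as low-coverage", c.gene_id, c.ref_nt_pos)
            c.filters_failed.add(FILTER_LOW_COV)
        else:
            depth, alt_frac = rec
            if depth < min_cov:
                c.filters_failed.add(FILTER_LOW_COV)
            elif lo <= alt_frac <= hi:
                c.filters_failed.add(FILTER_HET)
        out.append(c)
    return out


def read_coverage_tsv(path: str | Path) -> dict[int, tuple[int, float]]:
    """Per-site TSV with columns position, depth, alt_fraction."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"position", "depth", "alt_fraction"}
    if not required.issubset(df.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    return {
        int(row.position): (int(row.depth), float(row.alt_fraction))
        for row in df.itertuples()
    }


# ---------------------------------------------------------------------------
# reporting


def calls_frame(calls: Sequence[PseudogeneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "lesion_type": c.lesion_type,
                "ref_codon_index": c.ref_codon_index,
                "ref_nt_pos": c.ref_nt_pos,
                "detail": c.detail,
                "filters_failed": ";".join(sorted(c.filters_failed)),
                "verdict": "candidate" if c.passes else "filtered",
            }
            for c in calls
        ]
    )


def alignment_excerpt(pair: AlignedPair, call: PseudogeneCall, context: int = 15) -> str:
    """A local alignment window around a lesion, for reports."""
    # locate the alignment column of the call's ref position
    ref_pos = -1
    col = 0
    for col, ch in enumerate(pair.ref_seq):
        if ch != GAP:
            ref_pos += 1
            if ref_pos == call.ref_nt_pos:
                break
    lo, hi = max(0, col - context), min(len(pair.ref_seq), col + context + 1)
    marker = " " * (col - lo) + "^"
    return (
        f"ref    {pair.ref_seq[lo:hi]}\n"
        f"target {pair.target_seq[lo:hi]}\n"
        f"       {marker} {call.lesion_type} {call.detail}"
    )
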