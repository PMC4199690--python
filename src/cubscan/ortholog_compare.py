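"""Between-genome comparison of per-gene codon bias for shared orthologs.

Each ortholog pair contributes a point (D_a, D_b); genes with equal bias in
both species sit on the identity diagonal.  The signed difference
delta = D_a - D_b is the primary ranking key (negative: more biased in
species A); its perpendicular distance from the diagonal, |delta|/sqrt(2),
is the magnitude plotted in between-genome scatters.  Distribution
asymmetry (more strongly biased orthologs in one species) is summarized by
threshold counts and an assumption-free sign test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cub_entropy import CUBResult

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


@dataclass
class OrthologPair:
    gene_id: str
    d_a: float
    d_b: float

    @property
    def delta(self) -> float:
        return self.d_a - self.d_b

    @property
    def diag_dist(self) -> float:
        return abs(self.delta) / SQRT2


@dataclass
class PairingSummary:
    pairs: list[OrthologPair]
    unpaired_a: int
    unpaired_b: int
    skipped_map_rows: int


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping species-A gene ids to species-B gene ids."""
    mapping: dict[str, str] = {}
    dups = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            a, b = fields[0], fields[1]
            if a in mapping:
                dups += 1
                continue
            mapping[a] = b
    if dups:
        logger.warning("deduplicated %d repeated ortholog-map rows", dups)
    return mapping


def pair_orthologs(
    results_a: Sequence[CUBResult],
    results_b: Sequence[CUBResult],
    ortholog_map: Mapping[str, str] | None = None,
) -> PairingSummary:
    """Pair per-species scores via an ortholog map (identity map if None).

    Scores from different estimators are not comparable and are refused.
    Map rows referencing genes unscored in either species are skipped with
    a log message.
    """
    est_a = {r.estimator for r in results_a}
    est_b = {r.estimator for r in results_b}
    if est_a and est_b and est_a != est_b:
        raise ValueError(
            f"estimator mismatch between species: {sorted(est_a)} vs {sorted(est_b)}"
        )
    d_a = {r.gene_id: r.d for r in results_a}
    d_b = {r.gene_id: r.d for r in results_b}
    if ortholog_map is None:
        ortholog_map = {g: g for g in d_a}
    seen_map = {}
    dup_rows = 0
    for a, b in ortholog_map.items():
        if a in seen_map:
            dup_rows += 1
            continue
        seen_map[a] = b

    pairs: list[OrthologPair] = []
    skipped = 0
    paired_a: set[str] = set()
    paired_b: set[str] = set()
    for a, b in sorted(seen_map.items()):
        if a not in d_a or b not in d_b:
            skipped += 1
            continue
        pairs.append(OrthologPair(gene_id=a, d_a=d_a[a], d_b=d_b[b]))
        paired_a.add(a)
        paired_b.add(b)
    if skipped:
        logger.info("skipped %d map rows referencing unscored genes", skipped)
    if not pairs:
        logger.warning("no ortholog pairs shared between the two score sets")
    return PairingSummary(
        pairs=pairs,
        unpaired_a=len(d_a) - len(paired_a),
        unpaired_b=len(d_b) - len(paired_b),
        skipped_map_rows=skipped + dup_rows,
    )


def rank_pairs(
    pairs: Sequence[OrthologPair], direction: str = "a_more_biased"
) -> list[OrthologPair]:
    """Order pairs by differential bias.

    ``a_more_biased``: most negative delta first; ``b_more_biased``: most
    positive delta first; ``either``: by distance from the diagonal,
    descending.
    """
    if direction == "a_more_biased":
        return sorted(pairs, key=lambda p: (p.delta, p.gene_id))
    if direction == "b_more_biased":
        return sorted(pairs, key=lambda p: (-p.delta, p.gene_id))
    if direction == "either":
        return sorted(pairs, key=lambda p: (-p.diag_dist, p.gene_id))
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class AsymmetrySummary:
    threshold: float
    n_a_more_biased: int  # delta < -t
    n_b_more_biased: int  # delta > +t
    sign_test_p: float | None
    median_delta: float


def mad_threshold(pairs: Sequence[OrthologPair], k: float = 2.0) -> float:
    """k times the median absolute deviation of deltas: a scale-adaptive
    cutoff for calling a pair differentially biased."""
    deltas = np.array([p.delta for p in pairs])
    return float(k * np.median(np.abs(deltas - np.median(deltas))))


def asymmetry(pairs: Sequence[OrthologPair], threshold: float) -> AsymmetrySummary:
    """Count strongly shifted pairs each way and sign-test their symmetry."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    deltas = np.array([p.delta for p in pairs])
    n_neg = int((deltas < -threshold).sum())
    n_pos = int((deltas > threshold).sum())
    if n_neg + n_pos == 0:
        logger.warning("no pair exceeds threshold %.4g; sign test undefined", threshold)
        p = None
    else:
        p = float(stats.binomtest(n_neg, n_neg + n_pos, 0.5).pvalue)
    return AsymmetrySummary(
        threshold=threshold,
        n_a_more_biased=n_neg,
        n_b_more_biased=n_pos,
        sign_test_p=p,
        median_delta=float(np.median(deltas)) if len(deltas) else float("nan"),
    )


def pairs_frame(pairs: Sequence[OrthologPair], direction: str = "a_more_biased") -> pd.DataFrame:
    ranked = rank_pairs(pairs, direction)
    return pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "d_a": p.d_a,
                "d_b": p.d_b,
                "delta": p.delta,
                "diag_dist": p.diag_dist,
                "rank": i,
            }
            for i, p in enumerate(ranked, 1)
        ]
    )
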