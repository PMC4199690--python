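"""Flexible-threshold ranked-list enrichment (minimum hypergeometric, mHG).

Given a ranked gene list (best first) and a gene-set collection, the mHG
score of a set is the minimum, over every prefix length n, of the
hypergeometric tail probability of seeing b(n) set members in the top n.
Because the threshold is optimized, the raw score is not a p-value; the
exact p-value is computed by dynamic programming over the lattice of
(prefix length, members seen) states, counting the probability that a
random permutation of set labels never enters the rejection region.
Benjamini-Hochberg q-values are computed across all tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: relative tolerance for "tail probability <= mHG score" when building the
#: DP rejection region; absorbs float round-off in scipy's sf
_REL_TOL = 1e-9


@dataclass
class GeneSetCollection:
    """term_id -> member gene symbols, with optional display names."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str]

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{ln}: GMT needs >= 3 tab-separated fields")
                term, name, *genes = fields
                sets[term] = frozenset(g for g in genes if g)
                names[term] = name
        return cls(sets=sets, names=names)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.sets):
                genes = "\t".join(sorted(self.sets[term]))
                fh.write(f"{term}\t{self.names.get(term, term)}\t{genes}\n")


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    n_universe: int
    b_term: int
    n_star: int
    b_star: int
    mhg_score: float
    p_value: float
    q_value: float | None
    leading_genes: tuple[str, ...]


def dedup_ranked(ranked: Sequence[str]) -> tuple[list[str], int]:
    """Keep the first (best-ranked) occurrence of each symbol."""
    seen: set[str] = set()
    out: list[str] = []
    removed = 0
    for g in ranked:
        if g in seen:
            removed += 1
            continue
        seen.add(g)
        out.append(g)
    if removed:
        logger.info("removed %d duplicate symbols from ranked list", removed)
    return out, removed


def hypergeom_tail(b: int, n_universe: int, b_term: int, n: int) -> float:
    """P(X >= b) for X ~ Hypergeometric(N, B, n)."""
    if not (0 <= b <= min(n, b_term) and b_term <= n_universe and n <= n_universe):
        raise ValueError(
            f"invalid hypergeometric arguments b={b}, N={n_universe}, B={b_term}, n={n}"
        )
    if b == 0:
        return 1.0
    return float(stats.hypergeom.sf(b - 1, n_universe, b_term, n))


def mhg(ranked: Sequence[str], term_set: Iterable[str]) -> tuple[float, int, int]:
    """Minimum hypergeometric tail over all prefix thresholds.

    Returns (mhg_score, n_star, b_star) with ties on the score resolved to
    the smallest threshold.
    """
    members = set(term_set) & set(ranked)
    if not members:
        raise ValueError("term empty after intersection with ranked list")
    n_univ = len(ranked)
    b_total = len(members)
    indicator = np.fromiter((g in members for g in ranked), dtype=bool, count=n_univ)
    b_at = np.cumsum(indicator)
    n_arr = np.arange(1, n_univ + 1)
    tails = np.where(
        b_at > 0, stats.hypergeom.sf(b_at - 1, n_univ, b_total, n_arr), 1.0
    )
    i = int(np.argmin(tails))  # argmin takes the first (smallest n) on ties
    return float(tails[i]), int(n_arr[i]), int(b_at[i])


def mhg_pvalue(mhg_score: float, n_universe: int, b_term: int) -> float:
    """Exact p-value of an mHG score by lattice dynamic programming.

    A random ranking corresponds to a uniformly random path from (0, 0) to
    (N, B) in (prefix length, members seen) space.  Cells whose
    hypergeometric tail is <= the observed score form the rejection region;
    the DP accumulates the probability of reaching (N, B) without touching
    it, and p is the complement.
    """
    if b_term == 0 or b_term > n_universe:
        raise ValueError("term size must satisfy 0 < B <= N")
    if mhg_score >= 1.0 or b_term == n_universe:
        return 1.0  # degenerate: score uninformative or only one labeling
    n_univ, b_tot = n_universe, b_term
    cutoff = mhg_score * (1.0 + _REL_TOL)
    # rejection[b, n]: tail prob of >= b members in prefix n is <= score
    b_grid = np.arange(b_tot + 1)
    prob = np.zeros(b_tot + 1)
    prob[0] = 1.0
    survive = 0.0
    for n in range(1, n_univ + 1):
        lo = max(0, b_tot - (n_univ - n))  # members that must already be seen
        hi = min(n, b_tot)
        # advance one step: at prefix n-1 with b members, next gene is a
        # member with prob (B - b)/(N - (n-1))
        remaining = n_univ - (n - 1)
        p_member = (b_tot - b_grid) / remaining
        new = prob * (1.0 - p_member)
        new[1:] += prob[:-1] * p_member[:-1]
        # zero out the rejection region at this prefix length
        bs = np.arange(lo, hi + 1)
        tails = np.where(bs > 0, stats.hypergeom.sf(bs - 1, n_univ, b_tot, n), 1.0)
        reject = tails <= cutoff
        new[lo : hi + 1] = np.where(reject, 0.0, new[lo : hi + 1])
        prob = new
    survive = prob[b_tot]
    p = 1.0 - float(survive)
    return min(1.0, max(p, mhg_score))  # p can never fall below the raw tail


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(
    ranked: Sequence[str],
    collection: GeneSetCollection | Mapping[str, Iterable[str]],
    min_size: int = 3,
    max_size: int = 2000,
) -> list[EnrichmentResult]:
    """Run the full single-ranked-list enrichment.

    The ranked list is deduplicated (best occurrence kept).  The universe is
    restricted to ranked genes carrying at least one annotation; terms are
    intersected with that universe and filtered to ``min_size <= B <=
    max_size``.  Results are sorted by p-value.
    """
    if isinstance(collection, GeneSetCollection):
        sets, names = collection.sets, collection.names
    else:
        sets = {t: frozenset(g) for t, g in collection.items()}
        names = {t: t for t in sets}
    ranked_dedup, _ = dedup_ranked(ranked)
    annotated = set().union(*sets.values()) if sets else set()
    universe = [g for g in ranked_dedup if g in annotated]
    dropped = len(ranked_dedup) - len(universe)
    if dropped:
        logger.info("dropped %d unannotated genes from the universe", dropped)
    if not universe:
        return []

    results: list[EnrichmentResult] = []
    for term in sorted(sets):
        members = sets[term] & set(universe)
        b_tot = len(members)
        if not (min_size <= b_tot <= max_size):
            continue
        score, n_star, b_star = mhg(universe, members)
        p = mhg_pvalue(score, len(universe), b_tot)
        leading = tuple(g for g in universe[:n_star] if g in members)
        results.append(
            EnrichmentResult(
                term_id=term,
                name=names.get(term, term),
                n_universe=len(universe),
                b_term=b_tot,
                n_star=n_star,
                b_star=b_star,
                mhg_score=score,
                p_value=p,
                q_value=None,
                leading_genes=leading,
            )
        )
    if results:
        qs = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "N": r.n_universe,
                "B": r.b_term,
                "n_star": r.n_star,
                "b_star": r.b_star,
                "mhg_score": r.mhg_score,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "leading_genes": ";".join(r.leading_genes),
            }
            for r in results
        ]
    )
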