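"""End-to-end orchestration of the two analysis arms.

Within-genome: score every CDS, rank by differential entropy, run
ranked-list enrichment, and emit the genome-wide usage table.
Between-genome: pair ortholog scores from two runs and summarize the
asymmetry of differential bias.  Validation: ENC per gene and its
correlation with the entropy statistic.

Every artifact is a TSV with a provenance header (tool version, config
hash, master seed) so that runs with equal headers are byte-identical.
A stage that fails mid-write leaves ``<output>.failed`` beside the partial
file instead of a silently truncated artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .codon_core import count_codons
from .cub_entropy import CUBConfig, CUBResult, rank_genes, score_genes
from .enc_stat import enc_genes, enc_vs_entropy
from .enrichment import GeneSetCollection, enrich, results_frame
from .ortholog_compare import (
    asymmetry,
    mad_threshold,
    pair_orthologs,
    pairs_frame,
    read_ortholog_map,
)
from .seq_io import CodingSequence, read_cds_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    cds_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "."
    policy: str = "trim"
    n_random: int = 20
    estimator: str = "codon_shannon"
    null_model: str = "uniform_synonymous"
    master_seed: int = 0
    min_term_size: int = 3
    max_term_size: int = 2000

    def cub_config(self) -> CUBConfig:
        return CUBConfig(
            n_random=self.n_random,
            estimator=self.estimator,
            null_model=self.null_model,
            master_seed=self.master_seed,
        )

    def config_hash(self) -> str:
        # output location does not affect artifact content, so it is not
        # part of the identity hash
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_header(config: RunConfig, **extra: object) -> str:
    fields = {
        "tool": f"cubscan {__version__}",
        "config_hash": config.config_hash(),
        "seed": config.master_seed,
        "estimator": config.estimator,
        **extra,
    }
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def write_tsv(df: pd.DataFrame, path: str | Path, header: str = "") -> None:
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
    except Exception:
        path.with_name(path.name + ".failed").touch()
        raise


def scores_frame(results: Sequence[CUBResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_codons": r.n_codons,
                "h_obs": r.h_obs,
                "h_null_mean": r.h_null_mean,
                "h_null_sd": r.h_null_sd,
                "d": r.d,
                "rank": r.rank,
            }
            for r in results
        ]
    )


def read_scores_tsv(path: str | Path) -> tuple[list[CUBResult], dict[str, str]]:
    """Read a score TSV back, including its provenance header."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
    df = pd.read_csv(path, sep="\t", comment="#")
    results = [
        CUBResult(
            gene_id=str(row.gene_id),
            h_obs=float(row.h_obs),
            h_null_mean=float(row.h_null_mean),
            h_null_sd=float(row.h_null_sd),
            d=float(row.d),
            n_codons=int(row.n_codons),
            estimator=meta.get("estimator", "codon_shannon"),
            seed=0,
            rank=int(row.rank) if pd.notna(row.rank) else None,
        )
        for row in df.itertuples()
    ]
    return results, meta


@dataclass
class WithinGenomeOutput:
    ranked: list[CUBResult]
    skipped: list[str]
    enrichment: list
    usage_frame: pd.DataFrame


def run_within_genome(
    config: RunConfig, genes: Sequence[CodingSequence] | None = None
) -> WithinGenomeOutput:
    """score -> dedup -> rank -> enrich, plus the genome usage table."""
    if genes is None:
        if config.cds_path is None:
            raise ValueError("no CDS input provided")
        genes = read_cds_fasta(config.cds_path, policy=config.policy)
    logger.info("read %d genes", len(genes))

    usage = count_codons(genes)
    results, skipped = score_genes(genes, config.cub_config())
    ranked = rank_genes(results)

    enr = []
    if config.gmt_path is not None:
        collection = GeneSetCollection.from_gmt(config.gmt_path)
        enr = enrich(
            [r.gene_id for r in ranked],
            collection,
            min_size=config.min_term_size,
            max_size=config.max_term_size,
        )
    else:
        logger.warning("no gene-set GMT supplied; enrichment stage skipped")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(config)
    write_tsv(scores_frame(ranked), out_dir / "scores.tsv", header)
    write_tsv(usage.to_frame(), out_dir / "usage_table.tsv", header)
    if enr:
        write_tsv(results_frame(enr), out_dir / "enrichment.tsv", header)
    logger.info(
        "scored %d genes (%d ineligible), %d enriched terms tested",
        len(ranked),
        len(skipped),
        len(enr),
    )
    return WithinGenomeOutput(
        ranked=ranked, skipped=skipped, enrichment=enr, usage_frame=usage.to_frame()
    )


@dataclass
class BetweenGenomeOutput:
    pairs_table: pd.DataFrame
    summary: object
    unpaired_a: int
    unpaired_b: int


def run_between_genomes(
    config: RunConfig,
    scores_a_path: str | Path,
    scores_b_path: str | Path,
    map_path: str | Path | None = None,
    threshold: float | None = None,
) -> BetweenGenomeOutput:
    results_a, meta_a = read_scores_tsv(scores_a_path)
    results_b, meta_b = read_scores_tsv(scores_b_path)
    if meta_a.get("estimator") != meta_b.get("estimator"):
        raise ValueError(
            "estimator mismatch between score files: "
            f"{meta_a.get('estimator')} vs {meta_b.get('estimator')}"
        )
    mapping = read_ortholog_map(map_path) if map_path else None
    pairing = pair_orthologs(results_a, results_b, mapping)
    if threshold is None:
        threshold = mad_threshold(pairing.pairs) or 1e-9
    summary = asymmetry(pairing.pairs, threshold)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(config, threshold=threshold)
    table = pairs_frame(pairing.pairs)
    write_tsv(table, out_dir / "ortholog_pairs.tsv", header)
    summary_df = pd.DataFrame(
        [
            {
                "threshold": summary.threshold,
                "n_a_more_biased": summary.n_a_more_biased,
                "n_b_more_biased": summary.n_b_more_biased,
                "sign_test_p": summary.sign_test_p,
                "median_delta": summary.median_delta,
                "unpaired_a": pairing.unpaired_a,
                "unpaired_b": pairing.unpaired_b,
            }
        ]
    )
    write_tsv(summary_df, out_dir / "asymmetry_summary.tsv", header)
    return BetweenGenomeOutput(
        pairs_table=table,
        summary=summary,
        unpaired_a=pairing.unpaired_a,
        unpaired_b=pairing.unpaired_b,
    )


@dataclass
class ValidationOutput:
    enc_frame: pd.DataFrame
    correlation: float | None
    scatter: pd.DataFrame | None


def run_validation(
    config: RunConfig, genes: Sequence[CodingSequence] | None = None
) -> ValidationOutput:
    """ENC per gene plus the ENC-vs-differential-entropy correlation."""
    if genes is None:
        if config.cds_path is None:
            raise ValueError("no CDS input provided")
        genes = read_cds_fasta(config.cds_path, policy=config.policy)
    enc_results, flagged = enc_genes(genes)
    results, _ = score_genes(genes, config.cub_config())

    enc_df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "enc": r.enc,
                "F2": r.f2,
                "F3": r.f3,
                "F4": r.f4,
                "F6": r.f6,
                "families_used": r.families_used,
            }
            for r in enc_results
        ]
    )
    correlation, scatter = None, None
    try:
        correlation, scatter = enc_vs_entropy(enc_results, results)
    except ValueError as exc:
        logger.warning("ENC-vs-entropy correlation undefined: %s", exc)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(config, flagged_genes=len(flagged))
    write_tsv(enc_df, out_dir / "enc.tsv", header)
    if scatter is not None:
        write_tsv(scatter, out_dir / "enc_vs_entropy.tsv", header)
    return ValidationOutput(enc_frame=enc_df, correlation=correlation, scatter=scatter)
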