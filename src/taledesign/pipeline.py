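"""End-to-end design and audit pipelines.

``run_design`` chains candidate generation -> genome-distance filtering ->
mismatch-bounded scanning -> selection of the closest off-targets ->
off-target scoring -> neverword scoring -> ranking, and writes ranked
reports.  ``run_audit`` produces the mismatch census and (given an
annotation) the gene-category table for a single, already-designed EBE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from taledesign.candidate_generation import (
    GenerationConfig,
    filter_by_genome_distance,
    generate_candidates,
    write_candidates_fasta,
)
from taledesign.gene_context import (
    build_gene_models,
    classify_site,
    summarize_categories,
    write_category_table,
)
from taledesign.genome_scan import (
    GenomeLike,
    MismatchCensus,
    census_by_mismatch,
    closest_offtargets,
    load_genome,
    scan_genome,
    write_hits_bed,
    write_hits_tsv,
)
from taledesign.offtarget_scoring import (
    CandidateReport,
    neverword_score,
    rank_candidates,
    score_offtarget,
    write_reports_json,
    write_reports_tsv,
)
from taledesign.preference import PreferenceMatrix, default_preference_matrix
from taledesign.tale_code import EBESequence, ebe_to_rvds

logger = logging.getLogger("taledesign")

__all__ = ["DesignRunConfig", "run_design", "run_audit"]


@dataclass
class DesignRunConfig:
    """Parameters of one design or audit run."""

    genome: GenomeLike | str | Path
    annotation: str | Path | None = None
    matrix: PreferenceMatrix | None = None
    n_candidates: int = 100
    ebe_length: int = 19
    max_mismatch: int = 4            # census budget (<75% identity excluded)
    scoring_max_mismatch: int = 6    # scan ceiling when collecting scorable sites
    min_genome_distance: int = 3
    min_pairwise_distance: int = 2
    n_closest: int = 200
    min_score_mismatch: int = 3
    strands: str = "both"
    seed: int = 0
    out_dir: str | Path | None = None
    base_weights: dict[str, float] | None = None

    def resolved_matrix(self) -> PreferenceMatrix:
        return self.matrix if self.matrix is not None else default_preference_matrix()


def run_design(config: DesignRunConfig) -> list[CandidateReport]:
    """Design an orthogonal EBE: generate, filter, scan, score, rank.

    Returns reports ordered by rank (rank 1 = selected design); writes
    ranked TSV/JSON and per-candidate hit tables under ``out_dir`` when
    one is configured.  Deterministic for a fixed seed.
    """
    genome = load_genome(config.genome)
    matrix = config.resolved_matrix()
    gen_config = GenerationConfig(
        length=config.ebe_length,
        n_candidates=config.n_candidates,
        min_pairwise_distance=config.min_pairwise_distance,
        min_genome_distance=config.min_genome_distance,
        rng_seed=config.seed,
        **(
            {"base_weights": dict(config.base_weights)}
            if config.base_weights
            else {}
        ),
    )
    candidates = generate_candidates(gen_config)
    logger.info("stage generate: %d candidates (seed %d)", len(candidates), config.seed)
    kept = filter_by_genome_distance(candidates, genome, config.min_genome_distance)
    logger.info(
        "stage filter: %d/%d candidates at genome distance >= %d",
        len(kept), len(candidates), config.min_genome_distance,
    )
    reports = []
    for ebe in kept:
        report = _score_candidate(ebe, genome, matrix, config)
        if report is not None:
            reports.append(report)
    logger.info("stage score: %d candidates with scorable off-target sets", len(reports))
    ranked = rank_candidates(reports)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_candidates_fasta(kept, out / "candidates.fasta")
        write_reports_tsv(ranked, out / "ranked_candidates.tsv")
        write_reports_json(ranked, out / "ranked_candidates.json")
    return ranked


def _score_candidate(
    ebe: EBESequence,
    genome: GenomeLike,
    matrix: PreferenceMatrix,
    config: DesignRunConfig,
) -> CandidateReport | None:
    hits = scan_genome(
        ebe, genome, max_mismatch=config.scoring_max_mismatch, strands=config.strands
    )
    closest, short = closest_offtargets(
        hits, n=config.n_closest, min_mismatch=config.min_score_mismatch
    )
    if not closest:
        # perfectly orthogonal at the scan ceiling: nothing to score
        return None
    rvds = ebe_to_rvds(ebe)
    scores = [
        score_offtarget(ebe, rvds, h.site_sequence, matrix) for h in closest
    ]
    result = neverword_score(scores)
    census = census_by_mismatch(hits, max_mismatch=config.scoring_max_mismatch)
    return CandidateReport(
        ebe=ebe,
        s_n=result.s_n,
        ratio=result.ratio,
        n_offtargets_by_mismatch={k: v for k, v in census.counts.items() if v},
        n_scored=result.n,
        short_set=short,
    )


def run_audit(
    ebe: EBESequence,
    config: DesignRunConfig,
    expressed_gene_ids: set[str] | None = None,
    up_gene_ids: set[str] | None = None,
    down_gene_ids: set[str] | None = None,
) -> dict:
    """Audit one EBE against a genome: census, hits, and gene categories.

    Returns a dict with ``hits``, ``census``, and — when an annotation is
    configured — ``annotations`` and ``category_table``.  Optional gene-ID
    sets (computed externally, e.g. by differential expression) populate
    '# Expressed'/'# Up'/'# Down' columns.  Writes BED/TSV outputs under
    ``out_dir`` when configured.
    """
    genome = load_genome(config.genome)
    hits = scan_genome(
        ebe, genome, max_mismatch=config.max_mismatch, strands=config.strands
    )
    census = census_by_mismatch(hits, max_mismatch=config.max_mismatch)
    logger.info(
        "audit: %d hits within %d mismatches", len(hits), config.max_mismatch
    )
    result: dict = {"hits": hits, "census": census}
    if config.annotation is not None:
        genes = build_gene_models(config.annotation)
        annotations = [a for h in hits for a in classify_site(h, genes)]
        table = summarize_categories(
            annotations,
            expressed_gene_ids=expressed_gene_ids,
            up_gene_ids=up_gene_ids,
            down_gene_ids=down_gene_ids,
        )
        result["annotations"] = annotations
        result["category_table"] = table
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_hits_bed(hits, out / "hits.bed")
        write_hits_tsv(hits, out / "hits.tsv")
        _write_census(census, out / "census.tsv")
        if "category_table" in result:
            write_category_table(result["category_table"], out / "categories.tsv")
    return result


def _write_census(census: MismatchCensus, path: Path) -> None:
    lines = ["# n_mismatch\tn_sites"]
    for k in sorted(census.counts):
        lines.append(f"{k}\t{census.counts[k]}")
    path.write_text("\n".join(lines) + "\n")
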