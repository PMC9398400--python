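"""Random candidate EBE generation and genome-distance filtering.

Candidates are "neverwords": sequences absent from the host genome by a
margin of at least a minimum Hamming distance on either strand.  They are
produced generate-then-filter — seeded rejection sampling of T-initial
19-mers with rice-like composition weights and a minimum pairwise
distance, followed by a genome scan that discards any candidate with a
too-close genomic window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from taledesign.genome_scan import GenomeLike, load_genome, scan_genome
from taledesign.tale_code import EBESequence, validate_ebe

__all__ = [
    "GenerationConfig",
    "InfeasibleGenerationError",
    "generate_candidates",
    "filter_by_genome_distance",
    "write_candidates_fasta",
    "read_candidates",
]

#: Default base composition A:C:G:T used for positions after T0;
#: 4:5:5:5 approximates rice GC content (~53% GC over sampled positions).
DEFAULT_BASE_WEIGHTS = {"A": 4.0, "C": 5.0, "G": 5.0, "T": 5.0}


class InfeasibleGenerationError(RuntimeError):
    """Rejection sampling exhausted its attempt budget without producing
    the requested number of mutually distant candidates."""


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the candidate generator.

    ``min_genome_distance`` is the Hamming margin a candidate must keep to
    every same-length genomic window on either strand (default 3, the
    "minimal edit distance of three" of the generating procedure);
    ``min_pairwise_distance`` is the margin between any two candidates.
    """

    length: int = 19
    n_candidates: int = 100
    base_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_WEIGHTS)
    )
    min_genome_distance: int = 3
    min_pairwise_distance: int = 2
    rng_seed: int = 0
    max_attempts_factor: int = 100

    def __post_init__(self) -> None:
        if self.length < 12:
            raise ValueError("length must be >= 12")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if set(self.base_weights) != set("ACGT"):
            raise ValueError("base_weights must cover exactly A, C, G, T")
        if any(w <= 0 for w in self.base_weights.values()):
            raise ValueError("base weights must be positive")
        if self.min_genome_distance < 0 or self.min_pairwise_distance < 0:
            raise ValueError("distances must be >= 0")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_candidates(config: GenerationConfig) -> list[EBESequence]:
    """Draw ``n_candidates`` distinct T-initial sequences.

    Bases 2..L are i.i.d. with the configured composition weights; T0 is
    fixed, not sampled.  Accepted candidates keep pairwise Hamming
    distance >= ``min_pairwise_distance``.  Deterministic for a fixed
    ``rng_seed``; raises :class:`InfeasibleGenerationError` after
    ``max_attempts_factor * n_candidates`` rejections.
    """
    # domain-separated stream: the same user seed must not replay the
    # base draws of other components (e.g. a fixture genome built from it)
    rng = np.random.default_rng([config.rng_seed, 0xCA7D])
    bases = np.array(list("ACGT"))
    weights = np.array([config.base_weights[b] for b in "ACGT"], dtype=float)
    probs = weights / weights.sum()
    accepted: list[str] = []
    max_attempts = config.max_attempts_factor * config.n_candidates
    attempts = 0
    while len(accepted) < config.n_candidates:
        if attempts >= max_attempts:
            raise InfeasibleGenerationError(
                f"accepted only {len(accepted)}/{config.n_candidates} candidates "
                f"after {attempts} attempts (length={config.length}, "
                f"min_pairwise_distance={config.min_pairwise_distance})"
            )
        attempts += 1
        tail = "".join(rng.choice(bases, size=config.length - 1, p=probs))
        seq = "T" + tail
        if all(_hamming(seq, prev) >= config.min_pairwise_distance for prev in accepted):
            accepted.append(seq)
    return [validate_ebe(s, length=config.length) for s in accepted]


def filter_by_genome_distance(
    candidates: list[EBESequence],
    genome: GenomeLike | str | Path,
    min_distance: int = 3,
) -> list[EBESequence]:
    """Keep candidates whose closest genomic window has >= min_distance
    mismatches (ungapped Hamming, both strands); order-preserving subset.
    """
    if min_distance <= 0:
        return list(candidates)
    contigs = load_genome(genome)
    kept = []
    for ebe in candidates:
        close = scan_genome(ebe, contigs, max_mismatch=min_distance - 1, strands="both")
        if not close:
            kept.append(ebe)
    return kept


def write_candidates_fasta(candidates: list[EBESequence], path: str | Path) -> None:
    """Multi-record FASTA with sequential candidate IDs."""
    lines = []
    for i, ebe in enumerate(candidates, start=1):
        lines.append(f">candidate_{i}")
        lines.append(str(ebe))
    Path(path).write_text("\n".join(lines) + "\n")


def read_candidates(path: str | Path, length: int = 19) -> list[EBESequence]:
    """Read candidates from multi-record FASTA or one-sequence-per-line text."""
    from Bio import SeqIO

    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [
            validate_ebe(str(rec.seq), length=length)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    return [
        validate_ebe(line, length=length)
        for line in text.splitlines()
        if line.strip()
    ]
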