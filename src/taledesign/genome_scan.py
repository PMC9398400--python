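"""Mismatch-bounded genome search for EBE near-matches, on both strands.

``scan_genome`` finds every genomic window within a mismatch budget of an
EBE using a pigeonhole seed filter: a window with at most k mismatches
must contain at least one of k+1 disjoint exact blocks of the query, so
only windows anchored by an exact block occurrence need full verification.
``brute_force_scan`` is the position-by-position oracle the filter must
agree with exactly; it is meant for tests and small inputs.

Coordinates are 0-based half-open; site sequences are reported in binding
orientation (reverse-complemented for minus-strand hits) so that mismatch
positions are EBE positions.  Soft-masked (lowercase) genome bases are
uppercased before comparison; any window containing a non-ACGT character
is disqualified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from taledesign.preference import position_factor
from taledesign.tale_code import EBESequence, MismatchProfile

__all__ = [
    "OffTargetHit",
    "MismatchCensus",
    "GenomeLike",
    "load_genome",
    "reverse_complement",
    "scan_genome",
    "brute_force_scan",
    "census_by_mismatch",
    "closest_offtargets",
    "write_hits_bed",
    "write_hits_tsv",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_ACGT = frozenset("ACGT")

GenomeLike = dict[str, str]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_genome(source: GenomeLike | str | Path) -> GenomeLike:
    """Return an ordered {contig name: uppercase sequence} mapping.

    Accepts an in-memory dict or a FASTA path (read via pyfaidx).
    """
    if isinstance(source, dict):
        return {name: seq.upper() for name, seq in source.items()}
    import pyfaidx

    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    fasta = pyfaidx.Fasta(str(path))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


@dataclass(frozen=True, order=True)
class OffTargetHit:
    """One near-match genomic window.

    ``site_sequence`` is in binding orientation (the strand the EBE would
    align to), so ``profile`` positions index into the EBE directly.
    Identity for deduplication and censusing is (chrom, start, strand).
    """

    chrom: str
    start: int
    end: int
    strand: str
    site_sequence: str
    profile: MismatchProfile

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.start, self.strand)


@dataclass(frozen=True)
class MismatchCensus:
    """Distinct-site histogram keyed by mismatch count (0..max)."""

    counts: dict[int, int]

    def __getitem__(self, k: int) -> int:
        return self.counts.get(k, 0)

    def total(self, min_mismatch: int = 0, max_mismatch: int | None = None) -> int:
        """Number of distinct sites with min_mismatch <= count (<= max)."""
        return sum(
            v
            for k, v in self.counts.items()
            if k >= min_mismatch and (max_mismatch is None or k <= max_mismatch)
        )


def _window_profile(query: str, window: str) -> MismatchProfile | None:
    """Mismatch profile, or None if the window holds a non-ACGT character."""
    positions = []
    for i, (q, w) in enumerate(zip(query, window), start=1):
        if w not in _ACGT:
            return None
        if q != w:
            positions.append(i)
    return MismatchProfile(tuple(positions))


def _strand_queries(ebe: EBESequence, strands: str) -> list[tuple[str, str]]:
    if strands not in {"+", "-", "both"}:
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    queries = []
    if strands in {"+", "both"}:
        queries.append(("+", str(ebe)))
    if strands in {"-", "both"}:
        # an EBE binding the minus strand appears as its reverse
        # complement on the plus-strand text we scan
        queries.append(("-", reverse_complement(str(ebe))))
    return queries


def _make_hit(
    ebe: EBESequence, chrom: str, start: int, strand: str, window: str
) -> OffTargetHit | None:
    site = window if strand == "+" else reverse_complement(window)
    profile = _window_profile(str(ebe), site)
    if profile is None:
        return None
    return OffTargetHit(
        chrom=chrom,
        start=start,
        end=start + len(ebe),
        strand=strand,
        site_sequence=site,
        profile=profile,
    )


def brute_force_scan(
    ebe: EBESequence,
    genome: GenomeLike | str | Path,
    max_mismatch: int = 4,
    strands: str = "both",
) -> list[OffTargetHit]:
    """Sliding-window oracle: compare the EBE against every window.

    Exactly equivalent to :func:`scan_genome`; quadratic-ish and intended
    for tests and small fixtures.
    """
    contigs = load_genome(genome)
    L = len(ebe)
    hits: list[OffTargetHit] = []
    for chrom, seq in contigs.items():
        for start in range(0, len(seq) - L + 1):
            window = seq[start : start + L]
            for strand, _ in _strand_queries(ebe, strands):
                hit = _make_hit(ebe, chrom, start, strand, window)
                if hit is not None and hit.profile.count <= max_mismatch:
                    hits.append(hit)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def _seed_blocks(query: str, n_blocks: int) -> list[tuple[int, str]]:
    """Split the query into n_blocks contiguous, near-equal exact blocks."""
    L = len(query)
    bounds = [round(i * L / n_blocks) for i in range(n_blocks + 1)]
    return [(bounds[i], query[bounds[i] : bounds[i + 1]]) for i in range(n_blocks)]


def scan_genome(
    ebe: EBESequence,
    genome: GenomeLike | str | Path,
    max_mismatch: int = 4,
    strands: str = "both",
) -> list[OffTargetHit]:
    """All windows within ``max_mismatch`` of the EBE, both strands by default.

    Pigeonhole filter: the query is split into max_mismatch+1 disjoint
    blocks; every window with <= max_mismatch mismatches matches at least
    one block exactly at its offset, so block occurrences (found with the
    C-level ``str.find``) anchor the only windows that need verification.
    Hits are sorted by (chrom, start, strand).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    contigs = load_genome(genome)
    L = len(ebe)
    hits: dict[tuple[str, int, str], OffTargetHit] = {}
    for strand, query in _strand_queries(ebe, strands):
        blocks = _seed_blocks(query, max_mismatch + 1)
        for chrom, seq in contigs.items():
            if len(seq) < L:
                continue
            candidate_starts: set[int] = set()
            for offset, block in blocks:
                if not block:
                    continue
                pos = seq.find(block)
                while pos != -1:
                    start = pos - offset
                    if 0 <= start <= len(seq) - L:
                        candidate_starts.add(start)
                    pos = seq.find(block, pos + 1)
            for start in candidate_starts:
                key = (chrom, start, strand)
                if key in hits:
                    continue
                window = seq[start : start + L]
                hit = _make_hit(ebe, chrom, start, strand, window)
                if hit is not None and hit.profile.count <= max_mismatch:
                    hits[key] = hit
    return sorted(hits.values(), key=lambda h: (h.chrom, h.start, h.strand))


def census_by_mismatch(
    hits: list[OffTargetHit], max_mismatch: int = 4
) -> MismatchCensus:
    """Histogram of distinct (chrom, start, strand) sites per mismatch count."""
    seen: set[tuple[str, int, str]] = set()
    counts = {k: 0 for k in range(max_mismatch + 1)}
    for hit in hits:
        if hit.key in seen:
            continue
        seen.add(hit.key)
        if hit.profile.count <= max_mismatch:
            counts[hit.profile.count] += 1
    return MismatchCensus(counts)


def closest_offtargets(
    hits: list[OffTargetHit],
    n: int = 200,
    min_mismatch: int = 3,
) -> tuple[list[OffTargetHit], bool]:
    """The n closest scorable off-targets (default the 200 with >= 3 mismatches).

    "Closest" orders primarily by ascending mismatch count; within a count
    class, windows whose mismatches sit T0-proximal (larger summed
    position factor, hence larger potential |S_OFF|) come first, then
    genomic coordinate for determinism.  Returns (hits, short_set) where
    short_set is True when fewer than n eligible sites exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = [h for h in hits if h.profile.count >= min_mismatch]
    eligible.sort(
        key=lambda h: (
            h.profile.count,
            -sum(position_factor(p) for p in h.profile.positions),
            h.chrom,
            h.start,
            h.strand,
        )
    )
    return eligible[:n], len(eligible) < n


def write_hits_bed(
    hits: list[OffTargetHit],
    path: str | Path,
    scores: dict[tuple[str, int, str], float] | None = None,
) -> None:
    """BED6: name = mismatch count; score = round(1000 * normalized S_OFF)
    when per-site scores are supplied, else 0."""
    if scores:
        lo = min(scores.values())
        hi = max(scores.values())
        span = (hi - lo) or 1.0
    lines = []
    for h in hits:
        if scores and h.key in scores:
            bed_score = round(1000 * (scores[h.key] - lo) / span)
        else:
            bed_score = 0
        lines.append(
            f"{h.chrom}\t{h.start}\t{h.end}\t{h.profile.count}\t{bed_score}\t{h.strand}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_hits_tsv(hits: list[OffTargetHit], path: str | Path) -> None:
    """Full hit table with binding-orientation sequence and mismatch profile."""
    lines = ["# chrom\tstart\tend\tstrand\tsite_sequence\tn_mismatch\tmismatch_positions"]
    for h in hits:
        positions = ",".join(map(str, h.profile.positions))
        lines.append(
            f"{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{h.site_sequence}\t"
            f"{h.profile.count}\t{positions}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
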