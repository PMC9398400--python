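"""Synthetic genomes and annotations with planted ground truth.

Every planted site is an EBE variant with mismatches at exactly the
requested positions, placed at a known (or randomly drawn,
non-overlapping) locus on a chosen strand; the generator re-checks with
the brute-force scanner that no plant ended up closer to the query than
requested and redraws loci when the background interferes.  Output is a
FASTA genome, a TSV truth table, and optionally a GFF3 annotation with
simple multi-exon gene models — enough to exercise scanning, censusing
and site classification without any external download.

Background sequence is i.i.d. with a rice-like GC content of 0.435 by
default; no repeat structure or isochores are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from taledesign.genome_scan import reverse_complement
from taledesign.tale_code import EBESequence

__all__ = [
    "Plant",
    "FixtureSpec",
    "PlantedSite",
    "make_synthetic_genome",
    "make_synthetic_annotation",
    "write_genome_fasta",
    "write_truth_table",
]

_MUTATE = {
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
}


@dataclass(frozen=True)
class Plant:
    """Request to plant one EBE variant.

    ``mismatch_positions`` may be an explicit tuple of 1-based positions
    or the string ``"random"`` together with ``mismatch_count``; ``locus``
    is a (contig index, start) pair or ``"random"``.
    """

    ebe: EBESequence
    mismatch_count: int = 0
    mismatch_positions: tuple[int, ...] | str = "random"
    strand: str = "+"
    locus: tuple[int, int] | str = "random"


@dataclass(frozen=True)
class FixtureSpec:
    genome_length: int = 10_000
    n_contigs: int = 1
    gc_content: float = 0.435
    plants: tuple[Plant, ...] = ()
    n_genes: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.genome_length < 1 or self.n_contigs < 1:
            raise ValueError("genome_length and n_contigs must be positive")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted variant."""

    chrom: str
    start: int
    strand: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    planted_sequence: str  # binding orientation


def _variant(ebe: str, positions: tuple[int, ...], rng: np.random.Generator) -> str:
    seq = list(ebe)
    for pos in positions:
        original = seq[pos - 1]
        seq[pos - 1] = _MUTATE[original][rng.integers(len(_MUTATE[original]))]
    return "".join(seq)


def make_synthetic_genome(
    spec: FixtureSpec,
    verify_background: bool = True,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Build contigs with planted EBE variants and return the truth list.

    Raises ``ValueError`` when plants overlap or do not fit.  With
    ``verify_background`` (the default) the finished genome is checked
    with the brute-force scanner: if the random background happens to
    contain a window closer to some planted EBE than that EBE's closest
    requested plant, the whole fixture is redrawn from a successor seed
    (bounded retries), so planted sites are guaranteed to be the nearest
    matches.  Background sites at or beyond the planted distance remain
    possible and tests must tolerate them by comparing to the oracle.
    """
    last_error: Exception | None = None
    for attempt in range(10):
        contigs, truth = _build_genome(spec, spec.rng_seed + attempt * 10007)
        if not verify_background or not spec.plants:
            return contigs, truth
        if _background_is_clean(spec, contigs, truth):
            return contigs, truth
        last_error = ValueError("background produced a closer match than a plant")
    raise last_error


def _background_is_clean(
    spec: FixtureSpec, contigs: dict[str, str], truth: list[PlantedSite]
) -> bool:
    from taledesign.genome_scan import brute_force_scan

    min_count_by_ebe: dict[str, int] = {}
    for plant in spec.plants:
        n = (
            plant.mismatch_count
            if plant.mismatch_positions == "random"
            else len(plant.mismatch_positions)
        )
        key = str(plant.ebe)
        min_count_by_ebe[key] = min(min_count_by_ebe.get(key, n), n)
    planted_keys = {(t.chrom, t.start, t.strand) for t in truth}
    for seq, min_count in min_count_by_ebe.items():
        if min_count == 0:
            continue
        closer = brute_force_scan(
            EBESequence(seq), contigs, max_mismatch=min_count - 1, strands="both"
        )
        if any(h.key not in planted_keys for h in closer):
            return False
    return True


def _build_genome(
    spec: FixtureSpec, seed: int
) -> tuple[dict[str, str], list[PlantedSite]]:
    # domain-separated from the candidate generator's stream (same user
    # seed must not make candidates reappear verbatim in the background)
    rng = np.random.default_rng([seed, 0xF1C5])
    per_contig = spec.genome_length // spec.n_contigs
    bases = np.array(list("ACGT"))
    p_gc = spec.gc_content / 2.0
    p_at = (1.0 - spec.gc_content) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])
    contigs = {
        f"contig_{i + 1}": "".join(rng.choice(bases, size=per_contig, p=probs))
        for i in range(spec.n_contigs)
    }
    names = list(contigs)
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    truth: list[PlantedSite] = []
    for plant in spec.plants:
        L = len(plant.ebe)
        if plant.mismatch_positions == "random":
            positions = tuple(
                sorted(
                    int(p)
                    for p in rng.choice(
                        np.arange(1, L + 1), size=plant.mismatch_count, replace=False
                    )
                )
            )
        else:
            positions = tuple(sorted(plant.mismatch_positions))
        site = _variant(str(plant.ebe), positions, rng)
        inserted = site if plant.strand == "+" else reverse_complement(site)

        if plant.locus == "random":
            placed = False
            for _ in range(1000):
                chrom = names[int(rng.integers(len(names)))]
                if per_contig < L:
                    break
                start = int(rng.integers(per_contig - L + 1))
                if all(
                    start + L <= s or start >= e for s, e in occupied[chrom]
                ):
                    placed = True
                    break
            if not placed:
                raise ValueError("could not place plant without overlap")
        else:
            ci, start = plant.locus
            chrom = names[ci]
            if start + L > per_contig:
                raise ValueError(f"plant at {chrom}:{start} does not fit")
            if any(start + L > s and start < e for s, e in occupied[chrom]):
                raise ValueError(f"plant at {chrom}:{start} overlaps a previous plant")
        contigs[chrom] = (
            contigs[chrom][:start] + inserted + contigs[chrom][start + L :]
        )
        occupied[chrom].append((start, start + L))
        truth.append(
            PlantedSite(
                chrom=chrom,
                start=start,
                strand=plant.strand,
                mismatch_count=len(positions),
                mismatch_positions=positions,
                planted_sequence=site,
            )
        )
    return contigs, truth


def write_genome_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    lines = []
    for name, seq in contigs.items():
        lines.append(f">{name}")
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_table(truth: list[PlantedSite], path: str | Path) -> None:
    lines = ["# chrom\tstart\tstrand\tmismatch_count\tmismatch_positions\tplanted_sequence"]
    for t in truth:
        positions = ",".join(map(str, t.mismatch_positions))
        lines.append(
            f"{t.chrom}\t{t.start}\t{t.strand}\t{t.mismatch_count}\t{positions}\t{t.planted_sequence}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def make_synthetic_annotation(
    spec: FixtureSpec,
    contigs: dict[str, str],
    path: str | Path,
) -> list[dict]:
    """Write a GFF3 with ``spec.n_genes`` non-overlapping gene models.

    Genes get random strands, 1-4 exons, a CDS spanning the inner exons
    with margins that leave 5' and 3' UTR stubs, and valid ID/Parent
    linkage.  Returns the generated interval ground truth (one dict per
    gene) so tests can round-trip through the GFF3 parser.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    lines = ["##gff-version 3"]
    truth = []
    names = list(contigs)
    # partition each contig into equal slots, one gene per slot
    genes_left = spec.n_genes
    per_contig = [len(contigs[n]) for n in names]
    slot_assignments: list[tuple[str, int, int]] = []
    ci = 0
    while genes_left > 0:
        name = names[ci % len(names)]
        length = per_contig[ci % len(names)]
        n_here = min(genes_left, max(1, length // 600))
        slot = length // n_here
        for k in range(n_here):
            slot_assignments.append((name, k * slot, (k + 1) * slot))
        genes_left -= n_here
        ci += 1
        if ci > len(names) * 4 and genes_left > 0:
            raise ValueError(f"insufficient space for {spec.n_genes} genes")
    for idx, (chrom, lo, hi) in enumerate(slot_assignments[: spec.n_genes], start=1):
        usable = hi - lo - 100
        if usable < 300:
            raise ValueError("insufficient space for a gene model in its slot")
        g_len = int(rng.integers(300, min(usable, 2000) + 1))
        g_start = lo + 50  # 0-based
        g_end = g_start + g_len
        strand = "+" if rng.integers(2) == 0 else "-"
        n_exons = int(rng.integers(1, 5))
        gid = f"gene{idx:04d}"
        mid = f"{gid}.1"
        # split the span into exons separated by >=20 bp introns
        cuts = sorted(rng.choice(np.arange(60, g_len - 60), size=2 * (n_exons - 1), replace=False)) if n_exons > 1 else []
        exons = []
        prev = 0
        for i in range(n_exons - 1):
            a, b = int(cuts[2 * i]), int(cuts[2 * i + 1])
            if b - a < 20:
                b = a + 20
            exons.append((g_start + prev, g_start + a))
            prev = b
        exons.append((g_start + prev, g_end))
        exons = [(s, e) for s, e in exons if e > s]
        # CDS: trim margins off the first and last exon for UTRs
        utr5_len, utr3_len = int(rng.integers(10, 50)), int(rng.integers(10, 50))
        cds = [list(iv) for iv in exons]
        if strand == "+":
            cds[0][0] = min(cds[0][0] + utr5_len, cds[0][1] - 1)
            cds[-1][1] = max(cds[-1][1] - utr3_len, cds[-1][0] + 1)
        else:
            cds[0][0] = min(cds[0][0] + utr3_len, cds[0][1] - 1)
            cds[-1][1] = max(cds[-1][1] - utr5_len, cds[-1][0] + 1)
        cds = [tuple(iv) for iv in cds]
        lines.append(
            f"{chrom}\ttaledesign\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={gid}"
        )
        lines.append(
            f"{chrom}\ttaledesign\tmRNA\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={mid};Parent={gid}"
        )
        for s, e in exons:
            lines.append(
                f"{chrom}\ttaledesign\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={mid}"
            )
        for s, e in cds:
            lines.append(
                f"{chrom}\ttaledesign\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\tParent={mid}"
            )
        truth.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "gene_span": (g_start, g_end),
                "exons": tuple(exons),
                "cds": tuple(cds),
            }
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return truth
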