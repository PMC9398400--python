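"""Gene models from GFF3 and positional classification of off-target sites.

Each gene is reduced to one representative transcript (the longest mRNA)
from which introns are derived as exon gaps and UTRs are taken from
explicit features or derived as exonic-minus-CDS.  A site is classified
against every gene within a 5 kbp window: genic overlap resolves by the
precedence CDS > 5'UTR > 3'UTR > intron; a site in the 5' or 3' flank of
its *nearest* gene is upstream/downstream of it, while flank associations
to farther genes are reported as intergenic.  Sites with no gene within
the window are "unassociated".

The upstream-versus-intergenic boundary is an interpretation: both labels
describe sites within the flank window, and which association counts as
"upstream" (rather than merely near a gene) is resolved here by gene
proximity.  See the methods documentation.

Intervals are 0-based half-open internally; GFF3 input coordinates
(1-based inclusive) are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gffutils

from taledesign.genome_scan import OffTargetHit

__all__ = [
    "GeneModel",
    "SiteAnnotation",
    "CATEGORY_PRECEDENCE",
    "TABLE_CATEGORY_ORDER",
    "build_gene_models",
    "classify_site",
    "summarize_categories",
    "write_category_table",
]

Interval = tuple[int, int]

#: Highest-precedence first, used when one gene collects several categories.
CATEGORY_PRECEDENCE = (
    "CDS",
    "5'UTR",
    "3'UTR",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

#: Row order of the per-category summary table.
TABLE_CATEGORY_ORDER = (
    "intergenic",
    "upstream",
    "CDS",
    "downstream",
    "intron",
    "3'UTR",
    "5'UTR",
)


@dataclass(frozen=True)
class GeneModel:
    """One gene with features of its representative (longest) mRNA."""

    gene_id: str
    chrom: str
    strand: str
    gene_span: Interval
    cds_intervals: tuple[Interval, ...] = ()
    utr5_intervals: tuple[Interval, ...] = ()
    utr3_intervals: tuple[Interval, ...] = ()
    intron_intervals: tuple[Interval, ...] = ()


@dataclass(frozen=True)
class SiteAnnotation:
    """Category of one site relative to one gene (or 'unassociated')."""

    site_key: tuple[str, int, str]
    gene_id: str | None
    category: str
    distance_bp: int | None


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _overlaps_any(iv: Interval, ivs: tuple[Interval, ...]) -> bool:
    return any(_overlaps(iv, other) for other in ivs)


def _to_interval(feature: gffutils.Feature) -> Interval:
    return (feature.start - 1, feature.end)


def _subtract(intervals: list[Interval], cut: list[Interval]) -> list[Interval]:
    """Set-subtract cut intervals from intervals (all half-open)."""
    result = []
    for s, e in intervals:
        pieces = [(s, e)]
        for cs, ce in cut:
            next_pieces = []
            for ps, pe in pieces:
                if ce <= ps or cs >= pe:
                    next_pieces.append((ps, pe))
                    continue
                if ps < cs:
                    next_pieces.append((ps, cs))
                if ce < pe:
                    next_pieces.append((ce, pe))
            pieces = next_pieces
        result.extend(pieces)
    return sorted(result)


def build_gene_models(annotation: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into one model per gene.

    The longest mRNA is the representative transcript; introns are the
    gaps between its exons; UTRs come from explicit five_prime_UTR /
    three_prime_UTR features when present, otherwise exonic-minus-CDS
    split 5'/3' around the CDS span by strand.  Malformed genes (e.g. CDS
    outside the mRNA span) are skipped with a warning rather than
    aborting the run.
    """
    db = gffutils.create_db(
        str(annotation),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        try:
            models.append(_model_for_gene(db, gene))
        except ValueError as e:
            warnings.warn(f"skipping gene {gene.id}: {e}")
    return models


def _model_for_gene(db: gffutils.FeatureDB, gene: gffutils.Feature) -> GeneModel:
    mrnas = list(db.children(gene, featuretype="mRNA"))
    span = _to_interval(gene)
    if mrnas:
        rep = max(mrnas, key=lambda m: (m.end - m.start, m.id))
        exon_parent = rep
    else:
        rep = gene
        exon_parent = gene
    exons = sorted(_to_interval(f) for f in db.children(exon_parent, featuretype="exon"))
    cds = sorted(_to_interval(f) for f in db.children(exon_parent, featuretype="CDS"))
    if not exons:
        exons = [_to_interval(rep)]
    for s, e in exons + cds:
        if s < span[0] or e > span[1]:
            raise ValueError(f"feature [{s}, {e}) outside gene span {span}")
    introns = [
        (exons[i][1], exons[i + 1][0])
        for i in range(len(exons) - 1)
        if exons[i][1] < exons[i + 1][0]
    ]
    utr5 = sorted(
        _to_interval(f)
        for f in db.children(exon_parent, featuretype=("five_prime_UTR", "5UTR"))
    )
    utr3 = sorted(
        _to_interval(f)
        for f in db.children(exon_parent, featuretype=("three_prime_UTR", "3UTR"))
    )
    if cds and not utr5 and not utr3:
        non_cds = _subtract(exons, cds)
        cds_lo = min(s for s, _ in cds)
        cds_hi = max(e for _, e in cds)
        left = [iv for iv in non_cds if iv[1] <= cds_lo]
        right = [iv for iv in non_cds if iv[0] >= cds_hi]
        if gene.strand == "-":
            utr5, utr3 = tuple(right), tuple(left)
        else:
            utr5, utr3 = tuple(left), tuple(right)
    return GeneModel(
        gene_id=gene.id,
        chrom=gene.seqid,
        strand=gene.strand,
        gene_span=span,
        cds_intervals=tuple(cds),
        utr5_intervals=tuple(utr5),
        utr3_intervals=tuple(utr3),
        intron_intervals=tuple(introns),
    )


def _genic_category(site_iv: Interval, gene: GeneModel) -> str:
    if _overlaps_any(site_iv, gene.cds_intervals):
        return "CDS"
    if _overlaps_any(site_iv, gene.utr5_intervals):
        return "5'UTR"
    if _overlaps_any(site_iv, gene.utr3_intervals):
        return "3'UTR"
    return "intron"


def classify_site(
    site: OffTargetHit,
    genes: list[GeneModel],
    window: int = 5000,
) -> list[SiteAnnotation]:
    """Annotate one site against every gene within ``window`` bp.

    Genic overlap gets a genic category at distance 0.  Flank distance is
    measured from the site midpoint to the gene span boundary; a flank
    association is upstream/downstream only for the site's nearest gene,
    intergenic for any farther gene within the window.  With no gene in
    range a single 'unassociated' record (gene_id None) is returned.
    """
    site_iv = (site.start, site.end)
    midpoint = (site.start + site.end) // 2
    in_range: list[tuple[GeneModel, int, bool]] = []  # (gene, distance, genic)
    for gene in genes:
        if gene.chrom != site.chrom:
            continue
        if _overlaps(site_iv, gene.gene_span):
            in_range.append((gene, 0, True))
            continue
        if midpoint < gene.gene_span[0]:
            d = gene.gene_span[0] - midpoint
        elif midpoint >= gene.gene_span[1]:
            d = midpoint - (gene.gene_span[1] - 1)
        else:
            d = 0
        if d <= window:
            in_range.append((gene, d, False))
    if not in_range:
        return [
            SiteAnnotation(
                site_key=site.key, gene_id=None, category="unassociated", distance_bp=None
            )
        ]
    min_d = min(d for _, d, _ in in_range)
    annotations = []
    for gene, d, genic in sorted(in_range, key=lambda t: (t[1], t[0].gene_id)):
        if genic:
            category = _genic_category(site_iv, gene)
        elif d == min_d:
            before_start = midpoint < gene.gene_span[0]
            if (gene.strand == "+") == before_start:
                category = "upstream"
            else:
                category = "downstream"
        else:
            category = "intergenic"
        annotations.append(
            SiteAnnotation(
                site_key=site.key, gene_id=gene.gene_id, category=category, distance_bp=d
            )
        )
    return annotations


def summarize_categories(
    annotations: list[SiteAnnotation],
    expressed_gene_ids: set[str] | None = None,
    up_gene_ids: set[str] | None = None,
    down_gene_ids: set[str] | None = None,
    mode: str = "first",
) -> "pandas.DataFrame":
    """Per-category counts of distinct genes.

    ``mode='first'`` counts each gene once, under its highest-precedence
    category; ``mode='all'`` counts a gene in every category it collects.
    Optional gene-ID sets add '# Expressed' / '# Up' / '# Down' columns by
    intersection (those lists are produced externally, e.g. from RNA-seq).
    """
    import pandas as pd

    if mode not in {"first", "all"}:
        raise ValueError("mode must be 'first' or 'all'")
    by_gene: dict[str, set[str]] = {}
    for a in annotations:
        if a.gene_id is None or a.category == "unassociated":
            continue
        by_gene.setdefault(a.gene_id, set()).add(a.category)
    rows = []
    for category in TABLE_CATEGORY_ORDER:
        if mode == "first":
            genes_here = {
                g
                for g, cats in by_gene.items()
                if min(cats, key=CATEGORY_PRECEDENCE.index) == category
            }
        else:
            genes_here = {g for g, cats in by_gene.items() if category in cats}
        row = {"category": category, "n_genes": len(genes_here)}
        if expressed_gene_ids is not None:
            row["n_expressed"] = len(genes_here & expressed_gene_ids)
        if up_gene_ids is not None:
            row["n_up"] = len(genes_here & up_gene_ids)
        if down_gene_ids is not None:
            row["n_down"] = len(genes_here & down_gene_ids)
        rows.append(row)
    return pd.DataFrame(rows)


def write_category_table(table: "pandas.DataFrame", path: str | Path) -> None:
    header = "# " + "\t".join(table.columns)
    body = "\n".join("\t".join(str(v) for v in row) for row in table.itertuples(index=False))
    Path(path).write_text(header + "\n" + body + "\n")
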