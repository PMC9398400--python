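"""Gene model construction from GFF3 and site classification."""

import pytest

from taledesign.gene_context import (
    GeneModel,
    build_gene_models,
    classify_site,
    summarize_categories,
    write_category_table,
)
from taledesign.genome_scan import OffTargetHit
from taledesign.tale_code import MismatchProfile


def site_at(start: int, chrom: str = "chr1", strand: str = "+") -> OffTargetHit:
    return OffTargetHit(
        chrom=chrom,
        start=start,
        end=start + 19,
        strand=strand,
        site_sequence="T" + "A" * 18,
        profile=MismatchProfile((3, 7, 9)),
    )


def gene(gene_id, span, strand="+", chrom="chr1", **features) -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        gene_span=span,
        cds_intervals=features.get("cds", ()),
        utr5_intervals=features.get("utr5", ()),
        utr3_intervals=features.get("utr3", ()),
        intron_intervals=features.get("introns", ()),
    )


class TestBuildGeneModels:
    def test_derives_introns_and_utrs(self, toy_gff3):
        (model,) = build_gene_models(toy_gff3)
        # GFF 1-based inclusive coordinates -> 0-based half-open
        assert model.gene_span == (1000, 3000)
        assert model.intron_intervals == ((1500, 2000),)
        assert model.utr5_intervals == ((1000, 1200),)
        assert model.utr3_intervals == ((2800, 3000),)
        assert model.cds_intervals == ((1200, 1500), (2000, 2800))

    def test_minus_strand_swaps_utr_labels(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\ttest\tgene\t1001\t3000\t.\t-\t.\tID=g1\n"
            "chr1\ttest\tmRNA\t1001\t3000\t.\t-\t.\tID=g1.1;Parent=g1\n"
            "chr1\ttest\texon\t1001\t1500\t.\t-\t.\tParent=g1.1\n"
            "chr1\ttest\texon\t2001\t3000\t.\t-\t.\tParent=g1.1\n"
            "chr1\ttest\tCDS\t1201\t1500\t.\t-\t0\tParent=g1.1\n"
            "chr1\ttest\tCDS\t2001\t2800\t.\t-\t0\tParent=g1.1\n"
        )
        path = tmp_path / "minus.gff3"
        path.write_text(text)
        (model,) = build_gene_models(path)
        assert model.utr5_intervals == ((2800, 3000),)
        assert model.utr3_intervals == ((1000, 1200),)

    def test_single_exon_cds_gene_has_no_introns_or_utrs(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\ttest\tgene\t501\t800\t.\t+\t.\tID=g1\n"
            "chr1\ttest\tmRNA\t501\t800\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "chr1\ttest\texon\t501\t800\t.\t+\t.\tParent=g1.1\n"
            "chr1\ttest\tCDS\t501\t800\t.\t+\t0\tParent=g1.1\n"
        )
        path = tmp_path / "single.gff3"
        path.write_text(text)
        (model,) = build_gene_models(path)
        assert model.intron_intervals == ()
        assert model.utr5_intervals == () and model.utr3_intervals == ()

    def test_longest_mrna_is_representative(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\ttest\tgene\t1\t1000\t.\t+\t.\tID=g1\n"
            "chr1\ttest\tmRNA\t1\t400\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "chr1\ttest\texon\t1\t400\t.\t+\t.\tParent=g1.1\n"
            "chr1\ttest\tmRNA\t1\t1000\t.\t+\t.\tID=g1.2;Parent=g1\n"
            "chr1\ttest\texon\t1\t500\t.\t+\t.\tParent=g1.2\n"
            "chr1\ttest\texon\t601\t1000\t.\t+\t.\tParent=g1.2\n"
        )
        path = tmp_path / "iso.gff3"
        path.write_text(text)
        (model,) = build_gene_models(path)
        assert model.intron_intervals == ((500, 600),)

    def test_malformed_gene_skipped_with_warning(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "chr1\ttest\tgene\t100\t200\t.\t+\t.\tID=bad\n"
            "chr1\ttest\tmRNA\t100\t200\t.\t+\t.\tID=bad.1;Parent=bad\n"
            "chr1\ttest\texon\t100\t500\t.\t+\t.\tParent=bad.1\n"
            "chr1\ttest\tgene\t601\t900\t.\t+\t.\tID=good\n"
            "chr1\ttest\tmRNA\t601\t900\t.\t+\t.\tID=good.1;Parent=good\n"
            "chr1\ttest\texon\t601\t900\t.\t+\t.\tParent=good.1\n"
        )
        path = tmp_path / "mixed.gff3"
        path.write_text(text)
        with pytest.warns(UserWarning, match="bad"):
            models = build_gene_models(path)
        assert [m.gene_id for m in models] == ["good"]


class TestClassifySite:
    def test_cds_overlap_wins_with_distance_zero(self, toy_gff3):
        genes = build_gene_models(toy_gff3)
        (ann,) = classify_site(site_at(1250), genes)
        assert ann.category == "CDS" and ann.distance_bp == 0

    def test_intron_and_utr_categories(self, toy_gff3):
        genes = build_gene_models(toy_gff3)
        assert classify_site(site_at(1700), genes)[0].category == "intron"
        assert classify_site(site_at(1020), genes)[0].category == "5'UTR"
        assert classify_site(site_at(2900), genes)[0].category == "3'UTR"

    def test_upstream_within_window_of_nearest_gene(self):
        """A site ~1.7 kbp 5' of the start codon on a + strand gene."""
        g = gene("g1", (10_000, 12_000), strand="+")
        site = site_at(10_000 - 1700 - 9)  # midpoint 1.7 kbp before gene start
        (ann,) = classify_site(site, [g])
        assert ann.category == "upstream"
        assert ann.distance_bp == 1700

    def test_downstream_and_strand_awareness(self):
        plus = gene("gp", (10_000, 12_000), strand="+")
        minus = gene("gm", (10_000, 12_000), strand="-")
        before, after = site_at(8_000), site_at(13_000)
        assert classify_site(before, [plus])[0].category == "upstream"
        assert classify_site(after, [plus])[0].category == "downstream"
        assert classify_site(before, [minus])[0].category == "downstream"
        assert classify_site(after, [minus])[0].category == "upstream"

    def test_beyond_window_is_unassociated(self):
        g = gene("g1", (50_000, 52_000))
        (ann,) = classify_site(site_at(40_000), [g])
        assert ann.category == "unassociated" and ann.gene_id is None

    def test_flank_of_farther_gene_is_intergenic(self):
        near = gene("near", (10_000, 12_000), strand="+")
        far = gene("far", (16_000, 18_000), strand="+")
        site = site_at(12_500)  # 0.5 kbp downstream of near, 3.5 kbp upstream of far
        annotations = classify_site(site, [near, far])
        by_gene = {a.gene_id: a.category for a in annotations}
        assert by_gene == {"near": "downstream", "far": "intergenic"}

    def test_translation_invariance(self, toy_gff3):
        genes = build_gene_models(toy_gff3)
        shift = 10_000
        shifted = [
            GeneModel(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                gene_span=(g.gene_span[0] + shift, g.gene_span[1] + shift),
                cds_intervals=tuple((s + shift, e + shift) for s, e in g.cds_intervals),
                utr5_intervals=tuple((s + shift, e + shift) for s, e in g.utr5_intervals),
                utr3_intervals=tuple((s + shift, e + shift) for s, e in g.utr3_intervals),
                intron_intervals=tuple((s + shift, e + shift) for s, e in g.intron_intervals),
            )
            for g in genes
        ]
        for start in [980, 1250, 1700, 2900, 3500]:
            a = classify_site(site_at(start), genes)[0]
            b = classify_site(site_at(start + shift), shifted)[0]
            assert (a.category, a.distance_bp) == (b.category, b.distance_bp)

    def test_genic_and_flank_mutually_exclusive_per_pair(self, toy_gff3):
        genes = build_gene_models(toy_gff3)
        for start in range(900, 3200, 37):
            for ann in classify_site(site_at(start), genes):
                genic = ann.distance_bp == 0
                assert genic == (ann.category in {"CDS", "5'UTR", "3'UTR", "intron"})


class TestSummarizeCategories:
    def ann(self, gene_id, category):
        from taledesign.gene_context import SiteAnnotation

        return SiteAnnotation(("chr1", 0, "+"), gene_id, category, 0)

    def test_counts_and_expressed_intersection(self):
        annotations = [
            self.ann("g1", "CDS"),
            self.ann("g2", "upstream"),
            self.ann(None, "unassociated"),
        ]
        table = summarize_categories(annotations, expressed_gene_ids={"g2"})
        by_cat = dict(zip(table["category"], table["n_genes"]))
        assert by_cat["CDS"] == 1 and by_cat["upstream"] == 1
        assert table["n_genes"].sum() == 2
        expressed = dict(zip(table["category"], table["n_expressed"]))
        assert expressed == {
            "intergenic": 0, "upstream": 1, "CDS": 0, "downstream": 0,
            "intron": 0, "3'UTR": 0, "5'UTR": 0,
        }

    def test_first_mode_counts_gene_once_at_highest_precedence(self):
        annotations = [self.ann("g1", "CDS"), self.ann("g1", "upstream")]
        first = summarize_categories(annotations, mode="first")
        assert dict(zip(first["category"], first["n_genes"]))["upstream"] == 0
        every = summarize_categories(annotations, mode="all")
        assert dict(zip(every["category"], every["n_genes"]))["upstream"] == 1

    def test_empty_annotations_give_zero_table(self):
        table = summarize_categories([])
        assert table["n_genes"].sum() == 0
        assert list(table["category"]) == [
            "intergenic", "upstream", "CDS", "downstream", "intron", "3'UTR", "5'UTR",
        ]

    def test_table_write(self, tmp_path):
        table = summarize_categories([self.ann("g1", "CDS")])
        path = tmp_path / "categories.tsv"
        write_category_table(table, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# category")
        assert len(lines) == 8
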