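"""Catalogue parsing, curation criteria, classification and year splitting."""

import pytest

from exomescreen import catalogue as cat
from exomescreen.errors import ConfigurationError, ValidationError

HEADER = "record_id\tgene\tlocation\tbuild\tchrom\tref\talt\tlocation_class\tinheritance\tyear\tphene\tis_disease"


def write_catalogue(path, rows):
    path.write_text("\n".join([HEADER] + rows) + "\n")
    return path


def row(rid="R1", gene="GENE1", location="g.1234", build="CanFam3.1", chrom="chr1",
        ref="A", alt="G", loc_class="CDS", inh="autosomal recessive", year="2010",
        phene="trait", disease="1"):
    return "\t".join([rid, gene, location, build, chrom, ref, alt, loc_class, inh,
                      year, phene, disease])


class TestParse:
    def test_empty_data_section_gives_empty_list(self, tmp_path):
        p = write_catalogue(tmp_path / "c.tsv", [])
        assert cat.parse_catalogue(p) == []

    def test_well_formed_row_preserves_location_and_order(self, tmp_path):
        p = write_catalogue(tmp_path / "c.tsv", [row(rid="A"), row(rid="B", location="m.55")])
        recs = cat.parse_catalogue(p)
        assert [r.record_id for r in recs] == ["A", "B"]
        assert recs[0].location_string == "g.1234"
        assert recs[1].location_string == "m.55"

    def test_blank_gene_parses_as_absent_without_error(self, tmp_path):
        p = write_catalogue(tmp_path / "c.tsv", [row(gene="")])
        (rec,) = cat.parse_catalogue(p)
        assert rec.gene_symbol is None

    def test_missing_mandatory_column_names_the_column(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("record_id\tgene\nR1\tG1\n")
        with pytest.raises(ConfigurationError, match="location"):
            cat.parse_catalogue(p)


class TestCurate:
    @pytest.mark.parametrize(
        "bad_row, reason",
        [
            (row(location="c.76del"), cat.Reason.NO_GENOMIC_LOCATION),
            (row(location="g.1234", chrom=""), cat.Reason.NO_GENOMIC_LOCATION),
            (row(build="CanFam2.0"), cat.Reason.WRONG_BUILD),
            (row(gene=""), cat.Reason.BAD_GENE_SYMBOL),
            (row(gene="not a gene!"), cat.Reason.BAD_GENE_SYMBOL),
            (row(ref="NN", alt="A"), cat.Reason.BAD_ALLELES),
            (row(ref="A" * 21, alt="G"), cat.Reason.SIZE_GT_MAX),
        ],
    )
    def test_single_violation_is_excluded_with_its_reason(self, tmp_path, bad_row, reason):
        p = write_catalogue(tmp_path / "c.tsv", [bad_row])
        variants, report = cat.curate(cat.parse_catalogue(p))
        assert variants == []
        assert report.exclusions == [("R1", reason)]

    def test_size_boundary_20bp_is_retained(self, tmp_path):
        p = write_catalogue(tmp_path / "c.tsv", [row(ref="A" * 20, alt="G")])
        variants, report = cat.curate(cat.parse_catalogue(p))
        assert len(variants) == 1 and variants[0].size_bp == 20

    def test_mitochondrial_location_forces_mt_chromosome(self, tmp_path):
        p = write_catalogue(tmp_path / "c.tsv", [row(location="m.303", chrom="")])
        (v,), _ = cat.curate(cat.parse_catalogue(p))
        assert v.chromosome == "MT" and v.position == 303

    def test_report_counts_reconcile(self, tmp_path):
        rows = [row(rid=f"R{i}") for i in range(5)]
        rows += [row(rid="X1", location="bad"), row(rid="X2", ref="A" * 25, alt="G")]
        _, report = cat.curate(cat.parse_catalogue(write_catalogue(tmp_path / "c.tsv", rows)))
        assert report.n_input == 7
        assert report.n_excluded_stage1 == 1  # annotation failure
        assert report.n_excluded_stage2 == 1  # size failure
        assert report.n_retained == 5
        assert report.n_input == (
            report.n_excluded_stage1 + report.n_excluded_stage2 + report.n_retained
        )

    def test_curation_is_idempotent_on_clean_records(self, curated):
        """Re-curating the survivors of curation excludes nothing."""
        clean = [
            cat.RawCatalogueRecord(
                record_id=v.record_id,
                gene_symbol=v.gene_symbol,
                location_string=f"{'m' if v.chromosome == 'MT' else 'g'}.{v.position}",
                build_tag="CanFam3.1",
                ref_allele=v.ref_allele,
                alt_allele=v.alt_allele,
                chromosome=v.chromosome,
                publication_year=v.publication_year,
                location_class_raw="CDS" if v.category is cat.Category.CDS_1BP else "intron",
                inheritance_raw=v.inheritance.value,
                phene=v.phene,
                is_disease=v.is_disease,
            )
            for v in curated.variants
        ]
        again, report = cat.curate(clean)
        assert report.exclusions == []
        assert len(again) == len(curated.variants)


class TestClassify:
    @pytest.mark.parametrize(
        "size, loc_class, expected",
        [
            (1, "CDS", cat.Category.CDS_1BP),
            (1, "intron", cat.Category.NONCODING_1BP),
            (1, "UTR", cat.Category.NONCODING_1BP),
            (1, "promoter", cat.Category.NONCODING_1BP),
            (5, "CDS", cat.Category.LARGER),
            (20, "intron", cat.Category.LARGER),
        ],
    )
    def test_category_assignment(self, size, loc_class, expected):
        assert cat.classify(size, loc_class) == expected

    @pytest.mark.parametrize("size", [0, 21])
    def test_size_outside_contract_raises(self, size):
        with pytest.raises(ValidationError):
            cat.classify(size, "CDS")

    def test_every_curated_variant_has_exactly_one_category(self, curated):
        by_cat = {}
        for v in curated.variants:
            by_cat[v.category] = by_cat.get(v.category, 0) + 1
        assert sum(by_cat.values()) == len(curated.variants)
        for v in curated.variants:
            assert (v.category in (cat.Category.CDS_1BP, cat.Category.NONCODING_1BP)) == (
                v.size_bp == 1
            )


class TestSplitByYear:
    def test_boundary_year_is_pre_design(self, mkvar):
        vs = [mkvar(record_id=f"V{y}", publication_year=y) for y in (2010, 2014, 2015)]
        split = cat.split_by_year(vs, design_year=2014)
        assert {v.publication_year for v in split.pre_design} == {2010, 2014}
        assert {v.publication_year for v in split.post_design} == {2015}

    def test_all_pre_design_gives_empty_post_list(self, mkvar):
        vs = [mkvar(record_id=f"V{y}", publication_year=y) for y in (2000, 2014)]
        split = cat.split_by_year(vs)
        assert split.post_design == []

    def test_missing_year_is_reported_and_in_neither_list(self, mkvar):
        vs = [mkvar(record_id="A", publication_year=None), mkvar(record_id="B")]
        split = cat.split_by_year(vs)
        assert [v.record_id for v in split.missing_year] == ["A"]
        assert [v.record_id for v in split.pre_design] == ["B"]

    def test_synthetic_catalogue_post_design_count(self, curated, study):
        """The generator plants 170 post-2014 variants (118 CDS / 6 non-coding / 46 larger)."""
        split = cat.split_by_year(curated.variants, design_year=study.truth["design_year"])
        assert len(split.post_design) == 170
        by_cat = {}
        for v in split.post_design:
            by_cat[v.category.value] = by_cat.get(v.category.value, 0) + 1
        assert by_cat == {"CDS_1BP": 118, "NONCODING_1BP": 6, "LARGER": 46}
        assert len(split.pre_design) + len(split.post_design) == len(curated.variants)
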