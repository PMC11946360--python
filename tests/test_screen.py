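"""VCF scanning, zygosity interpretation and per-dog summaries."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from exomescreen import screen as scr
from exomescreen.catalogue import Inheritance
from exomescreen.errors import ConfigurationError, ValidationError

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000>
    ##contig=<ID=X,length=100000>
    ##contig=<ID=MT,length=20000>
    ##FILTER=<ID=LowQual,Description="failed hard filter">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    """
)


def write_vcf(path, samples, rows):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    body = [cols + "\t" + "\t".join(samples)] + rows
    path.write_text(VCF_HEADER + "\n".join(body) + "\n")
    return path


def meta(samples_sexes):
    return pd.DataFrame(
        [{"sample_id": s, "sex": x, "breed": "Crossbreed"} for s, x in samples_sexes]
    )


class TestInterpret:
    @pytest.mark.parametrize(
        "alt_count, inheritance, sex, chrom, expected",
        [
            (0, Inheritance.AUTOSOMAL_RECESSIVE, "female", "chr12", scr.Status.WILDTYPE),
            (1, Inheritance.AUTOSOMAL_RECESSIVE, "female", "chr12", scr.Status.CARRIER),
            (2, Inheritance.AUTOSOMAL_RECESSIVE, "male", "chr12", scr.Status.HOMOZYGOUS_ALT),
            (1, Inheritance.AUTOSOMAL_DOMINANT, "male", "chr3", scr.Status.CARRIER),
            (1, Inheritance.X_LINKED, "male", "X", scr.Status.HEMIZYGOUS_ALT),
            (1, Inheritance.X_LINKED, "female", "X", scr.Status.CARRIER),
            (2, Inheritance.X_LINKED, "female", "X", scr.Status.HOMOZYGOUS_ALT),
            (1, Inheritance.MITOCHONDRIAL, "male", "MT", scr.Status.MITO_PRESENT),
            (0, Inheritance.MITOCHONDRIAL, "female", "MT", scr.Status.WILDTYPE),
        ],
    )
    def test_status_mapping(self, alt_count, inheritance, sex, chrom, expected):
        assert scr.interpret(alt_count, inheritance, sex, chrom) == expected

    def test_male_x_dosage_two_is_inconsistent_but_hemizygous(self, caplog):
        with caplog.at_level("WARNING"):
            status = scr.interpret(2, Inheritance.X_LINKED, "male", "X")
        assert status == scr.Status.HEMIZYGOUS_ALT
        assert any("hemizygous" in r.message for r in caplog.records)

    def test_unknown_sex_raises(self):
        with pytest.raises(ValidationError):
            scr.interpret(1, Inheritance.AUTOSOMAL_RECESSIVE, "unknown", "chr1")


class TestScanVcf:
    def test_planted_het_snv_is_a_carrier(self, tmp_path, mkvar):
        v = mkvar(record_id="V1", position=100, ref="A", alt="G")
        vcf = write_vcf(tmp_path / "t.vcf", ["d1"], ["chr1\t100\tV1\tA\tG\t50\tPASS\t.\tGT\t0/1"])
        (call,) = scr.scan_vcf(vcf, [v], meta([("d1", "female")]))
        assert call.alt_count == 1 and call.status == scr.Status.CARRIER

    def test_filter_failed_site_is_not_assessable(self, tmp_path, mkvar):
        v = mkvar(record_id="V1", position=100)
        vcf = write_vcf(
            tmp_path / "t.vcf", ["d1"], ["chr1\t100\tV1\tA\tG\t50\tLowQual\t.\tGT\t1/1"]
        )
        (call,) = scr.scan_vcf(vcf, [v], meta([("d1", "female")]))
        assert call.status == scr.Status.NOT_ASSESSABLE and not call.filter_pass

    def test_half_missing_genotype_is_not_assessable(self, tmp_path, mkvar):
        v = mkvar(record_id="V1", position=100)
        vcf = write_vcf(tmp_path / "t.vcf", ["d1"], ["chr1\t100\tV1\tA\tG\t50\tPASS\t.\tGT\t./1"])
        (call,) = scr.scan_vcf(vcf, [v], meta([("d1", "female")]))
        assert call.status == scr.Status.NOT_ASSESSABLE

    def test_multiallelic_site_matches_correct_alt_index(self, tmp_path, mkvar):
        v = mkvar(record_id="V1", position=100, ref="A", alt="G")
        vcf = write_vcf(
            tmp_path / "t.vcf",
            ["d1", "d2"],
            ["chr1\t100\tV1\tA\tG,T\t50\tPASS\t.\tGT\t0/1\t0/2"],
        )
        calls = scr.scan_vcf(vcf, [v], meta([("d1", "female"), ("d2", "male")]))
        by_sample = {c.sample_id: c for c in calls}
        assert by_sample["d1"].alt_count == 1  # carries the panel allele
        assert by_sample["d2"].alt_count == 0  # carries only the decoy allele

    def test_indel_in_different_anchor_representation_matches(self, tmp_path, mkvar):
        # catalogue: pure 2 bp deletion at 101; VCF: anchored at 100
        v = mkvar(record_id="V1", position=101, ref="TG", alt="")
        vcf = write_vcf(
            tmp_path / "t.vcf", ["d1"], ["chr1\t100\tV1\tATG\tA\t50\tPASS\t.\tGT\t0/1"]
        )
        (call,) = scr.scan_vcf(vcf, [v], meta([("d1", "female")]))
        assert call.alt_count == 1 and call.status == scr.Status.CARRIER

    def test_absent_site_wildtype_only_when_depth_qualified(self, tmp_path, mkvar):
        from exomescreen import depthqc as dq

        v = mkvar(record_id="V1", position=100)
        vcf = write_vcf(tmp_path / "t.vcf", ["d1", "d2"], [])
        qm = dq.QualificationMatrix(
            entries={("d1", "V1", 10): True, ("d2", "V1", 10): False},
            thresholds=(10,),
        )
        calls = scr.scan_vcf(
            vcf, [v], meta([("d1", "female"), ("d2", "female")]), qm=qm, depth_threshold=10
        )
        by_sample = {c.sample_id: c.status for c in calls}
        assert by_sample == {"d1": scr.Status.WILDTYPE, "d2": scr.Status.NOT_ASSESSABLE}

    def test_metadata_sample_missing_from_vcf_is_fatal(self, tmp_path, mkvar):
        vcf = write_vcf(tmp_path / "t.vcf", ["d1"], [])
        with pytest.raises(ConfigurationError, match="ghost"):
            scr.scan_vcf(vcf, [mkvar()], meta([("ghost", "female")]))


class TestPerDogSummary:
    def make_dm(self, data, samples, records):
        return pd.DataFrame(data, index=samples, columns=records, dtype=float)

    def test_no_detections_puts_all_mass_at_zero(self, mkvar):
        dm = self.make_dm(np.zeros((3, 2)), ["a", "b", "c"], ["V1", "V2"])
        panel = [mkvar(record_id="V1"), mkvar(record_id="V2")]
        s = scr.per_dog_summary(dm, panel)
        assert s.histogram == {0: 3} and s.n_with_at_least_one == 0

    def test_counts_are_zygosity_agnostic_and_distinct_per_record(self, mkvar):
        dm = self.make_dm([[2, 1], [0, 0]], ["a", "b"], ["V1", "V2"])
        panel = [mkvar(record_id="V1"), mkvar(record_id="V2")]
        s = scr.per_dog_summary(dm, panel)
        assert s.counts_per_sample["a"] == 2  # hom and het each count once
        assert s.n_with_at_least_one == 1

    def test_disease_only_counts_never_exceed_all_variant_counts(self, mkvar):
        dm = self.make_dm([[1, 1], [1, 0]], ["a", "b"], ["V1", "V2"])
        panel = [mkvar(record_id="V1", is_disease=False), mkvar(record_id="V2")]
        s_all = scr.per_dog_summary(dm, panel, disease_only=False)
        s_dis = scr.per_dog_summary(dm, panel, disease_only=True)
        for sid in ("a", "b"):
            assert s_dis.counts_per_sample[sid] <= s_all.counts_per_sample[sid]

    def test_not_assessable_sites_do_not_count_as_detections(self, mkvar):
        dm = self.make_dm([[np.nan, 1]], ["a"], ["V1", "V2"])
        panel = [mkvar(record_id="V1"), mkvar(record_id="V2")]
        assert scr.per_dog_summary(dm, panel).counts_per_sample["a"] == 1


class TestRoundTrip:
    def test_scan_recovers_planted_dosages_at_all_assessable_sites(
        self, study, curated, metadata, calls
    ):
        """Generator truth table vs scan output: exact dosage recovery."""
        truth = study.truth
        emitted = set(truth["emitted"])
        failed = set(truth["filter_failed"])
        n_checked = 0
        for c in calls:
            expected = truth["dosages"][c.record_id][c.sample_id]
            if c.record_id in emitted and c.record_id not in failed:
                assert c.alt_count == expected, (c.record_id, c.sample_id)
                assert c.status is not scr.Status.NOT_ASSESSABLE
                n_checked += 1
            elif c.record_id in failed:
                assert c.status is scr.Status.NOT_ASSESSABLE
            else:  # absent from VCF: truth dosage must be zero
                assert expected == 0
        assert n_checked > 0

    def test_shifted_indel_representations_are_planted_and_recovered(self, study, calls):
        shifted = set(study.truth["shifted_representation"]) - set(study.truth["filter_failed"])
        assert shifted, "generator must plant representation-shifted indels"
        seen = set()
        for c in calls:
            if c.record_id in shifted:
                assert c.alt_count == study.truth["dosages"][c.record_id][c.sample_id]
                seen.add(c.record_id)
        assert seen == shifted
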