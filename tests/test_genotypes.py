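"""Genotype containers, file dialects, allele orientation and SNP priority."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kbas.genotypes import (
    MISSING,
    CohortPair,
    GenotypeFormatError,
    GenotypeMatrix,
    NotBiallelicError,
    SnpAnnotation,
    determine_minor_allele,
    prioritize_representative_snps,
    read_genotype_table,
    read_vcf_biallelic,
    write_genotype_table,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


class TestGenotypeMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(GenotypeFormatError):
            GenotypeMatrix(["a", "a"], ["x"], np.zeros((2, 1), dtype=np.int8))
        with pytest.raises(GenotypeFormatError):
            GenotypeMatrix(["a"], ["x"], np.array([[5]], dtype=np.int8))
        with pytest.raises(GenotypeFormatError):
            GenotypeMatrix(["a"], ["x", "y"], np.zeros((1, 1), dtype=np.int8))

    def test_subset_preserves_order_and_errors_on_unknown(self, tiny_matrix):
        sub = tiny_matrix.subset_snps(["rsC", "rsA"])
        assert sub.snp_ids == ["rsC", "rsA"]
        assert sub.values[0].tolist() == [2, 0]
        with pytest.raises(KeyError):
            tiny_matrix.subset_snps(["rsZ"])

    def test_monomorphic_detection(self):
        values = np.array([[0, 1], [0, 2], [0, MISSING]], dtype=np.int8)
        m = GenotypeMatrix(["a", "b", "c"], ["mono", "poly"], values)
        assert m.monomorphic_snps() == ["mono"]

    def test_cohort_pair_rejects_shared_subjects_and_mismatched_snps(self, tiny_matrix):
        other = GenotypeMatrix(["s1"], tiny_matrix.snp_ids, np.zeros((1, 3), np.int8))
        with pytest.raises(GenotypeFormatError):
            CohortPair(tiny_matrix, other)
        renamed = GenotypeMatrix(["t1"], ["rsA", "rsB", "rsX"], np.zeros((1, 3), np.int8))
        with pytest.raises(GenotypeFormatError):
            CohortPair(tiny_matrix, renamed)


class TestNumericDialect:
    def test_parse_values_and_missing(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("subject_id\trs1\trs2\nA\t0\tNA\nB\t2\t1\n")
        m = read_genotype_table(p)
        assert m.subject_ids == ["A", "B"]
        assert m.values.tolist() == [[0, MISSING], [2, 1]]

    def test_header_only_is_valid_empty_matrix(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("subject_id\trs1\trs2\n")
        m = read_genotype_table(p)
        assert m.n_subjects == 0 and m.snp_ids == ["rs1", "rs2"]

    @pytest.mark.parametrize(
        "body", ["A\t3\t0\n", "A\t0\tx\n", "A\t0\n"], ids=["value3", "alpha", "short-row"]
    )
    def test_bad_cells_raise(self, tmp_path, body):
        p = tmp_path / "g.tsv"
        p.write_text("subject_id\trs1\trs2\n" + body)
        with pytest.raises(GenotypeFormatError):
            read_genotype_table(p)

    def test_duplicate_ids_raise(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("subject_id\trs1\nA\t0\nA\t1\n")
        with pytest.raises(GenotypeFormatError):
            read_genotype_table(p)

    def test_round_trip_identity(self, tiny_matrix, tmp_path):
        p = tmp_path / "rt.tsv"
        write_genotype_table(tiny_matrix, p)
        back = read_genotype_table(p)
        assert back.subject_ids == tiny_matrix.subject_ids
        assert back.snp_ids == tiny_matrix.snp_ids
        assert np.array_equal(back.values, tiny_matrix.values)

    @settings(max_examples=25, deadline=None)
    @given(
        values=st.lists(
            st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    def test_round_trip_property(self, tmp_path_factory, values):
        m = GenotypeMatrix(
            [f"s{i}" for i in range(len(values))],
            ["a", "b", "c"],
            np.array(values, dtype=np.int8),
        )
        p = tmp_path_factory.mktemp("rt") / "m.tsv"
        write_genotype_table(m, p)
        back = read_genotype_table(p)
        assert np.array_equal(back.values, m.values)


class TestAllelePairDialect:
    def test_major_allele_encodes_zero(self, tmp_path):
        # allele counts A:3, B:1 -> A is major, so AA=0 and AB=1
        p = tmp_path / "ap.tsv"
        p.write_text("subject_id\trs1\nX\tAA\nY\tAB\n")
        m = read_genotype_table(p, dialect="allele_pair")
        assert m.values[:, 0].tolist() == [0, 1]

    def test_missing_and_minor_hom(self, tmp_path):
        p = tmp_path / "ap.tsv"
        p.write_text("subject_id\trs1\nX\tGG\nY\tNN\nZ\tGT\nW\tGG\n")
        m = read_genotype_table(p, dialect="allele_pair")
        # G:5, T:1 -> G major; GG=0, GT=1, NN=missing
        assert m.values[:, 0].tolist() == [0, MISSING, 1, 0]


class TestMinorAllele:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 300, "B": 100}, ("A", "B")),
            ({"A": 200, "G": 200}, ("A", "G")),  # tie: later string is minor
            ({"C": 0, "T": 50}, ("T", "C")),  # monomorphic edge
        ],
    )
    def test_examples(self, counts, expected):
        assert determine_minor_allele(counts) == expected

    def test_more_than_two_alleles_rejected(self):
        with pytest.raises(NotBiallelicError):
            determine_minor_allele({"A": 1, "C": 1, "G": 1})


class TestVcfReader:
    def test_alt_minor_gives_dose_and_missing(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            + "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/0\t./.\t0/1\n"
        )
        m = read_vcf_biallelic(p)
        assert m.snp_ids == ["rs1", "rs2"]
        assert m.values[:, 0].tolist() == [0, 1, 2]  # ALT pooled minor
        assert m.values[:, 1].tolist() == [0, MISSING, 1]

    def test_ref_alt_orientation_invariance(self, tmp_path):
        # same cohort written with swapped REF/ALT: encoding must not change
        a = tmp_path / "a.vcf"
        a.write_text(VCF_HEADER + "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\n")
        b = tmp_path / "b.vcf"
        b.write_text(VCF_HEADER + "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\n")
        ma, mb = read_vcf_biallelic(a), read_vcf_biallelic(b)
        assert ma.values.tolist() == mb.values.tolist() == [[0], [0], [1]]

    def test_alt_major_flips_encoding(self, tmp_path):
        # ALT G is the pooled major allele -> G/G homozygote encodes to 0
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\n")
        m = read_vcf_biallelic(p)
        assert m.values[:, 0].tolist() == [0, 0, 1]

    def test_multiallelic_and_indel_skipped(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "1\t100\ttri\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2\n"
            + "1\t150\tindel\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            + "1\t200\tok\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        m = read_vcf_biallelic(p)
        assert m.snp_ids == ["ok"]

    def test_sample_subset_and_unknown_sample(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        m = read_vcf_biallelic(p, sample_subset=["S3", "S1"])
        assert m.subject_ids == ["S3", "S1"]
        assert m.values[:, 0].tolist() == [0, 2] or m.values[:, 0].tolist() == [2, 0]
        with pytest.raises(KeyError):
            read_vcf_biallelic(p, sample_subset=["nope"])


class TestRepresentativeSnps:
    def test_category_priority(self):
        anns = [
            SnpAnnotation("rs_intron", "tx1", "intronic", 100),
            SnpAnnotation("rs_nonsyn", "tx1", "nonsynonymous_coding", 500),
        ]
        assert prioritize_representative_snps(anns, 1) == ["rs_nonsyn"]

    def test_position_tie_break_within_category(self):
        anns = [
            SnpAnnotation("rs_far", "tx1", "intronic", 900),
            SnpAnnotation("rs_near", "tx1", "intronic", 100),
        ]
        assert prioritize_representative_snps(anns, 1) == ["rs_near"]

    def test_empty_and_bounds(self):
        assert prioritize_representative_snps([], 1) == []
        anns = [
            SnpAnnotation(f"rs{i}", f"tx{i % 3}", "promoter", i) for i in range(12)
        ]
        out = prioritize_representative_snps(anns, 2)
        assert len(out) <= 2 * 3
        assert out == prioritize_representative_snps(anns, 2)  # deterministic

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            SnpAnnotation("rs1", "tx1", "weird", 1)
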