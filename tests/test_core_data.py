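"""Genotype/phenotype I/O, minor-allele orientation and dataset splitting."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxscreen.core_data import (
    DataError,
    FormatError,
    GenotypeDataset,
    SampleTable,
    orient_minor_allele,
    read_annotations,
    read_genotype_tsv,
    read_phenotypes,
    read_plink_text,
    split_datasets,
    write_annotations,
    write_genotype_tsv,
    write_phenotypes,
    write_plink_text,
)
from conftest import make_genotypes, make_samples

PED = """\
F1 S1 0 0 0 -9 A A C C
F2 S2 0 0 0 -9 A G 0 0
F3 S3 0 0 0 -9 G G C T
"""
MAP = """\
1 rs1 0 1000
1 rs2 0 2000
"""


class TestPlinkText:
    def test_minor_allele_doses(self):
        ds = read_plink_text(io.StringIO(PED), io.StringIO(MAP))
        # rs1: G is rarer (3 of 6) -> actually A=3, G=3 tie -> A minor by tie rule
        assert ds.snp_ids == ["rs1", "rs2"]
        assert ds.dose("rs1").tolist() == [2.0, 1.0, 0.0]

    def test_missing_code_gives_nan(self):
        ds = read_plink_text(io.StringIO(PED), io.StringIO(MAP))
        assert np.isnan(ds.dose("rs2").loc["S2"])

    def test_triallelic_snp_named_in_error(self):
        bad = PED.replace("C T", "G T")  # rs2 now C/G/T
        with pytest.raises(DataError, match="rs2"):
            read_plink_text(io.StringIO(bad), io.StringIO(MAP))

    def test_ped_map_length_mismatch(self):
        with pytest.raises(FormatError):
            read_plink_text(io.StringIO(PED), io.StringIO("1 rs1 0 1000\n"))

    def test_round_trip_through_files(self, tmp_path):
        ds = read_plink_text(io.StringIO(PED), io.StringIO(MAP))
        write_plink_text(ds, tmp_path / "o.ped", tmp_path / "o.map")
        back = read_plink_text(tmp_path / "o.ped", tmp_path / "o.map")
        np.testing.assert_array_equal(
            np.nan_to_num(back.calls, nan=-1), np.nan_to_num(ds.calls, nan=-1)
        )


class TestOrientation:
    def _raw(self, genos):
        # genos: list of samples, each list of "XY" strings per SNP
        arr = np.array(
            [[[g[0], g[1]] for g in row] for row in genos], dtype=object
        )
        return arr

    def test_less_frequent_allele_is_minor(self):
        raw = self._raw([["AG"], ["AA"], ["AA"], ["AG"], ["GG"]])
        ds = orient_minor_allele(raw, ["rs1"], [f"S{i}" for i in range(5)])
        assert ds.allele_labels[0] == ("A", "G")  # G freq 0.4 -> minor
        assert ds.calls[:, 0].tolist() == [1, 0, 0, 1, 2]

    def test_tie_broken_lexicographically(self):
        raw = self._raw([["AG"], ["AG"]])
        ds = orient_minor_allele(raw, ["rs1"], ["S1", "S2"])
        assert ds.allele_labels[0][1] == "A"

    def test_monomorphic_flagged_all_zero(self):
        raw = self._raw([["AA"], ["AA"]])
        ds = orient_minor_allele(raw, ["rs1"], ["S1", "S2"])
        assert ds.monomorphic[0]
        assert (ds.calls == 0).all()

    def test_reference_subset_controls_orientation(self):
        # G common overall but rare within the reference subset
        raw = self._raw([["GG"], ["GG"], ["AA"], ["AG"]])
        ds = orient_minor_allele(raw, ["rs1"], list("WXYZ"), reference_sample_ids=["Y", "Z"])
        assert ds.allele_labels[0] == ("A", "G")

    def test_idempotent_on_dose_representation(self):
        raw = self._raw([["AG"], ["GG"], ["AA"]])
        ds1 = orient_minor_allele(raw, ["rs1"], ["S1", "S2", "S3"])
        # re-expressing the oriented dataset's calls as allele pairs and
        # re-orienting yields the same doses
        major, minor = ds1.allele_labels[0]
        back = [[(major, major), (major, minor), (minor, minor)][int(d)] for d in ds1.calls[:, 0]]
        raw2 = np.array([[list(g)] for g in back], dtype=object)
        ds2 = orient_minor_allele(raw2, ["rs1"], ["S1", "S2", "S3"])
        np.testing.assert_array_equal(ds1.calls, ds2.calls)

    def test_empty_reference_rejected(self):
        raw = self._raw([["AG"]])
        with pytest.raises(DataError):
            orient_minor_allele(raw, ["rs1"], ["S1"], reference_sample_ids=[])


class TestGenotypeTsv:
    @given(
        st.lists(
            st.lists(st.sampled_from([0.0, 1.0, 2.0, np.nan]), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_round_trip_preserves_calls_and_missingness(self, rows):
        ds = make_genotypes(np.array(rows))
        buf = io.StringIO()
        write_genotype_tsv(ds, buf)
        buf.seek(0)
        back = read_genotype_tsv(buf)
        assert back.sample_ids == ds.sample_ids
        assert back.snp_ids == ds.snp_ids
        np.testing.assert_array_equal(
            np.nan_to_num(back.calls, nan=-1), np.nan_to_num(ds.calls, nan=-1)
        )

    def test_bad_dose_rejected(self):
        with pytest.raises(DataError):
            read_genotype_tsv(io.StringIO("sample_id\trs1\nS1\t3\n"))


class TestPhenotypes:
    def test_response_derived_from_recist(self):
        tsv = (
            "sample_id\tregimen\trecist\tcr_grade\tchem_history\n"
            "S1\tS-1\tPR\t0\tFalse\nS2\tS-1\tNC\t1\tTrue\n"
            "S3\t5-FU/MTX\tCR\t0\tFalse\nS4\thigh-dose 5-FU\tPD\t2\tTrue\n"
        )
        table = read_phenotypes(io.StringIO(tsv))
        assert table.response_series().tolist() == [1, 0, 1, 0]

    def test_unknown_recist_rejected(self):
        tsv = "sample_id\tregimen\trecist\tcr_grade\tchem_history\nS1\tS-1\tXX\t0\tFalse\n"
        with pytest.raises(DataError, match="RECIST"):
            read_phenotypes(io.StringIO(tsv))

    def test_duplicate_sample_rejected(self):
        tsv = (
            "sample_id\tregimen\trecist\tcr_grade\tchem_history\n"
            "S1\tS-1\tPR\t0\tFalse\nS1\tS-1\tNC\t0\tFalse\n"
        )
        with pytest.raises(DataError, match="duplicate"):
            read_phenotypes(io.StringIO(tsv))

    def test_write_read_round_trip(self):
        table = make_samples(["CR", "PD", "NC"], regimen=["S-1", "S-1", "5-FU/MTX"])
        buf = io.StringIO()
        write_phenotypes(table, buf)
        buf.seek(0)
        back = read_phenotypes(buf)
        pd.testing.assert_frame_equal(back.frame, table.frame)


class TestAnnotations:
    def test_semicolon_list_and_flags(self):
        tsv = (
            "snp_id\tgene\tpubmed_ids\tcancer_flag\n"
            "rs1\tGENE1\t123;456\t0\nrs2\tGENE2\t\t1\n"
        )
        ann = read_annotations(io.StringIO(tsv))
        assert ann.loc[0, "pubmed_ids"] == ["123", "456"]
        assert ann.loc[1, "pubmed_ids"] == []
        assert bool(ann.loc[1, "cancer_flag"])

    def test_round_trip(self):
        ann = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2"],
                "gene": ["A", "B"],
                "pubmed_ids": [["1", "2"], []],
                "cancer_flag": [False, True],
            }
        )
        buf = io.StringIO()
        write_annotations(ann, buf)
        buf.seek(0)
        back = read_annotations(buf)
        assert back["pubmed_ids"].tolist() == [["1", "2"], []]
        assert back["cancer_flag"].tolist() == [False, True]


class TestSplitDatasets:
    def test_study_shape_58_of_119(self):
        regimen = ["S-1"] * 58 + ["5-FU/MTX"] * 27 + ["high-dose 5-FU"] * 33 + ["low-dose 5-FU"]
        table = make_samples(["NC"] * 119, regimen=regimen)
        first, second = split_datasets(table)
        assert len(first) == 58 and len(second) == 119
        assert set(first) <= set(second)

    def test_no_s1_warns_and_empty_first(self):
        table = make_samples(["NC", "PR"], regimen=["5-FU/MTX", "high-dose 5-FU"])
        with pytest.warns(UserWarning):
            first, second = split_datasets(table)
        assert first == [] and len(second) == 2

    def test_all_s1_first_equals_second(self):
        table = make_samples(["NC", "PR", "CR"])
        first, second = split_datasets(table)
        assert first == second


class TestGenotypeDatasetValidation:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            GenotypeDataset(["S1"], ["rs1", "rs2"], np.zeros((1, 1)), [("A", "G")] * 2)

    def test_identical_alleles_rejected(self):
        with pytest.raises(DataError):
            make_genotypes([[0.0]]).__class__(
                ["S1"], ["rs1"], np.zeros((1, 1)), [("A", "A")]
            )

    def test_subset_samples_preserves_order(self):
        ds = make_genotypes([[0, 1], [2, 0], [1, 1]])
        sub = ds.subset_samples(["S3", "S1"])
        assert sub.sample_ids == ["S3", "S1"]
        np.testing.assert_array_equal(sub.calls, ds.calls[[2, 0]])
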