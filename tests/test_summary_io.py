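import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_table
from mr2s import (ConfigurationError, DataError, harmonize, has_intermediate_af,
                  is_palindromic, read_summary_table)

TSV_HEADER = "SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tsamplesize\n"


def _write(tmp_path, rows, name="gwas.tsv"):
    path = tmp_path / name
    path.write_text(TSV_HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


class TestReadSummaryTable:
    def test_well_formed_rows_read_verbatim(self, tmp_path):
        rows = [(f"rs{i}", "A", "G", 0.3, 0.1, 0.01, 1e-10, 20000) for i in range(5)]
        t = read_summary_table(_write(tmp_path, rows))
        assert len(t) == 5
        assert list(t.data["snp_id"]) == [f"rs{i}" for i in range(5)]
        assert t.data["beta"].tolist() == [0.1] * 5

    def test_zero_se_row_dropped(self, tmp_path):
        rows = [("rs1", "A", "G", 0.3, 0.1, 0.01, 1e-10, 20000),
                ("rs2", "A", "G", 0.3, 0.1, 0.0, 1e-10, 20000)]
        t = read_summary_table(_write(tmp_path, rows))
        assert list(t.data["snp_id"]) == ["rs1"]

    def test_duplicate_snp_id_keeps_first(self, tmp_path):
        rows = [("rs1", "A", "G", 0.3, 0.1, 0.01, 1e-10, 20000),
                ("rs1", "T", "C", 0.4, 0.2, 0.02, 1e-9, 20000)]
        t = read_summary_table(_write(tmp_path, rows))
        assert len(t) == 1
        assert t.data.iloc[0]["beta"] == 0.1

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tbeta\tse\nrs1\t0.1\t0.01\n")
        with pytest.raises(ConfigurationError):
            read_summary_table(path)

    def test_column_map_override(self, tmp_path):
        path = tmp_path / "alt.tsv"
        path.write_text("rsid\tA1\tA2\tfreq\tb\tstderr\tp\tN\n"
                        "rs1\tA\tG\t0.3\t0.1\t0.01\t1e-10\t20000\n")
        t = read_summary_table(path, column_map={
            "snp_id": "rsid", "effect_allele": "A1", "other_allele": "A2",
            "eaf": "freq", "beta": "b", "se": "stderr", "pvalue": "p", "n": "N"})
        assert len(t) == 1

    def test_all_rows_invalid_is_data_error(self, tmp_path):
        rows = [("rs1", "A", "A", 0.3, 0.1, 0.01, 1e-10, 20000)]
        with pytest.raises(DataError):
            read_summary_table(_write(tmp_path, rows))


@pytest.mark.parametrize("ea,oa,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("T", "G", False), ("G", "A", False),
])
def test_palindrome_is_complementary_pair(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def test_palindrome_rejects_invalid_alleles():
    with pytest.raises(DataError):
        is_palindromic("A", "N")


@pytest.mark.parametrize("eaf,expected", [
    (0.15, True), (0.5, False), (0.30, False), (0.01, False), (0.02, True),
    (0.29, True), (0.005, False),
])
def test_intermediate_frequency_window_is_strict(eaf, expected):
    assert has_intermediate_af(eaf) is expected


def test_intermediate_frequency_custom_window():
    assert has_intermediate_af(0.4, window=(0.3, 0.7))
    assert not has_intermediate_af(0.3, window=(0.3, 0.7))


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.10, 0.01)])
        out = make_table([("rs1", "G", "A", 0.7, -0.05, 0.01)])
        h = harmonize(exp, out)
        assert h.k == 1
        assert h.Gamma[0] == pytest.approx(0.05)
        assert bool(h.flags["flipped"][0])

    def test_matching_alleles_kept_as_is(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.10, 0.01)])
        out = make_table([("rs1", "A", "G", 0.3, -0.05, 0.01)])
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(-0.05)
        assert not bool(h.flags["flipped"][0])

    def test_strand_complement_resolved(self):
        # exposure A/G, outcome reported on the other strand as T/C
        exp = make_table([("rs1", "A", "G", 0.3, 0.10, 0.01)])
        out = make_table([("rs1", "T", "C", 0.3, 0.07, 0.01)])
        h = harmonize(exp, out)
        assert h.Gamma[0] == pytest.approx(0.07)
        # complement of the swapped pair: outcome C/T aligns with a flip
        out2 = make_table([("rs1", "C", "T", 0.7, 0.07, 0.01)])
        h2 = harmonize(exp, out2)
        assert h2.Gamma[0] == pytest.approx(-0.07)

    def test_palindromic_intermediate_dropped(self):
        exp = make_table([("rs1", "A", "T", 0.15, 0.10, 0.01),
                          ("rs2", "A", "G", 0.15, 0.10, 0.01)])
        out = make_table([("rs1", "A", "T", 0.15, 0.05, 0.01),
                          ("rs2", "A", "G", 0.15, 0.05, 0.01)])
        h = harmonize(exp, out)
        assert list(h.snp_id) == ["rs2"]
        assert h.drops.iloc[0].tolist() == ["rs1", "palindromic_intermediate"]

    def test_palindromic_outside_window_kept_and_freq_oriented(self):
        # eaf 0.45 is outside (0.01, 0.30); outcome frequency on the other
        # side of 0.5 signals the opposite strand/orientation
        exp = make_table([("rs1", "A", "T", 0.45, 0.10, 0.01)])
        out = make_table([("rs1", "A", "T", 0.55, 0.05, 0.01)])
        h = harmonize(exp, out)
        assert h.k == 1
        assert h.Gamma[0] == pytest.approx(-0.05)

    def test_palindromic_missing_eaf_dropped(self):
        exp = make_table([("rs1", "A", "T", np.nan, 0.10, 0.01)])
        out = make_table([("rs1", "A", "T", 0.45, 0.05, 0.01)])
        with pytest.raises(DataError):
            harmonize(exp, out)  # sole SNP dropped -> nothing harmonizable

    def test_allele_mismatch_dropped_not_kept(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.10, 0.01),
                          ("rs2", "A", "G", 0.3, 0.10, 0.01)])
        out = make_table([("rs1", "A", "C", 0.3, 0.05, 0.01),
                          ("rs2", "A", "G", 0.3, 0.05, 0.01)])
        h = harmonize(exp, out)
        assert list(h.snp_id) == ["rs2"]
        assert dict(zip(h.drops["snp_id"], h.drops["reason"]))["rs1"] == "allele_mismatch"

    def test_low_maf_dropped(self):
        exp = make_table([("rs1", "A", "G", 0.005, 0.10, 0.01),
                          ("rs2", "A", "G", 0.3, 0.10, 0.01)])
        out = make_table([("rs1", "A", "G", 0.005, 0.05, 0.01),
                          ("rs2", "A", "G", 0.3, 0.05, 0.01)])
        h = harmonize(exp, out)
        assert list(h.snp_id) == ["rs2"]
        assert "low_maf" in set(h.drops["reason"])

    def test_proxy_lookup_used_when_target_missing(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.10, 0.01)])
        out = make_table([("rs9", "A", "G", 0.3, 0.05, 0.01)])
        h = harmonize(exp, out, proxy_table={"rs1": "rs9"})
        assert h.k == 1
        assert h.flags["proxy"][0] == "rs9"

    def test_missing_in_outcome_logged(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.10, 0.01),
                          ("rs2", "A", "G", 0.3, 0.10, 0.01)])
        out = make_table([("rs2", "A", "G", 0.3, 0.05, 0.01)])
        h = harmonize(exp, out)
        assert dict(zip(h.drops["snp_id"], h.drops["reason"]))["rs1"] == "missing_in_outcome"

    def test_every_input_snp_accounted_for(self):
        exp = make_table([
            ("rs1", "A", "G", 0.3, 0.10, 0.01), ("rs2", "A", "T", 0.15, 0.1, 0.01),
            ("rs3", "C", "G", 0.45, 0.1, 0.01), ("rs4", "A", "C", 0.005, 0.1, 0.01),
            ("rs5", "T", "C", 0.4, 0.1, 0.01),
        ])
        out = make_table([
            ("rs1", "G", "A", 0.7, 0.05, 0.01), ("rs2", "A", "T", 0.15, 0.05, 0.01),
            ("rs3", "C", "G", 0.45, 0.05, 0.01), ("rs4", "A", "C", 0.005, 0.05, 0.01),
        ])
        h = harmonize(exp, out)
        assert h.k + len(h.drops) == len(exp)
        assert set(h.snp_id) | set(h.drops["snp_id"]) == set(exp.data["snp_id"])
        assert not h.drops["snp_id"].duplicated().any()

    def test_involution_already_harmonized_pair_is_identity(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.10, 0.01),
                          ("rs2", "C", "T", 0.45, -0.20, 0.02)])
        out = make_table([("rs1", "G", "A", 0.7, -0.05, 0.01),
                          ("rs2", "T", "C", 0.55, 0.04, 0.01)])
        h1 = harmonize(exp, out)
        # rebuild the outcome table from the harmonized effects (aligned alleles)
        out2 = make_table([
            (sid, exp.data.iloc[i]["effect_allele"], exp.data.iloc[i]["other_allele"],
             exp.data.iloc[i]["eaf"], h1.Gamma[i], h1.sigma_y[i])
            for i, sid in enumerate(h1.snp_id)])
        h2 = harmonize(exp, out2)
        assert h2.k == h1.k and len(h2.drops) == 0
        assert not h2.flags["flipped"].any()
        np.testing.assert_allclose(h2.Gamma, h1.Gamma)

    @settings(max_examples=50, deadline=None)
    @given(beta=st.floats(-0.5, 0.5, allow_nan=False),
           eaf=st.floats(0.31, 0.69),
           pair=st.sampled_from([("A", "G"), ("T", "C"), ("A", "T"), ("C", "G")]))
    def test_flip_symmetry(self, beta, eaf, pair):
        """Re-expressing the outcome record on the other allele (negated beta,
        swapped labels, reflected frequency) must not change the result."""
        ea, oa = pair
        exp = make_table([("rs1", ea, oa, eaf, 0.10, 0.01)])
        out = make_table([("rs1", ea, oa, eaf, beta, 0.01)])
        out_swapped = make_table([("rs1", oa, ea, 1 - eaf, -beta, 0.01)])
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, out_swapped)
        assert h1.Gamma[0] == pytest.approx(h2.Gamma[0])
        assert h1.k == h2.k
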