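"""IO and allele-harmonization behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hy_st

from tsmr.exceptions import (
    ConfigurationError,
    EmptyIntersectionError,
    InvalidAlleleError,
    RowParseError,
)
from tsmr.gwas_io import (
    HarmonizedDataset,
    complement_alleles,
    harmonize,
    is_palindromic,
    read_summary_stats,
    validate_summary_stats,
    write_summary_stats,
)


class TestReadSummaryStats:
    def test_reads_published_instrument_table(self, ua_instruments_tsv):
        df = read_summary_stats(ua_instruments_tsv)
        assert len(df) == 11
        assert df["snp"].iloc[0] == "rs10305838"
        assert df["beta"].iloc[0] == pytest.approx(0.130)
        assert df["se"].iloc[0] == pytest.approx(0.016)
        validate_summary_stats(df)

    def test_header_only_file_yields_empty_frame(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("SNP\tCHR\tPOS\tEA\tOA\tBETA\tSE\tP\tN\n")
        assert len(read_summary_stats(path)) == 0

    def test_nonpositive_se_row_is_dropped(self, tmp_path):
        path = tmp_path / "bad_se.tsv"
        path.write_text(
            "SNP\tCHR\tPOS\tEA\tOA\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.1\t0.0\t1e-9\t1000\n"
            "rs2\t1\t200\tA\tG\t0.1\t0.02\t1e-9\t1000\n"
        )
        df = read_summary_stats(path)
        assert list(df["snp"]) == ["rs2"]

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = tmp_path / "no_se.tsv"
        path.write_text("SNP\tCHR\tPOS\tEA\tOA\tBETA\tP\tN\nrs1\t1\t1\tA\tG\t0.1\t0.5\t10\n")
        with pytest.raises(ConfigurationError, match="SE"):
            read_summary_stats(path)

    def test_unparsable_numeric_names_line(self, tmp_path):
        path = tmp_path / "bad_num.tsv"
        path.write_text(
            "SNP\tCHR\tPOS\tEA\tOA\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.1\t0.02\t1e-9\t1000\n"
            "rs2\t1\t200\tA\tG\tnot_a_number\t0.02\t1e-9\t1000\n"
        )
        with pytest.raises(RowParseError) as err:
            read_summary_stats(path)
        assert err.value.line_number == 3

    def test_custom_column_map_and_delimiter(self, tmp_path):
        path = tmp_path / "custom.csv"
        path.write_text(
            "rsid,chr,bp,a1,a2,b,stderr,pval,samples\n"
            "rs9,2,500,a,g,0.2,0.05,1e-10,5000\n"
        )
        df = read_summary_stats(
            path,
            column_map={"snp": "rsid", "chrom": "chr", "pos": "bp", "ea": "a1",
                        "oa": "a2", "beta": "b", "se": "stderr",
                        "pvalue": "pval", "n": "samples"},
            delimiter=",",
        )
        assert df["ea"].iloc[0] == "A"  # upper-cased
        assert df["pos"].iloc[0] == 500

    def test_roundtrip_through_writer(self, ua_instruments, tmp_path):
        path = tmp_path / "out.tsv"
        write_summary_stats(ua_instruments, path)
        back = read_summary_stats(path)
        pd.testing.assert_series_equal(back["beta"], ua_instruments["beta"])
        assert list(back["snp"]) == list(ua_instruments["snp"])


@pytest.mark.parametrize(
    "ea, oa, expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("C", "T", False), ("a", "t", True)],
)
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


@pytest.mark.parametrize(
    "pair, expected",
    [(("A", "G"), ("T", "C")), (("C", "T"), ("G", "A")), (("A", "T"), ("T", "A"))],
)
def test_complement_alleles(pair, expected):
    assert complement_alleles(*pair) == expected


@pytest.mark.parametrize("func", [is_palindromic, complement_alleles])
def test_allele_alphabet_is_enforced(func):
    with pytest.raises(InvalidAlleleError):
        func("N", "A")


def _frame(rows):
    return pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se",
                       "pvalue", "n"]
    )


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exposure = _frame([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.01, 1e-9, 1000)])
        outcome = _frame([("rs1", "1", 100, "G", "A", 0.7, -0.05, 0.02, 0.01, 1000)])
        ds = harmonize(exposure, outcome)
        assert ds.Gamma[0] == pytest.approx(0.05)
        assert ds.sign_flipped[0]
        assert not ds.strand_complemented[0]

    def test_palindromic_exposure_variant_is_dropped(self):
        exposure = _frame([
            ("rs1", "1", 100, "A", "T", 0.3, 0.10, 0.01, 1e-9, 1000),
            ("rs2", "1", 200, "A", "G", 0.3, 0.10, 0.01, 1e-9, 1000),
        ])
        outcome = _frame([
            ("rs1", "1", 100, "A", "T", 0.3, 0.05, 0.02, 0.01, 1000),
            ("rs2", "1", 200, "A", "G", 0.3, 0.05, 0.02, 0.01, 1000),
        ])
        ds = harmonize(exposure, outcome)
        assert list(ds.snp) == ["rs2"]
        assert ("rs1", "palindromic") in ds.dropped

    def test_identical_frames_pass_through_unchanged(self):
        rows = [(f"rs{i}", "1", 100 * i, "A", "G", 0.3, 0.1 * i, 0.01, 1e-9, 1000)
                for i in range(1, 6)]
        ds = harmonize(_frame(rows), _frame(rows))
        assert np.allclose(ds.Gamma, ds.gamma)
        assert not ds.sign_flipped.any()
        assert not ds.strand_complemented.any()

    def test_strand_complement_resolves_opposite_strand_report(self):
        exposure = _frame([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.01, 1e-9, 1000)])
        # T/C is A/G reported on the other strand, same orientation
        outcome = _frame([("rs1", "1", 100, "T", "C", 0.3, 0.07, 0.02, 0.01, 1000)])
        ds = harmonize(exposure, outcome)
        assert ds.Gamma[0] == pytest.approx(0.07)
        assert ds.strand_complemented[0]
        assert not ds.sign_flipped[0]
        # C/T is A/G on the other strand, swapped
        outcome2 = _frame([("rs1", "1", 100, "C", "T", 0.3, 0.07, 0.02, 0.01, 1000)])
        ds2 = harmonize(exposure, outcome2)
        assert ds2.Gamma[0] == pytest.approx(-0.07)
        assert ds2.sign_flipped[0] and ds2.strand_complemented[0]

    def test_unresolvable_pair_dropped_with_reason(self):
        exposure = _frame([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.01, 1e-9, 1000)])
        outcome = _frame([("rs1", "1", 100, "A", "C", 0.3, 0.07, 0.02, 0.01, 1000)])
        ds = harmonize(exposure, outcome)
        assert ds.n_snps == 0
        assert ds.dropped == [("rs1", "allele_mismatch")]

    def test_no_shared_snps_raises(self):
        exposure = _frame([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.01, 1e-9, 1000)])
        outcome = _frame([("rs2", "1", 100, "A", "G", 0.3, 0.07, 0.02, 0.01, 1000)])
        with pytest.raises(EmptyIntersectionError):
            harmonize(exposure, outcome)

    def test_idempotent_on_aligned_data(self, ua_instruments):
        outcome = ua_instruments.copy()
        outcome["beta"] = outcome["beta"] * 0.5
        once = harmonize(ua_instruments, outcome)
        # rebuild outcome records from the harmonized frame and harmonize again
        exp2 = ua_instruments[ua_instruments["snp"].isin(set(once.snp))].copy()
        out2 = exp2.copy()
        gmap = dict(zip(once.snp, once.Gamma))
        smap = dict(zip(once.snp, once.se_Gamma))
        out2["beta"] = out2["snp"].map(gmap)
        out2["se"] = out2["snp"].map(smap)
        twice = harmonize(exp2, out2)
        np.testing.assert_array_equal(once.Gamma, twice.Gamma)
        assert not twice.sign_flipped.any()

    def test_sign_flip_involution(self, ua_instruments):
        """Swapping outcome alleles and negating betas leaves Gamma unchanged."""
        outcome = ua_instruments.copy()
        outcome["beta"] = outcome["beta"] * 0.5
        plain = harmonize(ua_instruments, outcome)
        swapped = outcome.copy()
        swapped[["ea", "oa"]] = swapped[["oa", "ea"]].to_numpy()
        swapped["beta"] = -swapped["beta"]
        flipped = harmonize(ua_instruments, swapped)
        np.testing.assert_allclose(plain.Gamma, flipped.Gamma)
        assert flipped.sign_flipped.all()

    def test_output_never_exceeds_either_input(self, ua_instruments):
        outcome = ua_instruments.iloc[:7].copy()
        ds = harmonize(ua_instruments, outcome)
        assert ds.n_snps <= min(len(ua_instruments), len(outcome))
        dropped_ids = {snp for snp, _ in ds.dropped}
        assert len(dropped_ids) == len(ds.dropped)  # one reason per SNP


_NONPAL_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"),
                 ("T", "C"), ("G", "A"), ("C", "A"), ("T", "G")]


@given(
    rows=hy_st.lists(
        hy_st.tuples(
            hy_st.sampled_from(_NONPAL_PAIRS),
            hy_st.floats(-1, 1, allow_nan=False, allow_infinity=False),
            hy_st.booleans(),  # report outcome on swapped alleles
            hy_st.booleans(),  # report outcome on the opposite strand
        ),
        min_size=1, max_size=8,
    )
)
@settings(max_examples=60, deadline=None)
def test_harmonize_recovers_effects_under_any_frame_change(rows):
    """Whatever combination of allele swap and strand flip the outcome study
    reports in, harmonization recovers the outcome effect on the exposure's
    allele frame exactly."""
    exposure = _frame([
        (f"rs{i}", "1", 100 + i, ea, oa, 0.3, 0.1, 0.01, 1e-9, 1000)
        for i, ((ea, oa), _, _, _) in enumerate(rows)
    ])
    out_rows = []
    for i, ((ea, oa), gamma_out, swap, flip) in enumerate(rows):
        beta = gamma_out
        if swap:
            ea, oa = oa, ea
            beta = -beta
        if flip:
            ea, oa = complement_alleles(ea, oa)
        out_rows.append((f"rs{i}", "1", 100 + i, ea, oa, 0.3, beta, 0.02, 0.5, 1000))
    ds = harmonize(exposure, _frame(out_rows))
    assert ds.n_snps == len(rows)
    np.testing.assert_allclose(ds.Gamma, [r[1] for r in rows])


class TestHarmonizedDataset:
    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError, match="length"):
            HarmonizedDataset(snp=["a"], gamma=[0.1, 0.2], se_gamma=[0.1],
                              Gamma=[0.1], se_Gamma=[0.1])

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError, match="positive"):
            HarmonizedDataset(snp=["a"], gamma=[0.1], se_gamma=[0.0],
                              Gamma=[0.1], se_Gamma=[0.1])

    def test_dataframe_roundtrip(self, two_snp_dataset):
        back = HarmonizedDataset.from_dataframe(two_snp_dataset.to_dataframe())
        np.testing.assert_array_equal(back.gamma, two_snp_dataset.gamma)
        np.testing.assert_array_equal(back.snp, two_snp_dataset.snp)
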