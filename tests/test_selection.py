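"""Instrument-screening stages: significance, clumping, F, palindromes, confounders."""

import numpy as np
import pandas as pd
import pytest

from tsmr.exceptions import LDLookupError
from tsmr.selection import (
    LDMatrix,
    SelectionParams,
    clump,
    f_statistic,
    filter_confounders,
    filter_palindromic,
    filter_significance,
    filter_weak,
    instrument_strength,
    per_snp_r2,
    select_instruments,
)
from tsmr.simulate import selection_demo_study


def _records(rows):
    return pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se",
                       "pvalue", "n"]
    )


class TestSignificance:
    def test_published_instruments_all_pass_genome_wide(self, ua_instruments):
        # largest printed p is 3.35e-8, still under 5e-8
        assert len(filter_significance(ua_instruments, 5e-8)) == 11

    def test_zero_threshold_empties(self, ua_instruments):
        assert len(filter_significance(ua_instruments, 0.0)) == 0

    def test_strict_inequality_at_threshold(self):
        recs = _records([
            ("rs1", "1", 1, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100),
            ("rs2", "1", 2, "A", "G", 0.3, 0.1, 0.01, 1e-7, 100),
        ])
        assert list(filter_significance(recs, 5e-8)["snp"]) == ["rs1"]


def _ld(ids, pairs):
    index = {s: i for i, s in enumerate(ids)}
    r2 = np.eye(len(ids))
    for a, b, v in pairs:
        r2[index[a], index[b]] = r2[index[b], index[a]] = v
    return LDMatrix(snp_ids=ids, r2=r2)


def brute_force_clump(records, ld, clump_r2, window_kb):
    """Independent literal reimplementation of greedy index selection."""
    remaining = {r["snp"]: r for _, r in records.iterrows()}
    kept = []
    while remaining:
        index_snp = min(
            remaining.values(),
            key=lambda r: (r["pvalue"], r["pos"], r["snp"]),
        )["snp"]
        kept.append(index_snp)
        idx = remaining.pop(index_snp)
        for other in list(remaining):
            o = remaining[other]
            same_chrom = o["chrom"] == idx["chrom"]
            close = abs(o["pos"] - idx["pos"]) <= window_kb * 1000
            if same_chrom and close and ld.r2_between(index_snp, other) >= clump_r2:
                del remaining[other]
    return kept


class TestClump:
    def test_correlated_neighbour_removed_independent_kept(self):
        recs = _records([
            ("A", "1", 1_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 100),
            ("B", "1", 1_050_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100),
            ("C", "1", 1_100_000, "A", "G", 0.3, 0.1, 0.01, 1e-8, 100),
        ])
        ld = _ld(["A", "B", "C"], [("A", "B", 0.5), ("A", "C", 0.001)])
        assert list(clump(recs, ld, 0.01, 10_000)["snp"]) == ["A", "C"]

    def test_independent_snps_pass_through(self):
        recs = _records([
            ("A", "1", 1, "A", "G", 0.3, 0.1, 0.01, 1e-10, 100),
            ("B", "1", 2, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100),
        ])
        ld = _ld(["A", "B"], [])
        assert len(clump(recs, ld, 0.01, 10_000)) == 2

    def test_window_applies_within_chromosome_only(self):
        recs = _records([
            ("A", "1", 1_000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 100),
            ("B", "2", 1_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100),
        ])
        ld = _ld(["A", "B"], [("A", "B", 0.9)])
        assert len(clump(recs, ld, 0.01, 10_000)) == 2

    def test_missing_snp_in_ld_matrix_raises(self):
        recs = _records([("A", "1", 1, "A", "G", 0.3, 0.1, 0.01, 1e-10, 100)])
        ld = _ld(["B"], [])
        with pytest.raises(LDLookupError, match="A"):
            clump(recs, ld, 0.01, 10_000)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(2, 21))
        ids = [f"rs{i}" for i in range(j)]
        chrom = rng.choice(["1", "2"], j)
        pos = rng.integers(1, 30_000_000, j)
        p = 10.0 ** rng.uniform(-12, -4, j)
        recs = _records([
            (ids[i], chrom[i], int(pos[i]), "A", "G", 0.3, 0.1, 0.01, p[i], 100)
            for i in range(j)
        ])
        a = rng.uniform(0, 1, (j, j))
        r2 = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(snp_ids=ids, r2=r2)
        got = list(clump(recs, ld, 0.1, 5_000)["snp"])
        assert got == brute_force_clump(recs, ld, 0.1, 5_000)

    def test_retained_pairs_are_independent(self):
        rng = np.random.default_rng(42)
        j = 15
        ids = [f"rs{i}" for i in range(j)]
        recs = _records([
            (ids[i], "1", int(rng.integers(1, 5_000_000)), "A", "G", 0.3,
             0.1, 0.01, 10.0 ** rng.uniform(-12, -6), 100)
            for i in range(j)
        ])
        a = rng.uniform(0, 1, (j, j))
        r2 = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(snp_ids=ids, r2=r2)
        kept = clump(recs, ld, 0.2, 10_000)
        for i in range(len(kept)):
            for k in range(i + 1, len(kept)):
                within = abs(kept["pos"].iat[i] - kept["pos"].iat[k]) <= 10_000_000
                if within:
                    assert ld.r2_between(kept["snp"].iat[i], kept["snp"].iat[k]) < 0.2


class TestStrength:
    def test_zscore_r2_matches_hand_evaluation(self):
        rec = {"beta": 0.130, "se": 0.016, "n": 456_468}
        z = 0.130 / 0.016
        assert per_snp_r2(rec) == pytest.approx(z * z / (z * z + 456_468 - 2))
        assert per_snp_r2(rec) == pytest.approx(1.446e-4, rel=1e-3)

    def test_frequency_r2_matches_hand_evaluation(self):
        assert per_snp_r2({"beta": 0.1, "eaf": 0.5}, "frequency") == pytest.approx(0.005)

    def test_null_effect_gives_zero_r2(self):
        assert per_snp_r2({"beta": 0.0, "se": 0.1, "n": 100}) == 0.0
        assert per_snp_r2({"beta": 0.0, "eaf": 0.2}, "frequency") == 0.0

    def test_frequency_mode_requires_eaf(self):
        with pytest.raises(ValueError, match="frequency"):
            per_snp_r2({"beta": 0.1, "eaf": np.nan}, "frequency")

    def test_f_statistic_hand_values(self):
        assert f_statistic(1.0001e-4, 456_468, 1) == pytest.approx(45.65, rel=1e-3)
        assert f_statistic(0.0, 456_468, 1) == 0.0
        assert f_statistic(0.5, 4, 1) == pytest.approx(2.0)

    def test_f_statistic_domain_guard(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 2, 1)

    def test_f_statistic_increasing_in_r2(self):
        values = [f_statistic(r2, 1000, 1) for r2 in np.linspace(0, 0.9, 25)]
        assert np.all(np.diff(values) > 0)

    def test_filter_weak_boundary_keeps_f_equal_to_threshold(self):
        recs = _records([
            (s, "1", i, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100)
            for i, s in enumerate(["a", "b", "c"])
        ])
        strengths = pd.DataFrame({"snp": ["a", "b", "c"], "f_stat": [9.99, 10.0, 45.6]})
        assert list(filter_weak(recs, strengths, 10.0)["snp"]) == ["b", "c"]

    def test_filter_weak_empty_input(self):
        recs = _records([])
        strengths = pd.DataFrame(columns=["snp", "f_stat"])
        assert len(filter_weak(recs, strengths, 10.0)) == 0


class TestConfounders:
    def test_associated_snp_removed(self):
        recs = _records([("X", "1", 1, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100)])
        table = pd.DataFrame({"snp": ["X"], "phenotype": ["diabetes"], "pvalue": [1e-6]})
        assert len(filter_confounders(recs, table, 1e-5)) == 0

    def test_empty_table_is_identity(self, ua_instruments):
        out = filter_confounders(ua_instruments, None, 1e-5)
        assert list(out["snp"]) == list(ua_instruments["snp"])

    def test_boundary_p_is_retained(self):
        recs = _records([("X", "1", 1, "A", "G", 0.3, 0.1, 0.01, 1e-9, 100)])
        table = pd.DataFrame({"snp": ["X"], "phenotype": ["obesity"], "pvalue": [1e-5]})
        assert len(filter_confounders(recs, table, 1e-5)) == 1


class TestPipelineCascade:
    def test_demo_fixture_produces_expected_audit(self):
        exposure, ld, confounders, expected = selection_demo_study()
        selected, audit = select_instruments(exposure, ld, confounders)
        assert audit.counts == expected
        assert len(selected) == expected[-1]
        assert audit.stages == ["input", "significance", "clumping",
                                "f_statistic", "palindrome", "confounder"]
        reasons = set(audit.dropped.values())
        assert {"not_genome_wide_significant", "in_ld_with_index_snp",
                "palindromic", "confounder_associated"} <= reasons

    def test_nothing_significant_gives_empty_with_audit(self):
        exposure, ld, confounders, _ = selection_demo_study()
        params = SelectionParams(p_threshold=1e-30)
        selected, audit = select_instruments(exposure, ld, confounders, params)
        assert len(selected) == 0
        assert audit.counts[0] == 100 and audit.counts[1] == 0

    def test_params_roundtrip_preserves_selection(self):
        exposure, ld, confounders, _ = selection_demo_study()
        params = SelectionParams()
        rt = SelectionParams.from_dict(params.to_dict())
        a, _ = select_instruments(exposure, ld, confounders, params)
        b, _ = select_instruments(exposure, ld, confounders, rt)
        assert list(a["snp"]) == list(b["snp"])

    @pytest.mark.parametrize("stage", ["significance", "palindrome", "confounder"])
    def test_filters_are_contractions_and_idempotent(self, stage, ua_instruments):
        table = pd.DataFrame({"snp": ["rs10305838"], "phenotype": ["obesity"],
                              "pvalue": [1e-7]})
        filt = {
            "significance": lambda df: filter_significance(df, 1e-8),
            "palindrome": filter_palindromic,
            "confounder": lambda df: filter_confounders(df, table, 1e-5),
        }[stage]
        once = filt(ua_instruments)
        assert set(once["snp"]) <= set(ua_instruments["snp"])
        twice = filt(once)
        assert list(twice["snp"]) == list(once["snp"])


class TestLDMatrix:
    def test_validation_rejects_asymmetry_and_bad_diagonal(self):
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            LDMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))

    def test_square_and_long_formats_roundtrip(self, tmp_path):
        ld = _ld(["a", "b", "c"], [("a", "b", 0.4)])
        sq = tmp_path / "ld_square.tsv"
        lg = tmp_path / "ld_long.tsv"
        ld.to_square_tsv(sq)
        ld.to_long_tsv(lg)
        for loaded in (LDMatrix.from_square_tsv(sq), LDMatrix.from_long_tsv(lg)):
            assert loaded.snp_ids == ld.snp_ids
            np.testing.assert_allclose(loaded.r2, ld.r2)

    def test_instrument_strength_table_covers_all_records(self, ua_instruments):
        table = instrument_strength(ua_instruments)
        assert list(table["snp"]) == list(ua_instruments["snp"])
        assert (table["f_stat"] > 10).all()  # all published instruments are strong
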