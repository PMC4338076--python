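"""Percent-binding classification, group comparison, SGF and immunoblot."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allerscreen.maize_study import (
    EXTRACTS,
    QUALITATIVE_ELISA_ODS,
    band_matrices,
    immunoblot_tables,
)
from allerscreen.serology import (
    AnchorError,
    BandMatrix,
    BandMatrixError,
    Category,
    Group,
    ImmunoblotTable,
    ODTable,
    Presence,
    StabilityCall,
    categorize,
    classify_table,
    compare_groups,
    immunoblot_concordance,
    match_bands,
    percent_binding,
    qualitative_gm_call,
    read_band_matrix,
    read_immunoblot_tables,
    read_od_table,
    sgf_stability,
)
from allerscreen.synth import SerologySpec, make_band_matrix, make_od_table


class TestPercentBinding:
    def test_patient_at_control_gives_zero(self):
        assert percent_binding(0.03, 0.03, 0.83) == pytest.approx(0.0)

    def test_patient_at_max_gives_hundred(self):
        assert percent_binding(0.83, 0.03, 0.83) == pytest.approx(100.0)

    def test_midpoint_arithmetic(self):
        assert percent_binding(0.43, 0.03, 0.83) == pytest.approx(50.0)

    def test_out_of_range_not_clipped(self):
        assert percent_binding(0.01, 0.03, 0.83) < 0
        assert percent_binding(1.2, 0.03, 0.83) > 100

    def test_degenerate_anchor_rejected(self):
        with pytest.raises(AnchorError):
            percent_binding(0.5, 0.5, 0.5)

    @settings(max_examples=100, deadline=None)
    @given(
        od=st.floats(0, 2),
        ctrl=st.floats(0, 1),
        span=st.floats(0.05, 2),
        a=st.floats(0.1, 10),
        b=st.floats(0, 5),
    )
    def test_affine_invariance(self, od, ctrl, span, a, b):
        """od -> a*od + b leaves percent binding unchanged (a > 0)."""
        before = percent_binding(od, ctrl, ctrl + span)
        after = percent_binding(a * od + b, a * ctrl + b, a * (ctrl + span) + b)
        assert after == pytest.approx(before, rel=1e-9, abs=1e-9)


class TestCategorize:
    @pytest.mark.parametrize(
        "percent, expected",
        [
            (14.999, Category.LOW),
            (15.0, Category.MODERATE),
            (29.999, Category.MODERATE),
            (30.0, Category.SIGNIFICANT),
            (45.0, Category.SIGNIFICANT),
            (60.0, Category.SIGNIFICANT),
            (60.001, Category.VERY_HIGH),
            (-5.0, Category.LOW),
        ],
    )
    def test_boundaries(self, percent, expected):
        assert categorize(percent) is expected

    def test_monotone_step_function(self):
        order = [categorize(p) for p in np.linspace(-10, 110, 200)]
        ranks = [list(Category).index(c) for c in order]
        assert ranks == sorted(ranks)


class TestClassifyTable:
    def test_planted_counts_recovered_exactly(self):
        spec = SerologySpec(
            n_patients=20,
            n_controls=5,
            category_counts={"ag1": (8, 6, 4, 2), "ag2": (10, 5, 5, 0)},
            seed=42,
        )
        result = classify_table(make_od_table(spec))
        assert tuple(result.counts.loc["ag1"]) == (8, 6, 4, 2)
        assert tuple(result.counts.loc["ag2"]) == (10, 5, 5, 0)
        # positives assigned to the lowest-indexed patients: joint set = min
        assert len(result.selected_sera) == 5

    def test_patients_at_control_mean_are_all_low(self):
        od = pd.DataFrame(
            {"ag": [0.05, 0.05, 0.05, 0.05, 0.9]},
            index=["p1", "p2", "c1", "c2", "pos"],
        )
        groups = {
            "p1": Group.PATIENT,
            "p2": Group.PATIENT,
            "c1": Group.CONTROL,
            "c2": Group.CONTROL,
            "pos": Group.POSITIVE_CONTROL,
        }
        result = classify_table(ODTable(od=od, groups=groups))
        assert tuple(result.counts.loc["ag"]) == (2, 0, 0, 0)
        assert result.selected_sera == ()

    def test_max_patient_anchor_used_without_positive_control(self):
        od = pd.DataFrame(
            {"ag": [0.83, 0.43, 0.03, 0.03]}, index=["p1", "p2", "c1", "c2"]
        )
        groups = {
            "p1": Group.PATIENT,
            "p2": Group.PATIENT,
            "c1": Group.CONTROL,
            "c2": Group.CONTROL,
        }
        result = classify_table(ODTable(od=od, groups=groups))
        assert result.anchors.loc["ag", "max_positive"] == pytest.approx(0.83)
        by_subject = {r.subject: r for r in result.results}
        assert by_subject["p1"].percent == pytest.approx(100.0)
        assert by_subject["p2"].percent == pytest.approx(50.0)

    def test_missing_controls_raise_anchor_error(self):
        od = pd.DataFrame({"ag": [0.5]}, index=["p1"])
        with pytest.raises(AnchorError):
            classify_table(ODTable(od=od, groups={"p1": Group.PATIENT}))

    def test_tidy_round_trip(self, tmp_path):
        spec = SerologySpec(
            n_patients=6, n_controls=3, category_counts={"ag": (3, 2, 1, 0)}, seed=1
        )
        table = make_od_table(spec)
        path = tmp_path / "od.tsv"
        table.to_tidy().to_csv(path, sep="\t", index=False)
        back = read_od_table(path)
        pd.testing.assert_frame_equal(back.od.rename_axis(None), table.od, check_like=True)


class TestQualitativeCall:
    @pytest.mark.parametrize(
        "sample, blank, expected",
        [(0.2, 0.07, True), (0.17, 0.07, False), (0.16, 0.07, False)],
    )
    def test_cutoff_is_blank_mean_plus_point_one(self, sample, blank, expected):
        assert qualitative_gm_call([sample], [blank]).positive is expected

    def test_study_gm_extracts_all_positive(self):
        for extract, (sample, blank) in QUALITATIVE_ELISA_ODS.items():
            res = qualitative_gm_call([sample], [blank])
            assert res.positive, extract

    def test_replicates_averaged(self):
        res = qualitative_gm_call([0.19, 0.21], [0.06, 0.08])
        assert res.sample_mean == pytest.approx(0.2)
        assert res.cutoff == pytest.approx(0.17)
        assert res.positive

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            qualitative_gm_call([], [0.07])


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        res = compare_groups([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_mean_sem_convention(self):
        res = compare_groups([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.mean_a == pytest.approx(0.2)
        assert res.sem_a == pytest.approx(0.0577, abs=2e-4)

    def test_large_shift_always_detected(self):
        """5 pooled-SD shift at n=39 vs 11 rejects essentially always."""
        rng = np.random.default_rng(55)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            controls = rng.normal(0.03, 0.01, size=11)
            patients = rng.normal(0.03 + 5 * 0.01, 0.01, size=39)
            if compare_groups(patients, controls).p_value < 0.001:
                rejections += 1
        assert rejections >= 0.99 * n_rep

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([0.1], [0.2, 0.3])


class TestSgfStability:
    def test_nonGM_study_matrix_six_stable_six_partial(self):
        result = sgf_stability(band_matrices()["nonGM"])
        assert result.counts == {"stable": 6, "partial": 6, "digested": 0}
        assert sorted(result.stable_fractions()) == [10, 14, 19, 28, 38, 60]

    def test_all_fractions_gone_by_15_min(self):
        matrix = BandMatrix.from_codes(
            "x", [50.0, 30.0], ["ppfaaaa", "pffaaaa"]
        )
        result = sgf_stability(matrix)
        assert result.counts == {"stable": 0, "partial": 0, "digested": 2}
        assert all(c.last_seen <= 5 for c in result.calls)

    def test_random_matrices_agree_with_final_lane_oracle(self):
        for seed in range(10):
            matrix = make_band_matrix("x", 10, [0, 3, 7], seed=seed)
            result = sgf_stability(matrix)
            final = matrix.time_points[-1]
            for call in result.calls:
                state = matrix.presence.loc[call.fraction, final]
                expected = {
                    Presence.PRESENT: StabilityCall.STABLE,
                    Presence.FAINT: StabilityCall.PARTIAL,
                    Presence.ABSENT: StabilityCall.DIGESTED,
                }[state]
                assert call.call is expected

    def test_fraction_absent_at_time_zero_rejected(self):
        with pytest.raises(BandMatrixError):
            BandMatrix.from_codes("x", [50.0], ["appaaaa"])

    def test_band_matrix_tsv_round_trip(self, tmp_path):
        matrix = make_band_matrix("x", 8, [0, 1], seed=3)
        rows = []
        for kd in matrix.fractions:
            row = {"fraction": kd}
            for t in matrix.time_points:
                row[str(t)] = matrix.presence.loc[kd, t].value[0]
            rows.append(row)
        path = tmp_path / "m.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        back = read_band_matrix(path, extract="x")
        assert sgf_stability(back).counts == sgf_stability(matrix).counts


class TestImmunoblot:
    def test_study_cases_union_seven_identical_across_extracts(self):
        result = immunoblot_concordance(immunoblot_tables())
        assert set(result.per_extract_union) == set(EXTRACTS)
        for extract in EXTRACTS:
            assert result.union_size(extract) == 7
        assert result.shared == (28.0, 33.0, 41.0, 48.0, 68.0, 78.0, 88.0)

    def test_single_case_single_band(self):
        result = immunoblot_concordance(
            [ImmunoblotTable(case_id="c1", extract="e", bands=(41.0,))]
        )
        assert result.per_extract_union == {"e": (41.0,)}

    def test_duplicate_bands_across_cases_collapse(self):
        tables = [
            ImmunoblotTable(case_id="c1", extract="e", bands=(41.0, 48.0)),
            ImmunoblotTable(case_id="c2", extract="e", bands=(41.0, 48.0)),
        ]
        assert immunoblot_concordance(tables).per_extract_union["e"] == (41.0, 48.0)

    def test_union_never_shrinks_when_adding_a_case(self):
        rng = np.random.default_rng(77)
        tables = []
        prev = 0
        for i in range(8):
            bands = tuple(sorted(set(rng.integers(10, 100, size=3).astype(float))))
            tables.append(ImmunoblotTable(case_id=f"c{i}", extract="e", bands=bands))
            size = immunoblot_concordance(tables).union_size("e")
            assert size >= prev
            prev = size

    def test_blot_tsv_reader(self, tmp_path):
        path = tmp_path / "blot.tsv"
        path.write_text(
            "case\textract\tband_kd\nc1\te1\t41\nc1\te1\t48\nc2\te2\t41\n"
        )
        tables = read_immunoblot_tables(path)
        assert len(tables) == 2
        assert tables[0].bands == (41.0, 48.0)


class TestMatchBands:
    def test_greedy_nearest_matching(self):
        res = match_bands([28, 33, 41], [28, 31, 60], rel_tol=0.10)
        assert set(res.pairs) == {(28, 28), (33, 31)}
        assert res.unmatched_a == (41,)
        assert res.unmatched_b == (60,)

    def test_identical_sets_fully_matched(self):
        res = match_bands([28, 41, 88], [28, 41, 88], rel_tol=0.10)
        assert len(res.pairs) == 3
        assert res.unmatched_a == () and res.unmatched_b == ()

    def test_each_band_used_once(self):
        res = match_bands([40, 41], [40], rel_tol=0.10)
        assert len(res.pairs) == 1

    @pytest.mark.parametrize("tol", [0.0, 0.5, -0.1])
    def test_tolerance_bounds_enforced(self, tol):
        with pytest.raises(ValueError):
            match_bands([28], [28], rel_tol=tol)
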