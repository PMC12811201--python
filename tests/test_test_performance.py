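"""FIT characteristics: packaged table, decomposition, record recomputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gateopener.errors import DegenerateCountsError, UnsupportedCutoffError
from gateopener.test_performance import (
    FINDING_CATEGORIES,
    FITCharacteristics,
    FITRecord,
    GroupCounts,
    PerStateTestProfile,
    builtin_characteristics,
    characteristics_from_records,
    decompose_to_per_state,
    load_characteristics_table,
    read_fit_records,
    sensitivity_positivity_curve,
    supported_cutoffs,
    write_fit_records,
)


class TestBuiltinCharacteristics:
    @pytest.mark.parametrize(
        "cutoff, expected",
        [
            (17, (0.10, 0.196, 0.394, 0.907, 0.933)),
            (10, (0.15, 0.274, 0.485, 0.963, 0.889)),
            (8, (0.19, 0.321, 0.534, 0.981, 0.851)),
            (6, (0.29, 0.408, 0.595, 0.981, 0.747)),
            (4, (0.44, 0.545, 0.683, 0.981, 0.582)),
            (3, (0.51, 0.604, 0.727, 0.981, 0.511)),
        ],
    )
    def test_packaged_rows(self, cutoff, expected):
        row = builtin_characteristics(cutoff)
        got = (
            row.positivity,
            row.sens_any_neoplasm,
            row.sens_advanced_neoplasm,
            row.sens_preclinical_crc,
            row.spec_no_advanced,
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_unsupported_cutoff_raises(self):
        with pytest.raises(UnsupportedCutoffError):
            builtin_characteristics(5)

    def test_nesting_and_cutoff_monotonicity_of_packaged_table(self):
        rows = [builtin_characteristics(c) for c in supported_cutoffs()]
        for r in rows:
            assert (
                r.sens_preclinical_crc
                >= r.sens_advanced_neoplasm
                >= r.sens_any_neoplasm
            )
        for hi, lo in zip(rows, rows[1:]):  # sorted by decreasing cutoff
            assert lo.positivity >= hi.positivity
            assert lo.sens_any_neoplasm >= hi.sens_any_neoplasm
            assert lo.sens_advanced_neoplasm >= hi.sens_advanced_neoplasm
            assert lo.sens_preclinical_crc >= hi.sens_preclinical_crc
            assert lo.spec_no_advanced <= hi.spec_no_advanced

    def test_override_table(self, tmp_path):
        df = load_characteristics_table()
        df.loc[df["cutoff"] == 17, "positivity"] = 0.11
        path = tmp_path / "alt.csv"
        df.to_csv(path, index=False)
        alt = load_characteristics_table(path)
        assert builtin_characteristics(17, table=alt).positivity == 0.11


class TestGroupCounts:
    def test_reference_cohort_partition(self, blitz_counts):
        c = blitz_counts
        assert c.n_no_advanced + c.n_advanced_neoplasm == 7398
        assert c.n_no_neoplasm == 7398 - 2115 == 5283
        assert c.exclusive_counts().sum() == c.n_total

    def test_invalid_nesting_rejected(self):
        with pytest.raises(ValueError):
            GroupCounts(100, 10, 20, 5, 80)
        with pytest.raises(ValueError):
            GroupCounts(100, 10, 5, 2, 80)  # partition broken


class TestDecomposition:
    def test_reference_cohort_cutoff17(self, blitz_counts):
        """Hand-solved mixture arithmetic on the packaged cutoff-17 row."""
        profile = decompose_to_per_state(builtin_characteristics(17), blitz_counts)
        assert profile.p_pos_nonadvanced_adenoma == pytest.approx(0.092, abs=5e-4)
        assert profile.p_pos_advanced_adenoma == pytest.approx(0.353, abs=5e-4)
        assert profile.p_pos_no_neoplasm == pytest.approx(0.060, abs=5e-4)
        assert profile.p_pos_preclinical_crc == pytest.approx(0.907)

    def test_homogeneous_mixture_collapses(self, blitz_counts):
        s = 0.3
        agg = FITCharacteristics(10, s, s, s, s, 1 - s)
        profile = decompose_to_per_state(agg, blitz_counts)
        assert np.allclose(profile.as_array(), s)

    def test_degenerate_test_collapses_to_zero(self, blitz_counts):
        agg = FITCharacteristics(10, 0.0, 0.0, 0.0, 0.0, 1.0)
        profile = decompose_to_per_state(agg, blitz_counts)
        assert np.allclose(profile.as_array(), 0.0)

    def test_zero_subgroup_raises(self):
        counts = GroupCounts(100, 10, 10, 10, 90)  # no advanced adenomas
        with pytest.raises(DegenerateCountsError):
            decompose_to_per_state(
                FITCharacteristics(10, 0.2, 0.3, 0.4, 0.5, 0.9), counts
            )

    def test_inconsistent_aggregates_clamped_with_warning(self, blitz_counts):
        # any-neoplasm sensitivity far below advanced forces a negative solve
        agg = FITCharacteristics(10, 0.1, 0.05, 0.9, 0.95, 0.95)
        with pytest.warns(UserWarning, match="clamping"):
            profile = decompose_to_per_state(agg, blitz_counts)
        assert (profile.as_array() >= 0).all() and (profile.as_array() <= 1).all()

    @pytest.mark.parametrize("cutoff", [17, 10, 8, 6, 4, 3])
    def test_round_trip_within_half_point(self, blitz_counts, cutoff):
        agg = builtin_characteristics(cutoff)
        profile = decompose_to_per_state(agg, blitz_counts)
        back = profile.reaggregate(blitz_counts, cutoff)
        for field in (
            "positivity",
            "sens_any_neoplasm",
            "sens_advanced_neoplasm",
            "sens_preclinical_crc",
            "spec_no_advanced",
        ):
            assert getattr(back, field) == pytest.approx(
                getattr(agg, field), abs=0.005
            )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        probs=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=4
        ),
        counts=st.lists(st.integers(min_value=1, max_value=5000), min_size=4, max_size=4),
    )
    def test_profile_aggregate_decompose_is_identity(self, probs, counts):
        """Aggregating a per-state profile and decomposing again recovers it."""
        n_no, n_nonadv, n_adv, n_crc = counts
        gc = GroupCounts(
            n_total=sum(counts),
            n_any_neoplasm=n_nonadv + n_adv + n_crc,
            n_advanced_neoplasm=n_adv + n_crc,
            n_preclinical_crc=n_crc,
            n_no_advanced=n_no + n_nonadv,
        )
        profile = PerStateTestProfile(*probs)
        agg = profile.reaggregate(gc, cutoff=10)
        recovered = decompose_to_per_state(agg, gc)
        assert np.allclose(recovered.as_array(), profile.as_array(), atol=1e-9)


HAND_RECORDS = [
    # (hb_value, finding); tallied exhaustively in the oracle below
    (0.0, "no_neoplasm"),
    (2.1, "no_neoplasm"),
    (9.9, "no_neoplasm"),
    (25.0, "no_neoplasm"),
    (0.0, "nonadvanced_adenoma"),
    (10.0, "nonadvanced_adenoma"),
    (3.3, "advanced_adenoma"),
    (44.0, "advanced_adenoma"),
    (8.0, "preclinical_crc"),
    (120.0, "preclinical_crc"),
]


def _brute_force_tally(records, cutoff):
    """Independent exhaustive tally of the aggregate characteristics."""
    pos = [hb >= cutoff for hb, _ in records]
    n = len(records)

    def rate(group):
        hits = [p for p, (_, f) in zip(pos, records) if f in group]
        return sum(hits) / len(hits) if hits else float("nan")

    any_group = {"nonadvanced_adenoma", "advanced_adenoma", "preclinical_crc"}
    adv_group = {"advanced_adenoma", "preclinical_crc"}
    no_adv_group = {"no_neoplasm", "nonadvanced_adenoma"}
    return {
        "positivity": sum(pos) / n,
        "sens_any_neoplasm": rate(any_group),
        "sens_advanced_neoplasm": rate(adv_group),
        "sens_preclinical_crc": rate({"preclinical_crc"}),
        "spec_no_advanced": 1.0 - rate(no_adv_group),
    }


class TestCharacteristicsFromRecords:
    @pytest.mark.parametrize("cutoff", [0.0, 3, 8, 10, 17, 50, 1000])
    def test_matches_brute_force_tally(self, cutoff):
        records = [FITRecord(hb, f) for hb, f in HAND_RECORDS]
        got = characteristics_from_records(records, cutoff)
        expected = _brute_force_tally(HAND_RECORDS, cutoff)
        for field, value in expected.items():
            if np.isnan(value):
                assert np.isnan(getattr(got, field))
            else:
                assert getattr(got, field) == pytest.approx(value)

    def test_cutoff_zero_everything_positive(self):
        records = [FITRecord(hb, f) for hb, f in HAND_RECORDS]
        got = characteristics_from_records(records, 0.0)
        assert got.positivity == 1.0
        assert got.spec_no_advanced == 0.0

    def test_empty_diseased_subgroup_is_undefined_not_zero(self):
        records = [FITRecord(5.0, "no_neoplasm"), FITRecord(1.0, "no_neoplasm")]
        got = characteristics_from_records(records, 3.0)
        assert np.isnan(got.sens_preclinical_crc)
        assert np.isnan(got.sens_any_neoplasm)
        assert got.positivity == 0.5

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            characteristics_from_records([], 10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotonicity_in_cutoff(self, seed):
        """Lowering the cutoff never decreases positivity or sensitivities
        and never increases specificity, for arbitrary record sets."""
        rng = np.random.default_rng(seed)
        findings = rng.choice(FINDING_CATEGORIES, size=200)
        hb = rng.gamma(1.2, 8.0, size=200)
        df = pd.DataFrame({"hb_value": hb, "finding": findings})
        curve = sensitivity_positivity_curve(df, [40, 20, 10, 5, 2, 1])
        for col in (
            "positivity",
            "sens_any_neoplasm",
            "sens_advanced_neoplasm",
            "sens_preclinical_crc",
        ):
            assert (np.diff(curve[col]) >= -1e-12).all()
        assert (np.diff(curve["spec_no_advanced"]) <= 1e-12).all()


class TestCurve:
    def test_single_cutoff_matches_single_call(self):
        records = [FITRecord(hb, f) for hb, f in HAND_RECORDS]
        curve = sensitivity_positivity_curve(records, [8])
        single = characteristics_from_records(records, 8)
        assert curve.loc[0, "positivity"] == single.positivity
        assert curve.loc[0, "sens_advanced_neoplasm"] == single.sens_advanced_neoplasm

    def test_unsorted_input_sorted_with_notice(self, caplog):
        records = [FITRecord(hb, f) for hb, f in HAND_RECORDS]
        with caplog.at_level("INFO"):
            curve = sensitivity_positivity_curve(records, [3, 17, 8])
        assert list(curve["cutoff"]) == [17, 8, 3]
        assert any("sort" in r.message for r in caplog.records)

    def test_duplicate_cutoffs_duplicate_rows(self):
        records = [FITRecord(hb, f) for hb, f in HAND_RECORDS]
        curve = sensitivity_positivity_curve(records, [8, 8])
        assert len(curve) == 2
        assert curve.iloc[0].equals(curve.iloc[1])


class TestRecordIO:
    def test_csv_round_trip(self, tmp_path):
        records = [FITRecord(hb, f, sex="male", age=61) for hb, f in HAND_RECORDS]
        path = tmp_path / "records.csv"
        write_fit_records(records, path)
        df = read_fit_records(path)
        assert len(df) == len(records)
        assert characteristics_from_records(df, 8) == characteristics_from_records(
            records, 8
        )

    def test_unknown_finding_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {"hb_value": [1.0], "finding": ["polyp"], "sex": ["male"], "age": [60]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="finding"):
            read_fit_records(path)
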