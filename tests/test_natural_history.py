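"""Natural-history engine: initialisation, cycling, mortality, run_arm."""

import numpy as np
import pytest

from gateopener.errors import ParameterValidationError
from gateopener.natural_history import (
    NaturalHistoryParams,
    Scenario,
    advance_one_year,
    crc_death_probability,
    initialize_cohort,
    run_arm,
)

from conftest import make_params


class TestInitializeCohort:
    def test_degenerate_prevalence_all_in_first_state(self):
        params = make_params(prevalence=(1.0, 0.0, 0.0, 0.0))
        traj = initialize_cohort(params, 50, "male", 100_000)
        assert traj.occupancy[0, 0] == 100_000
        assert traj.occupancy[0, 1:].sum() == 0

    def test_expectation_mode_exact_proportional_split(self):
        prev = (0.7, 0.2, 0.08, 0.02)
        params = make_params(prevalence=prev)
        traj = initialize_cohort(params, 60, "female", 100_000)
        assert np.allclose(traj.occupancy[0, :4], np.array(prev) * 100_000)
        assert traj.cases_total == 0 and traj.deaths_total == 0
        assert traj.colonoscopies_total == 0 and traj.fits_total == 0

    def test_microsim_draw_within_binomial_noise(self):
        prev = np.array([0.7, 0.2, 0.08, 0.02])
        params = make_params(prevalence=tuple(prev))
        n = 100_000
        traj = initialize_cohort(params, 60, "male", n, mode="microsim", seed=11)
        sd = np.sqrt(n * prev * (1 - prev))
        assert (np.abs(traj.occupancy[0, :4] - n * prev) <= 4 * sd).all()

    def test_invalid_prevalence_sum_rejected(self):
        params = make_params(prevalence=(0.7, 0.2, 0.08, 0.02))
        bad = params.starting_prevalence.copy()
        bad.loc[bad["state"] == "no_neoplasm", "point"] = 0.6
        broken = NaturalHistoryParams(
            starting_prevalence=bad,
            transitions=params.transitions,
            other_cause_mortality=params.other_cause_mortality,
            case_fatality=params.case_fatality,
        )
        with pytest.raises(ParameterValidationError):
            initialize_cohort(broken, 60, "male", 1000)

    def test_microsim_requires_seed(self):
        params = make_params()
        with pytest.raises(ParameterValidationError, match="seed"):
            initialize_cohort(params, 60, "male", 100, mode="microsim")


class TestAdvanceOneYear:
    def test_all_rates_zero_is_identity(self):
        params = make_params(prevalence=(0.5, 0.3, 0.15, 0.05))
        traj = initialize_cohort(params, 60, "male", 10_000)
        advance_one_year(traj, params)
        assert np.allclose(traj.occupancy[1], traj.occupancy[0])

    def test_certain_other_cause_death_empties_alive_states(self):
        params = make_params(mortality=1.0, prevalence=(0.5, 0.3, 0.15, 0.05))
        traj = initialize_cohort(params, 60, "male", 10_000)
        advance_one_year(traj, params)
        assert traj.occupancy[1, 6] == pytest.approx(10_000)
        assert traj.occupancy[1, :6].sum() == pytest.approx(0.0)

    def test_three_year_occupancy_equals_matrix_power(self):
        """Expectation propagation must equal the independent linear-algebra
        oracle: occupancy after 3 years = v0 · M³ on the 5-state chain."""
        t = 0.1
        prev = np.array([0.7, 0.2, 0.08, 0.02])
        params = make_params(transitions=(t, t, t, t), prevalence=tuple(prev))
        traj = initialize_cohort(params, 60, "male", 100_000, horizon=3)
        for _ in range(3):
            advance_one_year(traj, params)
        M = np.array(
            [
                [1 - t, t, 0, 0, 0],
                [0, 1 - t, t, 0, 0],
                [0, 0, 1 - t, t, 0],
                [0, 0, 0, 1 - t, t],
                [0, 0, 0, 0, 1],
            ]
        )
        v0 = np.concatenate([prev * 100_000, [0.0]])
        expected = v0 @ np.linalg.matrix_power(M, 3)
        assert np.allclose(traj.occupancy[3, :5], expected)

    def test_probability_sum_validation_blocks_step(self):
        params = make_params(transitions=(0.6, 0.0, 0.0, 0.0), mortality=0.5)
        traj = initialize_cohort(params, 60, "male", 1000)
        with pytest.raises(ParameterValidationError, match="exceeds 1"):
            advance_one_year(traj, params)

    def test_advancing_past_horizon_rejected(self):
        params = make_params()
        traj = initialize_cohort(params, 60, "male", 100, horizon=1)
        advance_one_year(traj, params)
        with pytest.raises(ValueError, match="horizon"):
            advance_one_year(traj, params)

    def test_natural_diagnoses_are_symptom_detected(self):
        params = make_params(transitions=(0, 0, 0, 1.0), prevalence=(0, 0, 0, 1.0))
        traj = initialize_cohort(params, 60, "male", 1000)
        advance_one_year(traj, params)
        assert traj.clinical_detail[1, 1].sum() == pytest.approx(1000)  # symptom row
        assert traj.clinical_detail[1, 0].sum() == 0.0


class TestCaseFatality:
    def test_mode_equal_tables(self):
        params = make_params(cf_symptom=(0.2, 0.1), hazard_ratio=1.0)
        for y in (0, 1):
            assert crc_death_probability(y, "screen_detected", params) == (
                crc_death_probability(y, "symptom_detected", params)
            )

    def test_hazard_ratio_transform(self):
        """Screen-detected row equals the proportional-hazards transform
        1−(1−q)^HR of the symptom-detected row."""
        q = (0.2, 0.12, 0.05)
        params = make_params(cf_symptom=q, hazard_ratio=0.5)
        for y, qy in enumerate(q):
            assert crc_death_probability(y, "symptom_detected", params) == pytest.approx(qy)
            assert crc_death_probability(y, "screen_detected", params) == pytest.approx(
                1 - (1 - qy) ** 0.5
            )

    def test_flat_extrapolation_beyond_table(self):
        params = make_params(cf_symptom=(0.2, 0.1))
        assert crc_death_probability(25, "symptom_detected", params) == 0.1

    def test_screen_above_symptom_rejected_by_validation(self):
        params = make_params(cf_symptom=(0.2,), hazard_ratio=1.0)
        cf = params.case_fatality.copy()
        cf.loc[cf["mode"] == "screen_detected", "point"] = 0.5
        broken = NaturalHistoryParams(
            starting_prevalence=params.starting_prevalence,
            transitions=params.transitions,
            other_cause_mortality=params.other_cause_mortality,
            case_fatality=cf,
        )
        with pytest.raises(ParameterValidationError, match="screen-detected"):
            broken.validate()


class TestRunArm:
    def test_empty_disease_empty_outcomes(self):
        params = make_params(prevalence=(1.0, 0.0, 0.0, 0.0))
        traj = run_arm(params, Scenario(60, "male", 10_000), "no_screening")
        assert traj.cases_total == 0 and traj.deaths_total == 0

    def test_same_seed_bit_identical(self, default_params):
        scen = Scenario(60, "male", 20_000, mode="microsim", seed=99)
        a = run_arm(default_params, scen, "biennial_fit")
        b = run_arm(default_params, scen, "biennial_fit")
        assert np.array_equal(a.occupancy, b.occupancy)
        assert a.cases_total == b.cases_total
        assert a.colonoscopies_total == b.colonoscopies_total

    def test_conservation_every_cycle(self, default_params):
        for mode, seed in (("expectation", None), ("microsim", 5)):
            traj = run_arm(
                default_params,
                Scenario(60, "female", 50_000, mode=mode, seed=seed),
                "gateopener@6",
            )
            assert np.allclose(traj.occupancy.sum(axis=1), 50_000)

    def test_absorbing_death_states(self, default_params):
        traj = run_arm(
            default_params, Scenario(70, "male", 50_000, mode="microsim", seed=3),
            "biennial_fit",
        )
        assert (np.diff(traj.occupancy[:, 5]) >= 0).all()
        assert (np.diff(traj.occupancy[:, 6]) >= 0).all()

    def test_counters_non_decreasing(self, default_params):
        traj = run_arm(default_params, Scenario(60, "male"), "biennial_fit")
        for arr in (
            traj.cum_cases,
            traj.cum_deaths_crc,
            traj.cum_colonoscopies,
            traj.cum_fits,
        ):
            assert (np.diff(arr) >= -1e-9).all()

    def test_progression_dominance_without_screening(self):
        """Raising any progression rate never lowers 10-year incidence."""
        base = (0.01, 0.02, 0.03, 0.2)
        prev = (0.8, 0.12, 0.07, 0.01)
        low = make_params(transitions=base, prevalence=prev)
        ref = run_arm(low, Scenario(60, "male"), "no_screening").cases_total
        for i in range(4):
            raised = list(base)
            raised[i] *= 1.5
            hi = make_params(transitions=tuple(raised), prevalence=prev)
            assert run_arm(hi, Scenario(60, "male"), "no_screening").cases_total >= ref

    def test_screen_detection_mode_benefit(self):
        """With HR < 1, screen-detected diagnoses yield fewer cumulative CRC
        deaths than the same diagnoses detected by symptoms."""
        prev = (0.0, 0.0, 0.0, 1.0)
        sym = make_params(
            transitions=(0, 0, 0, 1.0), cf_symptom=(0.2, 0.15, 0.1),
            hazard_ratio=0.5, prevalence=prev,
        )
        natural = run_arm(sym, Scenario(60, "male", 10_000), "no_screening")
        from gateopener.strategies import AdherenceParams, ColonoscopyParams

        screened = run_arm(
            sym, Scenario(60, "male", 10_000), "colonoscopy_q10y",
            adherence=AdherenceParams(p_colonoscopy=1.0),
            colo_params=ColonoscopyParams(0.0, 0.0, 0.0),
        )
        assert screened.cases_total == pytest.approx(natural.cases_total)
        assert screened.deaths_total < natural.deaths_total

    def test_expectation_equals_mean_of_microsim_replicates(self, default_params):
        exp = run_arm(default_params, Scenario(60, "male", 50_000), "biennial_fit")
        cases = [
            run_arm(
                default_params,
                Scenario(60, "male", 50_000, mode="microsim", seed=200 + r),
                "biennial_fit",
            ).cases_total
            for r in range(20)
        ]
        se = np.std(cases, ddof=1) / np.sqrt(len(cases))
        assert abs(np.mean(cases) - exp.cases_total) <= 3 * se


class TestParamsIO:
    def test_yaml_round_trip(self, tmp_path, default_params):
        path = tmp_path / "params.yaml"
        default_params.to_yaml(path)
        loaded = NaturalHistoryParams.from_yaml(path)
        assert np.allclose(
            loaded.prevalence_vector(60, "male"),
            default_params.prevalence_vector(60, "male"),
        )
        assert loaded.transition_probability(
            "advanced_to_preclinical", 65, "female"
        ) == pytest.approx(
            default_params.transition_probability("advanced_to_preclinical", 65, "female")
        )

    def test_missing_section_reported(self, tmp_path):
        import yaml

        path = tmp_path / "bad.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump({"transitions": {}}, fh)
        with pytest.raises(ParameterValidationError):
            NaturalHistoryParams.from_yaml(path)

    def test_band_lookup_uses_containing_band(self, default_params):
        # single-year synthetic tables: ages between rows resolve to the row
        t64 = default_params.transition_probability("no_to_nonadvanced", 64, "male")
        t64_5 = default_params.transition_probability("no_to_nonadvanced", 64.5, "male")
        assert t64 == t64_5
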