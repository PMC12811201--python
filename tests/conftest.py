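import numpy as np
import pandas as pd
import pytest

from gateopener.natural_history import (
    DETECTION_MODES,
    NaturalHistoryParams,
    RateTable,
    SEXES,
    TRANSITION_NAMES,
)
from gateopener.synthetic import (
    calibrate_hb_model,
    derive_group_counts,
    generate_natural_history_params,
)
from gateopener.test_performance import builtin_characteristics, supported_cutoffs


def make_params(
    transitions=(0.0, 0.0, 0.0, 0.0),
    mortality=0.0,
    cf_symptom=(0.0,),
    hazard_ratio=1.0,
    prevalence=(1.0, 0.0, 0.0, 0.0),
    ages=(50, 90),
):
    """Constant-rate natural-history parameters with degenerate CIs,
    for hand-checkable toy scenarios."""
    from gateopener.test_performance import FINDING_CATEGORIES

    age_rows = [ages[0], ages[1]]

    def rate_rows(value):
        return pd.DataFrame(
            [
                {"age": a, "sex": sex, "point": value, "lower": value, "upper": value}
                for sex in SEXES
                for a in age_rows
            ]
        )

    prev_rows = []
    for sex in SEXES:
        for a in age_rows:
            for state, p in zip(FINDING_CATEGORIES, prevalence):
                prev_rows.append(
                    {"age": a, "sex": sex, "state": state,
                     "point": p, "lower": p, "upper": p}
                )

    cf_rows = []
    for y, q_sym in enumerate(cf_symptom):
        q_scr = q_sym if hazard_ratio == 1.0 else 1.0 - (1.0 - q_sym) ** hazard_ratio
        for mode, q in zip(DETECTION_MODES, (q_scr, q_sym)):
            cf_rows.append(
                {"years_since_dx": y, "mode": mode,
                 "point": q, "lower": q, "upper": q}
            )

    params = NaturalHistoryParams(
        starting_prevalence=pd.DataFrame(prev_rows),
        transitions={
            name: RateTable(rate_rows(t))
            for name, t in zip(TRANSITION_NAMES, transitions)
        },
        other_cause_mortality=RateTable(rate_rows(mortality)),
        case_fatality=pd.DataFrame(cf_rows),
    )
    params.validate()
    return params


@pytest.fixture(scope="session")
def blitz_counts():
    return derive_group_counts()


@pytest.fixture(scope="session")
def table1_targets():
    return [builtin_characteristics(c) for c in supported_cutoffs()]


@pytest.fixture(scope="session")
def calibrated_model(table1_targets, blitz_counts):
    return calibrate_hb_model(table1_targets, blitz_counts)


@pytest.fixture(scope="session")
def default_params():
    """The standard synthetic natural-history parameter set."""
    return generate_natural_history_params(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
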