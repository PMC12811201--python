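"""Discrete-time multistate natural-history engine for colorectal cancer.

The disease model follows the adenoma–carcinoma sequence as a chain of
annual-cycle states::

    no_neoplasm → nonadvanced_adenoma → advanced_adenoma → preclinical_crc
        → clinical_crc → dead_crc

with background (other-cause) mortality acting on every alive state and
colorectal-cancer case fatality acting on clinical cases as a function of
years since diagnosis and mode of detection (screen-detected cases carry
lower case fatality than symptom-detected ones, reflecting earlier stage at
diagnosis).  Progression is single-step: a person advances at most one state
per yearly cycle, and adenomas do not regress.

Within one cycle the event order is fixed as

1. screening events for the year (delegated to a strategy hook),
2. disease progression by one step (a natural preclinical→clinical
   transition records a *symptom-detected* diagnosis),
3. other-cause death applied to all alive states,
4. CRC death applied to clinical cases by ``case_fatality[years_since_dx,
   detection_mode]``,
5. years-since-diagnosis incremented.

Two execution modes share this logic exactly:

* ``expectation`` — cohort proportions are propagated deterministically;
  because every flow is linear in occupancy this is the exact mean of the
  microsimulation;
* ``microsim`` — each of the ``n`` individuals is simulated with seeded
  Bernoulli draws (vectorised; bit-reproducible for a fixed seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterValidationError

logger = logging.getLogger(__name__)

# Alive pre-diagnosis states (the "screening pool"), in chain order.  The
# ordering matches test_performance.FINDING_CATEGORIES.
STATE_NO_NEOPLASM = 0
STATE_NONADVANCED_ADENOMA = 1
STATE_ADVANCED_ADENOMA = 2
STATE_PRECLINICAL_CRC = 3
STATE_CLINICAL_CRC = 4
STATE_DEAD_CRC = 5
STATE_DEAD_OTHER = 6

STATE_NAMES = (
    "no_neoplasm",
    "nonadvanced_adenoma",
    "advanced_adenoma",
    "preclinical_crc",
    "clinical_crc",
    "dead_crc",
    "dead_other",
)

N_POOL_STATES = 4  # states eligible for screening
N_STATES = 7

MODE_SCREEN = 0
MODE_SYMPTOM = 1
DETECTION_MODES = ("screen_detected", "symptom_detected")

TRANSITION_NAMES = (
    "no_to_nonadvanced",
    "nonadvanced_to_advanced",
    "advanced_to_preclinical",
    "preclinical_to_clinical",
)

SEXES = ("female", "male")

#: Behaviour classes used to track repeated-round participation:
#: 0 = not (yet) enrolled, 1 = active participant, 2 = dropped out.
N_BEHAVIOR_CLASSES = 3

_BOUND_COLUMN = {"point": "point", "lower": "lower", "upper": "upper"}


class RateTable:
    """Age- and sex-indexed annual probability with 95% CI bounds.

    Rows give the lower edge of an age band (single-year tables are just
    one-year bands); lookup uses the band containing the requested age, with
    the last band extended upward.
    """

    REQUIRED = ("age", "sex", "point", "lower", "upper")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.REQUIRED) - set(frame.columns)
        if missing:
            raise ParameterValidationError(
                f"rate table lacks columns: {sorted(missing)}"
            )
        self._frame = frame[list(self.REQUIRED)].copy()
        self._by_sex: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for sex, sub in self._frame.groupby("sex"):
            sub = sub.sort_values("age")
            ages = sub["age"].to_numpy(dtype=float)
            if np.unique(ages).size != ages.size:
                raise ParameterValidationError(
                    f"duplicate age rows for sex={sex!r} in rate table"
                )
            values = sub[["point", "lower", "upper"]].to_numpy(dtype=float)
            self._by_sex[str(sex)] = (ages, values)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def sexes(self) -> tuple[str, ...]:
        return tuple(self._by_sex)

    def lookup(self, age: float, sex: str, bound: str = "point") -> float:
        try:
            ages, values = self._by_sex[sex]
        except KeyError:
            raise ParameterValidationError(
                f"no rates for sex={sex!r}; available: {sorted(self._by_sex)}"
            ) from None
        idx = int(np.searchsorted(ages, age, side="right")) - 1
        if idx < 0:
            raise ParameterValidationError(
                f"age {age} below first band ({ages[0]}) of rate table"
            )
        col = {"point": 0, "lower": 1, "upper": 2}[bound]
        return float(values[idx, col])


@dataclass
class NaturalHistoryParams:
    """Starting prevalences, transition probabilities, and mortality tables.

    ``starting_prevalence`` holds one row per (age band, sex, state) with
    point/lower/upper columns over the four pre-diagnosis states;
    ``transitions`` maps each chain transition name to a :class:`RateTable`;
    ``other_cause_mortality`` is a :class:`RateTable`; ``case_fatality``
    holds one row per (years_since_dx, detection mode) with point/lower/
    upper annual CRC death probabilities.
    """

    starting_prevalence: pd.DataFrame
    transitions: dict[str, RateTable]
    other_cause_mortality: RateTable
    case_fatality: pd.DataFrame
    _prevalence_tables: dict[str, RateTable] = field(default_factory=dict, repr=False)
    _cf_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        from .test_performance import FINDING_CATEGORIES

        need = {"age", "sex", "state", "point", "lower", "upper"}
        missing = need - set(self.starting_prevalence.columns)
        if missing:
            raise ParameterValidationError(
                f"starting_prevalence lacks columns: {sorted(missing)}"
            )
        bad_states = set(self.starting_prevalence["state"]) - set(FINDING_CATEGORIES)
        if bad_states:
            raise ParameterValidationError(
                f"unknown prevalence states: {sorted(bad_states)}"
            )
        missing_tr = set(TRANSITION_NAMES) - set(self.transitions)
        if missing_tr:
            raise ParameterValidationError(
                f"missing transition tables: {sorted(missing_tr)}"
            )
        for state in FINDING_CATEGORIES:
            sub = self.starting_prevalence[
                self.starting_prevalence["state"] == state
            ]
            self._prevalence_tables[state] = RateTable(sub)
        need_cf = {"years_since_dx", "mode", "point", "lower", "upper"}
        missing_cf = need_cf - set(self.case_fatality.columns)
        if missing_cf:
            raise ParameterValidationError(
                f"case_fatality lacks columns: {sorted(missing_cf)}"
            )

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        """Check probabilistic constraints; raise on violation."""
        for name, table in self.transitions.items():
            f = table.frame
            for col in ("point", "lower", "upper"):
                if not f[col].between(0.0, 1.0).all():
                    raise ParameterValidationError(
                        f"transition {name}: column {col} outside [0, 1]"
                    )
            if not ((f["lower"] <= f["point"]) & (f["point"] <= f["upper"])).all():
                raise ParameterValidationError(
                    f"transition {name}: CI bounds do not bracket point estimates"
                )
        f = self.other_cause_mortality.frame
        if not f["point"].between(0.0, 1.0).all():
            raise ParameterValidationError("other-cause mortality outside [0, 1]")

        prev = self.starting_prevalence
        for col in ("point", "lower", "upper"):
            if not prev[col].between(0.0, 1.0).all():
                raise ParameterValidationError(
                    f"starting prevalence column {col} outside [0, 1]"
                )
        sums = prev.groupby(["age", "sex"])["point"].sum()
        if not np.allclose(sums.to_numpy(), 1.0, atol=1e-9):
            raise ParameterValidationError(
                "starting prevalences do not sum to 1 within 1e-9 for every "
                "(age, sex)"
            )

        cf = self.case_fatality
        if not cf["point"].between(0.0, 1.0).all():
            raise ParameterValidationError("case fatality outside [0, 1]")
        wide = cf.pivot_table(index="years_since_dx", columns="mode", values="point")
        if set(DETECTION_MODES) - set(wide.columns):
            raise ParameterValidationError(
                f"case fatality must cover both modes {DETECTION_MODES}"
            )
        if not (wide["screen_detected"] <= wide["symptom_detected"] + 1e-12).all():
            raise ParameterValidationError(
                "screen-detected case fatality must not exceed symptom-detected"
            )

    # -- lookups --------------------------------------------------------

    def prevalence_vector(self, age: int, sex: str, bound: str = "point") -> np.ndarray:
        """Starting occupancy fractions over the four pool states.

        For CI-bound variants the lesion-state prevalences take the bound
        and the lesion-free fraction is set to the complement, so the vector
        always sums to 1.
        """
        from .test_performance import FINDING_CATEGORIES

        if bound == "point":
            return np.array(
                [
                    self._prevalence_tables[s].lookup(age, sex, "point")
                    for s in FINDING_CATEGORIES
                ]
            )
        lesions = np.array(
            [
                self._prevalence_tables[s].lookup(age, sex, bound)
                for s in FINDING_CATEGORIES[1:]
            ]
        )
        return np.concatenate([[1.0 - lesions.sum()], lesions])

    def transition_probability(
        self, name: str, age: float, sex: str, bound: str = "point"
    ) -> float:
        return self.transitions[name].lookup(age, sex, bound)

    def mortality(self, age: float, sex: str, bound: str = "point") -> float:
        return self.other_cause_mortality.lookup(age, sex, bound)

    def case_fatality_prob(self, years_since_dx: int, mode: str) -> float:
        """Annual CRC death probability; flat extrapolation beyond the table."""
        sub = self.case_fatality[self.case_fatality["mode"] == mode].sort_values(
            "years_since_dx"
        )
        if sub.empty:
            raise ParameterValidationError(f"no case-fatality rows for mode={mode!r}")
        years = sub["years_since_dx"].to_numpy()
        if years_since_dx > years[-1]:
            logger.info(
                "years_since_dx=%d beyond case-fatality table (max %d); "
                "using last row",
                years_since_dx,
                years[-1],
            )
            return float(sub["point"].iloc[-1])
        idx = int(np.searchsorted(years, years_since_dx, side="right")) - 1
        if idx < 0:
            raise ParameterValidationError("years_since_dx below table range")
        return float(sub["point"].iloc[idx])

    def case_fatality_matrix(self, max_years: int) -> np.ndarray:
        """(2, max_years+1) matrix of annual CRC death probabilities,
        rows ordered (screen_detected, symptom_detected)."""
        key = max_years
        if key not in self._cf_cache:
            self._cf_cache[key] = np.array(
                [
                    [self.case_fatality_prob(y, mode) for y in range(max_years + 1)]
                    for mode in DETECTION_MODES
                ]
            )
        return self._cf_cache[key]

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "starting_prevalence": self.starting_prevalence.to_dict("records"),
            "transitions": {
                name: table.frame.to_dict("records")
                for name, table in self.transitions.items()
            },
            "other_cause_mortality": self.other_cause_mortality.frame.to_dict(
                "records"
            ),
            "case_fatality": self.case_fatality.to_dict("records"),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_dict(cls, payload: dict) -> "NaturalHistoryParams":
        try:
            return cls(
                starting_prevalence=pd.DataFrame(payload["starting_prevalence"]),
                transitions={
                    name: RateTable(pd.DataFrame(rows))
                    for name, rows in payload["transitions"].items()
                },
                other_cause_mortality=RateTable(
                    pd.DataFrame(payload["other_cause_mortality"])
                ),
                case_fatality=pd.DataFrame(payload["case_fatality"]),
            )
        except KeyError as exc:
            raise ParameterValidationError(
                f"parameter file lacks section {exc}"
            ) from None

    @classmethod
    def from_yaml(cls, path) -> "NaturalHistoryParams":
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        params = cls.from_dict(payload)
        params.validate()
        return params


def crc_death_probability(
    years_since_dx: int, mode: str, params: NaturalHistoryParams
) -> float:
    """Annual CRC death probability by time since diagnosis and detection mode."""
    if years_since_dx < 0:
        raise ValueError("years_since_dx must be non-negative")
    if mode not in DETECTION_MODES:
        raise ValueError(f"mode must be one of {DETECTION_MODES}, got {mode!r}")
    return params.case_fatality_prob(years_since_dx, mode)


# ---------------------------------------------------------------------------
# Scenario and trajectory containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """One simulation arm's cohort definition."""

    age: int
    sex: str
    cohort_size: int = 100_000
    horizon_years: int = 10
    mode: str = "expectation"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.horizon_years < 0:
            raise ValueError("horizon_years must be >= 0")
        if self.mode not in ("expectation", "microsim"):
            raise ValueError("mode must be 'expectation' or 'microsim'")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class ScenarioMeta:
    """Metadata stamped onto a trajectory for comparisons and manifests."""

    strategy_label: str
    age: int
    sex: str
    n: int
    horizon: int
    mode: str
    seed: Optional[int]


class CohortTrajectory:
    """Year-by-year state occupancy and resource counters for one arm.

    ``occupancy[year]`` gives counts per top-level state (clinical CRC
    pooled); ``clinical_detail[year, mode, ysd]`` stratifies clinical cases
    by detection mode and years since diagnosis.  Cumulative counters are
    snapshots at the *end* of each yearly cycle (row 0 is baseline, before
    any event).  In expectation mode counts are fractional.
    """

    def __init__(self, meta: ScenarioMeta):
        self.meta = meta
        h = meta.horizon
        self.occupancy = np.zeros((h + 1, N_STATES))
        self.clinical_detail = np.zeros((h + 1, 2, h + 2))
        self.cum_cases = np.zeros(h + 1)
        self.cum_cases_screen = np.zeros(h + 1)
        self.cum_deaths_crc = np.zeros(h + 1)
        self.cum_colonoscopies = np.zeros(h + 1)
        self.cum_fits = np.zeros(h + 1)
        self.current_year = 0
        # live cumulative scalars (snapshotted by _record_row)
        self.cases_cum = 0.0
        self.cases_screen_cum = 0.0
        self.deaths_cum = 0.0
        self.colonoscopies_cum = 0.0
        self.fits_cum = 0.0
        # expectation-mode live state
        self.alive: Optional[np.ndarray] = None  # (classes, pool states)
        self.clinical: Optional[np.ndarray] = None  # (mode, ysd)
        self.dead_crc = 0.0
        self.dead_other = 0.0
        # microsim live state
        self.state: Optional[np.ndarray] = None
        self.ysd: Optional[np.ndarray] = None
        self.detect_mode: Optional[np.ndarray] = None
        self.behavior: Optional[np.ndarray] = None
        self.rng: Optional[np.random.Generator] = None

    # -- final outcomes -------------------------------------------------

    @property
    def cases_total(self) -> float:
        return float(self.cum_cases[self.current_year])

    @property
    def deaths_total(self) -> float:
        return float(self.cum_deaths_crc[self.current_year])

    @property
    def colonoscopies_total(self) -> float:
        return float(self.cum_colonoscopies[self.current_year])

    @property
    def fits_total(self) -> float:
        return float(self.cum_fits[self.current_year])

    def occupancy_sum(self, year: int) -> float:
        return float(self.occupancy[year].sum())

    def occupancy_frame(self) -> pd.DataFrame:
        """Tidy year × state occupancy table."""
        rows = []
        for year in range(self.current_year + 1):
            for s, name in enumerate(STATE_NAMES):
                rows.append({"year": year, "state": name, "count": self.occupancy[year, s]})
        return pd.DataFrame(rows)

    # -- recording ------------------------------------------------------

    def _record_row(self, year: int) -> None:
        if self.meta.mode == "expectation":
            occ = np.zeros(N_STATES)
            occ[:N_POOL_STATES] = self.alive.sum(axis=0)
            occ[STATE_CLINICAL_CRC] = self.clinical.sum()
            occ[STATE_DEAD_CRC] = self.dead_crc
            occ[STATE_DEAD_OTHER] = self.dead_other
            self.occupancy[year] = occ
            self.clinical_detail[year] = self.clinical
        else:
            self.occupancy[year] = np.bincount(self.state, minlength=N_STATES)
            for m in range(2):
                mask = (self.state == STATE_CLINICAL_CRC) & (self.detect_mode == m)
                if mask.any():
                    counts = np.bincount(
                        np.minimum(self.ysd[mask], self.meta.horizon + 1),
                        minlength=self.meta.horizon + 2,
                    )
                    self.clinical_detail[year, m] = counts
                else:
                    self.clinical_detail[year, m] = 0
        self.cum_cases[year] = self.cases_cum
        self.cum_cases_screen[year] = self.cases_screen_cum
        self.cum_deaths_crc[year] = self.deaths_cum
        self.cum_colonoscopies[year] = self.colonoscopies_cum
        self.cum_fits[year] = self.fits_cum


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


def initialize_cohort(
    params: NaturalHistoryParams,
    age: int,
    sex: str,
    n: int,
    *,
    strategy_label: str = "no_screening",
    mode: str = "expectation",
    horizon: int = 10,
    seed=None,
) -> CohortTrajectory:
    """Create a year-0 trajectory from the sex- and age-specific prevalences.

    Expectation mode splits the cohort proportionally; microsimulation mode
    draws each individual's baseline state (seed mandatory).  Nobody is
    clinically diagnosed or dead at baseline.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    prev = params.prevalence_vector(age, sex)
    if abs(prev.sum() - 1.0) > 1e-9:
        raise ParameterValidationError(
            f"starting prevalences for age={age}, sex={sex} sum to {prev.sum()!r}, "
            "not 1 within 1e-9"
        )
    meta = ScenarioMeta(
        strategy_label=strategy_label,
        age=age,
        sex=sex,
        n=n,
        horizon=horizon,
        mode=mode,
        seed=seed if isinstance(seed, int) or seed is None else None,
    )
    traj = CohortTrajectory(meta)
    if mode == "expectation":
        traj.alive = np.zeros((N_BEHAVIOR_CLASSES, N_POOL_STATES))
        traj.alive[0] = n * prev
        traj.clinical = np.zeros((2, horizon + 2))
    elif mode == "microsim":
        if seed is None:
            raise ParameterValidationError("seed is mandatory in microsim mode")
        traj.rng = np.random.default_rng(seed)
        traj.state = traj.rng.choice(N_POOL_STATES, size=n, p=prev).astype(np.int8)
        traj.ysd = np.zeros(n, dtype=np.int16)
        traj.detect_mode = np.full(n, -1, dtype=np.int8)
        traj.behavior = np.zeros(n, dtype=np.int8)
    else:
        raise ValueError("mode must be 'expectation' or 'microsim'")
    traj._record_row(0)
    return traj


def _validate_cycle(params: NaturalHistoryParams, age: float, sex: str, horizon: int) -> None:
    t = [params.transition_probability(nm, age, sex) for nm in TRANSITION_NAMES]
    m = params.mortality(age, sex)
    for nm, p in zip(TRANSITION_NAMES, t):
        if not 0.0 <= p <= 1.0:
            raise ParameterValidationError(f"{nm} at age {age} outside [0, 1]: {p}")
        if p + m > 1.0 + 1e-12:
            raise ParameterValidationError(
                f"outgoing probability sum for {nm} + other-cause mortality "
                f"exceeds 1 at age {age} ({p} + {m})"
            )
    if not 0.0 <= m <= 1.0:
        raise ParameterValidationError(f"mortality at age {age} outside [0, 1]: {m}")
    cf = params.case_fatality_matrix(horizon + 1)
    if (cf + m > 1.0 + 1e-12).any():
        raise ParameterValidationError(
            "clinical-state outgoing probability (case fatality + other-cause "
            f"mortality) exceeds 1 at age {age}"
        )


def _progress_expectation(traj: CohortTrajectory, params, age: float, sex: str) -> None:
    t1, t2, t3, t4 = (
        params.transition_probability(nm, age, sex) for nm in TRANSITION_NAMES
    )
    m = params.mortality(age, sex)
    alive = traj.alive
    # step 2: single-step chain progression (fluxes from pre-step occupancy)
    n0, n1, n2, n3 = alive[:, 0], alive[:, 1], alive[:, 2], alive[:, 3]
    symptom_flux = n3 * t4
    new = np.empty_like(alive)
    new[:, 0] = n0 * (1.0 - t1)
    new[:, 1] = n1 * (1.0 - t2) + n0 * t1
    new[:, 2] = n2 * (1.0 - t3) + n1 * t2
    new[:, 3] = n3 * (1.0 - t4) + n2 * t3
    alive[:] = new
    influx = float(symptom_flux.sum())
    traj.clinical[MODE_SYMPTOM, 0] += influx
    traj.cases_cum += influx
    # step 3: other-cause death on every alive state
    traj.dead_other += float(alive.sum() * m + traj.clinical.sum() * m)
    alive *= 1.0 - m
    traj.clinical *= 1.0 - m
    # step 4: CRC death by years since diagnosis and detection mode
    cf = params.case_fatality_matrix(traj.meta.horizon + 1)
    deaths = traj.clinical * cf
    traj.dead_crc += float(deaths.sum())
    traj.deaths_cum += float(deaths.sum())
    traj.clinical -= deaths
    # step 5: advance years since diagnosis (top bin absorbs overflow)
    shifted = np.zeros_like(traj.clinical)
    shifted[:, 1:] = traj.clinical[:, :-1]
    shifted[:, -1] += traj.clinical[:, -1]
    traj.clinical[:] = shifted


def _progress_microsim(traj: CohortTrajectory, params, age: float, sex: str) -> None:
    t1, t2, t3, t4 = (
        params.transition_probability(nm, age, sex) for nm in TRANSITION_NAMES
    )
    m = params.mortality(age, sex)
    rng = traj.rng
    state = traj.state
    n = state.size
    # step 2: progression
    u = rng.random(n)
    up1 = (state == STATE_NO_NEOPLASM) & (u < t1)
    up2 = (state == STATE_NONADVANCED_ADENOMA) & (u < t2)
    up3 = (state == STATE_ADVANCED_ADENOMA) & (u < t3)
    up4 = (state == STATE_PRECLINICAL_CRC) & (u < t4)
    state[up1] = STATE_NONADVANCED_ADENOMA
    state[up2] = STATE_ADVANCED_ADENOMA
    state[up3] = STATE_PRECLINICAL_CRC
    state[up4] = STATE_CLINICAL_CRC
    traj.detect_mode[up4] = MODE_SYMPTOM
    traj.ysd[up4] = 0
    traj.cases_cum += int(up4.sum())
    # step 3: other-cause death
    alive = state <= STATE_CLINICAL_CRC
    die_other = alive & (rng.random(n) < m)
    state[die_other] = STATE_DEAD_OTHER
    # step 4: CRC death
    clin = state == STATE_CLINICAL_CRC
    if clin.any():
        cf_matrix = params.case_fatality_matrix(traj.meta.horizon + 1)
        idx = np.flatnonzero(clin)
        ysd = np.minimum(traj.ysd[idx], traj.meta.horizon + 1)
        cf = cf_matrix[traj.detect_mode[idx], ysd]
        dead = idx[rng.random(idx.size) < cf]
        state[dead] = STATE_DEAD_CRC
        traj.deaths_cum += int(dead.size)
    # step 5: advance years since diagnosis
    traj.ysd[state == STATE_CLINICAL_CRC] += 1


StrategyHook = Callable[[CohortTrajectory, int], None]


def advance_one_year(
    trajectory: CohortTrajectory,
    params: NaturalHistoryParams,
    strategy_hook: Optional[StrategyHook] = None,
) -> CohortTrajectory:
    """Advance the cohort by one annual cycle (see module docstring for the
    within-cycle event order)."""
    meta = trajectory.meta
    year = trajectory.current_year
    if year >= meta.horizon:
        raise ValueError(f"trajectory already at horizon ({meta.horizon} years)")
    age_now = meta.age + year
    _validate_cycle(params, age_now, meta.sex, meta.horizon)
    if strategy_hook is not None:
        strategy_hook(trajectory, year)
    if meta.mode == "expectation":
        _progress_expectation(trajectory, params, age_now, meta.sex)
    else:
        _progress_microsim(trajectory, params, age_now, meta.sex)
    trajectory.current_year = year + 1
    trajectory._record_row(year + 1)
    return trajectory


def run_arm(
    params: NaturalHistoryParams,
    scenario: Scenario,
    strategy=None,
    adherence=None,
    profile=None,
    colo_params=None,
) -> CohortTrajectory:
    """Simulate one full arm: initialise, then run ``horizon_years`` cycles.

    ``strategy`` may be a :class:`~gateopener.strategies.Strategy`, a label
    string (e.g. ``"gateopener@6"``), or ``None`` for no screening.  A FIT
    profile is resolved from the packaged characteristics table when needed
    and not supplied.
    """
    from . import strategies as _strategies

    strat = _strategies.as_strategy(strategy)
    hook = _strategies.make_hook(strat, adherence, profile, colo_params)
    traj = initialize_cohort(
        params,
        scenario.age,
        scenario.sex,
        scenario.cohort_size,
        strategy_label=strat.label,
        mode=scenario.mode,
        horizon=scenario.horizon_years,
        seed=scenario.seed,
    )
    for _ in range(scenario.horizon_years):
        advance_one_year(traj, params, hook)
    return traj
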