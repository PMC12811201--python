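"""Synthetic inputs: calibrated FIT cohorts and natural-history parameters.

Two generators make the pipeline runnable without any external download:

* a *hemoglobin distribution model* — per finding category, a
  zero-inflated mixture of log-normal components for the quantitative fecal
  Hb value — calibrated so that thresholding the generated values at the
  packaged cutoffs reproduces the packaged diagnostic characteristics.
  Only the thresholded exceedance probabilities matter downstream, so the
  parametric family is a vehicle, not a claim about the true Hb
  distribution;

* a *natural-history parameter generator* producing a complete, schema-valid
  parameter set (starting prevalences, annual transition probabilities,
  other-cause mortality, case fatality by detection mode, each with 95% CI
  bounds) emulating a previously unscreened German screening-eligible
  population.  Defaults are fixed; see ``docs/methods.md`` for the rationale
  behind each value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, ndtr

from .errors import CalibrationError, ParameterValidationError
from .natural_history import (
    DETECTION_MODES,
    NaturalHistoryParams,
    RateTable,
    SEXES,
    TRANSITION_NAMES,
)
from .test_performance import (
    FINDING_CATEGORIES,
    FITCharacteristics,
    FITRecord,
    GroupCounts,
    decompose_to_per_state,
)

logger = logging.getLogger(__name__)

#: Assay limit of detection (μg Hb/g feces); generated values below it are
#: floored to 0 (undetectable).
LIMIT_OF_DETECTION = 1.7


def derive_group_counts() -> GroupCounts:
    """Diagnostic-group counts of the reference screening-colonoscopy cohort
    (7398 participants with pre-colonoscopy quantitative FITs)."""
    return GroupCounts(
        n_total=7398,
        n_any_neoplasm=2115,
        n_advanced_neoplasm=728,
        n_preclinical_crc=54,
        n_no_advanced=6670,
    )


# ---------------------------------------------------------------------------
# Hemoglobin distribution model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HbDistributionModel:
    """Zero-inflated log-normal mixture of fecal Hb per finding category.

    For state *s*, a value is 0 (undetectable) with probability
    ``zero_mass[s]``; otherwise it is drawn from a two-component log-normal
    mixture with weights ``weights[s]``, log-means ``mu[s]`` and log-SDs
    ``sigma[s]``.  ``state_weights`` are the mixture proportions of the four
    categories in the emulated cohort.
    """

    mu: np.ndarray  # (4, k)
    sigma: np.ndarray  # (4, k)
    weights: np.ndarray  # (4, k), rows sum to 1
    zero_mass: np.ndarray  # (4,)
    state_weights: np.ndarray  # (4,), sums to 1

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            raise ValueError("component weights must sum to 1 per state")
        if np.any((self.zero_mass < 0) | (self.zero_mass >= 1)):
            raise ValueError("zero_mass must lie in [0, 1)")
        if not np.isclose(self.state_weights.sum(), 1.0):
            raise ValueError("state mixture weights must sum to 1")

    def p_positive(self, state: int | str, cutoff: float) -> float:
        """P(Hb ≥ cutoff | state)."""
        s = FINDING_CATEGORIES.index(state) if isinstance(state, str) else int(state)
        z = (self.mu[s] - np.log(cutoff)) / self.sigma[s]
        return float((1.0 - self.zero_mass[s]) * np.dot(self.weights[s], ndtr(z)))

    def profile_array(self, cutoff: float) -> np.ndarray:
        return np.array([self.p_positive(s, cutoff) for s in range(4)])

    def implied_characteristics(
        self, cutoff: float, counts: GroupCounts
    ) -> FITCharacteristics:
        """Aggregate characteristics implied by the model at one cutoff."""
        from .test_performance import PerStateTestProfile

        return PerStateTestProfile(*self.profile_array(cutoff)).reaggregate(
            counts, cutoff
        )


def _mixture_exceedance(theta: np.ndarray, log_cutoffs: np.ndarray) -> np.ndarray:
    """Exceedance probabilities of one state's zero-inflated 2-component
    log-normal mixture, in an unconstrained parametrisation."""
    w = expit(theta[0])
    mu1, mu2 = theta[1], theta[3]
    s1, s2 = np.exp(theta[2]), np.exp(theta[4])
    pi0 = expit(theta[5])
    surv = w * ndtr((mu1 - log_cutoffs) / s1) + (1.0 - w) * ndtr(
        (mu2 - log_cutoffs) / s2
    )
    return (1.0 - pi0) * surv


def _fit_state_distribution(
    cutoffs: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares fit of one state's exceedance curve at the calibration
    cutoffs.  Several fixed starting points; deterministic."""
    log_c = np.log(cutoffs)

    def residuals(theta):
        return _mixture_exceedance(theta, log_c) - targets

    qmax = float(targets.max())
    anchor = float(np.interp(0.5 * qmax, targets[::-1], log_c[::-1]))
    pi_plateau = logit(np.clip(1.0 - qmax, 1e-4, 0.99))  # zero mass if the
    # exceedance curve plateaus below 1 at the lowest cutoffs
    starts = []
    for spread in (0.6, 1.2):
        for pi_logit in (-7.0, pi_plateau):
            starts.append(
                np.array([0.0, anchor + spread, np.log(spread), anchor - spread,
                          np.log(spread), pi_logit])
            )
    # degenerate single-component starts centred above the cutoff grid
    starts.append(np.array([3.0, log_c.max() + 1.0, 0.0, anchor, 0.0, pi_plateau]))
    starts.append(np.array([3.0, log_c.max() + 1.0, 0.0, anchor, 0.0, -7.0]))
    lower = np.array([-8.0, -5.0, -3.0, -5.0, -3.0, -9.5])
    upper = np.array([8.0, 9.0, 2.0, 9.0, 2.0, 8.0])
    best = None
    for x0 in starts:
        sol = optimize.least_squares(
            residuals,
            np.clip(x0, lower + 1e-6, upper - 1e-6),
            bounds=(lower, upper),
            method="trf",
            max_nfev=4000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return best.x, float(np.abs(residuals(best.x)).max())


def calibrate_hb_model(
    targets: Sequence[FITCharacteristics],
    counts: GroupCounts,
    tol: float = 0.02,
    seed: Optional[int] = None,
) -> HbDistributionModel:
    """Fit the per-state Hb model to aggregate characteristics at ≥3 cutoffs.

    Aggregates are first decomposed into per-state positive probabilities at
    every target cutoff; each state's exceedance curve is then fitted by
    least squares.  The fit is deterministic (``seed`` is accepted for
    interface symmetry but unused).  Raises
    :class:`~gateopener.errors.CalibrationError` carrying the achieved
    deviations when any implied aggregate misses its target by more than
    ``tol`` at any cutoff.
    """
    targets = sorted(targets, key=lambda t: -t.cutoff)
    if len(targets) < 3:
        raise ValueError("calibration needs at least 3 target cutoffs")
    cutoffs = np.array([t.cutoff for t in targets])
    per_state = np.array(
        [decompose_to_per_state(t, counts).as_array() for t in targets]
    )  # (n_cutoffs, 4)

    mu = np.zeros((4, 2))
    sigma = np.zeros((4, 2))
    weights = np.zeros((4, 2))
    zero_mass = np.zeros(4)
    for s in range(4):
        theta, _ = _fit_state_distribution(cutoffs, per_state[:, s])
        w = float(expit(theta[0]))
        weights[s] = (w, 1.0 - w)
        mu[s] = (theta[1], theta[3])
        sigma[s] = (np.exp(theta[2]), np.exp(theta[4]))
        zero_mass[s] = float(expit(theta[5]))

    model = HbDistributionModel(
        mu=mu,
        sigma=sigma,
        weights=weights,
        zero_mass=zero_mass,
        state_weights=counts.exclusive_counts() / counts.n_total,
    )

    deviations = {}
    fields_ = (
        "positivity",
        "sens_any_neoplasm",
        "sens_advanced_neoplasm",
        "sens_preclinical_crc",
        "spec_no_advanced",
    )
    for t in targets:
        implied = model.implied_characteristics(t.cutoff, counts)
        for name in fields_:
            deviations[(t.cutoff, name)] = getattr(implied, name) - getattr(t, name)
    worst = max(abs(v) for v in deviations.values())
    if worst > tol:
        raise CalibrationError(
            f"calibration missed targets: worst deviation {worst:.4f} > tol {tol}",
            deviations=deviations,
        )
    return model


def generate_fit_cohort(
    model: HbDistributionModel, n: int, seed: int
) -> list[FITRecord]:
    """Draw a reproducible synthetic FIT-record cohort from the model.

    States follow the model's mixture weights; Hb values follow the
    per-state zero-inflated log-normal mixtures, with values below the
    assay limit of detection floored to 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    states = rng.choice(4, size=n, p=model.state_weights)
    hb = np.zeros(n)
    comp_u = rng.random(n)
    zero_u = rng.random(n)
    normals = rng.standard_normal(n)
    for s in range(4):
        mask = states == s
        comp = (comp_u[mask] > model.weights[s, 0]).astype(int)
        values = np.exp(model.mu[s, comp] + model.sigma[s, comp] * normals[mask])
        values[zero_u[mask] < model.zero_mass[s]] = 0.0
        hb[mask] = values
    hb[hb < LIMIT_OF_DETECTION] = 0.0
    sexes = rng.choice(np.array(SEXES), size=n)
    ages = rng.integers(50, 80, size=n)
    return [
        FITRecord(
            hb_value=float(hb[i]),
            finding=FINDING_CATEGORIES[states[i]],
            sex=str(sexes[i]),
            age=int(ages[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Natural-history parameter generator
# ---------------------------------------------------------------------------


def _rng_range(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo > hi:
        raise ParameterValidationError(f"inverted range ({lo}, {hi})")
    if lo == hi:
        return lo
    return float(lo + rng.random() * (hi - lo))


@dataclass(frozen=True)
class SyntheticParamSpec:
    """Ranges for drawing a natural-history parameter set.

    Each ``*_base`` range is the annual probability (or prevalence) for a
    50-year-old man; female values are scaled by ``sex_multiplier_female``
    and age dependence is log-linear with the given per-year slope.  Ranges
    of zero width make the generated set fully deterministic.
    """

    ages: tuple[int, int] = (50, 85)
    # annual transition probability at age 50, men: (lo, hi)
    no_to_nonadvanced_base: tuple[float, float] = (0.011, 0.013)
    nonadvanced_to_advanced_base: tuple[float, float] = (0.014, 0.016)
    advanced_to_preclinical_base: tuple[float, float] = (0.028, 0.032)
    preclinical_to_clinical_base: tuple[float, float] = (0.21, 0.23)
    # log-linear age slopes per year, per transition
    transition_age_slopes: tuple[float, float, float, float] = (0.02, 0.02, 0.015, 0.0)
    sex_multiplier_female: tuple[float, float] = (0.75, 0.85)
    # baseline prevalence at age 50, men
    prev_nonadvanced_base: tuple[float, float] = (0.13, 0.15)
    prev_advanced_base: tuple[float, float] = (0.045, 0.055)
    prev_preclinical_base: tuple[float, float] = (0.0018, 0.0022)
    # per-decade multiplicative growth of the three lesion prevalences
    prev_decade_growth: tuple[float, float, float] = (1.25, 1.45, 2.0)
    # other-cause mortality: annual probability at 50 and log-linear slope
    mortality_base_male: tuple[float, float] = (0.0038, 0.0042)
    mortality_female_factor: float = 0.65
    mortality_age_slope: float = 0.085
    # CRC case fatality: first-year annual probability (symptom-detected),
    # geometric decline per year since diagnosis, screen-vs-symptom hazard ratio
    case_fatality_year0: tuple[float, float] = (0.11, 0.13)
    case_fatality_decline: float = 0.85
    case_fatality_years: int = 10
    screen_detection_hazard_ratio: tuple[float, float] = (0.45, 0.55)
    # relative 95% CI half-widths
    ci_halfwidth_transitions: float = 0.15
    ci_halfwidth_prevalence: float = 0.10

    def validate(self) -> None:
        for name in (
            "no_to_nonadvanced_base",
            "nonadvanced_to_advanced_base",
            "advanced_to_preclinical_base",
            "preclinical_to_clinical_base",
            "sex_multiplier_female",
            "prev_nonadvanced_base",
            "prev_advanced_base",
            "prev_preclinical_base",
            "mortality_base_male",
            "case_fatality_year0",
            "screen_detection_hazard_ratio",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterValidationError(f"{name}: inverted range ({lo}, {hi})")
            if lo < 0:
                raise ParameterValidationError(f"{name}: negative lower bound")


def generate_natural_history_params(
    spec: Optional[SyntheticParamSpec] = None, seed: int = 0
) -> NaturalHistoryParams:
    """Draw a complete, validated natural-history parameter set.

    Transition rates rise log-linearly with age, women carry lower lesion
    rates than men, and CI bounds bracket every point estimate (degenerate
    bounds for mortality and case fatality, whose uncertainty is not
    perturbed in sensitivity analyses).
    """
    spec = spec or SyntheticParamSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    bases = {
        name: _rng_range(rng, *getattr(spec, f"{name}_base"))
        for name in TRANSITION_NAMES
    }
    sex_mult = {"male": 1.0, "female": _rng_range(rng, *spec.sex_multiplier_female)}
    prev_bases = (
        _rng_range(rng, *spec.prev_nonadvanced_base),
        _rng_range(rng, *spec.prev_advanced_base),
        _rng_range(rng, *spec.prev_preclinical_base),
    )
    mort_base = _rng_range(rng, *spec.mortality_base_male)
    cf0 = _rng_range(rng, *spec.case_fatality_year0)
    hr = _rng_range(rng, *spec.screen_detection_hazard_ratio)

    ages = np.arange(spec.ages[0], spec.ages[1] + 1)
    hw_t = spec.ci_halfwidth_transitions
    hw_p = spec.ci_halfwidth_prevalence

    transitions = {}
    for name, slope in zip(TRANSITION_NAMES, spec.transition_age_slopes):
        rows = []
        for sex in SEXES:
            point = np.minimum(
                bases[name] * sex_mult[sex] * np.exp(slope * (ages - 50)), 0.95
            )
            for age, p in zip(ages, point):
                rows.append(
                    {
                        "age": int(age),
                        "sex": sex,
                        "point": float(p),
                        "lower": float(p * (1 - hw_t)),
                        "upper": float(min(p * (1 + hw_t), 1.0)),
                    }
                )
        transitions[name] = RateTable(pd.DataFrame(rows))

    prev_rows = []
    for sex in SEXES:
        for age in ages:
            lesions = np.array(
                [
                    base
                    * sex_mult[sex]
                    * growth ** ((age - 50) / 10.0)
                    for base, growth in zip(prev_bases, spec.prev_decade_growth)
                ]
            )
            total = lesions.sum()
            if total > 0.6:  # keep the lesion-free majority plausible
                lesions *= 0.6 / total
            lower = lesions * (1 - hw_p)
            upper = np.minimum(lesions * (1 + hw_p), 1.0)
            prev_rows.append(
                {
                    "age": int(age),
                    "sex": sex,
                    "state": "no_neoplasm",
                    "point": float(1.0 - lesions.sum()),
                    "lower": float(1.0 - upper.sum()),
                    "upper": float(1.0 - lower.sum()),
                }
            )
            for state, p, lo, up in zip(FINDING_CATEGORIES[1:], lesions, lower, upper):
                prev_rows.append(
                    {
                        "age": int(age),
                        "sex": sex,
                        "state": state,
                        "point": float(p),
                        "lower": float(lo),
                        "upper": float(up),
                    }
                )

    mort_rows = []
    for sex in SEXES:
        factor = 1.0 if sex == "male" else spec.mortality_female_factor
        point = np.minimum(
            mort_base * factor * np.exp(spec.mortality_age_slope * (ages - 50)), 0.95
        )
        for age, p in zip(ages, point):
            mort_rows.append(
                {
                    "age": int(age),
                    "sex": sex,
                    "point": float(p),
                    "lower": float(p),
                    "upper": float(p),
                }
            )

    cf_rows = []
    for y in range(spec.case_fatality_years):
        q_sym = cf0 * spec.case_fatality_decline**y
        q_scr = 1.0 - (1.0 - q_sym) ** hr  # proportional-hazards transform
        for mode, q in zip(DETECTION_MODES, (q_scr, q_sym)):
            cf_rows.append(
                {
                    "years_since_dx": y,
                    "mode": mode,
                    "point": float(q),
                    "lower": float(q),
                    "upper": float(q),
                }
            )

    params = NaturalHistoryParams(
        starting_prevalence=pd.DataFrame(prev_rows),
        transitions=transitions,
        other_cause_mortality=RateTable(pd.DataFrame(mort_rows)),
        case_fatality=pd.DataFrame(cf_rows),
    )
    params.validate()
    return params


def perturb_to_ci_bound(
    params: NaturalHistoryParams, which: str
) -> NaturalHistoryParams:
    """Replace every point estimate by its lower or upper 95% CI bound.

    Lesion-state starting prevalences take the bound and the lesion-free
    prevalence is set to the complement so the vector still sums to 1.
    Raises when any required bound is missing (NaN), listing the offenders.
    """
    if which not in ("lower", "upper"):
        raise ValueError("which must be 'lower' or 'upper'")

    offenders = []

    def _swap_rate_table(name: str, table: RateTable) -> RateTable:
        f = table.frame
        if f[which].isna().any():
            offenders.append(name)
            return table
        f = f.assign(point=f[which])
        return RateTable(f)

    new_transitions = {
        name: _swap_rate_table(f"transitions.{name}", table)
        for name, table in params.transitions.items()
    }
    new_mortality = _swap_rate_table(
        "other_cause_mortality", params.other_cause_mortality
    )

    prev = params.starting_prevalence.copy()
    if prev[which].isna().any():
        offenders.append("starting_prevalence")
    else:
        lesion = prev["state"] != "no_neoplasm"
        prev.loc[lesion, "point"] = prev.loc[lesion, which]
        lesion_sums = (
            prev[lesion].groupby(["age", "sex"])["point"].sum().rename("lesion_sum")
        )
        prev = prev.merge(lesion_sums, on=["age", "sex"], how="left")
        free = prev["state"] == "no_neoplasm"
        prev.loc[free, "point"] = 1.0 - prev.loc[free, "lesion_sum"]
        prev = prev.drop(columns="lesion_sum")

    cf = params.case_fatality.copy()
    if cf[which].isna().any():
        offenders.append("case_fatality")
    else:
        cf["point"] = cf[which]

    if offenders:
        raise ParameterValidationError(
            f"missing {which} CI bounds in: {offenders}"
        )
    return NaturalHistoryParams(
        starting_prevalence=prev,
        transitions=new_transitions,
        other_cause_mortality=new_mortality,
        case_fatality=cf,
    )
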