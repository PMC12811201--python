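"""Screening strategies, adherence dynamics, and colonoscopy effects.

Four policies are modelled:

* ``no_screening`` — the reference arm;
* ``colonoscopy_q10y`` — screening colonoscopy offered in 10-year
  intervals (within a 10-year horizon: once, at year 0), used by a fraction
  ``p_colonoscopy`` of invitees;
* ``biennial_fit`` — a FIT at the manufacturer preset cutoff of 17 μg/g
  every two years; first-round uptake ``p_fit_first``, with permanent
  drop-out between rounds;
* ``gateopener`` — a single low-cutoff FIT offered in 10-year intervals;
  only persons at or above the cutoff are invited to follow-up colonoscopy.

For any FIT-bearing strategy, a positive test leads to diagnostic
colonoscopy with compliance ``p_diag_colonoscopy``; the colonoscopy acts on
the *true* underlying state (so a false-positive FIT still removes
incidentally present adenomas), removes adenomas (subject to miss rates),
and converts preclinical cancer to screen-detected clinical cancer.

Drop-out mechanics: a participant of one biennial round takes part in the
next round with probability ``1 - dropout``; drop-out is absorbing, and
persons who declined the first offer never enrol later.  With the default
50% first-round uptake and 40% drop-out this yields round participations of
50%, 30%, 18%, 10.8%, 6.5% — a mean biennial participation of roughly 20%
and less than half the FIT kit usage of a program with sustained uptake,
matching observed German biennial participation.  See ``docs/methods.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ContractViolationError
from .natural_history import (
    CohortTrajectory,
    MODE_SCREEN,
    N_POOL_STATES,
    STATE_ADVANCED_ADENOMA,
    STATE_CLINICAL_CRC,
    STATE_NO_NEOPLASM,
    STATE_NONADVANCED_ADENOMA,
    STATE_PRECLINICAL_CRC,
    STATE_NAMES,
)
from .test_performance import PerStateTestProfile

logger = logging.getLogger(__name__)

STRATEGY_KINDS = ("no_screening", "colonoscopy_q10y", "biennial_fit", "gateopener")

#: Cutoffs with packaged FIT characteristics, available to the gateopener.
GATEOPENER_CUTOFFS = (17.0, 10.0, 8.0, 6.0, 4.0, 3.0)

BIENNIAL_FIT_CUTOFF = 17.0


@dataclass(frozen=True)
class Strategy:
    """A screening policy plus, for FIT-bearing policies, its Hb cutoff."""

    kind: str
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ConfigurationError(
                f"unknown strategy kind {self.kind!r}; expected one of {STRATEGY_KINDS}"
            )
        if self.kind == "biennial_fit":
            if self.cutoff is None:
                object.__setattr__(self, "cutoff", BIENNIAL_FIT_CUTOFF)
            elif float(self.cutoff) != BIENNIAL_FIT_CUTOFF:
                raise ConfigurationError(
                    "biennial FIT uses the manufacturer preset cutoff of "
                    f"{BIENNIAL_FIT_CUTOFF:g} μg/g"
                )
        elif self.kind == "gateopener":
            if self.cutoff is None or self.cutoff <= 0:
                raise ConfigurationError("gateopener requires a positive Hb cutoff")
        elif self.cutoff is not None:
            raise ConfigurationError(f"{self.kind} takes no cutoff")

    @property
    def uses_fit(self) -> bool:
        return self.kind in ("biennial_fit", "gateopener")

    @property
    def label(self) -> str:
        if self.kind == "gateopener":
            return f"gateopener@{self.cutoff:g}"
        return self.kind


def as_strategy(obj) -> Strategy:
    """Coerce ``None``, a label string, or a Strategy into a Strategy."""
    if obj is None:
        return Strategy("no_screening")
    if isinstance(obj, Strategy):
        return obj
    if isinstance(obj, str):
        if "@" in obj:
            kind, _, cut = obj.partition("@")
            return Strategy(kind, float(cut))
        return Strategy(obj)
    raise ConfigurationError(f"cannot interpret {obj!r} as a strategy")


@dataclass(frozen=True)
class AdherenceParams:
    """Participation behaviour of the invited population.

    ``p_colonoscopy``: use of the 10-yearly screening colonoscopy offer;
    ``p_fit_first``: first-offer FIT participation (biennial and gateopener);
    ``dropout``: between-round drop-out fraction for biennial FIT;
    ``p_diag_colonoscopy``: compliance with colonoscopy after a positive FIT.
    """

    p_colonoscopy: float = 0.15
    p_fit_first: float = 0.50
    dropout: float = 0.40
    p_diag_colonoscopy: float = 0.80

    def __post_init__(self) -> None:
        for name in ("p_colonoscopy", "p_fit_first", "dropout", "p_diag_colonoscopy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")

    def with_overrides(self, **kwargs) -> "AdherenceParams":
        return replace(self, **kwargs)


#: Named adherence presets for sensitivity analyses.
ADHERENCE_OVERLAYS = {
    "base": {},
    "adherence60": {"p_fit_first": 0.60},
    "dropout30": {"dropout": 0.30},
}


@dataclass(frozen=True)
class ColonoscopyParams:
    """Per-lesion miss probabilities of colonoscopy.

    Defaults approximate meta-analytic miss rates: small/non-advanced
    adenomas are missed far more often than advanced adenomas, and
    preclinical cancers are missed least often.
    """

    miss_nonadvanced: float = 0.26
    miss_advanced: float = 0.09
    miss_preclinical_crc: float = 0.05

    def __post_init__(self) -> None:
        for name in ("miss_nonadvanced", "miss_advanced", "miss_preclinical_crc"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v!r}")
        if self.miss_preclinical_crc > min(self.miss_nonadvanced, self.miss_advanced):
            raise ConfigurationError(
                "preclinical CRC miss rate must not exceed adenoma miss rates"
            )


DEFAULT_ADHERENCE = AdherenceParams()
DEFAULT_COLONOSCOPY = ColonoscopyParams()


def default_profile(cutoff: float) -> PerStateTestProfile:
    """Per-state FIT profile decomposed from the packaged characteristics
    at one of the supported cutoffs."""
    from .synthetic import derive_group_counts
    from .test_performance import builtin_characteristics, decompose_to_per_state

    return decompose_to_per_state(builtin_characteristics(cutoff), derive_group_counts())


# ---------------------------------------------------------------------------
# Scheduling and participation
# ---------------------------------------------------------------------------


def schedule_offers(strategy: Strategy, horizon_years: int = 10) -> list[int]:
    """Years (0-based cycle indices) at which the strategy makes an offer."""
    if horizon_years < 0:
        raise ValueError("horizon_years must be >= 0")
    strategy = as_strategy(strategy)
    if strategy.kind == "no_screening":
        return []
    if strategy.kind in ("colonoscopy_q10y", "gateopener"):
        return list(range(0, horizon_years, 10))
    return list(range(0, horizon_years, 2))  # biennial_fit


def per_round_retention(adherence: AdherenceParams) -> float:
    """Probability that a biennial-round participant returns next round."""
    return 1.0 - adherence.dropout


@dataclass
class ParticipationHistory:
    """Mutable per-person record of enrolment across repeated offers."""

    enrolled: bool = False
    dropped: bool = False


def participation(
    round_index: int,
    strategy: Strategy,
    adherence: AdherenceParams,
    participant_history: ParticipationHistory,
    rng: np.random.Generator,
) -> bool:
    """Decide one person's participation in one offer round.

    Colonoscopy offers are accepted with ``p_colonoscopy``.  FIT-bearing
    first offers are accepted with ``p_fit_first``.  For later biennial
    rounds, prior participants return with probability ``1 - dropout`` per
    round; drop-out and first-offer refusal are absorbing.
    The history object is updated in place.
    """
    strategy = as_strategy(strategy)
    if strategy.kind == "no_screening":
        return False
    if strategy.kind == "colonoscopy_q10y":
        return bool(rng.random() < adherence.p_colonoscopy)
    if round_index == 0:
        take = bool(rng.random() < adherence.p_fit_first)
        participant_history.enrolled = take
        return take
    if strategy.kind == "gateopener":
        # single offer per 10-year horizon; later rounds only arise with
        # longer horizons and are treated as fresh offers
        return bool(rng.random() < adherence.p_fit_first)
    if not participant_history.enrolled or participant_history.dropped:
        return False
    stay = bool(rng.random() < per_round_retention(adherence))
    if not stay:
        participant_history.dropped = True
    return stay


# ---------------------------------------------------------------------------
# Single-person test and exam operations
# ---------------------------------------------------------------------------


def _state_index(state) -> int:
    if isinstance(state, str):
        try:
            return STATE_NAMES.index(state)
        except ValueError:
            raise ContractViolationError(f"unknown state {state!r}") from None
    return int(state)


def apply_fit(state, profile: PerStateTestProfile, rng: np.random.Generator) -> bool:
    """Draw one FIT result conditional on the true disease state.

    Clinically diagnosed and dead persons are outside the screening pool;
    passing them in is a contract violation.
    """
    idx = _state_index(state)
    if idx >= N_POOL_STATES:
        raise ContractViolationError(
            f"state {STATE_NAMES[idx]!r} is outside the screening pool"
        )
    return bool(rng.random() < profile.as_array()[idx])


def apply_colonoscopy(
    state, colo_params: ColonoscopyParams, rng: np.random.Generator
):
    """Apply one colonoscopy to a person's true state.

    Adenomas are removed (state returns to no-neoplasm) unless missed;
    preclinical cancer is detected (becomes screen-detected clinical cancer)
    unless missed.  Returns ``(new_state, detection_event)``.
    """
    idx = _state_index(state)
    if idx >= N_POOL_STATES:
        raise ContractViolationError(
            f"state {STATE_NAMES[idx]!r} is outside the screening pool"
        )
    if idx == STATE_NO_NEOPLASM:
        return STATE_NO_NEOPLASM, False
    if idx == STATE_NONADVANCED_ADENOMA:
        missed = rng.random() < colo_params.miss_nonadvanced
        return (STATE_NONADVANCED_ADENOMA if missed else STATE_NO_NEOPLASM), False
    if idx == STATE_ADVANCED_ADENOMA:
        missed = rng.random() < colo_params.miss_advanced
        return (STATE_ADVANCED_ADENOMA if missed else STATE_NO_NEOPLASM), False
    missed = rng.random() < colo_params.miss_preclinical_crc
    if missed:
        return STATE_PRECLINICAL_CRC, False
    return STATE_CLINICAL_CRC, True


# ---------------------------------------------------------------------------
# Cohort-level strategy execution
# ---------------------------------------------------------------------------


def _colonoscopy_effect_expectation(
    traj: CohortTrajectory, mass: np.ndarray, colo: ColonoscopyParams
) -> np.ndarray:
    """Expected post-exam pool occupancy of an examined mass vector; books
    screen detections into the clinical compartment."""
    out = np.zeros(N_POOL_STATES)
    out[STATE_NO_NEOPLASM] = (
        mass[STATE_NO_NEOPLASM]
        + mass[STATE_NONADVANCED_ADENOMA] * (1.0 - colo.miss_nonadvanced)
        + mass[STATE_ADVANCED_ADENOMA] * (1.0 - colo.miss_advanced)
    )
    out[STATE_NONADVANCED_ADENOMA] = mass[STATE_NONADVANCED_ADENOMA] * colo.miss_nonadvanced
    out[STATE_ADVANCED_ADENOMA] = mass[STATE_ADVANCED_ADENOMA] * colo.miss_advanced
    detected = mass[STATE_PRECLINICAL_CRC] * (1.0 - colo.miss_preclinical_crc)
    out[STATE_PRECLINICAL_CRC] = mass[STATE_PRECLINICAL_CRC] * colo.miss_preclinical_crc
    traj.clinical[MODE_SCREEN, 0] += detected
    traj.cases_cum += detected
    traj.cases_screen_cum += detected
    return out


def _colonoscopy_effect_microsim(
    traj: CohortTrajectory, mask: np.ndarray, colo: ColonoscopyParams
) -> None:
    state = traj.state
    rng = traj.rng
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    s = state[idx]
    u = rng.random(idx.size)
    rem_nonadv = idx[(s == STATE_NONADVANCED_ADENOMA) & (u >= colo.miss_nonadvanced)]
    rem_adv = idx[(s == STATE_ADVANCED_ADENOMA) & (u >= colo.miss_advanced)]
    det = idx[(s == STATE_PRECLINICAL_CRC) & (u >= colo.miss_preclinical_crc)]
    state[rem_nonadv] = STATE_NO_NEOPLASM
    state[rem_adv] = STATE_NO_NEOPLASM
    state[det] = STATE_CLINICAL_CRC
    traj.detect_mode[det] = MODE_SCREEN
    traj.ysd[det] = 0
    traj.cases_cum += int(det.size)
    traj.cases_screen_cum += int(det.size)


def execute_strategy_year(
    trajectory: CohortTrajectory,
    year: int,
    strategy: Strategy,
    adherence: Optional[AdherenceParams] = None,
    profile: Optional[PerStateTestProfile] = None,
    colo_params: Optional[ColonoscopyParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> CohortTrajectory:
    """Apply one year's screening events to a cohort (no-op off schedule).

    Resource accounting: one FIT per participation; screening and
    diagnostic colonoscopies are pooled in a single colonoscopy counter.
    Positive-FIT refusers of diagnostic colonoscopy keep their FIT counted
    but receive no state change.
    """
    strategy = as_strategy(strategy)
    adherence = adherence or DEFAULT_ADHERENCE
    colo = colo_params or DEFAULT_COLONOSCOPY
    if strategy.kind == "no_screening":
        return trajectory
    if year not in schedule_offers(strategy, trajectory.meta.horizon):
        return trajectory
    if strategy.uses_fit and profile is None:
        raise ConfigurationError(
            f"strategy {strategy.label} requires a per-state FIT profile"
        )
    if trajectory.meta.mode == "expectation":
        _execute_expectation(trajectory, year, strategy, adherence, profile, colo)
    else:
        _execute_microsim(trajectory, year, strategy, adherence, profile, colo)
    return trajectory


def _execute_expectation(traj, year, strategy, adherence, profile, colo) -> None:
    alive = traj.alive  # (behaviour classes, pool states)
    if strategy.kind == "colonoscopy_q10y":
        part = alive[0] * adherence.p_colonoscopy
        alive[0] -= part
        traj.colonoscopies_cum += float(part.sum())
        alive[1] += _colonoscopy_effect_expectation(traj, part, colo)
        return

    p_pos = profile.as_array()
    if strategy.kind == "gateopener":
        part = alive[0] * adherence.p_fit_first
        alive[0] -= part
        traj.fits_cum += float(part.sum())
        pos = part * p_pos
        diag = pos * adherence.p_diag_colonoscopy
        traj.colonoscopies_cum += float(diag.sum())
        alive[1] += (part - diag) + _colonoscopy_effect_expectation(traj, diag, colo)
        return

    # biennial FIT
    if year == 0:
        move = alive[0] * adherence.p_fit_first
        alive[0] -= move
        alive[1] += move
    else:
        drop = alive[1] * adherence.dropout
        alive[1] -= drop
        alive[2] += drop
    active = alive[1].copy()
    traj.fits_cum += float(active.sum())
    pos = active * p_pos
    diag = pos * adherence.p_diag_colonoscopy
    traj.colonoscopies_cum += float(diag.sum())
    alive[1] = (active - diag) + _colonoscopy_effect_expectation(traj, diag, colo)


def _execute_microsim(traj, year, strategy, adherence, profile, colo) -> None:
    rng = traj.rng
    state = traj.state
    n = state.size
    pool = state < N_POOL_STATES

    if strategy.kind == "colonoscopy_q10y":
        part = pool & (rng.random(n) < adherence.p_colonoscopy)
        traj.colonoscopies_cum += int(part.sum())
        _colonoscopy_effect_microsim(traj, part, colo)
        return

    if strategy.kind == "gateopener":
        part = pool & (rng.random(n) < adherence.p_fit_first)
    else:  # biennial FIT: persistent behaviour classes with absorbing drop-out
        beh = traj.behavior
        if year == 0:
            join = rng.random(n) < adherence.p_fit_first
            beh[join] = 1
        else:
            leave = (beh == 1) & (rng.random(n) >= per_round_retention(adherence))
            beh[leave] = 2
        part = pool & (traj.behavior == 1)

    traj.fits_cum += int(part.sum())
    idx = np.flatnonzero(part)
    p_pos = profile.as_array()[state[idx]]
    positive = idx[rng.random(idx.size) < p_pos]
    comply = positive[rng.random(positive.size) < adherence.p_diag_colonoscopy]
    traj.colonoscopies_cum += int(comply.size)
    diag_mask = np.zeros(n, dtype=bool)
    diag_mask[comply] = True
    _colonoscopy_effect_microsim(traj, diag_mask, colo)


def make_hook(
    strategy: Strategy,
    adherence: Optional[AdherenceParams] = None,
    profile: Optional[PerStateTestProfile] = None,
    colo_params: Optional[ColonoscopyParams] = None,
):
    """Build the yearly strategy hook consumed by the engine.

    Resolves a default per-state FIT profile from the packaged
    characteristics table when the strategy needs one and none is given
    (failing early for unsupported cutoffs).
    """
    strategy = as_strategy(strategy)
    if strategy.uses_fit and profile is None:
        profile = default_profile(strategy.cutoff)

    def hook(traj: CohortTrajectory, year: int) -> None:
        execute_strategy_year(traj, year, strategy, adherence, profile, colo_params)

    return hook
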