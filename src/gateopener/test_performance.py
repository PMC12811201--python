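"""Diagnostic performance of quantitative fecal immunochemical tests (FITs).

A quantitative FIT measures fecal hemoglobin (Hb, in micrograms Hb per gram
of feces); a result at or above a chosen cutoff is called positive and, in a
screening program, triggers an invitation to diagnostic colonoscopy.

This module provides three complementary views on FIT performance:

* *aggregate characteristics* at a given cutoff — positivity among all
  tested persons, sensitivity within the nested lesion groups (any neoplasm
  ⊇ any advanced neoplasm ⊇ preclinical cancer), and specificity within the
  complementary no-advanced-neoplasm group;
* a *per-state decomposition* of those aggregates into the probability of a
  positive test conditional on the four mutually exclusive colonoscopy
  finding categories — this is the form a state-transition simulator
  consumes;
* *record-level recomputation* of the aggregates from individual
  participant records (Hb value + colonoscopy finding) at arbitrary
  cutoffs, which is how performance at non-packaged cutoffs is obtained
  (no interpolation between cutoffs is ever performed).

The packaged default characteristics describe SENTiFIT-FOB Gold evaluated
on a German screening-colonoscopy cohort at cutoffs of 17 (manufacturer
preset), 10, 8, 6, 4, and 3 μg Hb/g.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DegenerateCountsError, UnsupportedCutoffError

logger = logging.getLogger(__name__)

#: Mutually exclusive colonoscopy finding categories, ordered from benign to
#: most severe.  This ordering is shared with the disease-state engine.
FINDING_CATEGORIES = (
    "no_neoplasm",
    "nonadvanced_adenoma",
    "advanced_adenoma",
    "preclinical_crc",
)

CHARACTERISTIC_COLUMNS = (
    "cutoff",
    "positivity",
    "sens_any_neoplasm",
    "sens_advanced_neoplasm",
    "sens_preclinical_crc",
    "spec_no_advanced",
)

_BUILTIN_RESOURCE = "fit_characteristics_sentifit.csv"


def _check_fraction(name: str, value: float) -> None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return  # undefined rates (empty subgroup) are representable as NaN
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class FITCharacteristics:
    """Aggregate FIT diagnostic characteristics at one hemoglobin cutoff.

    All rates are stored as fractions.  A rate may be NaN when it was
    computed from records with an empty denominator group ("undefined", as
    opposed to zero).  Sensitivities refer to the *nested* lesion groups
    (any neoplasm includes advanced neoplasm, which includes preclinical
    cancer); specificity refers to the complementary no-advanced-neoplasm
    group, which still contains carriers of non-advanced adenomas.
    """

    cutoff: float
    positivity: float
    sens_any_neoplasm: float
    sens_advanced_neoplasm: float
    sens_preclinical_crc: float
    spec_no_advanced: float

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError(f"cutoff must be non-negative, got {self.cutoff!r}")
        for name in CHARACTERISTIC_COLUMNS[1:]:
            _check_fraction(name, getattr(self, name))


@dataclass(frozen=True)
class GroupCounts:
    """Participant counts of the nested diagnostic groups in a study cohort.

    The nested counts (any neoplasm ⊇ advanced neoplasm ⊇ preclinical
    cancer) imply mutually exclusive category counts, exposed as derived
    properties.
    """

    n_total: int
    n_any_neoplasm: int
    n_advanced_neoplasm: int
    n_preclinical_crc: int
    n_no_advanced: int

    def __post_init__(self) -> None:
        if not (
            self.n_any_neoplasm
            >= self.n_advanced_neoplasm
            >= self.n_preclinical_crc
            >= 0
        ):
            raise ValueError(
                "nested counts must satisfy any >= advanced >= preclinical >= 0"
            )
        if self.n_no_advanced + self.n_advanced_neoplasm != self.n_total:
            raise ValueError(
                "no_advanced + advanced_neoplasm must partition the total"
            )
        if min(self.n_no_neoplasm, self.n_nonadvanced_adenoma, self.n_advanced_adenoma) < 0:
            raise ValueError("derived exclusive counts must be non-negative")

    @property
    def n_no_neoplasm(self) -> int:
        return self.n_total - self.n_any_neoplasm

    @property
    def n_nonadvanced_adenoma(self) -> int:
        return self.n_any_neoplasm - self.n_advanced_neoplasm

    @property
    def n_advanced_adenoma(self) -> int:
        return self.n_advanced_neoplasm - self.n_preclinical_crc

    def exclusive_counts(self) -> np.ndarray:
        """Counts of the four mutually exclusive categories, in
        :data:`FINDING_CATEGORIES` order."""
        return np.array(
            [
                self.n_no_neoplasm,
                self.n_nonadvanced_adenoma,
                self.n_advanced_adenoma,
                self.n_preclinical_crc,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class PerStateTestProfile:
    """Probability of a positive FIT conditional on the true disease state.

    This is the representation the simulation engine consumes: one positive
    probability per mutually exclusive finding category.
    """

    p_pos_no_neoplasm: float
    p_pos_nonadvanced_adenoma: float
    p_pos_advanced_adenoma: float
    p_pos_preclinical_crc: float

    def __post_init__(self) -> None:
        for name, value in zip(FINDING_CATEGORIES, self.as_array()):
            _check_fraction(f"p_pos_{name}", float(value))

    def as_array(self) -> np.ndarray:
        """Positive probabilities ordered by :data:`FINDING_CATEGORIES`."""
        return np.array(
            [
                self.p_pos_no_neoplasm,
                self.p_pos_nonadvanced_adenoma,
                self.p_pos_advanced_adenoma,
                self.p_pos_preclinical_crc,
            ],
            dtype=float,
        )

    def reaggregate(self, counts: GroupCounts, cutoff: float) -> FITCharacteristics:
        """Count-weighted re-aggregation back to nested-group characteristics."""
        p = self.as_array()
        n = counts.exclusive_counts()

        def _mix(num: float, den: float) -> float:
            return float(num / den) if den else float("nan")

        positivity = _mix(np.dot(p, n), counts.n_total)
        sens_any = _mix(np.dot(p[1:], n[1:]), counts.n_any_neoplasm)
        sens_adv = _mix(np.dot(p[2:], n[2:]), counts.n_advanced_neoplasm)
        sens_crc = float(p[3])
        fpr_no_adv = _mix(np.dot(p[:2], n[:2]), counts.n_no_advanced)
        return FITCharacteristics(
            cutoff=cutoff,
            positivity=positivity,
            sens_any_neoplasm=sens_any,
            sens_advanced_neoplasm=sens_adv,
            sens_preclinical_crc=sens_crc,
            spec_no_advanced=1.0 - fpr_no_adv,
        )


@dataclass(frozen=True)
class FITRecord:
    """One participant's quantitative FIT result and colonoscopy finding."""

    hb_value: float
    finding: str
    sex: str = "unknown"
    age: int = 0

    def __post_init__(self) -> None:
        if self.hb_value < 0:
            raise ValueError(f"hb_value must be non-negative, got {self.hb_value!r}")
        if self.finding not in FINDING_CATEGORIES:
            raise ValueError(
                f"finding must be one of {FINDING_CATEGORIES}, got {self.finding!r}"
            )


RecordsLike = Union[pd.DataFrame, Iterable[FITRecord]]


def records_to_frame(records: RecordsLike) -> pd.DataFrame:
    """Normalise a record collection to a validated DataFrame."""
    if isinstance(records, pd.DataFrame):
        df = records
        missing = {"hb_value", "finding"} - set(df.columns)
        if missing:
            raise ValueError(f"record frame lacks required columns: {sorted(missing)}")
        bad = set(df["finding"].unique()) - set(FINDING_CATEGORIES)
        if bad:
            raise ValueError(f"unknown finding categories: {sorted(bad)}")
        if (df["hb_value"] < 0).any():
            raise ValueError("hb_value must be non-negative")
        return df
    rows = list(records)
    return pd.DataFrame(
        {
            "hb_value": [r.hb_value for r in rows],
            "finding": [r.finding for r in rows],
            "sex": [r.sex for r in rows],
            "age": [r.age for r in rows],
        }
    )


def read_fit_records(path) -> pd.DataFrame:
    """Read a FIT record CSV (columns ``hb_value, finding, sex, age``)."""
    return records_to_frame(pd.read_csv(path))


def write_fit_records(records: RecordsLike, path) -> None:
    """Write FIT records to CSV with the standard column layout."""
    records_to_frame(records).to_csv(path, index=False)


def load_characteristics_table(path=None) -> pd.DataFrame:
    """Load a cutoff-characteristics table (packaged default or override file).

    The table holds one row per cutoff with all rates as fractions; rows are
    returned sorted by decreasing cutoff.
    """
    if path is None:
        source = resources.files("gateopener.data").joinpath(_BUILTIN_RESOURCE)
        with source.open("r") as handle:
            df = pd.read_csv(handle)
    else:
        df = pd.read_csv(path)
    missing = set(CHARACTERISTIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"characteristics table lacks columns: {sorted(missing)}")
    for col in CHARACTERISTIC_COLUMNS[1:]:
        if not df[col].between(0.0, 1.0).all():
            raise ValueError(f"column {col} contains values outside [0, 1]")
    return df.sort_values("cutoff", ascending=False).reset_index(drop=True)


def builtin_characteristics(cutoff: float, table: pd.DataFrame | None = None) -> FITCharacteristics:
    """Return the packaged characteristics row for one supported cutoff.

    No interpolation is performed: a cutoff outside the packaged set raises
    :class:`~gateopener.errors.UnsupportedCutoffError`.  Performance at
    arbitrary cutoffs can be obtained from individual records via
    :func:`characteristics_from_records`.
    """
    df = load_characteristics_table() if table is None else table
    match = df[np.isclose(df["cutoff"].to_numpy(dtype=float), float(cutoff))]
    if match.empty:
        supported = sorted(df["cutoff"].tolist(), reverse=True)
        raise UnsupportedCutoffError(
            f"cutoff {cutoff} μg/g is not in the packaged table (supported: "
            f"{supported}); recompute from records for other cutoffs"
        )
    row = match.iloc[0]
    return FITCharacteristics(
        cutoff=float(row["cutoff"]),
        positivity=float(row["positivity"]),
        sens_any_neoplasm=float(row["sens_any_neoplasm"]),
        sens_advanced_neoplasm=float(row["sens_advanced_neoplasm"]),
        sens_preclinical_crc=float(row["sens_preclinical_crc"]),
        spec_no_advanced=float(row["spec_no_advanced"]),
    )


def supported_cutoffs(table: pd.DataFrame | None = None) -> tuple[float, ...]:
    """Cutoffs available in the packaged (or supplied) characteristics table."""
    df = load_characteristics_table() if table is None else table
    return tuple(float(c) for c in df["cutoff"])


def decompose_to_per_state(
    agg: FITCharacteristics, counts: GroupCounts
) -> PerStateTestProfile:
    """Decompose nested-group aggregates into per-state positive probabilities.

    The nested group rates are count-weighted mixtures of the mutually
    exclusive category rates, so the decomposition is a triangular linear
    solve: the cancer sensitivity is already conditional on one state, the
    advanced-neoplasm sensitivity mixes advanced adenomas with cancers, the
    any-neoplasm sensitivity additionally mixes in non-advanced adenomas,
    and the false-positive rate of the no-advanced-neoplasm group mixes
    lesion-free persons with non-advanced adenoma carriers.

    Published aggregates are rounded, so the solve can land slightly outside
    [0, 1]; results are clamped with a warning in that case.
    """
    if counts.n_advanced_adenoma == 0:
        raise DegenerateCountsError("no advanced-adenoma carriers: cannot separate "
                                    "advanced adenomas from cancers")
    if counts.n_nonadvanced_adenoma == 0:
        raise DegenerateCountsError("no non-advanced-adenoma carriers: cannot separate "
                                    "non-advanced adenomas from advanced neoplasms")
    if counts.n_no_neoplasm == 0:
        raise DegenerateCountsError("no lesion-free participants: cannot recover the "
                                    "false-positive rate among them")

    p_crc = agg.sens_preclinical_crc
    p_adv = (
        agg.sens_advanced_neoplasm * counts.n_advanced_neoplasm
        - p_crc * counts.n_preclinical_crc
    ) / counts.n_advanced_adenoma
    p_nonadv = (
        agg.sens_any_neoplasm * counts.n_any_neoplasm
        - agg.sens_advanced_neoplasm * counts.n_advanced_neoplasm
    ) / counts.n_nonadvanced_adenoma
    fpr_no_adv = 1.0 - agg.spec_no_advanced
    p_no = (
        fpr_no_adv * counts.n_no_advanced - p_nonadv * counts.n_nonadvanced_adenoma
    ) / counts.n_no_neoplasm

    raw = np.array([p_no, p_nonadv, p_adv, p_crc], dtype=float)
    clipped = np.clip(raw, 0.0, 1.0)
    if not np.allclose(raw, clipped, atol=1e-12):
        warnings.warn(
            "per-state decomposition produced probabilities outside [0, 1] "
            f"({raw.round(4).tolist()}); clamping — expected when aggregates "
            "are rounded",
            stacklevel=2,
        )
    return PerStateTestProfile(*clipped)


def characteristics_from_records(
    records: RecordsLike, cutoff: float
) -> FITCharacteristics:
    """Recompute aggregate characteristics from individual records.

    A record is called positive when ``hb_value >= cutoff`` (closed lower
    bound).  Group denominators follow the nested definitions: any neoplasm
    = any adenoma or cancer; advanced neoplasm = advanced adenoma or cancer;
    no advanced neoplasm = everyone else.  A sensitivity whose diseased
    subgroup is empty is reported as NaN (undefined), not zero.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("records must be non-empty")
    pos = df["hb_value"].to_numpy(dtype=float) >= float(cutoff)
    finding = df["finding"].to_numpy()

    is_crc = finding == "preclinical_crc"
    is_adv = is_crc | (finding == "advanced_adenoma")
    is_any = is_adv | (finding == "nonadvanced_adenoma")
    no_adv = ~is_adv

    def _rate(mask: np.ndarray) -> float:
        return float(pos[mask].mean()) if mask.any() else float("nan")

    spec = 1.0 - _rate(no_adv) if no_adv.any() else float("nan")
    return FITCharacteristics(
        cutoff=float(cutoff),
        positivity=float(pos.mean()),
        sens_any_neoplasm=_rate(is_any),
        sens_advanced_neoplasm=_rate(is_adv),
        sens_preclinical_crc=_rate(is_crc),
        spec_no_advanced=spec,
    )


def sensitivity_positivity_curve(
    records: RecordsLike, cutoffs: Sequence[float]
) -> pd.DataFrame:
    """Tabulate characteristics across cutoffs (one row per cutoff).

    Cutoffs are expected sorted descending; unsorted input is sorted
    internally with a log notice.  Duplicated cutoffs yield duplicated
    identical rows.
    """
    cutoffs = [float(c) for c in cutoffs]
    if any(a < b for a, b in zip(cutoffs, cutoffs[1:])):
        logger.info("cutoffs were not sorted descending; sorting internally")
        cutoffs = sorted(cutoffs, reverse=True)
    df = records_to_frame(records)
    rows = [characteristics_from_records(df, c) for c in cutoffs]
    return pd.DataFrame(
        [{col: getattr(r, col) for col in CHARACTERISTIC_COLUMNS} for r in rows]
    )
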