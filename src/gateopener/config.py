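"""Scenario configuration, grid orchestration, and result serialisation.

A :class:`ScenarioConfig` describes a full comparison grid: the strategies
to evaluate, the start ages and sexes, cohort size and horizon, execution
mode, and the adherence overlay.  :func:`run_scenario_grid` runs a matched
no-screening reference per (age, sex) cell plus every requested arm,
summarises outcomes, and optionally writes a tidy CSV plus a reproducibility
manifest.  :func:`run_sensitivity_suite` repeats the grid under the
parameter-uncertainty and adherence variants.

Reproducibility: a single global seed is expanded into per-arm independent
substreams keyed by the arm's (strategy, age, sex) identity, so adding or
removing arms never perturbs the results of the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .natural_history import NaturalHistoryParams, Scenario, SEXES, run_arm
from .outcomes import (
    OutcomeSummary,
    league_table,
    pool_sexes,
    summarize_arm,
)
from .strategies import (
    ADHERENCE_OVERLAYS,
    AdherenceParams,
    GATEOPENER_CUTOFFS,
    Strategy,
    as_strategy,
    default_profile,
)
from .synthetic import generate_natural_history_params, perturb_to_ci_bound

logger = logging.getLogger(__name__)

try:  # package version for manifests
    from importlib.metadata import version as _pkg_version

    _VERSION = _pkg_version("gateopener")
except Exception:  # pragma: no cover - not installed
    _VERSION = "unknown"


def default_grid_strategies() -> list[Strategy]:
    """The standard eight-arm comparison: conventional colonoscopy,
    conventional biennial FIT, and the gateopener at each packaged cutoff."""
    arms = [Strategy("colonoscopy_q10y"), Strategy("biennial_fit")]
    arms += [Strategy("gateopener", c) for c in GATEOPENER_CUTOFFS]
    return arms


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of a scenario grid."""

    strategies: tuple[Strategy, ...] = field(
        default_factory=lambda: tuple(default_grid_strategies())
    )
    ages: tuple[int, ...] = (50, 60, 70)
    sexes: tuple[str, ...] = SEXES
    cohort_size: int = 100_000
    horizon_years: int = 10
    mode: str = "expectation"
    seed: int = 0
    adherence_overlay: Optional[str] = None
    params_file: Optional[str] = None
    params_seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "strategies", tuple(as_strategy(s) for s in self.strategies)
        )
        if self.mode not in ("expectation", "microsim"):
            raise ConfigurationError("mode must be 'expectation' or 'microsim'")
        if self.mode == "microsim" and self.seed is None:
            raise ConfigurationError("seed is mandatory in microsim mode")
        for sex in self.sexes:
            if sex not in SEXES:
                raise ConfigurationError(f"unknown sex {sex!r}")
        if self.adherence_overlay is not None and self.adherence_overlay not in ADHERENCE_OVERLAYS:
            raise ConfigurationError(
                f"unknown adherence overlay {self.adherence_overlay!r}; "
                f"available: {sorted(ADHERENCE_OVERLAYS)}"
            )
        # fail fast on unsupported gateopener cutoffs (before any simulation)
        for strat in self.strategies:
            if strat.uses_fit:
                default_profile(strat.cutoff)

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "strategies": [
                {"kind": s.kind, "cutoff": s.cutoff} for s in self.strategies
            ],
            "ages": list(self.ages),
            "sexes": list(self.sexes),
            "cohort_size": self.cohort_size,
            "horizon_years": self.horizon_years,
            "mode": self.mode,
            "seed": self.seed,
            "adherence_overlay": self.adherence_overlay,
            "params_file": self.params_file,
            "params_seed": self.params_seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ScenarioConfig":
        payload = dict(payload)
        if "strategies" in payload:
            payload["strategies"] = tuple(
                Strategy(d["kind"], d.get("cutoff")) if isinstance(d, dict) else as_strategy(d)
                for d in payload["strategies"]
            )
        for key in ("ages", "sexes"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    def content_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    # -- resolution -----------------------------------------------------

    def resolve_adherence(self) -> AdherenceParams:
        base = AdherenceParams()
        if self.adherence_overlay:
            return base.with_overrides(**ADHERENCE_OVERLAYS[self.adherence_overlay])
        return base

    def resolve_params(self) -> NaturalHistoryParams:
        if self.params_file:
            return NaturalHistoryParams.from_yaml(self.params_file)
        params_seed = self.params_seed if self.params_seed is not None else self.seed
        return generate_natural_history_params(seed=params_seed)


def arm_seed(global_seed: int, strategy_label: str, age: int, sex: str) -> np.random.SeedSequence:
    """Independent, arm-keyed substream of the global seed."""
    key = zlib.crc32(f"{strategy_label}|{age}|{sex}".encode()) % (2**31)
    return np.random.SeedSequence([int(global_seed), key])


def run_scenario_grid(
    config: ScenarioConfig,
    out_dir=None,
    params: Optional[NaturalHistoryParams] = None,
    adherence: Optional[AdherenceParams] = None,
) -> tuple[pd.DataFrame, list[OutcomeSummary]]:
    """Run the grid: a no-screening reference per (age, sex) plus all arms.

    Returns the league table (empty when no comparator reference strategy is
    in the grid) and the per-arm outcome summaries (per sex and pooled).
    When ``out_dir`` is given, writes ``outcomes.csv``, ``league.csv`` and a
    run manifest.
    """
    params = params or config.resolve_params()
    adherence = adherence or config.resolve_adherence()
    summaries: list[OutcomeSummary] = []

    for age in config.ages:
        for sex in config.sexes:
            ref_scenario = Scenario(
                age=age,
                sex=sex,
                cohort_size=config.cohort_size,
                horizon_years=config.horizon_years,
                mode=config.mode,
                seed=arm_seed(config.seed, "no_screening", age, sex)
                if config.mode == "microsim"
                else None,
            )
            reference = run_arm(params, ref_scenario, "no_screening")
            summaries.append(summarize_arm(reference, reference, cutoff=None))
            for strat in config.strategies:
                scenario = replace(
                    ref_scenario,
                    seed=arm_seed(config.seed, strat.label, age, sex)
                    if config.mode == "microsim"
                    else None,
                )
                traj = run_arm(params, scenario, strat, adherence=adherence)
                summaries.append(summarize_arm(traj, reference, cutoff=strat.cutoff))

    if len(config.sexes) > 1:
        summaries = summaries + pool_sexes(summaries)

    labels = {s.strategy_label for s in summaries}
    refs = [r for r in ("colonoscopy_q10y", "biennial_fit") if r in labels]
    if refs:
        table = league_table(summaries, reference_labels=refs)
    else:
        table = pd.DataFrame()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
            out_dir / "outcomes.csv", index=False
        )
        if not table.empty:
            table.to_csv(out_dir / "league.csv", index=False)
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "package_version": _VERSION,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }
        with open(out_dir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
    return table, summaries


SENSITIVITY_VARIANTS = ("base", "ci_lower", "ci_upper", "adherence60", "dropout30")


def run_sensitivity_suite(
    config: ScenarioConfig, out_dir=None
) -> dict[str, tuple[pd.DataFrame, list[OutcomeSummary]]]:
    """Run the base grid plus the standard uncertainty variants.

    Variants: parameter point estimates replaced by lower / upper 95% CI
    bounds; FIT-based adherence raised to 60%; biennial drop-out reduced
    to 30%.
    """
    base_params = config.resolve_params()
    base_adherence = config.resolve_adherence()
    variants = {
        "base": (base_params, base_adherence),
        "ci_lower": (perturb_to_ci_bound(base_params, "lower"), base_adherence),
        "ci_upper": (perturb_to_ci_bound(base_params, "upper"), base_adherence),
        "adherence60": (
            base_params,
            base_adherence.with_overrides(**ADHERENCE_OVERLAYS["adherence60"]),
        ),
        "dropout30": (
            base_params,
            base_adherence.with_overrides(**ADHERENCE_OVERLAYS["dropout30"]),
        ),
    }
    results = {}
    for name, (params, adherence) in variants.items():
        sub_dir = None if out_dir is None else Path(out_dir) / name
        results[name] = run_scenario_grid(
            config, out_dir=sub_dir, params=params, adherence=adherence
        )
    return results
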