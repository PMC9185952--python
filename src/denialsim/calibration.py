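"""Iterative calibration of equation intercepts to empirical rate targets.

Each target statistic is paired with one adjustable intercept (firearm
homicide -> homicide-victim potential; firearm suicide -> suicide death;
the two arrest rates -> their arrest equations; the two misdemeanor
conviction rates -> the per-type conviction offsets; ownership and carrying
prevalence -> their equations).  Every iteration simulates a few short
replications, measures each statistic, and applies a damped update on the
logit scale::

    intercept += lam * (logit(p_target) - logit(p_simulated))

with identical replication seeds across iterations (common random numbers),
so iteration-to-iteration changes reflect the parameter moves rather than
resampling noise.  Measurement uses conditional-expectation statistics
(sums of per-agent event probabilities given the simulated state) rather
than realized Bernoulli counts; the two agree in expectation, and the
former makes a tight relative-tolerance stopping rule meaningful for rare
outcomes (a firearm-suicide rate near 1/100,000 realizes only a handful of
events per short replication).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import StepLog, run_simulation
from .params import CalibrationTargetSet, ParameterSet, default_targets

RATE_SCALE = 1e5


def _p_from_stat(name: str, value: float) -> float:
    """Statistic value -> per-person-year probability scale."""
    if name.endswith("_pct"):
        return value / 100.0
    return value / RATE_SCALE


# --------------------------------------------------------------------------
# Rate summaries
# --------------------------------------------------------------------------


def summarize_rates(logs: list[StepLog], population_size: int | None = None,
                    use_expected: bool = False) -> dict[str, float]:
    """Annualized headline statistics from step logs.

    Event rates are total events / total alive person-years x 100,000;
    prevalences are the mean of yearly prevalences, in percent.  With
    ``use_expected`` the realized event counts are replaced by their
    conditional expectations given each year's simulated state.
    """
    if not logs:
        raise ValueError("summarize_rates requires at least one step log")
    py = float(sum(lg.population for lg in logs))
    pops = np.array([lg.population for lg in logs], dtype=float)

    def total(realized, expected_key):
        if use_expected:
            return sum(lg.expected.get(expected_key, 0.0) for lg in logs)
        return sum(realized(lg) for lg in logs)

    out = {
        "firearm_homicide": total(lambda lg: lg.deaths_firearm_homicide, "firearm_homicide"),
        "firearm_suicide": total(lambda lg: lg.deaths_firearm_suicide, "firearm_suicide"),
        "alcohol_arrest": total(lambda lg: lg.arrests.get("alcohol", 0), "arrest_alcohol"),
        "drug_arrest": total(lambda lg: lg.arrests.get("drug", 0), "arrest_drug"),
        "alcohol_misdemeanor_conviction": total(
            lambda lg: lg.misdemeanor_convictions.get("alcohol", 0),
            "misdemeanor_conviction_alcohol"),
        "drug_misdemeanor_conviction": total(
            lambda lg: lg.misdemeanor_convictions.get("drug", 0),
            "misdemeanor_conviction_drug"),
    }
    out = {k: v / py * RATE_SCALE for k, v in out.items()}
    owners = np.array([lg.owners for lg in logs], dtype=float)
    carriers = np.array([lg.carriers for lg in logs], dtype=float)
    out["ownership_pct"] = float(np.mean(owners / pops) * 100.0)
    out["carrying_pct"] = float(np.mean(carriers / pops) * 100.0)
    return out


# --------------------------------------------------------------------------
# Adjustment mapping: statistic name -> (getter, setter) on a ParameterSet
# --------------------------------------------------------------------------


def _table_intercept(table_name: str):
    def get(ps: ParameterSet) -> float:
        return ps.tables[table_name].intercept

    def set_(ps: ParameterSet, v: float) -> None:
        ps.tables[table_name].intercept = v

    return get, set_


def _conviction_offset(atype: str):
    def get(ps: ParameterSet) -> float:
        return ps.conviction_type_offsets.get(atype, 0.0)

    def set_(ps: ParameterSet, v: float) -> None:
        ps.conviction_type_offsets[atype] = v

    return get, set_


ADJUSTMENTS = {
    "firearm_homicide": _table_intercept("homicide_victim_potential"),
    "firearm_suicide": _table_intercept("suicide_death"),
    "alcohol_arrest": _table_intercept("arrest_alcohol"),
    "drug_arrest": _table_intercept("arrest_drug"),
    "alcohol_misdemeanor_conviction": _conviction_offset("alcohol"),
    "drug_misdemeanor_conviction": _conviction_offset("drug"),
    "ownership_pct": _table_intercept("ownership"),
    "carrying_pct": _table_intercept("carrying"),
}


# --------------------------------------------------------------------------
# Calibration driver
# --------------------------------------------------------------------------


@dataclass
class CalibrationSettings:
    """Per-iteration simulation budget and update rule parameters.

    The default measurement window (10 burn-in + 30 observed years)
    matches the reporting window of the experiment layer, so calibrated
    levels transfer without drift from slowly-equilibrating histories.
    """

    replications: int = 2
    years: int = 30
    burn_in: int = 10
    max_iterations: int = 40
    damping: float = 0.5
    seed: int = 0
    max_step: float = 2.0  # clamp on a single logit update
    use_expected: bool = True


@dataclass
class CalibrationReport:
    trajectory: list[dict] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0
    final_adjustments: dict[str, float] = field(default_factory=dict)
    final_values: dict[str, float] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory)


def _default_simulate(params: ParameterSet, seed: int,
                      settings: CalibrationSettings) -> dict[str, float]:
    _, logs = run_simulation(params, policy=None, years=settings.years,
                             burn_in=settings.burn_in, seed=seed)
    return summarize_rates(logs, use_expected=settings.use_expected)


def calibrate(params: ParameterSet,
              targets: CalibrationTargetSet | None = None,
              settings: CalibrationSettings | None = None,
              simulate_fn=None,
              adjustments: dict | None = None,
              ) -> tuple[ParameterSet, CalibrationReport]:
    """Damped simultaneous intercept updates until all targets hit tolerance.

    ``simulate_fn(params, seed, settings) -> {statistic: value}`` defaults
    to running the full simulator; tests substitute closed-form toy models.
    Deterministic given ``settings.seed``.
    """
    targets = targets if targets is not None else default_targets()
    targets.validate()
    settings = settings if settings is not None else CalibrationSettings()
    simulate_fn = simulate_fn if simulate_fn is not None else _default_simulate
    adjustments = adjustments if adjustments is not None else ADJUSTMENTS
    tmap = targets.as_dict()
    for name in tmap:
        if name not in adjustments:
            raise ValueError(f"no adjustable parameter mapped to target '{name}'")
    ps = params.copy()
    report = CalibrationReport()
    py_floor = 1.0 / (settings.replications * max(1, settings.years) * params.population_size)
    for it in range(1, settings.max_iterations + 1):
        sims: dict[str, list[float]] = {n: [] for n in tmap}
        for r in range(settings.replications):
            seed_r = (settings.seed * 1000 + r) % (2**31 - 1)
            stats = simulate_fn(ps, seed_r, settings)
            for n in tmap:
                sims[n].append(stats[n])
        rel_errors = {}
        all_ok = True
        for name, (target, tol) in tmap.items():
            sim = float(np.mean(sims[name]))
            rel = abs(sim - target) / target
            rel_errors[name] = rel
            report.trajectory.append({
                "iteration": it, "statistic": name, "simulated": sim,
                "target": target, "relative_error": rel,
            })
            report.final_values[name] = sim
            if rel > tol:
                all_ok = False
        report.iterations = it
        if all_ok:
            report.converged = True
            break
        for name, (target, tol) in tmap.items():
            if rel_errors[name] <= tol:
                continue
            sim = float(np.mean(sims[name]))
            p_t = _p_from_stat(name, target)
            p_s = max(_p_from_stat(name, sim), py_floor)
            p_s = min(p_s, 1 - 1e-12)
            p_t = min(max(p_t, 1e-12), 1 - 1e-12)
            delta = settings.damping * (math.log(p_t / (1 - p_t)) - math.log(p_s / (1 - p_s)))
            if not np.isfinite(delta):
                raise ArithmeticError(
                    f"non-finite calibration update for '{name}' "
                    f"(target {target}, simulated {sim}): target unreachable"
                )
            delta = float(np.clip(delta, -settings.max_step, settings.max_step))
            get, set_ = adjustments[name]
            set_(ps, get(ps) + delta)
    report.final_adjustments = {
        name: adjustments[name][0](ps) - adjustments[name][0](params) for name in tmap
    }
    return ps, report
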