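"""Replicated scenario runs, percent decreases, subgroups, sensitivity.

A scenario (baseline or one of the 12 disqualification policies) is run as
independent replications with seeds derived from a master seed; baseline
and intervention use the *same* derived seeds (common random numbers), so
per-replication percent decreases are matched-pair contrasts.  Confidence
intervals are normal-approximation mean +/- 1.96 SD/sqrt(n) across
replications; a percentile bootstrap is available as an option.

High-risk subgroup rates restrict person-years and firearm deaths to
agents after they first satisfy a criterion ("ever qualified"), mirroring
how base rates among disqualified groups are tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import RATE_SCALE, summarize_rates
from .dynamics import StepLog, run_simulation
from .params import ParameterSet
from .policy import PolicySpec, all_policies
from .population import CRITERIA, TRIGGERS

#: statistics reported at scenario level (population + per-subgroup)
POPULATION_STATS = ("firearm_homicide", "firearm_suicide")


def _rep_seed(master_seed: int, rep: int) -> int:
    return (int(master_seed) * 100_003 + 7 * rep + 1) % (2**31 - 1)


def subgroup_rates(logs: list[StepLog], criterion: str, trigger: str,
                   use_expected: bool = False) -> dict[str, float]:
    """Firearm death rates among ever-qualified agents, per 100,000 p-y.

    Returns NaNs (with a warning) when no agent ever qualifies — an empty
    subgroup is undefined, not zero.  ``use_expected`` swaps realized death
    counts for their conditional expectations given the simulated state.
    """
    key = (criterion, trigger)
    py = fh = fs = 0
    for lg in logs:
        rec = lg.subgroup.get(key)
        if rec:
            py += rec[0]
            fh += rec[3] if use_expected else rec[1]
            fs += rec[4] if use_expected else rec[2]
    if py == 0:
        warnings.warn(f"empty subgroup {key}: rates undefined")
        return {"person_years": 0.0, "firearm_homicide": float("nan"),
                "firearm_suicide": float("nan")}
    return {
        "person_years": float(py),
        "firearm_homicide": fh / py * RATE_SCALE,
        "firearm_suicide": fs / py * RATE_SCALE,
    }


@dataclass
class ScenarioResult:
    label: str
    policy: PolicySpec | None
    stats: pd.DataFrame  # one row per replication
    n_runs: int
    years: int
    burn_in: int
    master_seed: int

    def mean(self, stat: str) -> float:
        return float(self.stats[stat].mean())

    def ci(self, stat: str) -> tuple[float, float, float]:
        """(mean, lower, upper) with the normal approximation."""
        v = self.stats[stat].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return float("nan"), float("nan"), float("nan")
        m = float(v.mean())
        half = 1.96 * float(v.std(ddof=1)) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        return m, m - half, m + half

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in self.stats.columns:
            m, lo, hi = self.ci(col)
            rows.append({"statistic": col, "mean": m, "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)


def run_scenario(params: ParameterSet, policy: PolicySpec | None,
                 n_runs: int = 100, years: int = 30,
                 burn_in: int | None = None, master_seed: int = 0,
                 label: str | None = None,
                 world_cache: dict | None = None) -> ScenarioResult:
    """Run ``n_runs`` independent replications of one scenario.

    ``world_cache`` (a plain dict, shared across matched scenarios) memoizes
    the pristine initialized world per (parameterization, seed); each
    replication then steps a deep copy, which is byte-identical to a fresh
    build but skips repeating initialization and network construction.
    """
    import copy

    from .network import build_social_network
    from .population import initialize_population

    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 (confidence interval undefined)")
    burn_in = params.burn_in if burn_in is None else burn_in
    cache_base = params.config_hash() if world_cache is not None else None
    rows = []
    for rep in range(n_runs):
        seed = _rep_seed(master_seed, rep)
        world = None
        if world_cache is not None:
            key = (cache_base, seed)
            if key not in world_cache:
                pristine = initialize_population(params, seed)
                build_social_network(pristine, params)
                world_cache[key] = pristine
            world = copy.deepcopy(world_cache[key])
        _, logs = run_simulation(params, policy=policy, years=years,
                                 burn_in=burn_in, seed=seed, world=world)
        row = dict(summarize_rates(logs))
        exp = summarize_rates(logs, use_expected=True)
        row["exp_firearm_homicide"] = exp["firearm_homicide"]
        row["exp_firearm_suicide"] = exp["firearm_suicide"]
        for c in CRITERIA:
            for t in TRIGGERS:
                sg = _quiet_subgroup(logs, c, t)
                sge = _quiet_subgroup(logs, c, t, use_expected=True)
                tshort = "single" if t == "single_event" else "two"
                row[f"sub_fh[{c}|{tshort}]"] = sg["firearm_homicide"]
                row[f"sub_fs[{c}|{tshort}]"] = sg["firearm_suicide"]
                row[f"sub_py[{c}|{tshort}]"] = sg["person_years"]
                row[f"sub_exp_fh[{c}|{tshort}]"] = sge["firearm_homicide"]
                row[f"sub_exp_fs[{c}|{tshort}]"] = sge["firearm_suicide"]
        row["replication"] = rep
        rows.append(row)
    stats = pd.DataFrame(rows).set_index("replication")
    return ScenarioResult(
        label=label or (policy.label if policy else "baseline"),
        policy=policy, stats=stats, n_runs=n_runs, years=years,
        burn_in=burn_in, master_seed=master_seed,
    )


def _quiet_subgroup(logs, c, t, use_expected=False):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return subgroup_rates(logs, c, t, use_expected=use_expected)


def percent_decrease(baseline: ScenarioResult, intervention: ScenarioResult,
                     stats: tuple[str, ...] = POPULATION_STATS,
                     paired: bool = True) -> pd.DataFrame:
    """Percent decrease (baseline - intervention) / baseline x 100.

    Default is per-replication pairing under common random numbers; the
    pooled alternative compares scenario means.  Negative values are
    legitimate (an intervention can come out slightly worse by chance).
    """
    if baseline.n_runs != intervention.n_runs:
        raise ValueError("replication counts differ between scenarios")
    rows = []
    for stat in stats:
        b = baseline.stats[stat].to_numpy(dtype=float)
        i = intervention.stats[stat].to_numpy(dtype=float)
        if paired:
            with np.errstate(divide="ignore", invalid="ignore"):
                dec = np.where(b != 0, (b - i) / b * 100.0, np.nan)
            n_eff = int(np.isfinite(dec).sum())
            if n_eff == 0:
                m, half = float("nan"), float("nan")
            else:
                m = float(np.nanmean(dec))
                half = (1.96 * float(np.nanstd(dec, ddof=1)) / np.sqrt(n_eff)
                        if n_eff > 1 else 0.0)
        else:
            bm, im = float(np.nanmean(b)), float(np.nanmean(i))
            m = (bm - im) / bm * 100.0 if bm else float("nan")
            half = float("nan")
        rows.append({"statistic": stat, "pct_decrease": m,
                     "ci_low": m - half, "ci_high": m + half})
    return pd.DataFrame(rows)


def bootstrap_ci(values: np.ndarray, n_boot: int = 2000, seed: int = 0
                 ) -> tuple[float, float, float]:
    """Percentile-bootstrap mean CI (optional alternative to the normal CI)."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    means = rng.choice(values, size=(n_boot, len(values)), replace=True).mean(axis=1)
    return float(values.mean()), float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975))


@dataclass
class SensitivitySettings:
    n_runs: int = 100
    years: int = 30
    master_seed: int = 0
    policies: list[PolicySpec] = field(default_factory=all_policies)
    recalibrate_ownership: bool = True
    ownership_target_pct: float = 11.0
    network_weights: tuple[float, float] = (0.10, 0.25)


def sensitivity_variants(params: ParameterSet,
                         settings: SensitivitySettings | None = None,
                         calibration_settings=None) -> dict[str, ParameterSet]:
    """The three robustness parameterizations: halved ownership and the
    low/high network-influence weights."""
    from .calibration import CalibrationSettings, calibrate
    from .params import CalibrationTargetSet, EMPIRICAL_TARGETS

    settings = settings or SensitivitySettings()
    variants: dict[str, ParameterSet] = {}
    halved = params.copy()
    if settings.recalibrate_ownership:
        tgt = dict(EMPIRICAL_TARGETS)
        tgt["ownership_pct"] = settings.ownership_target_pct
        targets = CalibrationTargetSet(
            entries=[(n, v, 0.05) for n, v in tgt.items()]
        )
        cs = calibration_settings or CalibrationSettings(
            replications=1, years=6, burn_in=4, max_iterations=15,
            seed=settings.master_seed,
        )
        halved, _ = calibrate(halved, targets, cs)
    else:
        # crude halving of the ownership intercept as a fallback
        halved.tables["ownership"].intercept -= 1.0
    variants["ownership_halved"] = halved
    for w in settings.network_weights:
        v = params.copy()
        v.network_influence_weight = float(w)
        variants[f"network_weight_{w:g}"] = v
    return variants


def sensitivity_suite(params: ParameterSet,
                      settings: SensitivitySettings | None = None
                      ) -> dict[str, dict[str, ScenarioResult]]:
    """Re-run baseline + policies under each robustness parameterization."""
    settings = settings or SensitivitySettings()
    out: dict[str, dict[str, ScenarioResult]] = {}
    for vname, vparams in sensitivity_variants(params, settings).items():
        runs: dict[str, ScenarioResult] = {}
        runs["baseline"] = run_scenario(
            vparams, None, n_runs=settings.n_runs, years=settings.years,
            master_seed=settings.master_seed,
        )
        for pol in settings.policies:
            runs[pol.label] = run_scenario(
                vparams, pol, n_runs=settings.n_runs, years=settings.years,
                master_seed=settings.master_seed,
            )
        out[vname] = runs
    return out


def results_table(baseline: ScenarioResult,
                  interventions: dict[str, ScenarioResult]) -> pd.DataFrame:
    """Scenario x statistic table with rates, CIs, and percent decreases."""
    rows = []
    for stat in POPULATION_STATS:
        m, lo, hi = baseline.ci(stat)
        rows.append({"scenario": "baseline", "statistic": stat, "mean": m,
                     "ci_low": lo, "ci_high": hi, "pct_decrease": np.nan,
                     "pct_ci_low": np.nan, "pct_ci_high": np.nan})
    for label, res in interventions.items():
        pdec = percent_decrease(baseline, res).set_index("statistic")
        for stat in POPULATION_STATS:
            m, lo, hi = res.ci(stat)
            rows.append({
                "scenario": label, "statistic": stat, "mean": m,
                "ci_low": lo, "ci_high": hi,
                "pct_decrease": pdec.loc[stat, "pct_decrease"],
                "pct_ci_low": pdec.loc[stat, "ci_low"],
                "pct_ci_high": pdec.loc[stat, "ci_high"],
            })
    return pd.DataFrame(rows)
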