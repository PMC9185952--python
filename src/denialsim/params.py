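"""Model parameterization: coefficient tables, structural constants, targets.

Every behavior and outcome in the simulator is governed by a logistic
(logit-link) equation over agent, neighborhood, and event features.  A
:class:`ParameterSet` bundles all coefficient tables together with the
structural constants of the model (population size, grid geometry, social
network settings, interaction radii, mortality schedule, demographic
marginals) and is the single object the simulator consumes.

The bundled default parameterization is synthetic: the survey-derived
regression coefficients behind the original model were never published, so
the defaults encode the documented qualitative structure (signs and rough
magnitudes of the predictors for each outcome) and leave the levels to the
calibration module, which tunes intercepts to the empirical rate targets.
"""

from __future__ import annotations

import copy
import hashlib
import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Feature registry
# --------------------------------------------------------------------------

#: Agent/neighborhood-level predictors a coefficient table may reference.
FEATURE_NAMES: tuple[str, ...] = (
    "age_std",
    "young_adult",
    "male",
    "race_black",
    "race_hispanic",
    "race_other",
    "income_low",
    "income_high",
    "educ_low",
    "educ_high",
    "partnered",
    "drinking_light",
    "drinking_heavy",
    "aud",
    "drug_use",
    "dud",
    "asb",
    "gad",
    "ied",
    "mdd",
    "mania",
    "ptsd",
    "psychosis",
    "mh_treatment",
    "ideation_history",
    "attempt_history",
    "owns_firearm",
    "carries_firearm",
    "ownership_history",
    "carrying_history",
    "victimization_history",
    "perpetration_history",
    "victimized_last_year",
    "ipv_victimization_history",
    "ipv_perpetration_history",
    "arrest_history_violent",
    "arrest_history_alcohol",
    "arrest_history_drug",
    "arrest_history_other",
    "any_arrest_history",
    "residence_short",
    "neighborhood_violence",
    "neighborhood_group",
)

#: Additional predictors available only to event-level tables
#: (misdemeanor/felony split, conviction, incarceration).
EVENT_FEATURE_NAMES: tuple[str, ...] = (
    "arrest_type_violent",
    "arrest_type_alcohol",
    "arrest_type_drug",
    "arrest_type_other",
    "charge_felony",
)

ALL_PREDICTORS = frozenset(FEATURE_NAMES) | frozenset(EVENT_FEATURE_NAMES)

#: Every outcome equation the simulator consumes.  The validator fails on
#: any omission.
REQUIRED_TABLES: tuple[str, ...] = (
    "ownership",
    "carrying",
    "drinking_light",
    "drinking_heavy",
    "alcohol_use_disorder",
    "drug_use",
    "drug_use_disorder",
    "asb",
    "gad",
    "ied",
    "mdd",
    "mania",
    "ptsd",
    "psychosis",
    "mh_treatment",
    "suicidal_ideation",
    "suicide_attempt",
    "suicide_death",
    "victimization",
    "perpetration",
    "ipv_victimization",
    "ipv_perpetration",
    "homicide_victim_potential",
    "movement",
    "arrest_violent",
    "arrest_alcohol",
    "arrest_drug",
    "arrest_other",
    "misdemeanor_split",
    "conviction",
    "incarceration",
)

ARREST_TYPES: tuple[str, ...] = ("violent", "alcohol", "drug", "other")

#: Statistic names the calibration/experiment layer computes.
STATISTIC_NAMES: tuple[str, ...] = (
    "firearm_homicide",
    "firearm_suicide",
    "alcohol_misdemeanor_conviction",
    "alcohol_arrest",
    "drug_misdemeanor_conviction",
    "drug_arrest",
    "ownership_pct",
    "carrying_pct",
)

FULL_POPULATION = 800_000
DEFAULT_NEIGHBORHOODS = 59
#: Target agent density per grid cell; the grid scales with the population so
#: that interaction radii (in cells) mean the same thing at every scale.
CELL_DENSITY = 5.0


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class ValidationError(ValueError):
    """A ParameterSet or config file violates the schema."""


# --------------------------------------------------------------------------
# Coefficient tables
# --------------------------------------------------------------------------


@dataclass
class CoefficientTable:
    """Logistic model for one outcome: P = expit(intercept + sum c_j x_j)."""

    outcome: str
    intercept: float
    terms: list[tuple[str, float]] = field(default_factory=list)

    def validate(self, extra_predictors: frozenset[str] = frozenset()) -> None:
        if not np.isfinite(self.intercept):
            raise ValidationError(f"table '{self.outcome}': non-finite intercept")
        seen = set()
        allowed = ALL_PREDICTORS | extra_predictors
        for name, coef in self.terms:
            if name not in allowed:
                raise ValidationError(
                    f"table '{self.outcome}': unknown predictor '{name}'"
                )
            if name in seen:
                raise ValidationError(
                    f"table '{self.outcome}': duplicate predictor '{name}'"
                )
            if not np.isfinite(coef):
                raise ValidationError(
                    f"table '{self.outcome}': non-finite coefficient for '{name}'"
                )
            seen.add(name)

    def linpred(self, features: dict[str, np.ndarray], offset: float = 0.0):
        """Linear predictor over a feature dict of equal-length arrays."""
        out = None
        for name, coef in self.terms:
            contrib = coef * features[name]
            out = contrib if out is None else out + contrib
        base = self.intercept + offset
        if out is None:
            n = len(next(iter(features.values()))) if features else 1
            return np.full(n, base)
        return out + base

    def prob(self, features: dict[str, np.ndarray], offset: float = 0.0):
        return sigmoid(self.linpred(features, offset))

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "terms": [[n, float(c)] for n, c in self.terms],
        }

    @classmethod
    def from_dict(cls, outcome: str, d: dict) -> "CoefficientTable":
        unknown = set(d) - {"intercept", "terms"}
        if unknown:
            raise ValidationError(
                f"table '{outcome}': unknown keys {sorted(unknown)}"
            )
        try:
            intercept = float(d["intercept"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"table '{outcome}': bad intercept") from exc
        terms = [(str(n), float(c)) for n, c in d.get("terms", [])]
        return cls(outcome=outcome, intercept=intercept, terms=terms)


# --------------------------------------------------------------------------
# Calibration targets
# --------------------------------------------------------------------------


@dataclass
class CalibrationTargetSet:
    """Empirical rate/prevalence targets the calibrated model must match.

    ``entries`` maps a statistic name to ``(target_value, tolerance)`` where
    rates are per 100,000 person-years and prevalences are percent; the
    tolerance is a relative fraction.
    """

    entries: list[tuple[str, float, float]]

    def validate(self) -> None:
        for name, value, tol in self.entries:
            if name not in STATISTIC_NAMES:
                raise ValidationError(f"unknown calibration statistic '{name}'")
            if not value > 0:
                raise ValidationError(f"target '{name}': value must be > 0")
            if not (0 < tol < 1):
                raise ValidationError(f"target '{name}': tolerance not in (0,1)")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {n: (v, t) for n, v, t in self.entries}


#: Empirical annualized estimates the original model was calibrated against
#: (vital statistics for firearm deaths, state criminal-justice data for
#: arrests/convictions, national survey data for ownership and carrying).
EMPIRICAL_TARGETS: dict[str, float] = {
    "firearm_homicide": 3.96,
    "firearm_suicide": 0.98,
    "alcohol_misdemeanor_conviction": 116.1,
    "alcohol_arrest": 134.9,
    "drug_misdemeanor_conviction": 525.7,
    "drug_arrest": 1329.1,
    "ownership_pct": 22.03,
    "carrying_pct": 3.94,
}


def default_targets(tolerance: float = 0.02) -> CalibrationTargetSet:
    ts = CalibrationTargetSet(
        entries=[(n, v, tolerance) for n, v in EMPIRICAL_TARGETS.items()]
    )
    ts.validate()
    return ts


# --------------------------------------------------------------------------
# ParameterSet
# --------------------------------------------------------------------------

_MARGINAL_KEYS = ("sex_male", "race", "income", "education", "marital", "age_decay")


@dataclass
class ParameterSet:
    """Everything the simulator consumes.

    Scalar structural constants, demographic marginals, the mortality
    schedule, homophily weights, and one :class:`CoefficientTable` per
    outcome equation.
    """

    population_size: int = FULL_POPULATION
    scale: float = 1.0
    n_neighborhoods: int = DEFAULT_NEIGHBORHOODS
    grid_width: int = 400
    grid_height: int = 400
    degree_min: int = 1
    degree_max: int = 9
    network_influence_weight: float = 0.15
    police_per_neighborhood: int = 2
    perp_search_radius: int = 15
    police_protection_radius: int = 2
    burn_in: int = 10
    seed: int = 0
    distance_metric: str = "chebyshev"
    #: count a death as firearm-related when only the victim had access
    #: (the attribution convention of this model family; configurable off).
    victim_access_counts: bool = True
    #: "two events within a 5-year period": max year gap, inclusive.
    two_event_max_gap: int = 4
    sentence_mean_extra_years: float = 1.0
    homophily_weights: dict[str, float] = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)
    #: rows of [age, q_female, q_male]; annual all-cause death probability.
    mortality_table: list[list[float]] = field(default_factory=list)
    conviction_type_offsets: dict[str, float] = field(default_factory=dict)
    tables: dict[str, CoefficientTable] = field(default_factory=dict)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.population_size < 1:
            raise ValidationError("population_size must be >= 1")
        if self.n_neighborhoods < 1:
            raise ValidationError("n_neighborhoods must be >= 1")
        if not (0 < self.scale <= 1):
            raise ValidationError("scale must be in (0, 1]")
        if self.grid_width < 1 or self.grid_height < 1:
            raise ValidationError("grid dimensions must be positive")
        if not (1 <= self.degree_min <= self.degree_max):
            raise ValidationError("degree range must satisfy 1 <= min <= max")
        if self.perp_search_radius < 0 or self.police_protection_radius < 0:
            raise ValidationError("interaction radii must be >= 0")
        if self.burn_in < 0:
            raise ValidationError("burn_in must be >= 0")
        if self.distance_metric not in ("chebyshev", "euclidean"):
            raise ValidationError("distance_metric must be chebyshev|euclidean")
        missing = [t for t in REQUIRED_TABLES if t not in self.tables]
        if missing:
            raise ValidationError(f"missing coefficient tables: {missing}")
        unknown = [t for t in self.tables if t not in REQUIRED_TABLES]
        if unknown:
            raise ValidationError(f"unknown coefficient tables: {unknown}")
        for t in self.tables.values():
            t.validate()
        for k in self.conviction_type_offsets:
            if k not in ARREST_TYPES:
                raise ValidationError(f"conviction offset for unknown type '{k}'")
        for w in self.homophily_weights.values():
            if w < 0 or not np.isfinite(w):
                raise ValidationError("homophily weights must be finite and >= 0")
        if not self.mortality_table:
            raise ValidationError("mortality_table is empty")
        for row in self.mortality_table:
            if len(row) != 3 or not all(np.isfinite(v) for v in row):
                raise ValidationError("mortality_table rows must be [age, qf, qm]")
            if not (0 <= row[1] <= 1 and 0 <= row[2] <= 1):
                raise ValidationError("mortality probabilities must be in [0,1]")

    # -- derived -----------------------------------------------------------

    def mortality_arrays(self) -> tuple[np.ndarray, np.ndarray, int]:
        """(q_female, q_male) indexed by age - min_age, plus min_age."""
        tab = np.asarray(self.mortality_table, dtype=float)
        ages = tab[:, 0].astype(int)
        min_age = int(ages.min())
        size = int(ages.max()) - min_age + 1
        qf = np.zeros(size)
        qm = np.zeros(size)
        qf[ages - min_age] = tab[:, 1]
        qm[ages - min_age] = tab[:, 2]
        return qf, qm, min_age

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "population_size": int(self.population_size),
            "scale": float(self.scale),
            "n_neighborhoods": int(self.n_neighborhoods),
            "grid_width": int(self.grid_width),
            "grid_height": int(self.grid_height),
            "degree_min": int(self.degree_min),
            "degree_max": int(self.degree_max),
            "network_influence_weight": float(self.network_influence_weight),
            "police_per_neighborhood": int(self.police_per_neighborhood),
            "perp_search_radius": int(self.perp_search_radius),
            "police_protection_radius": int(self.police_protection_radius),
            "burn_in": int(self.burn_in),
            "seed": int(self.seed),
            "distance_metric": self.distance_metric,
            "victim_access_counts": bool(self.victim_access_counts),
            "two_event_max_gap": int(self.two_event_max_gap),
            "sentence_mean_extra_years": float(self.sentence_mean_extra_years),
            "homophily_weights": {k: float(v) for k, v in sorted(self.homophily_weights.items())},
            "demographics": self.demographics,
            "mortality_table": [[float(v) for v in row] for row in self.mortality_table],
            "conviction_type_offsets": {k: float(v) for k, v in sorted(self.conviction_type_offsets.items())},
            "tables": {name: self.tables[name].to_dict() for name in sorted(self.tables)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        defaults = default_parameter_set().to_dict()
        unknown = set(d) - set(defaults)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(defaults)
        for k in d:
            merged[k] = d[k]
        missing = set(defaults) - set(d)
        if missing:
            logger.info("config: filling missing keys from defaults: %s", sorted(missing))
        tables = {
            name: CoefficientTable.from_dict(name, td)
            for name, td in merged["tables"].items()
        }
        kwargs = {k: v for k, v in merged.items() if k != "tables"}
        ps = cls(tables=tables, **kwargs)
        ps.validate()
        return ps

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ParameterSet":
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ValidationError("config root must be a mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def tables_to_csv(self) -> str:
        """All coefficient tables as 'outcome,predictor,coefficient' CSV."""
        buf = io.StringIO()
        buf.write("outcome,predictor,coefficient\n")
        for name in sorted(self.tables):
            t = self.tables[name]
            buf.write(f"{name},__intercept__,{t.intercept!r}\n")
            for pred, coef in t.terms:
                buf.write(f"{name},{pred},{coef!r}\n")
        return buf.getvalue()

    @staticmethod
    def tables_from_csv(text: str) -> dict[str, CoefficientTable]:
        tables: dict[str, CoefficientTable] = {}
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        if lines and lines[0].startswith("outcome,"):
            lines = lines[1:]
        for ln in lines:
            outcome, pred, coef = ln.split(",")
            coef = float(coef)
            if outcome not in tables:
                tables[outcome] = CoefficientTable(outcome, 0.0, [])
            if pred == "__intercept__":
                tables[outcome].intercept = coef
            else:
                tables[outcome].terms.append((pred, coef))
        return tables


def save_parameters(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(params.to_yaml())


def load_parameters(path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML config file."""
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ValidationError(f"config root of {path} must be a mapping")
    return ParameterSet.from_dict(d)


# --------------------------------------------------------------------------
# Bundled default parameterization
# --------------------------------------------------------------------------


def _default_mortality_table() -> list[list[float]]:
    # Smooth synthetic Gompertz schedule over init age range and beyond;
    # crude adult death rate comes out near 1.2%/year.
    rows = []
    b = 0.070
    for age in range(18, 111):
        qf = min(0.5, 0.00040 * math.exp(b * (age - 18)))
        qm = min(0.5, 0.00065 * math.exp(b * (age - 18)))
        rows.append([float(age), qf, qm])
    return rows


def _default_demographics() -> dict:
    return {
        "sex_male": 0.48,
        # white, black, hispanic, other
        "race": [0.33, 0.23, 0.29, 0.15],
        # low, mid, high
        "income": [0.30, 0.45, 0.25],
        # less than HS, HS/some college, college+
        "education": [0.22, 0.45, 0.33],
        # single, partnered, other (divorced/widowed)
        "marital": [0.38, 0.47, 0.15],
        # ages 18..84 weighted ~ exp(-age_decay * (age-18))
        "age_decay": 0.018,
    }


def _T(outcome: str, p0: float, *terms: tuple[str, float]) -> CoefficientTable:
    return CoefficientTable(outcome, logit(p0), list(terms))


def _default_tables() -> dict[str, CoefficientTable]:
    t: dict[str, CoefficientTable] = {}
    # Firearm states.  Ownership history makes ownership sticky; current
    # ownership is the strongest carrying predictor (illicit carrying exists
    # without ownership).  Pre-calibration levels sit near 22% / 4%.
    # Ownership is an entry/exit persistence process: last year's ownership
    # dominates, with a small extra effect of ever-ownership; the stationary
    # prevalence responds smoothly to the calibrated intercept.
    t["ownership"] = _T(
        "ownership", 0.036,
        ("owns_firearm", 4.6), ("ownership_history", 0.3), ("male", 0.5),
        ("age_std", 0.2), ("income_high", 0.3), ("perpetration_history", 0.3),
    )
    t["carrying"] = _T(
        "carrying", 0.009,
        ("owns_firearm", 1.6), ("carries_firearm", 2.2),
        ("carrying_history", 0.3), ("male", 0.6),
        ("young_adult", 0.4), ("drug_use", 0.5), ("perpetration_history", 0.6),
    )
    # Substance use.  AUD/DUD tables are conditional on current drinker/user.
    t["drinking_light"] = _T(
        "drinking_light", 0.50,
        ("male", 0.15), ("educ_high", 0.25), ("age_std", -0.10),
    )
    t["drinking_heavy"] = _T(
        "drinking_heavy", 0.055,
        ("male", 0.55), ("young_adult", 0.30), ("aud", 1.40),
        ("victimization_history", 0.20), ("drug_use", 0.40),
    )
    t["alcohol_use_disorder"] = _T(
        "alcohol_use_disorder", 0.055,
        ("drinking_heavy", 1.8), ("male", 0.4), ("young_adult", 0.3),
        ("aud", 1.6), ("arrest_history_alcohol", 0.6),
    )
    t["drug_use"] = _T(
        "drug_use", 0.055,
        ("young_adult", 0.45), ("male", 0.30), ("drinking_heavy", 0.60),
        ("dud", 1.70), ("drug_use", 1.20), ("arrest_history_drug", 0.70),
    )
    t["drug_use_disorder"] = _T(
        "drug_use_disorder", 0.16,
        ("drinking_heavy", 0.3), ("dud", 1.7), ("young_adult", 0.2),
    )
    # Seven mental disorders, chronic via self-persistence terms.
    t["asb"] = _T("asb", 0.012, ("male", 0.7), ("young_adult", 0.4), ("asb", 2.4))
    t["gad"] = _T("gad", 0.022, ("male", -0.3), ("victimization_history", 0.4), ("gad", 2.4))
    t["ied"] = _T("ied", 0.014, ("male", 0.3), ("young_adult", 0.3), ("ied", 2.4))
    t["mdd"] = _T(
        "mdd", 0.035,
        ("male", -0.4), ("victimization_history", 0.4), ("aud", 0.4), ("mdd", 2.4),
    )
    t["mania"] = _T("mania", 0.007, ("young_adult", 0.2), ("mania", 2.6))
    t["ptsd"] = _T(
        "ptsd", 0.018,
        ("male", -0.3), ("victimization_history", 0.8),
        ("ipv_victimization_history", 0.5), ("ptsd", 2.5),
    )
    t["psychosis"] = _T("psychosis", 0.004, ("drug_use", 0.5), ("psychosis", 2.8))
    t["mh_treatment"] = _T(
        "mh_treatment", 0.05,
        ("mdd", 1.0), ("gad", 0.8), ("psychosis", 1.2),
        ("attempt_history", 1.0), ("income_high", 0.3),
    )
    # Suicidality.  Ideation/attempt respond to current firearm states; the
    # death equation follows the documented predictor list (demographics,
    # drug use, heavy drinking) plus suicidality history.
    t["suicidal_ideation"] = _T(
        "suicidal_ideation", 0.018,
        ("mdd", 1.2), ("ptsd", 0.5), ("aud", 0.6), ("dud", 0.7),
        ("owns_firearm", 0.25), ("carries_firearm", 0.25),
        ("victimized_last_year", 0.5), ("ideation_history", 1.6),
    )
    t["suicide_attempt"] = _T(
        "suicide_attempt", 0.0035,
        ("ideation_history", 2.1), ("mdd", 0.8), ("dud", 0.8),
        ("attempt_history", 1.6), ("owns_firearm", 0.2),
    )
    # Completed suicide: demographic and substance predictors plus
    # suicidality history, with a strong lethal-means term — ready access
    # to a firearm (owning, and to a lesser degree carrying) raises the
    # probability that suicidality ends in death.
    t["suicide_death"] = _T(
        "suicide_death", 6e-6,
        ("attempt_history", 2.0), ("ideation_history", 1.1), ("mdd", 0.8),
        ("dud", 1.1), ("aud", 0.9), ("drinking_heavy", 0.7),
        ("drug_use", 0.8), ("male", 0.6),
        ("owns_firearm", 1.0), ("carries_firearm", 0.5),
    )
    # Interpersonal violence risk sets.
    # Involvement raises future risk (re-victimization/re-perpetration), but
    # the feedback is kept weak enough that, against mortality churn, the
    # population incidence settles near 1.5 per 100 per year.
    t["victimization"] = _T(
        "victimization", 0.009,
        ("young_adult", 0.4), ("male", 0.3), ("drug_use", 0.5),
        ("drinking_heavy", 0.4), ("carries_firearm", 0.3),
        ("victimization_history", 0.35), ("perpetration_history", 0.2),
        ("income_low", 0.3), ("neighborhood_violence", 0.1),
    )
    t["perpetration"] = _T(
        "perpetration", 0.007,
        ("male", 0.7), ("young_adult", 0.5), ("asb", 0.8), ("ied", 0.6),
        ("drug_use", 0.5), ("drinking_heavy", 0.5),
        ("perpetration_history", 0.45), ("victimization_history", 0.2),
        ("any_arrest_history", 0.25), ("carries_firearm", 0.4),
        ("neighborhood_violence", 0.1),
    )
    t["ipv_victimization"] = _T(
        "ipv_victimization", 0.006,
        ("male", -0.4), ("drinking_heavy", 0.4), ("ipv_victimization_history", 1.5),
    )
    t["ipv_perpetration"] = _T(
        "ipv_perpetration", 0.005,
        ("male", 0.4), ("drinking_heavy", 0.6), ("aud", 0.5),
        ("asb", 0.6), ("ipv_perpetration_history", 1.5),
    )
    # Probability a matched violence victim dies (homicide potential),
    # following the documented demographic + substance predictors.
    t["homicide_victim_potential"] = _T(
        "homicide_victim_potential", 0.0016,
        ("male", 0.6), ("young_adult", 0.4), ("race_black", 0.3),
        ("drug_use", 0.6), ("drinking_heavy", 0.5),
    )
    t["movement"] = _T(
        "movement", 0.035,
        ("income_low", 0.2), ("income_high", -0.1),
        ("residence_short", 0.5), ("victimized_last_year", 0.8),
    )
    # Justice.  Arrest equations put most of the mass on current users, so
    # substance-related denial criteria select a genuinely high-risk group.
    t["arrest_violent"] = _T(
        "arrest_violent", 0.0025,
        ("male", 0.7), ("young_adult", 0.4), ("perpetration_history", 1.1),
        ("arrest_history_violent", 1.2), ("drug_use", 0.5),
        ("drinking_heavy", 0.4), ("asb", 0.5),
    )
    t["arrest_alcohol"] = _T(
        "arrest_alcohol", 0.00045,
        ("drinking_heavy", 1.6), ("aud", 1.2), ("male", 0.5),
        ("young_adult", 0.3), ("arrest_history_alcohol", 1.5),
    )
    t["arrest_drug"] = _T(
        "arrest_drug", 0.0020,
        ("drug_use", 2.2), ("dud", 1.0), ("male", 0.5), ("young_adult", 0.4),
        ("race_black", 0.4), ("income_low", 0.3), ("arrest_history_drug", 1.5),
    )
    t["arrest_other"] = _T(
        "arrest_other", 0.012,
        ("male", 0.5), ("young_adult", 0.3), ("income_low", 0.3),
        ("any_arrest_history", 1.0),
    )
    # Event-level: charge class by arrest type, conviction, incarceration.
    t["misdemeanor_split"] = CoefficientTable(
        "misdemeanor_split", 0.0,
        [
            ("arrest_type_alcohol", 2.94),   # ~0.95 misdemeanor
            ("arrest_type_drug", 0.62),      # ~0.65
            ("arrest_type_violent", -0.20),  # ~0.45
            ("arrest_type_other", 1.39),     # ~0.80
        ],
    )
    t["conviction"] = CoefficientTable(
        "conviction", 0.0,
        [
            ("race_black", 0.20), ("male", 0.10), ("age_std", -0.10),
            ("neighborhood_group", 0.05), ("charge_felony", -0.20),
        ],
    )
    t["incarceration"] = _T(
        "incarceration", 0.5,
        ("arrest_type_violent", 0.5), ("any_arrest_history", 0.2),
    )
    return t


def rescale(params: ParameterSet, scale: float) -> ParameterSet:
    """Copy of ``params`` at a different population scale.

    The grid shrinks with the square root of the scale so cell density —
    and with it the meaning of the interaction radii — is preserved; all
    reported statistics are rates, so results are comparable across scales
    up to Monte-Carlo noise.
    """
    if not (0 < scale <= 1):
        raise ValidationError("scale must be in (0, 1]")
    out = params.copy()
    out.scale = float(scale)
    out.population_size = int(round(FULL_POPULATION * scale))
    side = max(20, int(round(math.sqrt(out.population_size / CELL_DENSITY))))
    out.grid_width = out.grid_height = side
    out.validate()
    return out


def default_parameter_set(seed: int = 0, scale: float = 1.0) -> ParameterSet:
    """Complete self-consistent default parameterization.

    Structural constants: tie degrees U{1..9}, perpetrator search radius
    15 cells, police protection radius 2 cells, 59 neighborhoods, 800,000
    agents at scale 1; the grid shrinks with ``scale`` so cell density, and
    hence radius semantics, stay fixed.  Deterministic given ``seed``.
    """
    if not (0 < scale <= 1):
        raise ValidationError("scale must be in (0, 1]")
    pop = int(round(FULL_POPULATION * scale))
    side = max(20, int(round(math.sqrt(pop / CELL_DENSITY))))
    ps = ParameterSet(
        population_size=pop,
        scale=float(scale),
        grid_width=side,
        grid_height=side,
        seed=int(seed),
        homophily_weights={
            "age": 1.0,
            "sex": 0.5,
            "race": 1.0,
            "education": 0.5,
            "ownership": 1.5,
            "drinking": 0.5,
            "drug_use": 0.5,
            "proximity": 1.5,
        },
        demographics=_default_demographics(),
        mortality_table=_default_mortality_table(),
        # initial per-type conviction offsets; calibration refines alcohol/drug
        conviction_type_offsets={"violent": 0.6, "alcohol": 2.3, "drug": 0.45, "other": 0.8},
        tables=_default_tables(),
    )
    ps.validate()
    return ps
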