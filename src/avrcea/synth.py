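"""Synthetic-data generators with known ground truth.

Four input classes feed the analysis and its recovery tests:

* life tables from a Gompertz–Makeham hazard (optionally grouped into
  abridged-table 5-year death probabilities, the form in which national
  mortality schedules are published);
* patient-level cohorts with the covariates used for propensity matching,
  logistic treatment assignment, and gamma/beta cost/utility observations;
* greedy 1:1 nearest-neighbour propensity matching without replacement;
* study-level binomial event counts with between-study heterogeneity for
  the meta-analysis module.

Everything is reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.linear_model import LogisticRegression

from .errors import SingleArmCohortError, ValidationError
from .meta import StudyArmCounts
from .params import LifeTable, beta_from_moments, gamma_from_moments

MATCHING_COVARIATES = (
    "age",
    "sex_male",
    "severe",
    "euroscore2",
    "lvef",
    "concomitant",
    "nyha",
)


# ---------------------------------------------------------------------------
# life tables


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz–Makeham hazard h(x) = makeham_c + gompertz_a * exp(gompertz_b * x)."""

    gompertz_a: float
    gompertz_b: float = 0.0
    makeham_c: float = 0.0
    age_min: int = 60
    age_max: int = 100
    #: width of the age groups whose death probability is tabulated per single
    #: year of age; 1 gives a plain single-age table, 5 emulates an abridged
    #: (5-year) published schedule.
    group_width: int = 1

    def __post_init__(self) -> None:
        if self.gompertz_a <= 0 or self.gompertz_b < 0 or self.makeham_c < 0:
            raise ValidationError("hazard parameters must be nonnegative (a > 0)")
        if self.age_min >= self.age_max:
            raise ValidationError("age_min must be below age_max")
        if self.group_width < 1:
            raise ValidationError("group_width must be >= 1")

    def hazard(self, age: float) -> float:
        return self.makeham_c + self.gompertz_a * math.exp(self.gompertz_b * age)


#: Stand-in for the Thai national mortality schedule: Gompertz–Makeham
#: calibrated to Thai demography (annual q(65) ~ 0.0135, remaining life
#: expectancy at 65 ~ 19.5 years), tabulated as 5-year grouped death
#: probabilities the way abridged national life tables are published.
THAI_LIKE_SPEC = LifeTableSpec(
    gompertz_a=3.34e-5,
    gompertz_b=0.090,
    makeham_c=0.002,
    age_min=60,
    age_max=100,
    group_width=5,
)


def gen_life_table(spec: LifeTableSpec, seed: int | None = None) -> LifeTable:
    """Deterministic life table from a hazard spec (seed reserved for future noise).

    With ``group_width`` w > 1, q(a) is the w-year death probability of the
    age group containing a (groups anchored at ``age_min``), applied to each
    single year of age in the group.
    """
    del seed  # deterministic; kept for interface symmetry with the other generators
    q: dict[int, float] = {}
    w = spec.group_width
    for age in range(spec.age_min, spec.age_max + 1):
        g = spec.age_min + w * ((age - spec.age_min) // w)
        cum = sum(spec.hazard(g + i) for i in range(w))
        q[age] = 1.0 - math.exp(-cum)
        if q[age] > 0.999:
            warnings.warn(f"q({age}) = {q[age]:.4f} near 1", stacklevel=2)
    return LifeTable(q)


# ---------------------------------------------------------------------------
# cohorts and matching


@dataclass(frozen=True)
class CovariateEffects:
    """Log-odds coefficients of the treatment-assignment model."""

    age: float = 0.0
    sex_male: float = 0.0
    severe: float = 0.0
    euroscore2: float = 0.0
    lvef: float = 0.0
    concomitant: float = 0.0
    nyha: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in MATCHING_COVARIATES}


#: A confounded assignment mechanism used by the recovery tests: older,
#: higher-risk, lower-EF patients are more likely to receive SUAVR.
CONFOUNDED_EFFECTS = CovariateEffects(
    age=0.06, severe=0.5, euroscore2=0.25, lvef=-0.03, concomitant=0.4, nyha=0.3
)

_COST_CV = 0.4  # patient-level coefficient of variation of cost components
_UTILITY_SD = 0.12  # patient-level SD of observed utility

#: default arm-level means for the observed records (2022 THB / utility)
DEFAULT_VALVE_COST = {"SUAVR": 458_818.0, "CAVR": 137_186.0}
DEFAULT_UTILITY = {"SUAVR": 0.8276, "CAVR": 0.8470}


def gen_cohort(
    n_trt: int,
    n_ctl: int,
    effects: CovariateEffects | None = None,
    seed: int = 0,
    valve_cost_mean: dict[str, float] | None = None,
    utility_mean: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Two-arm synthetic surgical cohort with logistic treatment assignment.

    ``n_trt``/``n_ctl`` fix the expected arm sizes; the realized split is
    Bernoulli per patient with probability logistic(intercept + effects.x),
    the intercept calibrated so the expected treated fraction matches.
    Observed valve cost is gamma with the arm mean; observed utility is beta.
    """
    if n_trt <= 0 or n_ctl <= 0:
        raise ValidationError("arm sizes must be positive")
    effects = effects or CovariateEffects()
    valve_cost_mean = valve_cost_mean or DEFAULT_VALVE_COST
    utility_mean = utility_mean or DEFAULT_UTILITY
    n = n_trt + n_ctl
    rng = np.random.default_rng(seed)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": np.clip(rng.normal(70.0, 8.0, n), 40.0, 90.0),
            "sex_male": rng.binomial(1, 0.55, n),
            "severe": rng.binomial(1, 0.70, n),
            "euroscore2": rng.lognormal(0.8, 0.5, n),
            "lvef": np.clip(rng.normal(58.0, 10.0, n), 20.0, 75.0),
            "concomitant": rng.binomial(1, 0.35, n),
            "nyha": rng.choice([1, 2, 3, 4], size=n, p=[0.10, 0.45, 0.35, 0.10]),
        }
    )
    eff = effects.as_dict()
    lp = sum(eff[c] * df[c].to_numpy(float) for c in MATCHING_COVARIATES)
    lp = np.asarray(lp, dtype=float)
    target = n_trt / n

    def mean_prob(intercept: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(intercept + lp))))) - target

    intercept = brentq(mean_prob, -40.0, 40.0)
    p_trt = 1.0 / (1.0 + np.exp(-(intercept + lp)))
    treated = rng.random(n) < p_trt
    df["arm"] = np.where(treated, "SUAVR", "CAVR")

    cost = np.empty(n)
    util = np.empty(n)
    for arm in ("SUAVR", "CAVR"):
        mask = (df["arm"] == arm).to_numpy()
        m = valve_cost_mean[arm]
        shape, scale = gamma_from_moments(m, _COST_CV * m)
        cost[mask] = rng.gamma(shape, scale, mask.sum())
        a, b = beta_from_moments(utility_mean[arm], _UTILITY_SD)
        util[mask] = rng.beta(a, b, mask.sum())
    df["cost_valve"] = cost
    df["utility"] = util
    return df


@dataclass(frozen=True)
class MatchedPairs:
    """Greedy 1:1 matching result: (treated id, control id, |score diff|)."""

    pairs: Sequence[tuple[int, int, float]]
    unmatched_treated: Sequence[int] = field(default_factory=tuple)

    def treated_ids(self) -> list[int]:
        return [p[0] for p in self.pairs]

    def control_ids(self) -> list[int]:
        return [p[1] for p in self.pairs]


def greedy_match_scores(
    treated: dict[int, float], controls: dict[int, float]
) -> MatchedPairs:
    """Greedy nearest-neighbour matching without replacement on raw scores.

    Treated units are processed in descending propensity score; each takes
    the unused control with the smallest absolute score difference (ties
    broken toward the lower control id for determinism).
    """
    available = dict(controls)
    pairs: list[tuple[int, int, float]] = []
    unmatched: list[int] = []
    for tid in sorted(treated, key=lambda i: (-treated[i], i)):
        if not available:
            unmatched.append(tid)
            continue
        cid = min(available, key=lambda j: (abs(available[j] - treated[tid]), j))
        pairs.append((tid, cid, abs(available[cid] - treated[tid])))
        del available[cid]
    return MatchedPairs(pairs=tuple(pairs), unmatched_treated=tuple(unmatched))


def propensity_scores(
    cohort: pd.DataFrame, covariates: Sequence[str] = MATCHING_COVARIATES
) -> pd.Series:
    """Fitted treatment probabilities from an unpenalized logistic model."""
    arms = set(cohort["arm"])
    if arms != {"SUAVR", "CAVR"}:
        raise SingleArmCohortError(f"need both arms, got {sorted(arms)}")
    x = cohort[list(covariates)].to_numpy(float)
    y = (cohort["arm"] == "SUAVR").to_numpy(int)
    model = LogisticRegression(C=np.inf, max_iter=2000)  # unpenalized
    model.fit(x, y)
    return pd.Series(model.predict_proba(x)[:, 1], index=cohort["id"].to_numpy())


def propensity_match(
    cohort: pd.DataFrame, covariates: Sequence[str] = MATCHING_COVARIATES
) -> MatchedPairs:
    """Fit propensity scores and greedily match each treated to a control."""
    scores = propensity_scores(cohort, covariates)
    ids = cohort.set_index("id")
    treated = {int(i): float(scores[i]) for i in ids.index[ids["arm"] == "SUAVR"]}
    controls = {int(i): float(scores[i]) for i in ids.index[ids["arm"] == "CAVR"]}
    return greedy_match_scores(treated, controls)


def standardized_mean_differences(
    cohort: pd.DataFrame,
    pairs: MatchedPairs | None = None,
    covariates: Sequence[str] = MATCHING_COVARIATES,
) -> pd.Series:
    """Absolute standardized mean difference per covariate.

    With ``pairs``, restricted to the matched subsample; the pooled SD in the
    denominator always comes from the full cohort so matched and unmatched
    values are on the same scale.
    """
    full_t = cohort[cohort["arm"] == "SUAVR"]
    full_c = cohort[cohort["arm"] == "CAVR"]
    if pairs is None:
        sub_t, sub_c = full_t, full_c
    else:
        sub_t = cohort[cohort["id"].isin(pairs.treated_ids())]
        sub_c = cohort[cohort["id"].isin(pairs.control_ids())]
    out = {}
    for c in covariates:
        pooled_sd = math.sqrt(
            0.5 * (full_t[c].var(ddof=1) + full_c[c].var(ddof=1))
        )
        diff = abs(sub_t[c].mean() - sub_c[c].mean())
        out[c] = diff / pooled_sd if pooled_sd > 0 else 0.0
    return pd.Series(out)


# ---------------------------------------------------------------------------
# meta-analysis studies


def gen_meta_studies(
    k: int,
    true_rr: float,
    tau2: float,
    baseline_risk: float,
    arm_size: int = 150,
    seed: int = 0,
    size_dispersion: float = 0.4,
) -> list[StudyArmCounts]:
    """Study-level binomial counts under a random-effects relative-risk model.

    Each study draws log RR ~ Normal(ln(true_rr), tau2); treated risk above 1
    is capped at 0.99 with a warning.  Arm sizes are lognormal around
    ``arm_size`` (equal in both arms of a study).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not 0.0 < baseline_risk < 1.0:
        raise ValidationError("baseline risk must be in (0, 1)")
    if true_rr <= 0 or tau2 < 0:
        raise ValidationError("true_rr must be positive and tau2 nonnegative")
    rng = np.random.default_rng(seed)
    studies = []
    for _ in range(k):
        log_rr = rng.normal(math.log(true_rr), math.sqrt(tau2)) if tau2 > 0 else math.log(true_rr)
        p_trt = baseline_risk * math.exp(log_rr)
        if p_trt >= 1.0:
            warnings.warn(f"capping treated risk {p_trt:.3f} at 0.99", stacklevel=2)
            p_trt = 0.99
        n = max(10, int(round(rng.lognormal(math.log(arm_size), size_dispersion))))
        studies.append(
            StudyArmCounts(
                events_trt=int(rng.binomial(n, p_trt)),
                n_trt=n,
                events_ctl=int(rng.binomial(n, baseline_risk)),
                n_ctl=n,
            )
        )
    return studies
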