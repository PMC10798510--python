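"""Model parameters: domain types, CSV/YAML ingestion, and moment matching.

Every uncertain quantity enters the model as a :class:`PointEstimate` holding a
mean and a printed (low, high) range.  The range — not a standard error — is
what source tables report; the probabilistic analysis derives a standard error
from it through a configurable rule (default: treat the range as a 95% CI) and
moment-matches a beta (probabilities, utilities) or gamma (costs) distribution.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import (
    InfeasibleMomentsError,
    LifeTableGapError,
    MalformedValueError,
    MissingInputError,
    ValidationError,
)

ARMS = ("SUAVR", "CAVR")
STRATA = ("overall", "isolated", "combined")

#: Admission-phase direct medical cost components (accrued at surgery, t=0).
ADMISSION_COMPONENTS = (
    "valve",
    "valve_materials",
    "anesthesia_operation",
    "drugs",
    "labs",
    "hospital_stay",
    "imaging",
    "special_diagnosis",
    "instruments",
    "blood",
    "rehabilitation",
)

#: The six modelled complications, in the fixed order used everywhere.
COMPLICATIONS = ("stroke", "af", "bleed", "aki", "ppm", "pvl")

#: Direct non-medical cost components (societal perspective only).
NONMED_COMPONENTS = ("transport", "food", "accommodation", "informal_care")


@dataclass(frozen=True)
class PointEstimate:
    """A mean with its printed range and sampling-distribution family."""

    mean: float
    low: float
    high: float
    dist_kind: str  # "beta" | "gamma" | "fixed"
    units: str  # "probability" | "THB" | "utility"

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ValidationError(
                f"range must bracket the mean: {self.low} <= {self.mean} <= {self.high}"
            )
        if self.units in ("probability", "utility"):
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValidationError(
                    f"{self.units} out of [0, 1]: ({self.low}, {self.mean}, {self.high})"
                )
        elif self.units == "THB":
            if self.low < 0:
                raise ValidationError(f"cost must be nonnegative, got low={self.low}")
        else:
            raise ValidationError(f"unknown units {self.units!r}")
        if self.dist_kind not in ("beta", "gamma", "fixed"):
            raise ValidationError(f"unknown distribution {self.dist_kind!r}")

    def se(self, rule: str = "range_as_95ci", explicit: float | None = None) -> float:
        return se_from_bounds(self.mean, self.low, self.high, rule, explicit)


@dataclass(frozen=True)
class StratumTreeParams:
    """30-day decision-tree probabilities for one arm and AVR stratum."""

    p_complication: PointEstimate
    p_death_given_comp: PointEstimate
    p_death_given_nocomp: PointEstimate


@dataclass(frozen=True)
class AnnualOutcomeParams:
    """Pooled 1-year outcome probabilities (applied from the first cycle on)."""

    p_death_1y: PointEstimate
    p_stroke: PointEstimate
    p_af: PointEstimate
    p_bleed: PointEstimate
    p_aki: PointEstimate
    p_ppm: PointEstimate
    p_pvl: PointEstimate

    def complication_probs(self) -> dict[str, PointEstimate]:
        return {c: getattr(self, f"p_{c}") for c in COMPLICATIONS}


@dataclass(frozen=True)
class CostSet:
    """All cost parameters for one arm, 2022 THB.

    ``admission`` and ``nonmed_admission`` are one-off surgery-admission costs;
    the remaining groups accrue per alive (or complication-state) year.
    """

    admission: Mapping[str, PointEstimate]
    followup_outpatient: PointEstimate
    inpatient_complication: Mapping[str, PointEstimate]
    outpatient_complication: Mapping[str, PointEstimate]
    nonmed_admission: Mapping[str, PointEstimate]
    nonmed_followup: Mapping[str, PointEstimate]


@dataclass(frozen=True)
class UtilitySet:
    u_30d: PointEstimate
    u_1y: PointEstimate


@dataclass(frozen=True)
class ArmParameters:
    """Complete parameter set for one arm and stratum."""

    arm: str
    stratum: str
    tree: StratumTreeParams
    annual: AnnualOutcomeParams
    costs: CostSet
    utilities: UtilitySet


@dataclass(frozen=True)
class ModelConfig:
    start_age: int = 65
    cycle_length: float = 1.0
    max_age: int = 100
    discount_cost: float = 0.03
    discount_health: float = 0.03
    perspective: str = "societal"
    stratum: str = "overall"
    wtp: float = 160_000.0
    ppp: float = 11.72
    psa_iterations: int = 1000
    seed: int = 20220
    half_cycle: bool = False
    #: occupancy used for per-cycle accrual: "start", "end", or "half".
    accrual: str = "start"
    #: mortality for cycles >= 2: "combined" folds the pooled 1-year trial
    #: mortality into background mortality for life; "asmr_only" uses the life
    #: table alone; "max" takes the larger of the two.
    long_term_mortality: str = "combined"
    #: "u30d_first_cycle" applies the 30-day utility to the first Markov year
    #: (the year between the two measurements), "u1y_throughout" does not.
    utility_timing: str = "u30d_first_cycle"
    se_rule: str = "range_as_95ci"

    def __post_init__(self) -> None:
        if self.start_age >= self.max_age:
            raise ValidationError("start_age must be below max_age")
        for name in ("discount_cost", "discount_health", "wtp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.ppp <= 0:
            raise ValidationError("ppp must be positive")
        if self.perspective not in ("societal", "provider"):
            raise ValidationError(f"unknown perspective {self.perspective!r}")
        if self.stratum not in STRATA:
            raise ValidationError(f"unknown stratum {self.stratum!r}")
        if self.accrual not in ("start", "end", "half"):
            raise ValidationError(f"unknown accrual {self.accrual!r}")
        if self.long_term_mortality not in ("combined", "asmr_only", "max"):
            raise ValidationError(
                f"unknown long_term_mortality {self.long_term_mortality!r}"
            )
        if self.utility_timing not in ("u30d_first_cycle", "u1y_throughout"):
            raise ValidationError(f"unknown utility_timing {self.utility_timing!r}")
        if self.se_rule not in ("range_as_95ci", "range_as_pm20", "explicit"):
            raise ValidationError(f"unknown se_rule {self.se_rule!r}")

    def effective_accrual(self) -> str:
        return "half" if self.half_cycle else self.accrual

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


class LifeTable:
    """Annual death probabilities q(age) over a contiguous age range.

    Ages above the tabulated maximum reuse q(a_max); ages below the minimum
    raise :class:`LifeTableGapError`.
    """

    def __init__(self, q: Mapping[int, float]):
        if not q:
            raise MissingInputError("empty life table")
        ages = sorted(q)
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ValidationError("life-table ages must be contiguous")
        for a, v in q.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"q({a})={v} outside [0, 1]")
        self._q = {int(a): float(q[a]) for a in ages}
        self.age_min = ages[0]
        self.age_max = ages[-1]

    def q(self, age: float) -> float:
        a = int(age)
        if a < self.age_min:
            raise LifeTableGapError(
                f"age {a} below life-table minimum {self.age_min}"
            )
        return self._q[min(a, self.age_max)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": list(self._q), "qx": list(self._q.values())}
        )

    @classmethod
    def from_csv(cls, path: Path | str) -> "LifeTable":
        path = Path(path)
        if not path.exists():
            raise MissingInputError(f"life table not found: {path}")
        df = pd.read_csv(path, comment="#")
        for col in ("age", "qx"):
            if col not in df.columns:
                raise MissingInputError(f"life table missing column {col!r}")
        try:
            ages = df["age"].astype(int)
            qx = df["qx"].astype(float)
        except (TypeError, ValueError) as exc:
            raise MalformedValueError(f"non-numeric life-table entry: {exc}") from exc
        return cls(dict(zip(ages, qx)))


@dataclass(frozen=True)
class ParameterBundle:
    """Everything a model run needs: per-arm parameters, config, life table."""

    arms: Mapping[tuple[str, str], ArmParameters]  # keyed by (arm, stratum)
    config: ModelConfig
    life_table: LifeTable
    table: pd.DataFrame = field(repr=False, compare=False, default=None)

    def arm(self, arm: str, stratum: str | None = None) -> ArmParameters:
        stratum = stratum or self.config.stratum
        key = (arm, stratum)
        if key not in self.arms:
            raise MissingInputError(f"no parameters for arm={arm}, stratum={stratum}")
        return self.arms[key]


# ---------------------------------------------------------------------------
# moment matching


def se_from_bounds(
    mean: float,
    low: float,
    high: float,
    rule: str = "range_as_95ci",
    explicit: float | None = None,
) -> float:
    """Standard error implied by a printed (low, high) summary.

    ``range_as_95ci``: (high - low) / 3.92, i.e. the range is a 95% CI.
    ``range_as_pm20``: mean * 0.2 / 1.96, i.e. the range is mean +/- 20%
    interpreted as a 95% CI half-width.
    ``explicit``: pass ``explicit`` through unchanged.
    """
    if low > high:
        raise ValidationError(f"low {low} > high {high}")
    if rule == "range_as_95ci":
        return (high - low) / 3.92
    if rule == "range_as_pm20":
        return mean * 0.2 / 1.96
    if rule == "explicit":
        if explicit is None:
            raise MissingInputError("se_rule 'explicit' requires an explicit se")
        return float(explicit)
    raise ValidationError(f"unknown se rule {rule!r}")


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape pair (alpha, beta) reproducing ``mean`` and variance ``se**2``."""
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must be in (0, 1), got {mean}")
    var = se * se
    if var <= 0.0:
        raise InfeasibleMomentsError(f"beta requires positive variance, got se={se}")
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"variance {var} infeasible for beta with mean {mean}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) reproducing ``mean`` and variance ``se**2``."""
    if mean <= 0.0 or se <= 0.0:
        raise InfeasibleMomentsError(
            f"gamma requires positive mean and se, got ({mean}, {se})"
        )
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


# ---------------------------------------------------------------------------
# ingestion

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ModelConfig)}


def _package_data(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def default_config_path() -> Path:
    return _package_data("default_config.yaml")


def _read_config(path: Path) -> tuple[ModelConfig, Path, Path]:
    if not path.exists():
        raise MissingInputError(f"config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise MalformedValueError(f"config {path} is not a mapping")
    for key in ("parameters_csv", "life_table_csv"):
        if key not in raw:
            raise MissingInputError(f"config missing required key {key!r}")

    def _resolve(name: str) -> Path:
        p = Path(raw[name])
        if not p.is_absolute():
            cand = path.parent / p
            p = cand if cand.exists() else _package_data(str(p))
        return p

    params_path = _resolve("parameters_csv")
    lt_path = _resolve("life_table_csv")
    cfg_kw = {}
    for k, v in raw.items():
        if k in ("parameters_csv", "life_table_csv"):
            continue
        if k not in _CONFIG_FIELDS:
            raise MissingInputError(f"unknown config key {k!r}")
        cfg_kw[k] = v
    try:
        cfg = ModelConfig(**cfg_kw)
    except TypeError as exc:
        raise MalformedValueError(f"bad config value: {exc}") from exc
    return cfg, params_path, lt_path


def read_parameter_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"parameter table not found: {path}")
    df = pd.read_csv(path, dtype={"arm": str, "stratum": str, "name": str})
    required = {"arm", "stratum", "name", "mean", "low", "high", "dist", "units"}
    missing = required - set(df.columns)
    if missing:
        raise MissingInputError(f"parameter table missing columns {sorted(missing)}")
    for col in ("mean", "low", "high"):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise MalformedValueError(f"non-numeric {col!r} in {path}: {exc}") from exc
    if df["mean"].isna().any():
        bad = df.loc[df["mean"].isna(), "name"].tolist()
        raise MalformedValueError(f"missing mean for {bad}")
    return df


def _estimate(row: pd.Series) -> PointEstimate:
    return PointEstimate(
        mean=float(row["mean"]),
        low=float(row["low"]),
        high=float(row["high"]),
        dist_kind=str(row["dist"]),
        units=str(row["units"]),
    )


class _Lookup:
    def __init__(self, df: pd.DataFrame, arm: str):
        self._df = df
        self._arm = arm

    def get(self, name: str, stratum: str = "all") -> PointEstimate:
        mask = (
            self._df["name"].eq(name)
            & self._df["stratum"].eq(stratum)
            & self._df["arm"].isin([self._arm, "both"])
        )
        sub = self._df[mask]
        if len(sub) == 0:
            raise MissingInputError(
                f"parameter {name!r} missing for arm={self._arm}, stratum={stratum}"
            )
        if len(sub) > 1:
            raise ValidationError(f"duplicate rows for parameter {name!r}")
        return _estimate(sub.iloc[0])


def _build_arm(df: pd.DataFrame, arm: str, stratum: str) -> ArmParameters:
    lk = _Lookup(df, arm)
    tree = StratumTreeParams(
        p_complication=lk.get("p_complication", stratum),
        p_death_given_comp=lk.get("p_death_given_comp", stratum),
        p_death_given_nocomp=lk.get("p_death_given_nocomp", stratum),
    )
    annual = AnnualOutcomeParams(
        **{f"p_{c}": lk.get(f"p_{c}") for c in COMPLICATIONS},
        p_death_1y=lk.get("p_death_1y"),
    )
    costs = CostSet(
        admission={c: lk.get(f"cost_{c}") for c in ADMISSION_COMPONENTS},
        followup_outpatient=lk.get("cost_followup_outpatient"),
        inpatient_complication={c: lk.get(f"cost_inpatient_{c}") for c in COMPLICATIONS},
        outpatient_complication={c: lk.get(f"cost_outpatient_{c}") for c in COMPLICATIONS},
        nonmed_admission={c: lk.get(f"cost_nonmed_admission_{c}") for c in NONMED_COMPONENTS},
        nonmed_followup={c: lk.get(f"cost_nonmed_followup_{c}") for c in NONMED_COMPONENTS},
    )
    utilities = UtilitySet(u_30d=lk.get("u_30d"), u_1y=lk.get("u_1y"))
    return ArmParameters(arm=arm, stratum=stratum, tree=tree, annual=annual,
                         costs=costs, utilities=utilities)


def load_parameters(config_path: Path | str | None = None) -> ParameterBundle:
    """Load and validate the full parameter bundle referenced by a config file.

    With no argument, loads the packaged default configuration (the transcribed
    clinical/cost/utility tables, the bundled synthetic Thai life table, and
    base-case settings).
    """
    path = Path(config_path) if config_path else default_config_path()
    cfg, params_path, lt_path = _read_config(path)
    df = read_parameter_table(params_path)
    lt = LifeTable.from_csv(lt_path)
    if lt.age_min > cfg.start_age:
        raise LifeTableGapError(
            f"life table starts at {lt.age_min}, above start_age {cfg.start_age}"
        )
    arms = {
        (arm, stratum): _build_arm(df, arm, stratum)
        for arm in ARMS
        for stratum in STRATA
    }
    return ParameterBundle(arms=arms, config=cfg, life_table=lt, table=df)


def write_parameter_table(df: pd.DataFrame, path: Path | str) -> None:
    """Write a parameter table back to CSV (round-trips with the reader)."""
    cols = ["arm", "stratum", "name", "mean", "low", "high", "dist", "units"]
    df[cols].to_csv(path, index=False)


def sampling_distribution(est: PointEstimate, rule: str = "range_as_95ci"):
    """(kind, params) pair used by the PSA to draw this parameter.

    Degenerate estimates (zero range, or probability mass at 0/1) are fixed.
    """
    se = est.se(rule)
    if est.dist_kind == "fixed" or se == 0.0 or math.isclose(est.high, est.low):
        return "fixed", (est.mean,)
    if est.dist_kind == "beta":
        if est.mean <= 0.0 or est.mean >= 1.0:
            return "fixed", (est.mean,)
        return "beta", beta_from_moments(est.mean, se)
    if est.dist_kind == "gamma":
        if est.mean <= 0.0:
            return "fixed", (est.mean,)
        return "gamma", gamma_from_moments(est.mean, se)
    raise ValidationError(f"unknown distribution {est.dist_kind!r}")
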