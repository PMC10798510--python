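"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis varies each parameter over its deterministic
range and records the incremental net monetary benefit at the configured
willingness-to-pay; the INMB is used instead of the ICER because the base
case sits in a dominance quadrant where the ratio is undefined.  The
probabilistic analysis redraws every uncertain parameter from its
moment-matched beta or gamma distribution (costs shared between arms —
the e-Claim complication and follow-up costs — are drawn once per
iteration), yielding the cost-effectiveness plane and acceptability curves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .cea import ArmResult, Comparison, base_case, compare_arms, evaluate_arm, inmb
from .errors import InfeasibleMomentsError, MissingInputError
from .params import (
    ADMISSION_COMPONENTS,
    COMPLICATIONS,
    NONMED_COMPONENTS,
    ArmParameters,
    CostSet,
    ModelConfig,
    ParameterBundle,
    PointEstimate,
    sampling_distribution,
)

# Canonical parameter-slot order (determinism of PSA streams depends on it).
ARM_SLOTS = (
    ["p_complication", "p_death_given_comp", "p_death_given_nocomp"]
    + ["p_death_1y"]
    + [f"p_{c}" for c in COMPLICATIONS]
    + ["u_30d", "u_1y"]
    + [f"cost_{c}" for c in ADMISSION_COMPONENTS]
    + [f"cost_nonmed_admission_{c}" for c in NONMED_COMPONENTS]
    + [f"cost_nonmed_followup_{c}" for c in NONMED_COMPONENTS]
)
SHARED_SLOTS = (
    ["cost_followup_outpatient"]
    + [f"cost_inpatient_{c}" for c in COMPLICATIONS]
    + [f"cost_outpatient_{c}" for c in COMPLICATIONS]
)


def arm_estimates(arm: ArmParameters) -> dict[str, PointEstimate]:
    """Arm-specific estimates keyed by slot name, in canonical order."""
    out: dict[str, PointEstimate] = {
        "p_complication": arm.tree.p_complication,
        "p_death_given_comp": arm.tree.p_death_given_comp,
        "p_death_given_nocomp": arm.tree.p_death_given_nocomp,
        "p_death_1y": arm.annual.p_death_1y,
        "u_30d": arm.utilities.u_30d,
        "u_1y": arm.utilities.u_1y,
    }
    for c in COMPLICATIONS:
        out[f"p_{c}"] = getattr(arm.annual, f"p_{c}")
    for c in ADMISSION_COMPONENTS:
        out[f"cost_{c}"] = arm.costs.admission[c]
    for c in NONMED_COMPONENTS:
        out[f"cost_nonmed_admission_{c}"] = arm.costs.nonmed_admission[c]
        out[f"cost_nonmed_followup_{c}"] = arm.costs.nonmed_followup[c]
    return {k: out[k] for k in ARM_SLOTS}


def shared_estimates(arm: ArmParameters) -> dict[str, PointEstimate]:
    """Estimates common to both arms (e-Claim follow-up/complication costs)."""
    out = {"cost_followup_outpatient": arm.costs.followup_outpatient}
    for c in COMPLICATIONS:
        out[f"cost_inpatient_{c}"] = arm.costs.inpatient_complication[c]
        out[f"cost_outpatient_{c}"] = arm.costs.outpatient_complication[c]
    return {k: out[k] for k in SHARED_SLOTS}


def _with_mean(est: PointEstimate, mean: float) -> PointEstimate:
    return dataclasses.replace(
        est, mean=mean, low=min(est.low, mean), high=max(est.high, mean)
    )


def rebuild_arm(
    arm: ArmParameters,
    means: dict[str, float] | None = None,
    shared_means: dict[str, float] | None = None,
) -> ArmParameters:
    """Copy of ``arm`` with selected estimate means replaced."""
    means = means or {}
    shared_means = shared_means or {}

    def a(name: str) -> PointEstimate:
        est = arm_estimates(arm)[name]
        return _with_mean(est, means[name]) if name in means else est

    def s(name: str) -> PointEstimate:
        est = shared_estimates(arm)[name]
        return _with_mean(est, shared_means[name]) if name in shared_means else est

    tree = dataclasses.replace(
        arm.tree,
        p_complication=a("p_complication"),
        p_death_given_comp=a("p_death_given_comp"),
        p_death_given_nocomp=a("p_death_given_nocomp"),
    )
    annual = dataclasses.replace(
        arm.annual,
        p_death_1y=a("p_death_1y"),
        **{f"p_{c}": a(f"p_{c}") for c in COMPLICATIONS},
    )
    costs = CostSet(
        admission={c: a(f"cost_{c}") for c in ADMISSION_COMPONENTS},
        followup_outpatient=s("cost_followup_outpatient"),
        inpatient_complication={c: s(f"cost_inpatient_{c}") for c in COMPLICATIONS},
        outpatient_complication={c: s(f"cost_outpatient_{c}") for c in COMPLICATIONS},
        nonmed_admission={c: a(f"cost_nonmed_admission_{c}") for c in NONMED_COMPONENTS},
        nonmed_followup={c: a(f"cost_nonmed_followup_{c}") for c in NONMED_COMPONENTS},
    )
    utilities = dataclasses.replace(arm.utilities, u_30d=a("u_30d"), u_1y=a("u_1y"))
    return dataclasses.replace(arm, tree=tree, annual=annual, costs=costs,
                               utilities=utilities)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    outcome_at_low: float
    outcome_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _dsa_range(est: PointEstimate) -> tuple[float, float]:
    """Deterministic range: the parameter's printed range where one exists,
    otherwise probabilities +/-10% (clamped to [0, 1]) and costs +/-20%.
    Stated-exact (fixed) parameters are not varied."""
    if est.dist_kind == "fixed":
        return est.mean, est.mean
    if est.high > est.low:
        return est.low, est.high
    if est.units in ("probability", "utility"):
        return max(0.0, est.mean * 0.9), min(1.0, est.mean * 1.1)
    return est.mean * 0.8, est.mean * 1.2


def _inmb_for(
    bundle: ParameterBundle,
    config: ModelConfig,
    trt_means: dict[str, float],
    ctl_means: dict[str, float],
    shared_means: dict[str, float],
) -> float:
    trt = rebuild_arm(bundle.arm("SUAVR", config.stratum), trt_means, shared_means)
    ctl = rebuild_arm(bundle.arm("CAVR", config.stratum), ctl_means, shared_means)
    lt = bundle.life_table
    cmp = compare_arms(evaluate_arm(trt, lt, config), evaluate_arm(ctl, lt, config))
    return inmb(cmp, config.wtp)


def one_way_tornado(
    bundle: ParameterBundle, config: ModelConfig | None = None
) -> list[TornadoEntry]:
    """One-way sensitivity of the incremental NMB, sorted by descending spread.

    Varied: every arm-specific and shared parameter over its deterministic
    range, plus both discount rates over [0, 0.06].
    """
    config = config or bundle.config
    entries: list[TornadoEntry] = []
    trt = bundle.arm("SUAVR", config.stratum)
    ctl = bundle.arm("CAVR", config.stratum)

    for arm_label, arm in (("SUAVR", trt), ("CAVR", ctl)):
        for name, est in arm_estimates(arm).items():
            lo, hi = _dsa_range(est)
            out = []
            for v in (lo, hi):
                means = {name: v}
                out.append(
                    _inmb_for(
                        bundle,
                        config,
                        means if arm_label == "SUAVR" else {},
                        means if arm_label == "CAVR" else {},
                        {},
                    )
                )
            entries.append(TornadoEntry(f"{arm_label}:{name}", out[0], out[1]))
    for name, est in shared_estimates(trt).items():
        lo, hi = _dsa_range(est)
        out = [_inmb_for(bundle, config, {}, {}, {name: v}) for v in (lo, hi)]
        entries.append(TornadoEntry(f"shared:{name}", out[0], out[1]))
    for rate_field in ("discount_cost", "discount_health"):
        out = []
        for v in (0.0, 0.06):
            cfg = config.replace(**{rate_field: v})
            out.append(_inmb_for(bundle, cfg, {}, {}, {}))
        entries.append(TornadoEntry(f"config:{rate_field}", out[0], out[1]))

    entries.sort(key=lambda e: -e.spread)
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSASample:
    draw: int
    delta_cost: float
    delta_qaly: float


def _draw_means(
    estimates: dict[str, PointEstimate], rng: np.random.Generator, rule: str
) -> dict[str, float]:
    out = {}
    for name, est in estimates.items():
        try:
            kind, pars = sampling_distribution(est, rule)
        except InfeasibleMomentsError as exc:
            raise InfeasibleMomentsError(f"parameter {name!r}: {exc}") from exc
        if kind == "fixed":
            out[name] = pars[0]
        elif kind == "beta":
            out[name] = float(rng.beta(*pars))
        else:
            out[name] = float(rng.gamma(*pars))
    return out


def run_psa(
    bundle: ParameterBundle,
    config: ModelConfig | None = None,
    iterations: int | None = None,
    seed: int | None = None,
) -> list[PSASample]:
    """Monte Carlo propagation of parameter uncertainty.

    Per iteration, shared e-Claim costs are drawn once and applied to both
    arms; all arm-specific parameters are drawn independently.  Fully
    reproducible given the seed.
    """
    config = config or bundle.config
    n = iterations if iterations is not None else config.psa_iterations
    seed = seed if seed is not None else config.seed
    rng = np.random.default_rng(seed)
    rule = config.se_rule
    trt_base = bundle.arm("SUAVR", config.stratum)
    ctl_base = bundle.arm("CAVR", config.stratum)
    lt = bundle.life_table

    samples: list[PSASample] = []
    for i in range(n):
        shared = _draw_means(shared_estimates(trt_base), rng, rule)
        trt_means = _draw_means(arm_estimates(trt_base), rng, rule)
        ctl_means = _draw_means(arm_estimates(ctl_base), rng, rule)
        trt = rebuild_arm(trt_base, trt_means, shared)
        ctl = rebuild_arm(ctl_base, ctl_means, shared)
        r_t = evaluate_arm(trt, lt, config)
        r_c = evaluate_arm(ctl, lt, config)
        samples.append(
            PSASample(
                draw=i,
                delta_cost=r_t.total_cost - r_c.total_cost,
                delta_qaly=r_t.qaly - r_c.qaly,
            )
        )
    return samples


def quadrant_proportions(samples: Sequence[PSASample]) -> dict[str, float]:
    """Cost-effectiveness-plane quadrant proportions (x = dQALY, y = dCost).

    Boundary (exactly zero) deltas count toward the positive side, so e.g.
    the upper-left (NW) quadrant is dQALY < 0 and dCost >= 0.
    """
    if not samples:
        raise MissingInputError("quadrant_proportions requires samples")
    n = len(samples)
    counts = {"NE": 0, "NW": 0, "SW": 0, "SE": 0}
    for s in samples:
        east = s.delta_qaly >= 0.0
        north = s.delta_cost >= 0.0
        key = ("N" if north else "S") + ("E" if east else "W")
        counts[key] += 1
    return {k: v / n for k, v in counts.items()}


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    p_ce_trt: float
    p_ce_ctl: float


def ceac(
    samples: Sequence[PSASample], wtp_grid: Iterable[float]
) -> list[CEACPoint]:
    """Two-strategy cost-effectiveness acceptability curve.

    At each threshold the treatment's acceptability is the proportion of
    draws with nonnegative incremental NMB; the comparator's is its
    complement.
    """
    grid = list(wtp_grid)
    if not samples:
        raise MissingInputError("ceac requires samples")
    if not grid:
        raise MissingInputError("ceac requires a WTP grid")
    dq = np.array([s.delta_qaly for s in samples])
    dc = np.array([s.delta_cost for s in samples])
    points = []
    for w in grid:
        p = float(np.mean(w * dq - dc >= 0.0))
        points.append(CEACPoint(wtp=float(w), p_ce_trt=p, p_ce_ctl=1.0 - p))
    return points


# ---------------------------------------------------------------------------
# scenario: differential discounting


def scenario_discount(
    bundle: ParameterBundle,
    cost_rate: float = 0.062,
    health_rate: float = 0.013,
    stratum: str | None = None,
    perspective: str | None = None,
) -> tuple[ArmResult, ArmResult, Comparison]:
    """Re-run the base case with differential cost/health discount rates."""
    cfg = bundle.config.replace(discount_cost=cost_rate, discount_health=health_rate)
    scen_bundle = dataclasses.replace(bundle, config=cfg)
    return base_case(scen_bundle, stratum, perspective)
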