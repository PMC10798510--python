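"""Arm aggregation, incremental cost-effectiveness, dominance, and reporting."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import MismatchedComparisonError, ValidationError
from .markov import run_markov
from .params import ArmParameters, LifeTable, ModelConfig, ParameterBundle
from .tree import evaluate_acute


@dataclass(frozen=True)
class ArmResult:
    """Lifetime discounted totals for one strategy."""

    arm: str
    stratum: str
    perspective: str
    total_cost: float
    ly: float
    qaly: float

    def __post_init__(self) -> None:
        if self.total_cost < 0 or self.ly < 0 or self.qaly < 0:
            raise ValidationError("arm totals must be nonnegative")
        if self.qaly > self.ly + 1e-9:
            raise ValidationError("QALYs cannot exceed life-years")


@dataclass(frozen=True)
class Comparison:
    """Incremental results of treatment (SUAVR) vs control (CAVR)."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_ly: float | str
    icer_qaly: float | str
    classification: str  # "dominant" | "dominated" | "icer"


def evaluate_arm(
    arm: ArmParameters, lt: LifeTable, config: ModelConfig
) -> ArmResult:
    """Run tree + Markov for one arm and collect discounted totals."""
    acute = evaluate_acute(arm, config)
    trace = run_markov(acute, arm, lt, config)
    return ArmResult(
        arm=arm.arm,
        stratum=arm.stratum,
        perspective=config.perspective,
        total_cost=trace.totals.cost,
        ly=trace.totals.ly,
        qaly=trace.totals.qaly,
    )


def _ratio_or_label(delta_cost: float, delta_eff: float) -> float | str:
    if delta_eff > 0 and delta_cost <= 0:
        return "dominant"
    if delta_eff < 0 and delta_cost >= 0:
        return "dominated"
    if delta_eff == 0:
        return "dominated" if delta_cost > 0 else "dominant"
    return delta_cost / delta_eff

def compare_arms(trt: ArmResult, ctl: ArmResult) -> Comparison:
    """Incremental cost-effectiveness of ``trt`` over ``ctl``.

    An ICER ratio is reported only in the trade-off quadrants; strict
    dominance quadrants yield the label instead (negative ratios are not
    interpretable).
    """
    if trt.stratum != ctl.stratum or trt.perspective != ctl.perspective:
        raise MismatchedComparisonError(
            f"cannot compare {trt.stratum}/{trt.perspective} with "
            f"{ctl.stratum}/{ctl.perspective}"
        )
    d_cost = trt.total_cost - ctl.total_cost
    d_ly = trt.ly - ctl.ly
    d_qaly = trt.qaly - ctl.qaly
    if d_qaly < 0 and d_cost > 0:
        classification = "dominated"
    elif d_qaly > 0 and d_cost < 0:
        classification = "dominant"
    else:
        classification = "icer"
    return Comparison(
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_ly=_ratio_or_label(d_cost, d_ly),
        icer_qaly=_ratio_or_label(d_cost, d_qaly),
        classification=classification,
    )


def inmb(cmp: Comparison, wtp: float) -> float:
    """Incremental net monetary benefit: wtp * dQALY - dCost.

    Positive iff the treatment is cost-effective at the given threshold;
    defined in every quadrant, unlike the ICER.
    """
    if wtp < 0:
        raise ValidationError("willingness-to-pay must be nonnegative")
    return wtp * cmp.delta_qaly - cmp.delta_cost


def thb_to_usd(x: float, ppp: float = 11.72) -> int:
    """Convert 2022 THB to USD by the PPP factor, rounded half-up to integer."""
    if ppp <= 0:
        raise ValidationError("ppp must be positive")
    return int(math.floor(x / ppp + 0.5))


def base_case(
    bundle: ParameterBundle,
    stratum: str | None = None,
    perspective: str | None = None,
) -> tuple[ArmResult, ArmResult, Comparison]:
    """Evaluate both arms and compare SUAVR against CAVR."""
    config = bundle.config
    if stratum:
        config = config.replace(stratum=stratum)
    if perspective:
        config = config.replace(perspective=perspective)
    trt = evaluate_arm(bundle.arm("SUAVR", config.stratum), bundle.life_table, config)
    ctl = evaluate_arm(bundle.arm("CAVR", config.stratum), bundle.life_table, config)
    return trt, ctl, compare_arms(trt, ctl)


def _fmt_icer(v: float | str) -> str:
    return v.capitalize() if isinstance(v, str) else f"{v:,.0f}"


def report_frame(bundle: ParameterBundle) -> pd.DataFrame:
    """Base-case summary across strata and perspectives (one row per arm)."""
    ppp = bundle.config.ppp
    rows = []
    for perspective in ("societal", "provider"):
        for stratum in ("overall", "isolated", "combined"):
            trt, ctl, cmp = base_case(bundle, stratum, perspective)
            for res in (trt, ctl):
                rows.append(
                    {
                        "perspective": perspective,
                        "stratum": stratum,
                        "arm": res.arm,
                        "total_cost_thb": res.total_cost,
                        "total_cost_usd": thb_to_usd(res.total_cost, ppp),
                        "ly": res.ly,
                        "qaly": res.qaly,
                        "icer_per_ly": _fmt_icer(cmp.icer_ly) if res.arm == "SUAVR" else "",
                        "icer_per_qaly": _fmt_icer(cmp.icer_qaly) if res.arm == "SUAVR" else "",
                    }
                )
    return pd.DataFrame(rows)
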