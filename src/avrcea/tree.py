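"""30-day decision tree: the acute phase that seeds the Markov cohort.

Immediately after valve replacement the cohort splits on early complication
(stroke, AF, AKI, major bleeding, pacemaker implantation, paravalvular
leakage, pooled into a single branch) and on death conditional on that branch.
Survivors enter the Markov model in the matching health state; the whole
cohort — decedents included, since surgery precedes death — accrues the
admission costs at time zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .params import ArmParameters, ModelConfig

#: length of the acute window in years
ACUTE_YEARS = 30.0 / 365.25


@dataclass(frozen=True)
class AcuteOutcome:
    """Result of the 30-day tree: initial state split, acute cost and QALY."""

    p_alive_nocomp: float
    p_alive_comp: float
    p_dead30: float
    cost_acute: float
    qaly_acute: float

    def __post_init__(self) -> None:
        total = self.p_alive_nocomp + self.p_alive_comp + self.p_dead30
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"acute state split sums to {total}, not 1")
        if self.cost_acute < 0:
            raise ValidationError("acute cost must be nonnegative")
        if not 0.0 <= self.qaly_acute <= ACUTE_YEARS + 1e-12:
            raise ValidationError("acute QALY outside [0, 30/365.25]")

    @property
    def ly_acute(self) -> float:
        """Acute-window life-years: survivors credited with the full 30 days."""
        return (1.0 - self.p_dead30) * ACUTE_YEARS


def evaluate_acute(arm: ArmParameters, config: ModelConfig) -> AcuteOutcome:
    """Evaluate the four-branch tree for one arm under the configured perspective."""
    p_c = arm.tree.p_complication.mean
    p_d_c = arm.tree.p_death_given_comp.mean
    p_d_nc = arm.tree.p_death_given_nocomp.mean
    for name, p in (("p_complication", p_c), ("p_death_given_comp", p_d_c),
                    ("p_death_given_nocomp", p_d_nc)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name}={p} outside [0, 1]")

    p_dead30 = (1.0 - p_c) * p_d_nc + p_c * p_d_c
    p_alive_comp = p_c * (1.0 - p_d_c)
    p_alive_nocomp = (1.0 - p_c) * (1.0 - p_d_nc)

    cost = sum(e.mean for e in arm.costs.admission.values())
    if config.perspective == "societal":
        cost += sum(e.mean for e in arm.costs.nonmed_admission.values())

    qaly = arm.utilities.u_30d.mean * ACUTE_YEARS * (1.0 - p_dead30)
    return AcuteOutcome(
        p_alive_nocomp=p_alive_nocomp,
        p_alive_comp=p_alive_comp,
        p_dead30=p_dead30,
        cost_acute=cost,
        qaly_acute=qaly,
    )
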