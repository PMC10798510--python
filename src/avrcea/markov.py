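"""Lifetime three-state Markov cohort engine.

States: ``as_nocomp`` (alive, no complication so far), ``as_comp`` (alive,
has experienced at least one complication; absorbing among the alive states),
``dead`` (absorbing).  Cycles are annual.  The first cycle applies the pooled
1-year trial mortality; later cycles combine that carried-forward trial
mortality with age-specific background mortality from the life table (the
composition is configurable).  The pooled 1-year complication probability is
carried forward unchanged for the whole horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .params import COMPLICATIONS, ArmParameters, LifeTable, ModelConfig
from .tree import AcuteOutcome

STATES = ("as_nocomp", "as_comp", "dead")
_MASS_TOL = 1e-12
_ALIVE_EPS = 1e-10


def annual_death_prob(
    cycle: int,
    age: float,
    arm: ArmParameters,
    lt: LifeTable,
    mode: str = "combined",
) -> float:
    """Probability of dying during one cycle.

    Cycle 1 returns the arm's pooled 1-year trial mortality.  Later cycles
    depend on ``mode``: ``asmr_only`` uses the life table alone; ``combined``
    (default) folds the carried-forward trial mortality into background
    mortality, 1-(1-q_trial)(1-q_asmr); ``max`` takes the larger of the two.
    """
    if cycle < 1:
        raise ValidationError(f"cycle must be >= 1, got {cycle}")
    q_trial = arm.annual.p_death_1y.mean
    if cycle == 1:
        return q_trial
    q_asmr = lt.q(age)
    if mode == "asmr_only":
        return q_asmr
    if mode == "max":
        return max(q_trial, q_asmr)
    if mode == "combined":
        return 1.0 - (1.0 - q_trial) * (1.0 - q_asmr)
    raise ValidationError(f"unknown mortality mode {mode!r}")


def combined_complication_prob(arm: ArmParameters) -> float:
    """1 - product of complication-free probabilities over the six events."""
    prod = 1.0
    for c in COMPLICATIONS:
        p = arm.annual.complication_probs()[c].mean
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p_{c}={p} outside [0, 1]")
        prod *= 1.0 - p
    return 1.0 - prod


def build_transition(
    cycle: int,
    age: float,
    arm: ArmParameters,
    lt: LifeTable,
    config: ModelConfig,
) -> np.ndarray:
    """Row-stochastic 3x3 transition matrix for one cycle."""
    p_death = annual_death_prob(cycle, age, arm, lt, config.long_term_mortality)
    p_comp = combined_complication_prob(arm)
    t = np.zeros((3, 3))
    t[0, 2] = p_death
    t[0, 1] = (1.0 - p_death) * p_comp
    t[0, 0] = 1.0 - t[0, 1] - t[0, 2]
    t[1, 2] = p_death
    t[1, 1] = 1.0 - p_death
    t[2, 2] = 1.0
    return t


def expected_complication_cost(arm: ArmParameters, setting: str) -> float:
    """Probability-weighted mean complication cost (weights p_i / sum p_j).

    ``setting`` selects the inpatient (incident-event) or outpatient
    (chronic follow-up) cost column.
    """
    probs = {c: arm.annual.complication_probs()[c].mean for c in COMPLICATIONS}
    total_p = sum(probs.values())
    if total_p == 0.0:
        return 0.0
    costs = (
        arm.costs.inpatient_complication
        if setting == "inpatient"
        else arm.costs.outpatient_complication
    )
    return sum(probs[c] * costs[c].mean for c in COMPLICATIONS) / total_p


def cost_accrual(
    state: np.ndarray,
    incident_comp_mass: float,
    arm: ArmParameters,
    config: ModelConfig,
) -> float:
    """Undiscounted cost accrued over one cycle.

    ``state`` is the occupancy vector used for person-time accrual.  Every
    alive member accrues outpatient follow-up (plus non-medical follow-up
    costs under the societal perspective); the mass newly entering the
    complication state accrues an expected inpatient complication admission;
    complication-state occupancy accrues expected chronic outpatient cost.
    """
    alive = float(state[0] + state[1])
    per_alive = arm.costs.followup_outpatient.mean
    if config.perspective == "societal":
        per_alive += sum(e.mean for e in arm.costs.nonmed_followup.values())
    cost = alive * per_alive
    cost += incident_comp_mass * expected_complication_cost(arm, "inpatient")
    cost += float(state[1]) * expected_complication_cost(arm, "outpatient")
    return cost


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    age: float
    state: np.ndarray  # occupancy at cycle end
    cost_cycle: float
    qaly_cycle: float
    ly_cycle: float
    disc_cost: float
    disc_qaly: float
    disc_ly: float


@dataclass(frozen=True)
class Totals:
    cost: float
    qaly: float
    ly: float
    cost_raw: float
    qaly_raw: float
    ly_raw: float


@dataclass(frozen=True)
class Trace:
    """Per-cycle occupancy and accrual streams plus lifetime totals.

    Totals include the acute-phase cost, QALY and life-years at time zero,
    undiscounted.
    """

    initial: np.ndarray
    records: Sequence[CycleRecord] = field(repr=False)
    totals: Totals = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cycle": r.cycle,
                "age": r.age,
                "as_nocomp": r.state[0],
                "as_comp": r.state[1],
                "dead": r.state[2],
                "cost_cycle": r.cost_cycle,
                "qaly_cycle": r.qaly_cycle,
                "ly_cycle": r.ly_cycle,
                "disc_cost": r.disc_cost,
                "disc_qaly": r.disc_qaly,
                "disc_ly": r.disc_ly,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def _check_state(s: np.ndarray) -> None:
    if (s < -_MASS_TOL).any() or abs(float(s.sum()) - 1.0) > 1e-9:
        raise ValidationError(f"invalid state vector {s}")


def run_markov(
    init: AcuteOutcome,
    arm: ArmParameters,
    lt: LifeTable,
    config: ModelConfig,
) -> Trace:
    """Run the cohort from the acute-phase split to extinction or ``max_age``."""
    s = np.array([init.p_alive_nocomp, init.p_alive_comp, init.p_dead30])
    _check_state(s)
    accrual = config.effective_accrual()
    u_30d = arm.utilities.u_30d.mean
    u_1y = arm.utilities.u_1y.mean
    p_comp = combined_complication_prob(arm)

    records: list[CycleRecord] = []
    cost_sum = qaly_sum = ly_sum = 0.0
    cost_raw = qaly_raw = ly_raw = 0.0
    n_cycles = config.max_age - config.start_age
    for cycle in range(1, n_cycles + 1):
        age = config.start_age + cycle - 1  # age during this cycle
        t = build_transition(cycle, age, arm, lt, config)
        s_end = s @ t
        p_death = t[0, 2]
        incident = s[0] * (1.0 - p_death) * p_comp

        if accrual == "start":
            occ = s
        elif accrual == "end":
            occ = s_end
        else:  # half-cycle correction
            occ = 0.5 * (s + s_end)

        alive = float(occ[0] + occ[1])
        u = u_30d if (cycle == 1 and config.utility_timing == "u30d_first_cycle") else u_1y
        ly_cycle = alive
        qaly_cycle = alive * u
        c_cycle = cost_accrual(occ, incident, arm, config)

        dc = (1.0 + config.discount_cost) ** cycle
        dh = (1.0 + config.discount_health) ** cycle
        rec = CycleRecord(
            cycle=cycle,
            age=age,
            state=s_end,
            cost_cycle=c_cycle,
            qaly_cycle=qaly_cycle,
            ly_cycle=ly_cycle,
            disc_cost=c_cycle / dc,
            disc_qaly=qaly_cycle / dh,
            disc_ly=ly_cycle / dh,
        )
        records.append(rec)
        cost_sum += rec.disc_cost
        qaly_sum += rec.disc_qaly
        ly_sum += rec.disc_ly
        cost_raw += c_cycle
        qaly_raw += qaly_cycle
        ly_raw += ly_cycle

        if s_end[2] + _MASS_TOL < s[2]:
            raise ValidationError("dead occupancy decreased")
        s = s_end
        if float(s[0] + s[1]) < _ALIVE_EPS:
            break

    totals = Totals(
        cost=init.cost_acute + cost_sum,
        qaly=init.qaly_acute + qaly_sum,
        ly=init.ly_acute + ly_sum,
        cost_raw=init.cost_acute + cost_raw,
        qaly_raw=init.qaly_acute + qaly_raw,
        ly_raw=init.ly_acute + ly_raw,
    )
    initial = np.array([init.p_alive_nocomp, init.p_alive_comp, init.p_dead30])
    return Trace(initial=initial, records=records, totals=totals)
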