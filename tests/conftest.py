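"""Shared fixtures: the packaged parameter bundle and small synthetic builders."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import settings

from avrcea.params import (
    ADMISSION_COMPONENTS,
    COMPLICATIONS,
    NONMED_COMPONENTS,
    AnnualOutcomeParams,
    ArmParameters,
    CostSet,
    LifeTable,
    ModelConfig,
    PointEstimate,
    StratumTreeParams,
    UtilitySet,
    load_parameters,
)

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    return load_parameters()


@pytest.fixture(scope="session")
def config(bundle):
    return bundle.config


def fixed(mean: float, units: str = "probability") -> PointEstimate:
    return PointEstimate(mean=mean, low=mean, high=mean, dist_kind="fixed", units=units)


def make_arm(
    arm: str = "SUAVR",
    stratum: str = "overall",
    p_comp: float = 0.2,
    p_death_comp: float = 0.1,
    p_death_nocomp: float = 0.05,
    p_death_1y: float = 0.04,
    comp_prob: float = 0.0,
    u_30d: float = 0.6,
    u_1y: float = 0.8,
    admission_cost: float = 1000.0,
    followup_cost: float = 100.0,
    inpatient_cost: float = 500.0,
    outpatient_cost: float = 50.0,
    nonmed_admission_cost: float = 10.0,
    nonmed_followup_cost: float = 5.0,
) -> ArmParameters:
    """Small fully-specified arm with stated-exact parameters for engine tests."""
    tree = StratumTreeParams(
        p_complication=fixed(p_comp),
        p_death_given_comp=fixed(p_death_comp),
        p_death_given_nocomp=fixed(p_death_nocomp),
    )
    annual = AnnualOutcomeParams(
        p_death_1y=fixed(p_death_1y),
        **{f"p_{c}": fixed(comp_prob) for c in COMPLICATIONS},
    )
    costs = CostSet(
        admission={c: fixed(admission_cost, "THB") for c in ADMISSION_COMPONENTS},
        followup_outpatient=fixed(followup_cost, "THB"),
        inpatient_complication={c: fixed(inpatient_cost, "THB") for c in COMPLICATIONS},
        outpatient_complication={c: fixed(outpatient_cost, "THB") for c in COMPLICATIONS},
        nonmed_admission={c: fixed(nonmed_admission_cost, "THB") for c in NONMED_COMPONENTS},
        nonmed_followup={c: fixed(nonmed_followup_cost, "THB") for c in NONMED_COMPONENTS},
    )
    utilities = UtilitySet(u_30d=fixed(u_30d, "utility"), u_1y=fixed(u_1y, "utility"))
    return ArmParameters(arm=arm, stratum=stratum, tree=tree, annual=annual,
                         costs=costs, utilities=utilities)


def make_lt(q: float, age_min: int = 50, age_max: int = 110) -> LifeTable:
    return LifeTable({a: q for a in range(age_min, age_max + 1)})


def make_config(**kw) -> ModelConfig:
    return ModelConfig(**kw)
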