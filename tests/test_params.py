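"""Parameter types, moment matching, ingestion, and fixture integrity."""

from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from avrcea.errors import (
    InfeasibleMomentsError,
    LifeTableGapError,
    MalformedValueError,
    MissingInputError,
    ValidationError,
)
from avrcea.params import (
    ARMS,
    STRATA,
    LifeTable,
    ModelConfig,
    PointEstimate,
    beta_from_moments,
    gamma_from_moments,
    load_parameters,
    read_parameter_table,
    sampling_distribution,
    se_from_bounds,
    write_parameter_table,
)


class TestSeFromBounds:
    def test_range_as_95ci_frozen(self):
        # stroke inpatient cost row: (92,854 - 61,903) / 3.92
        assert se_from_bounds(77379, 61903, 92854) == pytest.approx(
            30951 / 3.92, abs=1e-9
        )

    def test_range_as_pm20_frozen(self):
        assert se_from_bounds(77379, 61903, 92854, "range_as_pm20") == pytest.approx(
            77379 * 0.2 / 1.96, abs=1e-9
        )

    def test_explicit(self):
        assert se_from_bounds(1.0, 0.0, 2.0, "explicit", explicit=0.25) == 0.25

    def test_explicit_requires_value(self):
        with pytest.raises(MissingInputError):
            se_from_bounds(1.0, 0.0, 2.0, "explicit")

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            se_from_bounds(1.0, 2.0, 0.0)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValidationError):
            se_from_bounds(1.0, 0.0, 2.0, "nonsense")


class TestMomentMatching:
    def test_beta_frozen(self):
        # mean 0.5, se 0.1: nu = 0.25/0.01 - 1 = 24 -> (12, 12)
        a, b = beta_from_moments(0.5, 0.1)
        assert (a, b) == pytest.approx((12.0, 12.0), abs=1e-12)

    def test_gamma_frozen(self):
        # mean 100, se 50 -> shape (100/50)^2 = 4, scale 2500/100 = 25
        assert gamma_from_moments(100.0, 50.0) == pytest.approx((4.0, 25.0), abs=1e-12)

    def test_beta_infeasible_variance(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_from_moments(0.5, 0.5)

    def test_beta_mean_out_of_range(self):
        for m in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(InfeasibleMomentsError):
                beta_from_moments(m, 0.1)

    def test_gamma_invalid(self):
        with pytest.raises(InfeasibleMomentsError):
            gamma_from_moments(-1.0, 1.0)
        with pytest.raises(InfeasibleMomentsError):
            gamma_from_moments(1.0, 0.0)

    @given(
        mean=st.floats(0.01, 0.99),
        frac=st.floats(0.05, 0.9),
    )
    def test_beta_roundtrip(self, mean, frac):
        # any se strictly inside the feasible region round-trips to 1e-12
        se = frac * math.sqrt(mean * (1.0 - mean)) * 0.999
        a, b = beta_from_moments(mean, se)
        assert a > 0 and b > 0
        m = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1.0))
        assert m == pytest.approx(mean, abs=1e-12)
        assert var == pytest.approx(se * se, abs=1e-12)

    @given(mean=st.floats(1e-3, 1e6), cv=st.floats(0.01, 3.0))
    def test_gamma_roundtrip(self, mean, cv):
        se = cv * mean
        shape, scale = gamma_from_moments(mean, se)
        assert shape * scale == pytest.approx(mean, rel=1e-12)
        assert shape * scale * scale == pytest.approx(se * se, rel=1e-12)


class TestPointEstimate:
    def test_range_must_bracket_mean(self):
        with pytest.raises(ValidationError):
            PointEstimate(mean=0.5, low=0.6, high=0.7, dist_kind="beta",
                          units="probability")

    def test_probability_bounds(self):
        with pytest.raises(ValidationError):
            PointEstimate(mean=1.1, low=0.9, high=1.2, dist_kind="beta",
                          units="probability")

    def test_negative_cost_rejected(self):
        with pytest.raises(ValidationError):
            PointEstimate(mean=5.0, low=-1.0, high=6.0, dist_kind="gamma", units="THB")

    def test_unknown_units_and_dist(self):
        with pytest.raises(ValidationError):
            PointEstimate(mean=0.5, low=0.4, high=0.6, dist_kind="beta", units="EUR")
        with pytest.raises(ValidationError):
            PointEstimate(mean=0.5, low=0.4, high=0.6, dist_kind="weird",
                          units="probability")


class TestModelConfig:
    def test_defaults_are_base_case(self):
        cfg = ModelConfig()
        assert cfg.start_age == 65 and cfg.max_age == 100
        assert cfg.wtp == 160_000.0 and cfg.ppp == 11.72
        assert cfg.discount_cost == cfg.discount_health == 0.03

    def test_validation(self):
        with pytest.raises(ValidationError):
            ModelConfig(start_age=100, max_age=100)
        with pytest.raises(ValidationError):
            ModelConfig(discount_cost=-0.01)
        with pytest.raises(ValidationError):
            ModelConfig(perspective="payer")
        with pytest.raises(ValidationError):
            ModelConfig(stratum="mixed")
        with pytest.raises(ValidationError):
            ModelConfig(long_term_mortality="other")

    def test_half_cycle_overrides_accrual(self):
        assert ModelConfig(half_cycle=True, accrual="start").effective_accrual() == "half"
        assert ModelConfig(half_cycle=False, accrual="end").effective_accrual() == "end"


class TestLifeTable:
    def test_contiguity_required(self):
        with pytest.raises(ValidationError):
            LifeTable({60: 0.01, 62: 0.02})

    def test_clamps_above_max_raises_below_min(self):
        lt = LifeTable({60: 0.01, 61: 0.02, 62: 0.03})
        assert lt.q(62) == 0.03
        assert lt.q(90) == 0.03  # clamped
        with pytest.raises(LifeTableGapError):
            lt.q(59)

    def test_q_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            LifeTable({60: 1.5})

    def test_from_csv_missing_file(self, tmp_path):
        with pytest.raises(MissingInputError):
            LifeTable.from_csv(tmp_path / "nope.csv")

    def test_from_csv_missing_column(self, tmp_path):
        p = tmp_path / "lt.csv"
        p.write_text("age,death\n60,0.01\n")
        with pytest.raises(MissingInputError):
            LifeTable.from_csv(p)

    def test_from_csv_non_numeric(self, tmp_path):
        p = tmp_path / "lt.csv"
        p.write_text("age,qx\n60,abc\n")
        with pytest.raises(MalformedValueError):
            LifeTable.from_csv(p)


class TestLoadParameters:
    def test_default_bundle_complete(self, bundle):
        assert set(bundle.arms) == {(a, s) for a in ARMS for s in STRATA}
        assert bundle.life_table.age_min <= bundle.config.start_age

    def test_known_fixture_values(self, bundle):
        cavr = bundle.arm("CAVR", "overall")
        assert cavr.tree.p_complication.mean == pytest.approx(0.2795)
        assert cavr.annual.p_death_1y.mean == pytest.approx(0.0343)
        suavr = bundle.arm("SUAVR", "overall")
        assert suavr.costs.admission["valve"].mean == pytest.approx(458_818)
        assert suavr.utilities.u_1y.mean == pytest.approx(0.8276)

    def test_missing_arm_raises(self, bundle):
        with pytest.raises(MissingInputError):
            bundle.arm("TAVI", "overall")

    def test_config_missing_key(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("parameters_csv: parameters.csv\n")
        with pytest.raises(MissingInputError):
            load_parameters(p)

    def test_config_unknown_key(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "parameters_csv: parameters.csv\nlife_table_csv: "
            "thai_life_table_synthetic.csv\nbogus_key: 1\n"
        )
        with pytest.raises(MissingInputError):
            load_parameters(p)

    def test_invalid_probability_in_table(self, tmp_path, bundle):
        df = bundle.table.copy()
        df.loc[df["name"].eq("p_death_1y") & df["arm"].eq("CAVR"), "mean"] = 1.2
        df.loc[df["name"].eq("p_death_1y") & df["arm"].eq("CAVR"), "high"] = 1.3
        params = tmp_path / "parameters.csv"
        write_parameter_table(df, params)
        lt = tmp_path / "lt.csv"
        bundle.life_table.to_frame().to_csv(lt, index=False)
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("parameters_csv: parameters.csv\nlife_table_csv: lt.csv\n")
        with pytest.raises(ValidationError):
            load_parameters(cfg)

    def test_parameter_table_roundtrip(self, tmp_path, bundle):
        out = tmp_path / "params.csv"
        write_parameter_table(bundle.table, out)
        again = read_parameter_table(out)
        pd.testing.assert_frame_equal(
            bundle.table.reset_index(drop=True), again, check_like=True
        )


class TestFixtureIntegrity:
    def test_cost_ranges_symmetric(self, bundle):
        df = bundle.table
        costs = df[df["units"].eq("THB") & df["dist"].eq("gamma")]
        asym = (costs["mean"] - costs["low"]) - (costs["high"] - costs["mean"])
        assert (asym.abs() <= 2.0).all()

    def test_survey_cost_rows_are_pm20(self, bundle):
        # rows sourced from the reimbursement database / patient interviews
        df = bundle.table
        pm20 = df[
            df["name"].str.startswith(("cost_inpatient", "cost_outpatient",
                                       "cost_followup", "cost_nonmed"))
            & df["dist"].eq("gamma")
        ]
        assert len(pm20) > 20
        assert ((pm20["low"] - 0.8 * pm20["mean"]).abs() <= 1.0).all()
        assert ((pm20["high"] - 1.2 * pm20["mean"]).abs() <= 1.0).all()

    def test_probability_rows_in_unit_interval(self, bundle):
        df = bundle.table
        probs = df[df["units"].isin(["probability", "utility"])]
        assert (probs["low"] >= 0).all() and (probs["high"] <= 1).all()


class TestSamplingDistribution:
    def test_beta_parameter(self, bundle):
        est = bundle.arm("CAVR", "overall").tree.p_complication
        kind, pars = sampling_distribution(est)
        assert kind == "beta"
        a, b = pars
        assert a / (a + b) == pytest.approx(est.mean, abs=1e-12)

    def test_gamma_parameter(self, bundle):
        est = bundle.arm("SUAVR", "overall").costs.admission["valve"]
        kind, (shape, scale) = sampling_distribution(est)
        assert kind == "gamma"
        assert shape * scale == pytest.approx(est.mean, rel=1e-12)

    def test_degenerate_is_fixed(self, bundle):
        est = bundle.arm("SUAVR", "isolated").tree.p_death_given_comp
        assert sampling_distribution(est) == ("fixed", (0.0,))
        zero_cost = bundle.arm("SUAVR", "overall").costs.nonmed_admission["accommodation"]
        assert sampling_distribution(zero_cost)[0] == "fixed"
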