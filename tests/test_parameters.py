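import numpy as np
import pytest

import msmarkov as mm
from msmarkov.params import N_EDSS


class TestDefaultBundle:
    def test_validates_and_paper_values(self, default_params):
        p = default_params
        assert p.baseline.mean_age == 36.0
        assert p.baseline.female_fraction == 0.70
        assert p.baseline.mean_edss == pytest.approx(2.3, abs=1e-9)
        assert p.effects["NAT"].hr_cdp6 == 0.46
        assert p.effects["TER"].hr_cdp6 == 0.79
        assert p.config.discount_rate_costs == 0.03
        assert p.config.horizon_years == 10
        assert p.config.stop_threshold_edss == 7
        assert p.costs.dmt_annual_cost["TER"] == 10807.0
        assert p.costs.dmt_annual_cost["NAT"] == 25985.0

    def test_severity_split_derived_from_relapse_rows(self, default_params):
        # proportions of the (mild, moderate, severe) relapse counts 1.38/1.76/0.51 of 3.65
        np.testing.assert_allclose(
            default_params.relapse.severity_split,
            np.array([1.38, 1.76, 0.51]) / 3.65,
            atol=1e-12,
        )

    def test_provenance_flags_cover_paper_and_placeholder(self, default_params):
        prov = default_params.provenance
        assert prov["effects.NAT.hr_cdp6"] == "paper"
        assert prov["natural_history.p"] == "placeholder"
        assert set(prov.values()) <= {"paper", "placeholder"}

    def test_natural_history_is_row_stochastic_and_worsening_biased(self, default_params):
        p = default_params.natural_history.p
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        worsen = sum(p[i, i + 1 :].sum() for i in range(N_EDSS))
        improve = sum(p[i, :i].sum() for i in range(N_EDSS))
        assert worsen > improve


@pytest.mark.parametrize("fmt", ["csv-bundle", "json", "yaml"])
def test_round_trip(tmp_path, default_params, fmt):
    target = tmp_path / ("bundle" if fmt == "csv-bundle" else f"bundle.{fmt}")
    mm.write_parameters(default_params, target, format=fmt)
    again = mm.load_parameters(target, format=fmt)
    assert again == default_params
    # a second round trip is byte-stable content-wise
    target2 = tmp_path / ("bundle2" if fmt == "csv-bundle" else f"bundle2.{fmt}")
    mm.write_parameters(again, target2, format=fmt)
    assert mm.load_parameters(target2, format=fmt) == default_params


def test_written_config_records_horizon(tmp_path, default_params):
    mm.write_parameters(default_params, tmp_path / "b")
    text = (tmp_path / "b" / "config.yaml").read_text()
    assert "horizon_years: 10" in text


class TestValidationErrors:
    def test_bad_row_sum_names_row(self):
        bad = np.eye(N_EDSS)
        bad[3, 3] = 0.98
        with pytest.raises(mm.ParameterValidationError, match="row 3"):
            mm.NaturalHistoryMatrix(bad)

    def test_negative_cost_rejected(self, default_params):
        sc = {k: np.asarray(v).copy() for k, v in default_params.costs.state_costs.items()}
        sc["inpatient"][0] = -1.0
        with pytest.raises(mm.ParameterValidationError, match="inpatient"):
            mm.CostInputs(
                state_costs=sc,
                dmt_annual_cost=default_params.costs.dmt_annual_cost,
                relapse_cost_by_severity=default_params.costs.relapse_cost_by_severity,
            )

    def test_missing_table_named(self, tmp_path, default_params):
        mm.write_parameters(default_params, tmp_path / "b")
        (tmp_path / "b" / "arr.csv").unlink()
        with pytest.raises(mm.MissingInputError, match="arr.csv"):
            mm.load_parameters(tmp_path / "b")

    def test_empty_effects_rejected(self, default_params):
        import dataclasses

        with pytest.raises(mm.ParameterValidationError, match="no DMT"):
            dataclasses.replace(default_params, effects={})

    def test_missing_dmt_price_rejected(self, default_params):
        import dataclasses

        costs = mm.CostInputs(
            state_costs=default_params.costs.state_costs,
            dmt_annual_cost={"NAT": 1.0},  # others priced out
            relapse_cost_by_severity=default_params.costs.relapse_cost_by_severity,
        )
        with pytest.raises(mm.MissingInputError, match="price"):
            dataclasses.replace(default_params, costs=costs)

    def test_decreasing_disability_weights_rejected(self):
        with pytest.raises(mm.ParameterValidationError, match="non-decreasing"):
            mm.DisabilityWeights(np.linspace(0.9, 0.1, N_EDSS))

    def test_baseline_mass_above_edss6_rejected(self):
        d = np.zeros(N_EDSS)
        d[8] = 1.0
        with pytest.raises(mm.ParameterValidationError, match="EDSS 7-9"):
            mm.BaselineCohort(edss_distribution=d, mean_age=36.0, female_fraction=0.7)

    def test_mortality_multiplier_below_one_rejected(self, default_params):
        m = default_params.mortality
        with pytest.raises(mm.ParameterValidationError, match="multiplier"):
            mm.MortalityModel(
                ages=m.ages,
                q_female=m.q_female,
                q_male=m.q_male,
                le_female=m.le_female,
                le_male=m.le_male,
                multiplier_by_edss=np.full(N_EDSS, 0.5),
            )

    def test_age_outside_mortality_table_errors(self, default_params):
        with pytest.raises(mm.ParameterValidationError, match="outside table range"):
            default_params.mortality.q_general(130.0, 0.7)


def test_relapse_multiplier_anchoring(default_params):
    # a baseline-mix cohort on treatment reproduces the published on-treatment ARR
    p = default_params
    mult = p.relapse_multiplier("NAT")
    anchored = mult * p.reference_arr
    assert anchored == pytest.approx(p.effects["NAT"].arr_on_treatment, rel=1e-12)
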