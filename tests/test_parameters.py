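"""Parameter model: loading, validation, paths, distributions."""

import math

import numpy as np
import pytest
import yaml

from asthma_cea.parameters import (
    CSESubstateSplit,
    DistributionSpec,
    ValidationError,
    load_parameters,
    resolve_path,
    set_path,
    scalar_paths,
    to_config,
)
from asthma_cea.synthetic import reference_fixture


def test_fixture_round_trips_through_yaml(params):
    text = yaml.safe_dump(to_config(params), sort_keys=False)
    reloaded = load_parameters(text)
    assert reloaded == params


def test_loaded_fixture_carries_printed_rates(params):
    assert params.arm("mepolizumab").annual_cse_rate == 0.45
    assert params.arm("placebo").annual_cse_rate == 1.31


def test_missing_field_error_names_path(params):
    cfg = to_config(params)
    del cfg["util"]["u_no_cse"]
    with pytest.raises(ValidationError, match="util.u_no_cse"):
        load_parameters(cfg)


def test_substate_split_renormalized_with_warning(params, caplog):
    cfg = to_config(params)
    cfg["substate_split"] = {"p_ocs": 0.80, "p_hosp_ed": 0.14, "p_hosp": 0.08}
    with caplog.at_level("WARNING"):
        loaded = load_parameters(cfg)
    s = loaded.substate_split
    assert s.p_ocs + s.p_hosp_ed + s.p_hosp == pytest.approx(1.0, abs=1e-12)
    assert any("renormalizing" in r.message for r in caplog.records)


def test_zero_split_rejected():
    with pytest.raises(ValidationError):
        CSESubstateSplit.normalized(0.0, 0.0, 0.0)


def test_cny_money_fields_converted(params):
    cfg = to_config(params)
    fx = cfg["econ"]["exchange_rate_cny_per_usd"]
    wage_cny = params.econ.daily_wage * fx
    cfg["econ"]["daily_wage"] = {"cny": wage_cny}
    loaded = load_parameters(cfg)
    assert loaded.econ.daily_wage == pytest.approx(wage_cny / fx)


def test_unresolvable_sensitivity_path_rejected(params):
    cfg = to_config(params)
    cfg["dsa_ranges"]["econ.nonexistent_cost"] = [1.0, 2.0]
    with pytest.raises(ValidationError, match="nonexistent_cost"):
        load_parameters(cfg)


def test_path_resolution_and_assignment(params):
    p = params.copy()
    assert resolve_path(p, "econ.drug_unit_price") == 682.02
    assert resolve_path(p, "arms.placebo.annual_cse_rate") == 1.31
    v = resolve_path(p, "arms.mepolizumab.ae_profile.pneumonia.cost_per_event")
    assert v > 0
    set_path(p, "util.disutility_by_substate.CSE_HOSP", 0.4)
    assert p.util.disutility_by_substate["CSE_HOSP"] == 0.4
    with pytest.raises(ValidationError, match="no arm named"):
        resolve_path(p, "arms.nocebo.annual_cse_rate")


def test_derived_rate_ratio_path(params):
    p = params.copy()
    assert p.point_estimate("derived.cse_rr") == pytest.approx(0.45 / 1.31)
    p.apply("derived.cse_rr", 1.0)
    assert p.intervention.annual_cse_rate == p.comparator.annual_cse_rate


def test_scalar_paths_all_resolve(params):
    for path in scalar_paths(params):
        value = resolve_path(params, path)
        assert isinstance(value, (int, float))


def test_employment_rate_zero_beyond_last_band(params):
    assert params.econ.employment_rate(200.0) == 0.0
    assert params.econ.employment_rate(55.0) == pytest.approx(0.68)


@pytest.mark.parametrize(
    "spec, expected_mean",
    [
        (DistributionSpec("beta", (8.0, 2.0)), 0.8),
        (DistributionSpec("gamma", (4.0, 25.0)), 100.0),
        (DistributionSpec("lognormal", (0.0, 0.5)), math.exp(0.125)),
        (DistributionSpec("normal", (3.0, 1.0)), 3.0),
        (DistributionSpec("fixed", (7.0,)), 7.0),
    ],
)
def test_distribution_means(spec, expected_mean):
    spec.validate("x")
    assert spec.mean() == pytest.approx(expected_mean)
    rng = np.random.default_rng(0)
    draws = [spec.sample(rng) for _ in range(4000)]
    tol = 0.05 * abs(expected_mean) + 0.05
    assert np.mean(draws) == pytest.approx(expected_mean, abs=tol)


def test_moment_matching_constructors():
    b = DistributionSpec.beta_from_moments(0.84, 0.03)
    assert b.mean() == pytest.approx(0.84, abs=1e-12)
    g = DistributionSpec.gamma_from_moments(500.0, 100.0)
    assert g.mean() == pytest.approx(500.0, abs=1e-9)
    ln = DistributionSpec.lognormal_from_ci(0.25, 0.47)
    assert 0.25 < math.exp(ln.params[0]) < 0.47


def test_psa_spec_mean_deviation_rejected(params):
    cfg = to_config(params)
    # a gamma centred far from the drug price point estimate
    cfg["psa_specs"]["econ.drug_unit_price"] = {
        "family": "gamma", "params": [100.0, 10.0]}
    with pytest.raises(ValidationError, match="drug_unit_price"):
        load_parameters(cfg)


def test_settings_invariants():
    bundle = reference_fixture()
    p = bundle.parameters.copy()
    p.settings.wtp_lower = p.settings.wtp_upper
    with pytest.raises(ValidationError, match="wtp_lower"):
        p.validate()
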