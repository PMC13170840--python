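"""Base-case, subgroup, deterministic and probabilistic analyses."""

import numpy as np
import pytest

from asthma_cea.analyses import (
    ceac,
    default_wtp_grid,
    run_base_case,
    run_dsa,
    run_psa,
    run_subgroups,
)
from asthma_cea.conversions import ValidationError
from asthma_cea.parameters import DistributionSpec
from asthma_cea.economics import net_monetary_benefit


def test_base_case_regime_and_composition(base_case, params):
    """Added drug cost, gained QALYs, ICER below the WTP band; the cost
    ledgers add up to the arm totals."""
    r = base_case.result
    assert r.classification == "icer"
    assert r.delta_cost > 0 and r.delta_qaly > 0
    assert r.icer < params.settings.wtp_lower
    comp = base_case.cost_composition()
    for trace in (base_case.trace_intervention, base_case.trace_comparator):
        part = comp[(comp.arm == trace.arm_name) & (comp.component != "total")]
        assert part.discounted_total.sum() == pytest.approx(
            trace.cumulative_cost, abs=1e-6)


def test_identical_arms_give_null_increments(params):
    p = params.copy()
    p.intervention.annual_cse_rate = p.comparator.annual_cse_rate
    p.intervention.drug_dose_mg = 0.0
    p.intervention.ae_profile = p.comparator.ae_profile
    r = run_base_case(p, check_invariants=False).result
    assert r.delta_cost == pytest.approx(0.0, abs=1e-9)
    assert r.delta_qaly == pytest.approx(0.0, abs=1e-12)


def test_subgroups_base_rr_reproduces_base_case(params, base_case):
    """A subgroup whose RR equals the base-case rate ratio is the base case."""
    p = params.copy()
    base_rr = p.point_estimate("derived.cse_rr")
    p.subgroups = [type(p.subgroups[0])("base", base_rr,
                                        (base_rr * 0.9, base_rr * 1.1))]
    (_, r), = run_subgroups(p)
    assert r.delta_cost == pytest.approx(base_case.result.delta_cost, abs=1e-9)
    assert r.delta_qaly == pytest.approx(base_case.result.delta_qaly, abs=1e-9)


def test_subgroup_rr_one_driven_by_ae_difference_only(params):
    """RR = 1: equal exacerbation rates, so the QALY gain comes only from the
    lower adverse-event burden of the intervention arm."""
    p = params.copy()
    p.subgroups = [type(p.subgroups[0])("degenerate", 1.0, (0.8, 1.2))]
    (_, r), = run_subgroups(p)
    assert r.delta_qaly > 0  # AE disutility advantage only
    assert r.delta_qaly < 0.1


def test_subgroups_fixture_all_favorable(params):
    """Every fixture subgroup is either dominant or under the WTP band."""
    results = run_subgroups(params)
    assert len(results) == len(params.subgroups)
    for sg, r in results:
        assert r.delta_qaly > 0
        if r.classification == "icer":
            assert r.icer < params.settings.wtp_lower


def test_dsa_orders_by_spread_and_restores_base(params, base_case):
    entries = run_dsa(params)
    assert set(e.parameter_path for e in entries) == set(params.dsa_ranges)
    spreads = [e.spread for e in entries]
    assert spreads == sorted(spreads, reverse=True)
    # the sweep left the shared parameter set untouched
    after = run_base_case(params).result
    assert after.icer == pytest.approx(base_case.result.icer, abs=1e-9)


def test_dsa_zero_influence_parameter_has_zero_spread(params):
    p = params.copy()
    p.dsa_ranges = {"settings.wtp_lower": (12_000.0, 18_000.0)}
    entry, = run_dsa(p)
    assert entry.spread == pytest.approx(0.0, abs=1e-9)


def test_dsa_drug_price_direction(params):
    p = params.copy()
    p.dsa_ranges = {"econ.drug_unit_price": (0.8 * 682.02, 1.2 * 682.02)}
    entry, = run_dsa(p)
    assert entry.icer_at_high > entry.icer_at_low


def test_dsa_utility_range_clamped(params, caplog):
    p = params.copy()
    p.dsa_ranges = {"util.u_no_cse": (0.9, 1.2)}
    with caplog.at_level("WARNING"):
        entry, = run_dsa(p)
    assert entry.high_value == 1.0
    assert any("clamped" in r.message for r in caplog.records)


def test_psa_point_collapse_reproduces_base_case(params, base_case):
    """Degenerate distributions make every draw equal the base case."""
    p = params.copy()
    p.psa_specs = {
        path: DistributionSpec("fixed", (p.point_estimate(path),))
        for path in p.psa_specs
    }
    psa = run_psa(p, n=5, seed=0)
    assert np.allclose(psa.delta_cost, base_case.result.delta_cost, atol=1e-9)
    assert np.allclose(psa.delta_qaly, base_case.result.delta_qaly, atol=1e-12)


def test_psa_seed_reproducibility(params):
    a = run_psa(params, n=8, seed=123)
    b = run_psa(params, n=8, seed=123)
    assert np.array_equal(a.draws, b.draws)
    c = run_psa(params, n=8, seed=124)
    assert not np.array_equal(a.draws, c.draws)


def test_psa_streams_stable_under_added_parameter(params):
    """Adding an uncertain parameter must not reshuffle the others' draws."""
    p = params.copy()
    p.psa_specs = {"econ.drug_unit_price":
                   params.psa_specs["econ.drug_unit_price"]}
    only_price = run_psa(p, n=6, seed=5)

    q = params.copy()
    q.psa_specs = dict(p.psa_specs)
    q.psa_specs["econ.daily_wage"] = params.psa_specs["econ.daily_wage"]
    both = run_psa(q, n=6, seed=5)
    # drug-price draws unchanged => costs shift only through the wage channel
    # compare by re-deriving the price draws directly from the stream
    from asthma_cea.analyses import _path_rng
    rng1 = _path_rng(5, "econ.drug_unit_price")
    rng2 = _path_rng(5, "econ.drug_unit_price")
    draws1 = [params.psa_specs["econ.drug_unit_price"].sample(rng1)
              for _ in range(6)]
    draws2 = [params.psa_specs["econ.drug_unit_price"].sample(rng2)
              for _ in range(6)]
    assert draws1 == draws2


def test_psa_mean_near_base_case(params, base_case):
    """With distributions centred on the point estimates, the sample mean
    QALY increment approaches the base-case increment."""
    psa = run_psa(params, n=200, seed=2)
    se = psa.delta_qaly.std(ddof=1) / np.sqrt(psa.n_iterations)
    assert abs(psa.delta_qaly.mean() - base_case.result.delta_qaly) < 4 * se


def test_ceac_definition_and_monotonicity(params):
    psa = run_psa(params, n=150, seed=9)
    grid = default_wtp_grid(0, 45_000, 1_500)
    points = ceac(psa, grid)
    assert points[0].prob_cost_effective == pytest.approx(
        float(np.mean(psa.delta_cost < 0)))
    assert (psa.delta_qaly > 0).all()
    probs = [pt.prob_cost_effective for pt in points]
    assert all(b >= a for a, b in zip(probs, probs[1:]))
    assert probs[-1] >= 0.99  # far above the band, nearly all draws accepted


def test_ceac_rejects_empty_grid(params):
    psa = run_psa(params, n=2, seed=0)
    with pytest.raises(ValidationError):
        ceac(psa, [])


def test_run_subgroups_requires_subgroups(params):
    p = params.copy()
    p.subgroups = []
    with pytest.raises(ValidationError):
        run_subgroups(p)
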