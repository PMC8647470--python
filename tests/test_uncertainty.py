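"""Distribution fitting, PSA mechanics, CEAC/NMB, tornado."""

import numpy as np
import pytest

from asthmacea.parameters import Role, param_range
from asthmacea.uncertainty import (
    DistributionFitError,
    build_distributions,
    ceac,
    default_wtp_grid,
    fit_beta,
    fit_dirichlet,
    fit_gamma,
    nmb,
    one_way_dsa,
    quadrant_proportions,
    run_psa,
    tornado_frame,
)

# --- moment-matched fits ----------------------------------------------------


def test_beta_fit_of_relative_risk_range():
    pr = param_range(0.85, Role.RELATIVE_RISK, 0.78, 0.92)
    spec = fit_beta(pr)
    # closed-form check: sd = 0.14/3.92, nu = m(1-m)/s^2 - 1
    s = 0.14 / 3.92
    nu = 0.85 * 0.15 / s**2 - 1.0
    assert spec.params["alpha"] == pytest.approx(0.85 * nu)  # ~84.1
    assert spec.params["beta"] == pytest.approx(0.15 * nu)  # ~14.8
    assert spec.mean() == pytest.approx(0.85, abs=1e-12)
    assert spec.sd() == pytest.approx(s, abs=1e-9)


def test_gamma_fit_of_cost_range():
    spec = fit_gamma(param_range(60.0, Role.COST, 45.0, 75.0))
    s = 30.0 / 3.92
    assert spec.params["shape"] == pytest.approx((60.0 / s) ** 2)  # ~61.5
    assert spec.params["scale"] == pytest.approx(s**2 / 60.0)  # ~0.976
    assert spec.mean() == pytest.approx(60.0, abs=1e-9)


def test_dirichlet_fit_inverts_beta_marginal_variance():
    spec = fit_dirichlet([param_range(0.47, Role.PROBABILITY, 0.35, 0.59)])
    s = 0.24 / 3.92
    n = 0.47 * 0.53 / s**2 - 1.0
    assert n == pytest.approx(65.4, abs=0.1)
    assert spec.params["alpha"][0] == pytest.approx(0.47 * n)
    assert sum(spec.params["alpha"]) == pytest.approx(n)
    assert spec.mean() == pytest.approx(0.47, abs=1e-12)
    assert spec.sd() == pytest.approx(s, rel=1e-9)


def test_degenerate_range_collapses_to_fixed():
    spec = fit_beta(param_range(0.5, Role.UTILITY, 0.5, 0.5))
    assert spec.family == "fixed" and spec.sample(np.random.default_rng(0)) == 0.5
    assert fit_gamma(param_range(0.0, Role.COST, 0.0, 0.0)).family == "fixed"


def test_impossible_fits_raise():
    from asthmacea.parameters import ParamRange

    # range wider than a beta on (0,1) can support at this mean
    with pytest.raises(DistributionFitError):
        fit_beta(ParamRange(0.02, 0.0, 1.0, Role.PROBABILITY))
    with pytest.raises(DistributionFitError):
        fit_dirichlet([])


def test_all_bundle_fits_match_target_moments(bundle):
    specs = build_distributions(bundle)
    assert "annual_discount" not in specs  # DSA-only
    assert "cost_ocs_burst" not in specs  # zero-valued cost skipped
    assert "rr_exacerbation_triple" in specs and "persistence_dual" in specs
    for name, spec in specs.items():
        pr = spec.source
        assert abs(spec.mean() - pr.base) < 1e-6, name
        assert abs(spec.sd() - pr.width / 3.92) < 1e-4, name


def test_dirichlet_draws_live_on_the_simplex():
    rng = np.random.default_rng(1)
    spec = fit_dirichlet([param_range(0.47, Role.PROBABILITY, 0.35, 0.59)])
    draws = rng.dirichlet(spec.params["alpha"], size=10_000)
    assert np.allclose(draws.sum(axis=1), 1.0)
    se = spec.sd() / np.sqrt(10_000)
    assert abs(draws[:, 0].mean() - 0.47) < 3 * se + 1e-3


# --- PSA --------------------------------------------------------------------


def test_psa_is_seed_reproducible(bundle, life_table):
    a = run_psa(bundle, n_reps=10, seed=123, life_table=life_table)
    b = run_psa(bundle, n_reps=10, seed=123, life_table=life_table)
    assert np.array_equal(a.delta_cost, b.delta_cost)
    assert np.array_equal(a.delta_qaly, b.delta_qaly)
    c = run_psa(bundle, n_reps=10, seed=124, life_table=life_table)
    assert not np.array_equal(a.delta_cost, c.delta_cost)


def test_degenerate_psa_equals_deterministic_base_case(bundle, life_table):
    from asthmacea.markov import run_cohort
    from asthmacea.parameters import ParamRange, UNCERTAIN_PARAMETERS, get_param, set_param

    frozen = bundle.copy()
    for name in UNCERTAIN_PARAMETERS:
        pr = get_param(frozen, name)
        set_param(frozen, name, ParamRange(pr.base, pr.base, pr.base, pr.role, pr.source))
    psa = run_psa(frozen, n_reps=1, seed=0, life_table=life_table)
    det = {arm: run_cohort(frozen, arm, life_table) for arm in ("triple", "dual")}
    assert psa.cost["triple"][0] == pytest.approx(det["triple"].discounted_cost)
    assert psa.qaly["dual"][0] == pytest.approx(det["dual"].discounted_qaly)


def test_psa_outputs_valid_and_quadrants_partition(psa_small):
    for arm in ("triple", "dual"):
        assert np.all(psa_small.cost[arm] >= 0)
        assert np.all(psa_small.qaly[arm] >= 0)
    q = quadrant_proportions(psa_small)
    assert sum(q.values()) == pytest.approx(1.0)
    assert all(0.0 <= v <= 1.0 for v in q.values())


def test_quadrant_tie_points_assigned_conservatively(psa_small):
    import dataclasses

    tied = dataclasses.replace(
        psa_small,
        delta_cost=np.array([0.0, -1.0, 1.0, 1.0]),
        delta_qaly=np.array([0.0, 1.0, -1.0, 1.0]),
        n_reps=4,
    )
    q = quadrant_proportions(tied)
    assert q == {"q1": 0.5, "q2": 0.25, "q3": 0.0, "q4": 0.25}


def test_psa_means_converge_to_deterministic_under_narrow_distributions(
    bundle, life_table
):
    """With ranges shrunk to +/-1% the PSA mean must sit within Monte Carlo
    error of the deterministic result (symmetric, nearly linear region)."""
    from asthmacea.markov import run_cohort
    from asthmacea.parameters import ParamRange, UNCERTAIN_PARAMETERS, get_param, set_param

    narrow = bundle.copy()
    for name in UNCERTAIN_PARAMETERS:
        pr = get_param(narrow, name)
        if pr.degenerate or name == "annual_discount":
            continue
        set_param(
            narrow,
            name,
            ParamRange(pr.base, pr.base * 0.99, pr.base * 1.01, pr.role, pr.source),
        )
    psa = run_psa(narrow, n_reps=200, seed=5, life_table=life_table)
    det = run_cohort(narrow, "triple", life_table)
    se = psa.cost["triple"].std(ddof=1) / np.sqrt(psa.n_reps)
    assert abs(psa.cost["triple"].mean() - det.discounted_cost) < 3 * se + 1e-6


# --- NMB / CEAC -------------------------------------------------------------


def test_nmb_examples_and_identity():
    assert nmb(19_000.0, 1.55, 304.0) == pytest.approx(29_146.0)
    assert nmb(0.0, 2.0, 304.0) == -304.0
    # nmb > 0 iff ICER < wtp whenever dE > 0
    de, dc, wtp = 0.4, 900.0, 3000.0
    assert (nmb(wtp, de, dc) > 0) == (dc / de < wtp)


def test_ceac_all_dominant_is_one_everywhere(psa_small):
    import dataclasses

    dominant = dataclasses.replace(
        psa_small,
        delta_cost=-np.ones(psa_small.n_reps),
        delta_qaly=np.ones(psa_small.n_reps),
    )
    curve = ceac(dominant)
    assert all(p.prob_cost_effective == 1.0 for p in curve.points)
    assert curve.crossing_wtp == 0.0


def test_ceac_monotone_when_all_gains_positive(psa_small):
    import dataclasses

    positive = dataclasses.replace(psa_small, delta_qaly=np.abs(psa_small.delta_qaly) + 1e-9)
    probs = [p.prob_cost_effective for p in ceac(positive).points]
    assert np.all(np.diff(probs) >= 0)


def test_ceac_limits(psa_small):
    curve = ceac(psa_small, np.array([0.0, 1e12]))
    frac_cost_saving = float(np.mean(psa_small.delta_cost < 0))
    assert curve.points[0].prob_cost_effective == pytest.approx(frac_cost_saving)
    frac_effective = float(np.mean(psa_small.delta_qaly > 0))
    assert curve.points[-1].prob_cost_effective == pytest.approx(frac_effective, abs=0.05)


def test_ceac_rejects_bad_grid(psa_small):
    with pytest.raises(ValueError):
        ceac(psa_small, np.array([100.0, 50.0]))
    assert 19_000.0 in default_wtp_grid()


# --- one-way DSA ------------------------------------------------------------


@pytest.fixture(scope="module")
def dsa(bundle, life_table):
    return one_way_dsa(bundle, life_table)


def test_tornado_sorted_by_spread(dsa):
    rows, _ = dsa
    spreads = [r.spread for r in rows]
    assert spreads == sorted(spreads, reverse=True)
    assert "cost_ocs_burst" not in {r.parameter for r in rows}  # zero-valued cost


def test_degenerate_parameter_has_spread_from_one_side_only(dsa):
    rows, _ = dsa
    row = next(r for r in rows if r.parameter == "p_controlled_to_ocs")
    # printed high equals base, so the high-side ICER equals the base ICER
    assert row.icer_at_high is not None and row.icer_at_low is not None


def test_tornado_invariant_to_evaluation_order(bundle, life_table, dsa):
    rows, _ = dsa
    subset = ["u_controlled", "rr_exacerbation_triple", "annual_discount"]
    redone, _ = one_way_dsa(bundle, life_table, parameters=list(reversed(subset)))
    by_name = {r.parameter: r for r in rows}
    for r in redone:
        assert r.spread == pytest.approx(by_name[r.parameter].spread)


def test_discount_rate_extremes_give_valid_icers(dsa):
    rows, _ = dsa
    row = next(r for r in rows if r.parameter == "annual_discount")
    assert row.icer_at_low is not None and row.icer_at_high is not None
    assert row.spread >= 0

def test_tornado_frame_layout(dsa):
    df = tornado_frame(dsa[0])
    assert list(df.columns[:4]) == ["parameter", "icer_at_low", "icer_at_high", "spread"]
    assert df["spread"].is_monotonic_decreasing
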