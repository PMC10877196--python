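import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meniscea import (
    STATES,
    accumulate,
    build_parameter_set,
    discount_stream,
    run_arm,
    run_cohort,
    transition_matrices,
    within_cycle_correct,
)
from meniscea.life_tables import LifeTable
from meniscea.markov_engine import _NOOA_P, _NOOA_R0, max_cycles

from _microsim import simulate_events


def _near_zero_mortality_table():
    # LifeTable requires q > 0; use a vanishing hazard to emulate no deaths
    ages = np.arange(30, 111)
    return LifeTable(ages=ages, q=np.full(ages.size, 1e-12))


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

@given(
    p_fail=st.floats(0.0, 0.3),
    rr=st.floats(0.1, 1.5),
    p_tkr=st.floats(0.0, 0.2),
    p_mort=st.floats(0.0, 0.05),
    arm=st.sampled_from(["MR", "PM"]),
)
def test_rows_are_stochastic_for_random_valid_parameter_sets(
    life_table, p_fail, rr, p_tkr, p_mort, arm
):
    ps = build_parameter_set(overrides={
        "p_fail_mr_annual": p_fail,
        "rr_oa_mr_vs_pm": rr,
        "p_oa_to_tkr_annual": p_tkr,
        "p_procedure_mortality": p_mort,
    })
    P, E = transition_matrices(ps, life_table, arm)
    np.testing.assert_allclose(P.sum(axis=2), 1.0, atol=1e-12)
    assert np.all(P >= 0)
    assert np.all(E >= 0)


def test_failure_probability_zero_once_window_elapsed(base_params, life_table):
    P, _ = transition_matrices(base_params, life_table, "MR")
    revision_flow = P[:, _NOOA_P, _NOOA_R0]
    assert np.all(revision_flow[:3] > 0)
    assert np.all(revision_flow[3:] == 0)
    unlimited = base_params.replace(failure_window_years=None)
    P2, _ = transition_matrices(unlimited, life_table, "MR")
    assert np.all(P2[:, _NOOA_P, _NOOA_R0] > 0)


def test_pm_oa_exit_probability_is_first_band_in_early_cycles(base_params, life_table):
    lt = _near_zero_mortality_table()
    P, _ = transition_matrices(base_params, lt, "PM", horizon=3)
    # with negligible mortality, the OA flow is the first band among non-failed
    from meniscea.markov_engine import _OA_INTACT
    oa_flow = P[2, _NOOA_P, _OA_INTACT]
    assert oa_flow == pytest.approx(0.1127 * (1 - base_params.p_fail_pm_annual), rel=1e-9)


# ---------------------------------------------------------------------------
# cohort projection
# ---------------------------------------------------------------------------

def test_occupancy_conserves_cohort_at_every_cycle(base_params, life_table):
    for arm in ("MR", "PM"):
        trace = run_cohort(base_params, life_table, arm)
        np.testing.assert_allclose(
            trace.occupancy_internal.sum(axis=1), base_params.cohort_size, atol=1e-9
        )
        assert np.all(trace.occupancy_internal >= -1e-12)
        assert trace.occupancy.shape[1] == len(STATES)


def test_revisions_compound_over_window_when_mortality_off(base_params):
    lt = _near_zero_mortality_table()
    ps = base_params.replace(p_procedure_mortality=0.0)
    trace = run_cohort(ps, lt, "MR")
    expected = 1000 * (1 - (1 - 0.0912) ** 3)  # ~249.4
    assert accumulate(trace, ps).revisions == pytest.approx(expected, rel=2e-3)


def test_horizon_caps_at_max_age(base_params, life_table):
    trace = run_cohort(base_params, life_table, "PM", horizon=10_000)
    assert trace.n_cycles == max_cycles(base_params) == 76


def test_trace_export_is_bit_stable(base_params, life_table):
    a = run_cohort(base_params, life_table, "MR").to_frame().to_csv(index=False)
    b = run_cohort(base_params, life_table, "MR").to_frame().to_csv(index=False)
    assert a == b


# ---------------------------------------------------------------------------
# within-cycle correction and discounting
# ---------------------------------------------------------------------------

def test_single_cycle_survivor_gets_half_credit():
    # one person alive through exactly one cycle then dead
    lt = LifeTable(ages=np.array([35, 36, 37]), q=np.array([1e-12, 1.0, 1.0]))
    ps = build_parameter_set(overrides={
        "cohort_size": 1.0, "max_age": 37,
        "p_fail_mr_annual": 0.0, "p_oa_pm_y1_5": 0.0, "p_oa_pm_y6_10": 0.0,
        "p_oa_pm_y11plus": 0.0, "p_oa_to_tkr_annual": 0.0, "p_procedure_mortality": 0.0,
    })
    trace = run_cohort(ps, lt, "MR")
    alive_by_method = {
        method: within_cycle_correct(trace, method)[1][:-1].sum()  # exclude death
        for method in ("half_cycle", "trapezoid", "none")
    }
    assert alive_by_method["half_cycle"] == pytest.approx(0.5, abs=1e-9)
    assert alive_by_method["trapezoid"] == pytest.approx(0.5, abs=1e-9)
    assert alive_by_method["none"] == pytest.approx(0.0, abs=1e-12)


def test_constant_occupancy_unchanged_by_correction(base_params):
    lt = _near_zero_mortality_table()
    ps = base_params.replace(**{
        "p_fail_mr_annual": 0.0, "p_oa_pm_y1_5": 0.0, "p_oa_pm_y6_10": 0.0,
        "p_oa_pm_y11plus": 0.0, "p_procedure_mortality": 0.0,
    })
    trace = run_cohort(ps, lt, "MR", horizon=10)
    for method in ("half_cycle", "trapezoid", "none"):
        eff = within_cycle_correct(trace, method)
        np.testing.assert_allclose(eff.sum(axis=1), ps.cohort_size, atol=1e-6)


def test_half_cycle_and_trapezoid_agree_on_lifetime_qalys(base_params, life_table):
    for arm in ("MR", "PM"):
        trace = run_cohort(base_params, life_table, arm)
        hc = accumulate(trace, base_params, "half_cycle")
        tz = accumulate(trace, base_params, "trapezoid")
        assert hc.discounted_qalys == pytest.approx(tz.discounted_qalys, rel=1e-9)
        assert hc.discounted_cost == pytest.approx(tz.discounted_cost, rel=1e-9)


def test_unknown_correction_method_rejected(base_params, life_table):
    trace = run_cohort(base_params, life_table, "MR", horizon=2)
    with pytest.raises(ValueError):
        within_cycle_correct(trace, "simpson")


def test_discount_stream_closed_forms():
    assert discount_stream(np.ones(10), 0.0) == pytest.approx(10.0)
    assert discount_stream(np.array([103.0]), 0.03) == pytest.approx(100.0)
    annuity = (1 - 1.03 ** -10) / 0.03
    assert discount_stream(np.ones(10), 0.03) == pytest.approx(annuity, abs=1e-4)
    with pytest.raises(ValueError):
        discount_stream(np.ones(3), -0.1)


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------

def test_zero_utilities_leave_only_disutilities(base_params, life_table):
    ps = base_params.replace(u_no_oa=0.0, u_oa=0.0, u_post_tkr=0.0, u_post_rtkr=0.0)
    trace = run_cohort(ps, life_table, "MR")
    res = accumulate(trace, ps)
    assert res.discounted_qalys < 0
    assert res.undiscounted_qalys == pytest.approx(
        -(ps.cohort_size * ps.disutil_meniscal_procedure
          + res.revisions * ps.disutil_meniscal_procedure
          + res.tkrs * ps.disutil_tkr
          + res.rtkrs * ps.disutil_rtkr),
        rel=1e-9,
    )


def test_discounting_never_increases_qalys(base_params, life_table):
    res = run_arm(base_params, life_table, "MR")
    assert res.discounted_qalys <= res.undiscounted_qalys


def test_two_state_reduction_matches_closed_form_life_expectancy(life_table):
    ps = build_parameter_set(overrides={
        "p_fail_mr_annual": 0.0, "p_fail_pm_annual": 0.0,
        "p_oa_pm_y1_5": 0.0, "p_oa_pm_y6_10": 0.0, "p_oa_pm_y11plus": 0.0,
        "p_oa_to_tkr_annual": 0.0, "p_procedure_mortality": 0.0,
        "u_no_oa": 1.0, "disutil_meniscal_procedure": 0.0,
    })
    expected = ps.cohort_size * life_table.life_expectancy(35, discount_rate=0.03)
    res = run_arm(ps, life_table, "PM")
    assert res.discounted_qalys == pytest.approx(expected, rel=1e-9)


def test_more_mr_failures_mean_fewer_qalys_and_more_revisions(base_params, life_table):
    qalys, revisions = [], []
    for p in (0.05, 0.0912, 0.15, 0.25):
        res = run_arm(base_params.replace(p_fail_mr_annual=p), life_table, "MR")
        qalys.append(res.discounted_qalys)
        revisions.append(res.revisions)
    assert np.all(np.diff(qalys) < 0)
    assert np.all(np.diff(revisions) > 0)


# ---------------------------------------------------------------------------
# microsimulation oracle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("arm", ["MR", "PM"])
def test_cohort_events_match_individual_level_simulation(base_params, life_table, arm):
    """Expected event totals agree with an independent per-patient Monte Carlo."""
    n = 100_000
    sim = simulate_events(base_params, life_table, arm, n_individuals=n, seed=2024)
    trace = run_cohort(base_params, life_table, arm)
    cohort = dict(zip(("revision", "oa_incidence", "tkr", "rtkr", "death"),
                      trace.events.sum(axis=0)))
    for event, expected in cohort.items():
        p = expected / base_params.cohort_size  # per-person probability
        se = np.sqrt(p * (1 - p) / n)
        observed = sim[event] / n
        assert abs(observed - p) <= 3 * se + 1e-12, (
            f"{arm} {event}: microsim {observed:.5f} vs cohort {p:.5f} (3se={3*se:.5f})"
        )
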