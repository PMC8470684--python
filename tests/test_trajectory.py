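"""Trajectory pricing: NPV, risk lookup, year-0 and annual accounting, and the
expected-mode vs stochastic-mode equivalence oracle."""

import dataclasses
import math

import numpy as np
import pytest

from brcacost.cohort import PatientProfile
from brcacost.params import default_parameters
from brcacost.trajectory import (EventDraws, annual_step, annual_risk_lookup,
                                 draw_events, npv, simulate_lifetime_cost,
                                 year0_cost)
from brcacost.paths import LEAF_PATHS, path_template

from conftest import zero_hazard_params


def make_draws(horizon, **overrides) -> EventDraws:
    """Draw bundle with every event forced off (uniforms at 1); individual
    entries are then forced on by setting them to 0 via ``overrides`` like
    ``u_detect={1: 0.0}``."""
    d = EventDraws(
        u_surgery=np.ones(2), u_radiotherapy0=1.0,
        u_tumor=np.ones(horizon + 1), u_detect=np.ones(horizon + 1),
        u_biopsy=np.ones(horizon + 1), u_surgery_event=np.ones(horizon + 1),
        u_radiotherapy_event=np.ones(horizon + 1), u_residual=np.ones(horizon + 1),
    )
    for name, spec in overrides.items():
        arr = getattr(d, name)
        if isinstance(spec, dict):
            for idx, val in spec.items():
                arr[idx] = val
        else:
            setattr(d, name, spec)
    return d


class TestNpv:
    def test_zero_rate_identity(self):
        assert npv([100, 0, 0], 0.0) == 100

    def test_one_year_discount(self):
        assert npv([0, 100], 0.03) == pytest.approx(97.0874, abs=1e-4)

    def test_annuity_closed_form(self):
        # flat ultrasound tariff over years 1..35 vs the geometric-series oracle
        flows = [0.0] + [56.55] * 35
        annuity = 56.55 * (1 - 1.03 ** -35) / 0.03
        assert npv(flows, 0.03) == pytest.approx(annuity, rel=1e-6)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            npv([1.0], -1.5)


class TestRiskLookup:
    def test_published_bracket_values(self, params):
        assert annual_risk_lookup(params.new_incidence_risk, 45) == 0.03
        assert annual_risk_lookup(params.contralateral_risk, 25) == 0.0
        assert annual_risk_lookup(params.contralateral_risk, 50) == 0.03

    def test_ages_beyond_support_reuse_last_bracket(self, params):
        assert annual_risk_lookup(params.contralateral_risk, 85) == \
            annual_risk_lookup(params.contralateral_risk, 79)


class TestYear0:
    def test_path32_tariff_sum_without_events(self, tested_patient, params):
        draws = make_draws(35)
        cost, state, _ = year0_cost(tested_patient, path_template(32), params, draws)
        assert cost == pytest.approx(20.01 + 1107 + 16530)
        assert state.intact_breasts == 0 and state.reconstruction_age_years == 0

    def test_complicated_quadrantectomy_bills_repair_surgery(self, tested_patient, params):
        draws = make_draws(35, u_surgery=np.array([0.0, 1.0]))
        cost, _, _ = year0_cost(tested_patient, path_template(11), params, draws)
        assert cost == pytest.approx(20.01 + 1107 + 2717 + 4924)

    def test_degenerate_probabilities_are_deterministic(self, params):
        patient = PatientProfile(40, True, True, 0.0)
        ps = zero_hazard_params(params)
        rng = np.random.default_rng(0)
        costs = {year0_cost(patient, path_template(31), ps, draw_events(rng, 35))[0]
                 for _ in range(10)}
        assert costs == {20.01 + 1107 + 8265}

    def test_bilateral_completion_path_costs_more_than_surveillance(self, tested_patient, params):
        draws = make_draws(35)
        c11, _, _ = year0_cost(tested_patient, path_template(11), params, draws)
        c12, _, _ = year0_cost(tested_patient, path_template(12), params, draws)
        assert c12 >= c11


class TestAnnualStep:
    def _state(self, pid, params, patient):
        _, state, _ = year0_cost(patient, path_template(pid), params, make_draws(35))
        return state

    def test_intensive_followup_alone(self, tested_patient, params):
        state = self._state(11, params, tested_patient)
        cost, _, _ = annual_step(state, path_template(11), params, make_draws(35), 1)
        assert cost == pytest.approx(263.31)

    def test_recurrence_chain_billing(self, tested_patient, params):
        state = self._state(32, params, tested_patient)
        draws = make_draws(35, u_detect={1: 0.0}, u_biopsy={1: 0.0})
        cost, _, _ = annual_step(state, path_template(32), params, draws, 1)
        assert cost == pytest.approx(56.55 + 52.08 + 4583)

    def test_contralateral_event_switches_to_ultrasound(self, tested_patient, params):
        state = self._state(31, params, tested_patient)
        draws = make_draws(35, u_tumor={1: 0.0})
        cost, state, events = annual_step(state, path_template(31), params, draws, 1)
        assert state.intact_breasts == 0
        assert state.followup_regime == "ultrasound"
        assert any("cbc_mastectomy" in e for _, e in events)
        assert cost >= 263.31 + 8265

    def test_zeroed_hazards_leave_followup_tariff_only(self, params):
        patient = PatientProfile(40, True, True, 0.0)
        ps = zero_hazard_params(params)
        traj = simulate_lifetime_cost(patient, 11, ps, "stochastic",
                                      rng=np.random.default_rng(1))
        assert traj.annual_costs[0] == pytest.approx(20.01 + 1107 + 2354)
        assert np.allclose(traj.annual_costs[1:], 263.31)


class TestImplantReplacement:
    def test_fixed_cycle_from_year0_reconstruction(self, params):
        patient = PatientProfile(40, True, True, 0.0)
        ps = zero_hazard_params(params)
        traj = simulate_lifetime_cost(patient, 32, ps, "stochastic",
                                      rng=np.random.default_rng(0))
        years = {t for t in range(1, 36) if traj.annual_costs[t] > 56.55 + 1e-9}
        assert years == {15, 30}
        assert traj.annual_costs[15] == pytest.approx(56.55 + 4924)

    def test_interval_is_configurable(self, params):
        patient = PatientProfile(40, True, True, 0.0)
        ps = zero_hazard_params(params)
        ps.engine.implant_replacement_interval_years = 10
        traj = simulate_lifetime_cost(patient, 32, ps, "stochastic",
                                      rng=np.random.default_rng(0))
        years = {t for t in range(1, 36) if traj.annual_costs[t] > 56.55 + 1e-9}
        assert years == {10, 20, 30}

    def test_event_reconstruction_restarts_cycle(self, tested_patient, params):
        draws = make_draws(35, u_tumor={5: 0.0})
        traj = simulate_lifetime_cost(tested_patient, 11, params, "stochastic", draws=draws)
        assert any(e == "implant_replacement" and y == 20 for y, e in traj.event_log)


class TestLifetime:
    def test_expected_mode_is_deterministic(self, tested_patient, params):
        a = simulate_lifetime_cost(tested_patient, 21, params, "expected")
        b = simulate_lifetime_cost(tested_patient, 21, params, "expected")
        assert np.array_equal(a.annual_costs, b.annual_costs)
        assert a.discounted_total == b.discounted_total

    def test_npv_recomputable_from_annual_costs(self, tested_patient, params):
        for pid in LEAF_PATHS:
            traj = simulate_lifetime_cost(tested_patient, pid, params, "stochastic",
                                          rng=np.random.default_rng(pid))
            assert traj.discounted_total == pytest.approx(
                npv(traj.annual_costs, params.engine.discount_rate), rel=1e-9)

    def test_aggregate_is_share_weighted_mixture(self, tested_patient, params):
        draws = make_draws(35, u_tumor={3: 0.0})
        c30 = simulate_lifetime_cost(tested_patient, 30, params, "stochastic", draws=draws)
        c31 = simulate_lifetime_cost(tested_patient, 31, params, "stochastic", draws=draws)
        c32 = simulate_lifetime_cost(tested_patient, 32, params, "stochastic", draws=draws)
        assert c30.discounted_total == pytest.approx(
            0.7 * c31.discounted_total + 0.3 * c32.discounted_total, rel=1e-12)

    @pytest.mark.parametrize("pid", LEAF_PATHS)
    def test_hazard_gating_on_prophylactic_paths(self, tested_patient, params, pid):
        rng = np.random.default_rng(42)
        n_events = 0
        for _ in range(60):
            traj = simulate_lifetime_cost(tested_patient, pid, params, "stochastic", rng=rng)
            n_events += sum(1 for _, e in traj.event_log
                            if e.startswith(("cbc_", "tumor_")))
        if pid in (12, 22, 32):
            assert n_events == 0
        else:
            assert n_events > 0  # surveillance paths do see tumor events


@pytest.mark.parametrize("pid", LEAF_PATHS)
def test_expected_mode_matches_stochastic_mean(tested_patient, params, pid):
    """Central oracle: the analytic expectation equals the Monte Carlo mean.

    10,000 independent replicates of one patient per path; agreement within
    3 standard errors.
    """
    n = 10_000
    expected = simulate_lifetime_cost(tested_patient, pid, params, "expected").discounted_total
    rng = np.random.default_rng(1000 + pid)
    totals = np.fromiter(
        (simulate_lifetime_cost(tested_patient, pid, params, "stochastic",
                                rng=rng).discounted_total for _ in range(n)),
        dtype=float, count=n)
    se = totals.std(ddof=1) / math.sqrt(n)
    assert abs(totals.mean() - expected) < 3 * se, \
        f"path {pid}: MC mean {totals.mean():.1f} vs expected {expected:.1f} (SE {se:.1f})"


_COST_FIELDS = ["quadrantectomy", "mastectomy", "bilateral_mastectomy", "intensive_followup",
                "ultrasound_followup", "biopsy", "recurrence_surgery", "plastic_surgery",
                "radiotherapy", "genetic_counseling", "brca_testing"]
_PROB_FIELDS = ["radiotherapy_after_mastectomy", "radiotherapy_after_quadrantectomy",
                "recurrence_detection", "positive_biopsy", "residual_gland_carcinoma"]


@pytest.mark.parametrize("kind,name", [("cost", f) for f in _COST_FIELDS]
                         + [("prob", f) for f in _PROB_FIELDS]
                         + [("risk", "new_incidence"), ("risk", "contralateral"),
                            ("discount", "down")])
def test_expected_cost_monotone_in_parameters(tested_patient, params, kind, name):
    """Raising any tariff or hazard, or lowering the discount rate, never
    decreases an expected lifetime cost."""
    base = {pid: simulate_lifetime_cost(tested_patient, pid, params, "expected").discounted_total
            for pid in LEAF_PATHS}
    ps = params.copy()
    if kind == "cost":
        setattr(ps.costs, name, getattr(ps.costs, name) * 1.25)
        for b, c in ps.costs._PAIRS:  # keep the complication variants consistent
            if getattr(ps.costs, c) < getattr(ps.costs, b):
                setattr(ps.costs, c, getattr(ps.costs, b))
    elif kind == "prob":
        ps.probabilities[name] = min(1.0, ps.probabilities[name] + 0.2)
    elif kind == "risk":
        table = ps.new_incidence_risk if name == "new_incidence" else ps.contralateral_risk
        table.brackets = [(lo, hi, min(1.0, p + 0.01)) for lo, hi, p in table.brackets]
    else:
        ps.engine.discount_rate = 0.01
    ps.validate()
    for pid in LEAF_PATHS:
        after = simulate_lifetime_cost(tested_patient, pid, ps, "expected").discounted_total
        assert after >= base[pid] - 1e-9, f"path {pid} decreased under {kind}:{name}"
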