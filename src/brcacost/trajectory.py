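"""Lifetime cost trajectories: one patient x one therapeutic path.

A trajectory accrues year-0 charges (counseling, BRCA test, one or two
operations with Bernoulli complications, radiotherapy) and then, for each of
the ``horizon_years`` annual cycles: the follow-up tariff, the local-recurrence
workup chain (detection -> biopsy -> recurrence surgery), tumor events in
breast tissue still under surveillance (a new primary in a conserved breast
and/or contralateral breast cancer, treated as risk-reducing completion
surgery), the residual/ectopic-gland carcinoma risk after prophylactic surgery,
and periodic breast-implant replacement.  Totals are discounted to present
value at the configured annual rate (year 0 undiscounted).

Two pricing modes share the same cash-flow timing:

``stochastic``
    one realised history, driven by a :class:`EventDraws` bundle of uniform
    draws.  Reusing one bundle across paths yields common random numbers: a
    single draw decides each patient-year uncertainty for every path, and
    hazard tests are nested, so path cost differences reflect structure, not
    independent noise.
``expected``
    every Bernoulli branch replaced by its probability weight; deterministic
    given the patient's attributes.  Exact because each path's tumor-event
    process has a single absorbing transition, so the survival curve is closed
    form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import AgeRiskTable, ParameterSet
from .paths import SURGERY_KINDS, PathTemplate, aggregate_shares, path_template

__all__ = [
    "npv", "annual_risk_lookup", "EventDraws", "draw_events", "HealthState",
    "year0_cost", "annual_step", "simulate_lifetime_cost", "CostTrajectory",
]

_RT_PROB_KEY = {
    "after_quadrantectomy": "radiotherapy_after_quadrantectomy",
    "after_mastectomy": "radiotherapy_after_mastectomy",
}


def npv(cash_flows, rate: float) -> float:
    """Present value of annual cash flows; index 0 is the treatment year.

    ``sum_t cash[t] / (1 + rate)**t`` -- no half-cycle correction.
    """
    if rate <= -1:
        raise ValueError(f"discount rate must exceed -1, got {rate}")
    flows = np.asarray(cash_flows, dtype=float)
    t = np.arange(flows.shape[-1], dtype=float)
    return float(np.sum(flows / (1.0 + rate) ** t, axis=-1))


def annual_risk_lookup(table: AgeRiskTable, age) -> float:
    """Annual probability for the bracket containing ``age`` (clamped to 20-79)."""
    return table.lookup(age)


@dataclass
class EventDraws:
    """Uniform draws for one patient's trajectory uncertainties.

    Annual arrays are indexed 1..horizon (index 0 unused).  Sharing one bundle
    across paths implements common random numbers.
    """

    u_surgery: np.ndarray  # per year-0 operation slot (2,)
    u_radiotherapy0: float
    u_tumor: np.ndarray  # tumor-event test, per year
    u_detect: np.ndarray  # recurrence detection, per year
    u_biopsy: np.ndarray  # biopsy outcome, per year
    u_surgery_event: np.ndarray  # complication of an event surgery, per year
    u_radiotherapy_event: np.ndarray  # radiotherapy after an event surgery, per year
    u_residual: np.ndarray  # residual-gland carcinoma, per year


def draw_events(rng: np.random.Generator, horizon: int) -> EventDraws:
    head = rng.random(3)
    annual = rng.random((6, horizon + 1))
    return EventDraws(
        u_surgery=head[:2], u_radiotherapy0=float(head[2]),
        u_tumor=annual[0], u_detect=annual[1], u_biopsy=annual[2],
        u_surgery_event=annual[3], u_radiotherapy_event=annual[4], u_residual=annual[5],
    )


@dataclass
class HealthState:
    """Dynamic state of one patient on one path."""

    age: int
    intact_breasts: int  # breast sides still under surveillance (0, 1 or 2)
    contralateral_breast_present: bool
    followup_regime: str
    reconstruction_age_years: int | None  # years since last reconstruction
    post_prophylactic: bool
    residual_gland_event_used: bool = False
    complication_risk: float = 0.15


def _tumor_hazard(params: ParameterSet, intact_breasts: int, age: int) -> float:
    """Annual probability of a tumor event in remaining surveilled tissue.

    With two intact breasts (conserved affected breast + contralateral) the
    new-incidence and contralateral hazards combine as independent risks; with
    one, only the contralateral hazard applies.  Under the
    ``detection_chain_only`` relapse model the conserved breast carries no
    hazard beyond the flat recurrence chain.
    """
    if intact_breasts <= 0:
        return 0.0
    p_cbc = params.contralateral_risk.lookup(age)
    if intact_breasts == 2 and params.engine.relapse_model == "incidence_hazard":
        p_inc = params.new_incidence_risk.lookup(age)
        return 1.0 - (1.0 - p_inc) * (1.0 - p_cbc)
    return p_cbc


def _surgery_cost(kind: str, complicated: bool, costs) -> float:
    # any complicated operation is billed at its complication tariff plus the
    # plastic-surgery repair charge ("plastic surgery after complications")
    base_key, comp_key, _ = SURGERY_KINDS[kind]
    cost = getattr(costs, comp_key if complicated else base_key)
    if complicated:
        cost += costs.plastic_surgery
    return cost


def _expected_surgery_cost(kind: str, p_comp: float, costs) -> float:
    base_key, comp_key, _ = SURGERY_KINDS[kind]
    extra = getattr(costs, comp_key) - getattr(costs, base_key) + costs.plastic_surgery
    return getattr(costs, base_key) + p_comp * extra


def year0_cost(patient, template: PathTemplate, params: ParameterSet,
               draws: EventDraws | None = None, expected: bool = False):
    """Treatment-year charges and the resulting health state."""
    if template.is_aggregate:
        raise ValueError("year-0 pricing applies to leaf paths only")
    costs = params.costs
    events: list[tuple[int, str]] = []
    total = 0.0
    if template.includes_counseling:
        total += costs.genetic_counseling
    if template.includes_test:
        total += costs.brca_testing
    p = patient.complication_risk
    for slot, kind in enumerate(template.initial_surgeries):
        if expected:
            total += _expected_surgery_cost(kind, p, costs)
        else:
            complicated = bool(draws.u_surgery[slot] < p)
            total += _surgery_cost(kind, complicated, costs)
            events.append((0, kind + ("+complication" if complicated else "")))
    p_rt = params.probabilities[_RT_PROB_KEY[template.radiotherapy_key]] \
        if template.radiotherapy_key != "none" else 0.0
    if expected:
        total += p_rt * costs.radiotherapy
    elif draws.u_radiotherapy0 < p_rt:
        total += costs.radiotherapy
        events.append((0, "radiotherapy"))
    state = HealthState(
        age=patient.starting_age,
        intact_breasts=template.intact_breasts,
        contralateral_breast_present=template.contralateral_breast_present,
        followup_regime=template.followup_regime,
        reconstruction_age_years=0 if template.reconstruction_present else None,
        post_prophylactic=template.post_prophylactic,
        complication_risk=p,
    )
    return total, state, events


def annual_step(state: HealthState, template: PathTemplate, params: ParameterSet,
                draws: EventDraws, year: int):
    """One realised annual cycle; returns (cost, new state, events).

    Within-year ordering: follow-up, recurrence workup, tumor event,
    residual-gland event, implant replacement.  All charges land in the same
    annual bucket, so the ordering affects the event log only.
    """
    costs = params.costs
    events: list[tuple[int, str]] = []
    cost = 0.0
    recon_entering = state.reconstruction_age_years
    state = replace(state, age=state.age + 1)

    # (a) follow-up at the regime in force entering the year
    cost += costs.intensive_followup if state.followup_regime == "intensive" \
        else costs.ultrasound_followup

    # (b) local recurrence workup: detection -> biopsy -> surgery
    if draws.u_detect[year] < params.probabilities["recurrence_detection"]:
        cost += costs.biopsy
        events.append((year, "suspected_recurrence_biopsy"))
        if draws.u_biopsy[year] < params.probabilities["positive_biopsy"]:
            cost += costs.recurrence_surgery
            events.append((year, "recurrence_surgery"))

    # (c) tumor event in surveilled tissue -> risk-reducing completion surgery
    had_event = False
    h = _tumor_hazard(params, state.intact_breasts, state.age)
    if h > 0 and draws.u_tumor[year] < h:
        had_event = True
        kind = "bilateral_mastectomy" if state.intact_breasts == 2 else "mastectomy"
        complicated = bool(draws.u_surgery_event[year] < state.complication_risk)
        cost += _surgery_cost(kind, complicated, costs)
        if draws.u_radiotherapy_event[year] < params.probabilities["radiotherapy_after_mastectomy"]:
            cost += costs.radiotherapy
            events.append((year, "radiotherapy"))
        events.append((year, ("cbc_" if state.intact_breasts == 1 else "tumor_") + kind
                       + ("+complication" if complicated else "")))
        state = replace(state, intact_breasts=0, contralateral_breast_present=False,
                        followup_regime="ultrasound")

    # (d) residual/ectopic glandular carcinoma after prophylactic surgery
    if state.post_prophylactic and not state.residual_gland_event_used:
        if draws.u_residual[year] < params.residual_gland_annual_hazard():
            cost += costs.recurrence_surgery
            events.append((year, "residual_gland_carcinoma"))
            state = replace(state, residual_gland_event_used=True)

    # (e) implant replacement on a fixed cycle from the most recent reconstruction
    interval = params.engine.implant_replacement_interval_years
    if had_event:
        new_clock: int | None = 0  # event surgery included reconstruction
    elif recon_entering is not None:
        new_clock = recon_entering + 1
        if new_clock == interval:
            cost += costs.plastic_surgery
            events.append((year, "implant_replacement"))
            new_clock = 0
    else:
        new_clock = None
    state = replace(state, reconstruction_age_years=new_clock)
    return cost, state, events


@dataclass
class CostTrajectory:
    """Per-year cash flows for one patient x path and their discounted total."""

    path_id: int | str
    annual_costs: np.ndarray  # length horizon + 1; index 0 = treatment year
    discounted_total: float
    event_log: list[tuple[int, str]] = field(default_factory=list)


def _expected_trajectory(patient, template: PathTemplate, params: ParameterSet) -> CostTrajectory:
    eng = params.engine
    H = eng.horizon_years
    costs = params.costs
    annual = np.zeros(H + 1)
    annual[0], _, _ = year0_cost(patient, template, params, expected=True)

    chain = params.probabilities["recurrence_detection"] * (
        costs.biopsy + params.probabilities["positive_biopsy"] * costs.recurrence_surgery)
    h_rg = params.residual_gland_annual_hazard()
    kind = "bilateral_mastectomy" if template.intact_breasts == 2 else "mastectomy"
    event_cost = (_expected_surgery_cost(kind, patient.complication_risk, costs)
                  + params.probabilities["radiotherapy_after_mastectomy"] * costs.radiotherapy)
    interval = eng.implant_replacement_interval_years

    S_prev = 1.0  # P(no tumor event in years 1..t-1)
    f = np.zeros(H + 1)  # tumor-event year distribution
    s_rg = 1.0
    for t in range(1, H + 1):
        h = _tumor_hazard(params, template.intact_breasts, patient.starting_age + t)
        f[t] = S_prev * h
        c = chain
        if template.followup_regime == "intensive":
            c += S_prev * costs.intensive_followup + (1.0 - S_prev) * costs.ultrasound_followup
        else:
            c += costs.ultrasound_followup
        c += f[t] * event_cost
        if template.post_prophylactic:
            c += s_rg * h_rg * costs.recurrence_surgery
            s_rg *= 1.0 - h_rg
        S_prev -= f[t]
        # implant replacements: year-0 reconstruction on its fixed cycle while no
        # event has reset the clock; an event reconstruction starts a new cycle
        w = 0.0
        if template.reconstruction_present and t % interval == 0:
            w += S_prev
        tau = t - interval
        while tau >= 1:
            w += f[tau]
            tau -= interval
        c += w * costs.plastic_surgery
        annual[t] = c
    return CostTrajectory(template.path_id, annual, npv(annual, eng.discount_rate))


def _stochastic_trajectory(patient, template: PathTemplate, params: ParameterSet,
                           draws: EventDraws) -> CostTrajectory:
    H = params.engine.horizon_years
    annual = np.zeros(H + 1)
    annual[0], state, log = year0_cost(patient, template, params, draws=draws)
    for t in range(1, H + 1):
        annual[t], state, events = annual_step(state, template, params, draws, t)
        log.extend(events)
    return CostTrajectory(template.path_id, annual, npv(annual, params.engine.discount_rate), log)


def simulate_lifetime_cost(patient, path_id, params: ParameterSet, mode: str = "stochastic",
                           rng: np.random.Generator | None = None,
                           draws: EventDraws | None = None) -> CostTrajectory:
    """Price one patient on one path over the horizon.

    Aggregate nodes (0, 10, 20, 30) are priced as share-weighted mixtures of
    their children, with the children sharing the same draws in stochastic
    mode.  For leaf paths in stochastic mode, supply ``draws`` to couple paths
    (common random numbers) or ``rng`` / the patient's own event stream to
    sample fresh ones.
    """
    if params.engine.horizon_years < 1:
        raise ValueError("horizon must be >= 1 year")
    if mode not in ("stochastic", "expected"):
        raise ValueError(f"unknown mode {mode!r}")
    template = path_template(path_id)
    if mode == "stochastic" and draws is None and not template.is_aggregate:
        draws = draw_events(rng if rng is not None else patient.event_rng(),
                            params.engine.horizon_years)
    if template.is_aggregate:
        if mode == "stochastic" and draws is None:
            draws = draw_events(rng if rng is not None else patient.event_rng(),
                                params.engine.horizon_years)
        shares = aggregate_shares(template.path_id, params)
        annual = np.zeros(params.engine.horizon_years + 1)
        for child in template.sub_paths:
            sub = simulate_lifetime_cost(patient, child, params, mode, draws=draws)
            annual += shares[child] * sub.annual_costs
        return CostTrajectory(path_id, annual, npv(annual, params.engine.discount_rate))
    if mode == "expected":
        return _expected_trajectory(patient, template, params)
    return _stochastic_trajectory(patient, template, params, draws)
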