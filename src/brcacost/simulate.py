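"""Full probabilistic analysis: cohort x paths x decision, with summaries.

Each iteration samples one patient, prices every admissible strategy on that
patient's common-random-number stream, selects the optimum, samples the
historical "as is" path, and records the discounted net unit saving.  All model
inputs vary simultaneously across their distributions (probabilistic
sensitivity analysis); the default run uses 10,000 iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import sample_cohort
from .decision import (OptimalChoice, evaluate_paths, net_unit_savings,
                       sample_asis_path, select_optimal)
from .params import ParameterSet, ScenarioSpec, apply_scenario
from .paths import LEAF_PATHS
from .trajectory import draw_events, simulate_lifetime_cost

__all__ = ["SummaryStats", "SimulationResult", "run_simulation", "summarize",
           "convergence_check"]

RECORD_COLUMNS = ["iteration", "starting_age", "counseled", "tested",
                  "complication_risk", "asis_path", "asis_cost",
                  "optimal_path", "optimal_cost", "tie", "savings"]


@dataclass
class SummaryStats:
    n: int
    savings_mean: float
    savings_sd: float
    savings_min: float
    savings_max: float
    prob_savings_positive: float
    optimal_path_distribution: dict = field(default_factory=dict)
    asis_path_distribution: dict = field(default_factory=dict)
    mean_cost_per_path: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "Mean": self.savings_mean, "SD": self.savings_sd,
            "Min": self.savings_min, "Max": self.savings_max,
            "Prob(Net unit savings > 0)": self.prob_savings_positive,
        }
        return pd.DataFrame({"Net unit savings (EUR)": rows})


@dataclass
class SimulationResult:
    records: pd.DataFrame
    summary: SummaryStats
    manifest: dict = field(default_factory=dict)


def summarize(records: pd.DataFrame) -> SummaryStats:
    """Sample statistics over per-iteration savings and path distributions."""
    if len(records) == 0:
        raise ValueError("no records to summarize")
    s = records["savings"].to_numpy(dtype=float)
    n = len(s)
    dist_opt = records["optimal_path"].value_counts(normalize=True).to_dict()
    dist_asis = records["asis_path"].value_counts(normalize=True).to_dict()
    mean_costs = (records[records["tested"]].groupby("asis_path")["asis_cost"].mean().to_dict()
                  if records["tested"].any() else {})
    return SummaryStats(
        n=n,
        savings_mean=float(s.mean()),
        savings_sd=float(s.std(ddof=1)) if n > 1 else 0.0,
        savings_min=float(s.min()),
        savings_max=float(s.max()),
        prob_savings_positive=float((s > 0).mean()),
        optimal_path_distribution={int(k): float(v) for k, v in dist_opt.items()},
        asis_path_distribution={int(k): float(v) for k, v in dist_asis.items()},
        mean_cost_per_path={int(k): float(v) for k, v in mean_costs.items()},
    )


def _iterate_patient(patient, params: ParameterSet, mode: str, asis_rng) -> dict:
    eng = params.engine
    asis_path = sample_asis_path(patient, params, asis_rng)
    if not patient.tested:
        # Path 0: standard care, no optimisation possible.  The cost is
        # reported for audit; savings are zero by convention.
        if mode == "stochastic":
            variant = "0q" if asis_rng.random() < params.asis_shares.quadrantectomy_first else "0m"
            cost0 = simulate_lifetime_cost(patient, variant, params, "stochastic").discounted_total
        else:
            cost0 = simulate_lifetime_cost(patient, 0, params, "expected").discounted_total
        return dict(asis_path=0, asis_cost=cost0, optimal_path=0,
                    optimal_cost=math.nan, tie=False, savings=0.0)

    if mode == "stochastic":
        draws = draw_events(patient.event_rng(), eng.horizon_years)
        realized = evaluate_paths(patient, params, "stochastic", draws=draws)
        if eng.decision_basis == "expected":
            # policy basis: choose on expected costs, realise the consequences
            expected_set = evaluate_paths(patient, params, "expected")
            choice = select_optimal(expected_set, eng.tie_tolerance)
            argmin = min((31, 32, 21, 22, 11, 12), key=lambda p: expected_set.costs[p])
            choice = OptimalChoice(choice.reported_path, realized.costs[argmin], choice.tie)
        else:
            choice = select_optimal(realized, eng.tie_tolerance)
        asis_cost = realized.costs[asis_path]
    else:
        cost_set = evaluate_paths(patient, params, "expected")
        choice = select_optimal(cost_set, eng.tie_tolerance)
        asis_cost = cost_set.costs[asis_path]
    return dict(asis_path=asis_path, asis_cost=asis_cost,
                optimal_path=choice.reported_path, optimal_cost=choice.optimal_cost,
                tie=choice.tie, savings=net_unit_savings(asis_cost, choice))


def run_simulation(params: ParameterSet, scenario: ScenarioSpec | str | None = None,
                   n_iterations: int | None = None, seed: int | None = None,
                   mode: str | None = None) -> SimulationResult:
    """Run the probabilistic analysis and return per-iteration records + summary.

    Identical ``(params, scenario, n_iterations, seed, mode)`` give identical
    results bit-for-bit.  ``mode`` is ``stochastic`` (realised common-random-
    number trajectories; the headline setting) or ``expected`` (event
    uncertainty integrated analytically; patient-level uncertainty only).
    """
    if isinstance(scenario, str):
        scenario = ScenarioSpec(scenario)
    if scenario is not None:
        params = apply_scenario(params, scenario)
    else:
        params = params.copy().validate()
    eng = params.engine
    n = int(n_iterations if n_iterations is not None else eng.n_iterations)
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    seed = int(seed if seed is not None else eng.seed)
    mode = mode or eng.mode

    cohort = sample_cohort(params, n, seed)
    asis_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 2**20])))
    rows = []
    for i, patient in enumerate(cohort):
        rec = _iterate_patient(patient, params, mode, asis_rng)
        rec.update(iteration=i, starting_age=patient.starting_age,
                   counseled=patient.counseled, tested=patient.tested,
                   complication_risk=patient.complication_risk)
        rows.append(rec)
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    manifest = {
        "scenario": scenario.name if scenario is not None else "baseline",
        "n_iterations": n, "seed": seed, "mode": mode,
        "discount_rate": eng.discount_rate, "horizon_years": eng.horizon_years,
        "tie_tolerance": eng.tie_tolerance,
    }
    return SimulationResult(records, summarize(records), manifest)


def convergence_check(params: ParameterSet, scenario=None, seeds=(0, 1, 2, 3, 4),
                      n_iterations: int | None = None) -> dict:
    """Across-seed dispersion of the headline statistics.

    Flags the run if the across-seed SD of Prob(savings > 0) exceeds twice the
    binomial standard error at the configured iteration count.
    """
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    means, probs = [], []
    for s in seeds:
        res = run_simulation(params, scenario, n_iterations=n_iterations, seed=s)
        means.append(res.summary.savings_mean)
        probs.append(res.summary.prob_savings_positive)
    n = int(n_iterations if n_iterations is not None else params.engine.n_iterations)
    p = float(np.mean(probs))
    se = math.sqrt(max(p * (1 - p), 1e-12) / n)
    sd_prob = float(np.std(probs, ddof=1))
    return {
        "seeds": list(seeds),
        "mean_savings_by_seed": means,
        "prob_positive_by_seed": probs,
        "sd_mean_savings": float(np.std(means, ddof=1)),
        "sd_prob_positive": sd_prob,
        "binomial_se": se,
        "flagged": bool(sd_prob > 2 * se),
    }
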