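"""The experiment plan: baseline and the three scenario analyses.

* **baseline** -- historical counseling and testing uptake (45% each,
  sequential), so only ~20% of patients enter the optimisation.
* **scenario 1** -- genetic counseling extended to all patients; testing
  uptake stays at its historical 45%.
* **scenario 2** -- counseling and BRCA testing extended to all patients;
  optionally swept over starting-age means 20-70.
* **scenario 3** -- surgery only after the test result: a paired comparison,
  on a common tested cohort, of the two post-test strategies (unilateral
  mastectomy + intensive radiological follow-up vs bilateral mastectomy +
  ultrasound follow-up).

Scenario 3 is reported both as full lifetime costs and as one-sided excess
costs of each trajectory over the other (the excess is zero in the iterations
where that trajectory is the cheaper of the pair); the mean excess difference
equals the mean paired cost difference.  The comparison prices the
pre-test-labelled "Path 21" trajectory, which is clinically identical to the
post-test Path 31 the scenario text describes; output metadata carries both
labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import sample_cohort
from .params import ParameterSet, ScenarioSpec, apply_scenario
from .simulate import run_simulation
from .trajectory import draw_events, simulate_lifetime_cost

__all__ = ["build_scenario", "run_scenario3", "run_age_sweep", "sensitivity_scan",
           "DEFAULT_SWEEP_AGES"]

DEFAULT_SWEEP_AGES = (20, 30, 40, 50, 60, 70)


def build_scenario(name: str, ages=None):
    """Return the ScenarioSpec for a named experiment.

    ``scenario2_age_sweep`` returns one spec per starting age (mean shifted,
    SD unchanged).
    """
    if name == "baseline":
        return ScenarioSpec("baseline")
    if name == "scenario1":
        return ScenarioSpec("scenario1")
    if name == "scenario2":
        return ScenarioSpec("scenario2")
    if name == "scenario3":
        return ScenarioSpec("scenario3")
    if name == "scenario2_age_sweep":
        ages = DEFAULT_SWEEP_AGES if ages is None else tuple(ages)
        return [
            ScenarioSpec("scenario2_age_sweep",
                         overrides={"distributions.starting_age":
                                    {"family": "normal", "mean": float(a), "sd": 2.5}},
                         age_sweep_values=list(ages))
            for a in ages
        ]
    raise ValueError(f"unknown scenario name {name!r}")


def _stats(x: np.ndarray) -> dict:
    return {"mean": float(x.mean()), "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            "min": float(x.min()), "max": float(x.max())}


def run_scenario3(params: ParameterSet, n_iterations: int | None = None,
                  seed: int = 0) -> dict:
    """Paired lifetime-cost comparison of the two post-test strategies.

    Both trajectories are priced on the same tested cohort with common random
    numbers.  Returns full-cost summaries, the paired difference
    (bilateral+ultrasound minus unilateral+intensive), and the one-sided
    excess-cost distributions of each trajectory over the other.
    """
    ps = apply_scenario(params, ScenarioSpec("scenario3"))
    n = int(n_iterations if n_iterations is not None else ps.engine.n_iterations)
    cohort = sample_cohort(ps, n, seed)
    cost_uni = np.empty(n)
    cost_bil = np.empty(n)
    for i, patient in enumerate(cohort):
        draws = draw_events(patient.event_rng(), ps.engine.horizon_years)
        cost_uni[i] = simulate_lifetime_cost(patient, 21, ps, "stochastic",
                                             draws=draws).discounted_total
        cost_bil[i] = simulate_lifetime_cost(patient, 32, ps, "stochastic",
                                             draws=draws).discounted_total
    diff = cost_bil - cost_uni
    return {
        "labels": {
            "unilateral_intensive": "Path 21 (identical trajectory to post-test Path 31)",
            "bilateral_ultrasound": "Path 32",
        },
        "n": n, "seed": seed,
        "cost_unilateral_intensive": _stats(cost_uni),
        "cost_bilateral_ultrasound": _stats(cost_bil),
        "difference_bilateral_minus_unilateral": _stats(diff),
        "excess_unilateral_intensive": _stats(np.maximum(-diff, 0.0)),
        "excess_bilateral_ultrasound": _stats(np.maximum(diff, 0.0)),
    }


def run_age_sweep(params: ParameterSet, ages=None, n_iterations: int | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Scenario 2 swept over starting-age means; one summary row per age."""
    specs = build_scenario("scenario2_age_sweep", ages)
    rows = []
    for spec in specs:
        age = spec.overrides["distributions.starting_age"]["mean"]
        res = run_simulation(params, spec, n_iterations=n_iterations, seed=seed)
        s = res.summary
        rows.append({"starting_age": age, "mean": s.savings_mean, "sd": s.savings_sd,
                     "min": s.savings_min, "max": s.savings_max,
                     "prob_savings_positive": s.prob_savings_positive})
    return pd.DataFrame(rows)


def sensitivity_scan(params: ParameterSet, n_iterations: int = 2000, seed: int = 0,
                     tie_tolerances=(0.0, 250.0, 1000.0, 2500.0, 5000.0),
                     implant_intervals=(10, 15),
                     relapse_models=("incidence_hazard", "detection_chain_only")) -> pd.DataFrame:
    """Scenario-2 headline statistics across engine design options.

    Sweeps the tie tolerance, the implant replacement interval and the relapse
    hazard model, reporting mean savings, Prob(savings > 0) and the
    optimal-node-30 mass for each combination.
    """
    rows = []
    for model in relapse_models:
        for interval in implant_intervals:
            for tol in tie_tolerances:
                ps = params.copy()
                ps.engine.relapse_model = model
                ps.engine.implant_replacement_interval_years = int(interval)
                ps.engine.tie_tolerance = float(tol)
                res = run_simulation(ps, "scenario2", n_iterations=n_iterations, seed=seed)
                s = res.summary
                rows.append({
                    "relapse_model": model, "implant_interval": interval,
                    "tie_tolerance": tol, "mean_savings": s.savings_mean,
                    "prob_savings_positive": s.prob_savings_positive,
                    "prob_path30_optimal": s.optimal_path_distribution.get(30, 0.0),
                })
    return pd.DataFrame(rows)
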