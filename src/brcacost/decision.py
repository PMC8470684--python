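"""Per-patient decision logic: price every path, pick the cheapest, compare
with the historically sampled "as is" path, and compute net unit savings.

The five steps for a tested patient are: (1) price the six leaf strategies on
common random numbers, (2) choose the minimum-cost one -- reporting the parent
"no preference" node when both children of a decision node are within the tie
tolerance of the minimum, (3) sample the path the patient would historically
have followed, (4) compare its cost with the optimum, (5) report the
difference, floored at zero, as the discounted net unit saving.  Untested
patients follow Path 0 and contribute zero savings by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet
from .paths import AGGREGATE_PATHS, LEAF_PATHS, aggregate_shares
from .trajectory import EventDraws, draw_events, simulate_lifetime_cost

__all__ = ["PathCostSet", "OptimalChoice", "evaluate_paths", "select_optimal",
           "sample_asis_path", "net_unit_savings"]

#: leaves in argmin preference order: post-test strategies first, so that the
#: exact cost tie between the clinically identical paths 21 and 31 resolves to
#: the post-test label.
_LEAF_ORDER = (31, 32, 21, 22, 11, 12)

_SIBLING = {31: 32, 32: 31, 21: 22, 22: 21, 11: 12, 12: 11}
_PARENT = {31: 30, 32: 30, 21: 20, 22: 20, 11: 10, 12: 10}


@dataclass
class PathCostSet:
    """Discounted total cost per path for one patient (one pricing basis)."""

    costs: dict = field(default_factory=dict)  # path_id -> discounted_total
    mode: str = "stochastic"

    def leaf_costs(self) -> dict:
        return {p: self.costs[p] for p in LEAF_PATHS if p in self.costs}


@dataclass
class OptimalChoice:
    reported_path: int  # may be an aggregate node 10/20/30
    optimal_cost: float  # min over admissible leaf costs
    tie: bool = False


def evaluate_paths(patient, params: ParameterSet, mode: str | None = None,
                   draws: EventDraws | None = None,
                   rng: np.random.Generator | None = None) -> PathCostSet:
    """Price the six leaf strategies (plus reporting aggregates) for a patient.

    In stochastic mode all paths share one :class:`EventDraws` bundle (common
    random numbers from the patient's private stream), so cost differences are
    structural rather than sampling noise.
    """
    if not patient.tested:
        return PathCostSet({}, mode or params.engine.mode)
    mode = mode or params.engine.mode
    if mode == "stochastic" and draws is None:
        draws = draw_events(rng if rng is not None else patient.event_rng(),
                            params.engine.horizon_years)
    costs = {}
    for pid in LEAF_PATHS:
        costs[pid] = simulate_lifetime_cost(patient, pid, params, mode, draws=draws).discounted_total
    for node in AGGREGATE_PATHS:
        shares = aggregate_shares(node, params)
        costs[node] = sum(w * costs[child] for child, w in shares.items())
    return PathCostSet(costs, mode)


def select_optimal(cost_set: PathCostSet, tie_tolerance: float) -> OptimalChoice:
    """Cheapest strategy, with near-ties between siblings reported as their
    "no preference" aggregate node."""
    leaves = cost_set.leaf_costs()
    if not leaves:
        raise ValueError("empty path cost set")
    best = min(_LEAF_ORDER, key=lambda p: (leaves[p], _LEAF_ORDER.index(p)))
    best_cost = leaves[best]
    sibling_cost = leaves[_SIBLING[best]]
    if tie_tolerance > 0 and sibling_cost - best_cost <= tie_tolerance:
        return OptimalChoice(_PARENT[best], best_cost, tie=True)
    return OptimalChoice(best, best_cost, tie=False)


def sample_asis_path(patient, params: ParameterSet, rng: np.random.Generator):
    """Historical therapeutic path: 0 for untested patients, otherwise a leaf
    drawn from the observed clinical shares.

    The post-test share is marginal; the quadrantectomy/mastectomy-first split
    applies within the remaining pre-test mass, and second-level choices follow
    the conditional node shares.
    """
    if not patient.tested:
        return 0
    sh = params.asis_shares
    if rng.random() < sh.post_test:
        node = 30
    elif rng.random() < sh.quadrantectomy_first / (sh.quadrantectomy_first + sh.mastectomy_first):
        node = 10
    else:
        node = 20
    shares = aggregate_shares(node, params)
    children = sorted(shares)
    probs = np.array([shares[c] for c in children])
    return int(children[int(rng.choice(len(children), p=probs / probs.sum()))])


def net_unit_savings(asis_cost: float, choice: OptimalChoice | None) -> float:
    """Discounted saving from following the optimal rather than the as-is path,
    floored at zero; untested patients (no choice available) save nothing."""
    if choice is None:
        return 0.0
    return max(asis_cost - choice.optimal_cost, 0.0)
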