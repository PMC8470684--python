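"""Synthetic patient cohort with the stochastic structure the model assumes.

A simulated patient is a woman with a first breast-cancer diagnosis, eligible
for the BRCA testing programme.  Starting age is Normal (rounded to whole years
and clamped to the 20-79 risk-table support), counseling and testing are
sequential Bernoulli gates (a patient can only be tested if counseled), and the
surgery-complication risk is a patient-level Uniform(0.10, 0.20) draw.  Every
modeled patient is BRCA-positive: carriers are the only patients entering the
path comparison, so the population positivity rate is carried in the parameter
set but does not gate the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet

__all__ = ["PatientProfile", "sample_patient", "sample_cohort"]


@dataclass
class PatientProfile:
    starting_age: int
    counseled: bool
    tested: bool
    complication_risk: float
    brca_positive: bool = True
    event_seed: np.random.SeedSequence | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.tested and not self.counseled:
            raise ValueError("tested implies counseled")

    def event_rng(self) -> np.random.Generator:
        """Fresh generator on this patient's private event stream.

        Restarting the stream yields identical draws, which is what couples the
        per-path trajectories (common random numbers).
        """
        if self.event_seed is None:
            raise ValueError("patient has no event seed attached")
        return np.random.Generator(np.random.PCG64(self.event_seed))

    def key(self) -> tuple:
        return (self.starting_age, self.counseled, self.tested, round(self.complication_risk, 12))


def sample_patient(params: ParameterSet, rng: np.random.Generator,
                   event_seed: np.random.SeedSequence | None = None) -> PatientProfile:
    """Draw one patient profile from the configured input distributions."""
    age = int(round(params.distributions["starting_age"].sample(rng)))
    age = min(max(age, 20), 79)
    counseled = bool(rng.random() < params.p_counseling)
    tested = counseled and bool(rng.random() < params.p_testing)
    lo = params.distributions["complication_risk"]
    comp = float(lo.sample(rng))
    return PatientProfile(age, counseled, tested, comp, event_seed=event_seed)


def sample_cohort(params: ParameterSet, n: int, seed: int) -> list[PatientProfile]:
    """n independent patients; bit-reproducible for a given seed.

    Each patient owns two private sub-streams split from the master seed (one
    for profile attributes, one for trajectory events), so per-patient results
    do not depend on cohort size or iteration order.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n)
    cohort = []
    for child in children:
        attr_seed, event_seed = child.spawn(2)
        rng = np.random.Generator(np.random.PCG64(attr_seed))
        cohort.append(sample_patient(params, rng, event_seed=event_seed))
    return cohort
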