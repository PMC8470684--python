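"""Model parameters: probabilities, age-stratified risks, DRG tariffs, engine settings.

Every numeric input of the cost decision model lives here.  Defaults transcribe
the published Italian single-institute inputs: Bernoulli uptake probabilities and
event probabilities, age-bracket annual cancer hazards, DRG-tariff unit costs in
EUR, the historical ("as is") therapeutic-path shares, and the simulation engine
settings (3% discounting, 35-year horizon, 10,000 iterations).

Parameters load from a YAML document (sections ``probabilities``, ``risks``,
``costs``, ``asis_shares``, ``engine``); absent keys fall back to the defaults.
Age-risk tables may alternatively be supplied as CSV with columns
``age_lo, age_hi, probability``.
"""

from __future__ import annotations

import copy
import csv
import dataclasses
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ParameterError",
    "DistributionSpec",
    "AgeRiskTable",
    "CostTable",
    "AsIsShares",
    "EngineSettings",
    "ParameterSet",
    "ScenarioSpec",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "apply_scenario",
]


class ParameterError(ValueError):
    """A model parameter failed validation; the message names the offending key."""


def _check_prob(value: float, key: str) -> None:
    if not (isinstance(value, (int, float)) and 0.0 <= value <= 1.0):
        raise ParameterError(f"{key} must be a probability in [0, 1], got {value!r}")


@dataclass
class DistributionSpec:
    """A univariate sampling distribution for one model input.

    ``family`` is one of ``normal`` (params: mean, sd), ``uniform`` (min, max),
    ``bernoulli`` (p) or ``point`` (value).  ``point`` is the degenerate
    distribution used by scenario overrides (e.g. universal testing uptake).
    """

    family: str
    params: dict[str, float]

    _FAMILIES = ("normal", "uniform", "bernoulli", "point")

    def validate(self, key: str = "distribution") -> None:
        if self.family not in self._FAMILIES:
            raise ParameterError(f"{key}: unknown distribution family {self.family!r}")
        p = self.params
        try:
            if self.family == "normal":
                if p["sd"] < 0:
                    raise ParameterError(f"{key}: normal sd must be >= 0, got {p['sd']}")
            elif self.family == "uniform":
                if p["min"] > p["max"]:
                    raise ParameterError(f"{key}: uniform min {p['min']} > max {p['max']}")
            elif self.family == "bernoulli":
                _check_prob(p["p"], f"{key}.p")
            else:
                p["value"]
        except KeyError as exc:
            raise ParameterError(f"{key}: missing parameter {exc} for family {self.family!r}")

    def sample(self, rng) -> float:
        if self.family == "normal":
            return float(rng.normal(self.params["mean"], self.params["sd"]))
        if self.family == "uniform":
            return float(rng.uniform(self.params["min"], self.params["max"]))
        if self.family == "bernoulli":
            return float(rng.random() < self.params["p"])
        return float(self.params["value"])

    def mean(self) -> float:
        if self.family == "normal":
            return float(self.params["mean"])
        if self.family == "uniform":
            return (self.params["min"] + self.params["max"]) / 2.0
        if self.family == "bernoulli":
            return float(self.params["p"])
        return float(self.params["value"])

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": float(value)})


@dataclass
class AgeRiskTable:
    """Annual event probability by closed age bracket, e.g. (40, 49, 0.03).

    Brackets must be contiguous, non-overlapping and cover ages 20-79.  Lookups
    clamp to the table support, so ages beyond 79 reuse the last bracket.
    """

    brackets: list[tuple[int, int, float]]

    SUPPORT = (20, 79)

    def validate(self, key: str = "risk table") -> None:
        if not self.brackets:
            raise ParameterError(f"{key}: empty table")
        brs = sorted(self.brackets)
        lo0, hi_prev = brs[0][0], None
        if lo0 != self.SUPPORT[0]:
            raise ParameterError(f"{key}: first bracket starts at {lo0}, expected {self.SUPPORT[0]}")
        for lo, hi, p in brs:
            if hi < lo:
                raise ParameterError(f"{key}: inverted bracket ({lo}, {hi})")
            if hi_prev is not None and lo != hi_prev + 1:
                raise ParameterError(f"{key}: gap or overlap between age {hi_prev} and {lo}")
            _check_prob(p, f"{key}[{lo}-{hi}]")
            hi_prev = hi
        if hi_prev != self.SUPPORT[1]:
            raise ParameterError(f"{key}: last bracket ends at {hi_prev}, expected {self.SUPPORT[1]}")

    def lookup(self, age: float) -> float:
        a = min(max(int(age), self.SUPPORT[0]), self.SUPPORT[1])
        for lo, hi, p in self.brackets:
            if lo <= a <= hi:
                return p
        raise ParameterError(f"age {age} not covered by risk table")  # pragma: no cover

    @classmethod
    def from_csv(cls, source) -> "AgeRiskTable":
        """Read a table from a CSV path or file-like object with a header row."""
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = Path(source).read_text()
        rows = list(csv.DictReader(io.StringIO(text)))
        return cls([(int(r["age_lo"]), int(r["age_hi"]), float(r["probability"])) for r in rows])

    def to_csv(self) -> str:
        out = io.StringIO()
        w = csv.writer(out)
        w.writerow(["age_lo", "age_hi", "probability"])
        for lo, hi, p in self.brackets:
            w.writerow([lo, hi, p])
        return out.getvalue()


@dataclass
class CostTable:
    """Unit costs in EUR (Italian NHS DRG tariffs used as cost proxies)."""

    quadrantectomy: float = 2354.0
    quadrantectomy_with_complications: float = 2717.0
    mastectomy: float = 8265.0  # unilateral, incl. reconstructive surgery
    mastectomy_with_complications: float = 8872.0
    bilateral_mastectomy: float = 16530.0  # incl. reconstructive surgery
    bilateral_mastectomy_with_complications: float = 17744.0
    intensive_followup: float = 263.31  # annual: mammography + breast MRI
    ultrasound_followup: float = 56.55  # annual: breast examination + ultrasound
    biopsy: float = 52.08
    recurrence_surgery: float = 4583.0
    plastic_surgery: float = 4924.0  # after complications or implant replacement
    radiotherapy: float = 2936.0
    genetic_counseling: float = 20.01
    brca_testing: float = 1107.0

    _PAIRS = (
        ("quadrantectomy", "quadrantectomy_with_complications"),
        ("mastectomy", "mastectomy_with_complications"),
        ("bilateral_mastectomy", "bilateral_mastectomy_with_complications"),
    )

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v >= 0):
                raise ParameterError(f"costs.{f.name} must be a non-negative amount, got {v!r}")
        for base, comp in self._PAIRS:
            if getattr(self, comp) < getattr(self, base):
                raise ParameterError(
                    f"costs.{comp} ({getattr(self, comp)}) is below costs.{base} "
                    f"({getattr(self, base)})"
                )


@dataclass
class AsIsShares:
    """Historical therapeutic-choice shares ("as is" scenario).

    ``post_test`` is the marginal probability of operating only after the test
    result (node 30); the quadrantectomy/mastectomy-first split applies within
    the remaining mass.  Second-level shares are conditional on the first-level
    choice.
    """

    post_test: float = 0.26  # Path 30 family
    quadrantectomy_first: float = 0.70  # Path 10 family, within pre-test mass
    mastectomy_first: float = 0.30  # Path 20 family, within pre-test mass
    p11_given_quadrantectomy: float = 0.20
    p12_given_quadrantectomy: float = 0.80
    p21_given_mastectomy: float = 0.20
    p22_given_mastectomy: float = 0.80
    p31_given_post_test: float = 0.70
    p32_given_post_test: float = 0.30

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check_prob(getattr(self, f.name), f"asis_shares.{f.name}")
        for pair, total_key in (
            (("quadrantectomy_first", "mastectomy_first"), "pre-test surgery split"),
            (("p11_given_quadrantectomy", "p12_given_quadrantectomy"), "node 10 shares"),
            (("p21_given_mastectomy", "p22_given_mastectomy"), "node 20 shares"),
            (("p31_given_post_test", "p32_given_post_test"), "node 30 shares"),
        ):
            s = sum(getattr(self, k) for k in pair)
            if abs(s - 1.0) > 1e-9:
                raise ParameterError(f"asis_shares: {total_key} sum to {s}, expected 1")

    def node_shares(self, node: int) -> dict[int, float]:
        """Conditional child shares of an aggregate decision node (10, 20 or 30)."""
        return {
            10: {11: self.p11_given_quadrantectomy, 12: self.p12_given_quadrantectomy},
            20: {21: self.p21_given_mastectomy, 22: self.p22_given_mastectomy},
            30: {31: self.p31_given_post_test, 32: self.p32_given_post_test},
        }[node]


@dataclass
class EngineSettings:
    discount_rate: float = 0.03
    horizon_years: int = 35
    n_iterations: int = 10_000
    implant_replacement_interval_years: int = 15
    tie_tolerance: float = 2500.0  # EUR; see docs/methods.md
    seed: int = 0
    mode: str = "stochastic"  # headline cost mode: stochastic | expected
    relapse_model: str = "incidence_hazard"  # or detection_chain_only
    decision_basis: str = "realized"  # or expected

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError(f"engine.discount_rate must be >= 0, got {self.discount_rate}")
        if self.horizon_years < 1:
            raise ParameterError(f"engine.horizon_years must be >= 1, got {self.horizon_years}")
        if self.n_iterations < 1:
            raise ParameterError(f"engine.n_iterations must be >= 1, got {self.n_iterations}")
        if self.implant_replacement_interval_years < 1:
            raise ParameterError("engine.implant_replacement_interval_years must be >= 1")
        if self.tie_tolerance < 0:
            raise ParameterError(f"engine.tie_tolerance must be >= 0, got {self.tie_tolerance}")
        if self.mode not in ("stochastic", "expected"):
            raise ParameterError(f"engine.mode must be stochastic or expected, got {self.mode!r}")
        if self.relapse_model not in ("incidence_hazard", "detection_chain_only"):
            raise ParameterError(f"engine.relapse_model invalid: {self.relapse_model!r}")
        if self.decision_basis not in ("realized", "expected"):
            raise ParameterError(f"engine.decision_basis invalid: {self.decision_basis!r}")


def _default_distributions() -> dict[str, DistributionSpec]:
    return {
        "starting_age": DistributionSpec("normal", {"mean": 40.0, "sd": 2.5}),
        "brca_positive_rate": DistributionSpec("uniform", {"min": 0.10, "max": 0.20}),
        "counseling_uptake": DistributionSpec("bernoulli", {"p": 0.45}),
        "testing_uptake": DistributionSpec("bernoulli", {"p": 0.45}),
        "complication_risk": DistributionSpec("uniform", {"min": 0.10, "max": 0.20}),
    }


def _default_probabilities() -> dict[str, float]:
    return {
        "radiotherapy_after_mastectomy": 0.40,
        "radiotherapy_after_quadrantectomy": 0.95,
        "recurrence_detection": 0.05,
        "positive_biopsy": 0.60,
        "residual_gland_carcinoma": 0.05,  # lifetime, after prophylactic surgery
    }


_NEW_INCIDENCE = [(20, 29, 0.005), (30, 39, 0.015), (40, 49, 0.03),
                  (50, 59, 0.026), (60, 69, 0.012), (70, 79, 0.012)]
_CONTRALATERAL = [(20, 29, 0.0), (30, 39, 0.05), (40, 49, 0.04),
                  (50, 59, 0.03), (60, 69, 0.03), (70, 79, 0.03)]


@dataclass
class ParameterSet:
    """The complete, validated model configuration."""

    distributions: dict[str, DistributionSpec] = field(default_factory=_default_distributions)
    probabilities: dict[str, float] = field(default_factory=_default_probabilities)
    new_incidence_risk: AgeRiskTable = field(
        default_factory=lambda: AgeRiskTable(list(_NEW_INCIDENCE)))
    contralateral_risk: AgeRiskTable = field(
        default_factory=lambda: AgeRiskTable(list(_CONTRALATERAL)))
    costs: CostTable = field(default_factory=CostTable)
    asis_shares: AsIsShares = field(default_factory=AsIsShares)
    engine: EngineSettings = field(default_factory=EngineSettings)

    def validate(self) -> "ParameterSet":
        expected = set(_default_distributions())
        if set(self.distributions) != expected:
            raise ParameterError(
                f"distributions must have keys {sorted(expected)}, got {sorted(self.distributions)}")
        for key, dist in self.distributions.items():
            dist.validate(f"distributions.{key}")
        for key in ("counseling_uptake", "testing_uptake"):
            d = self.distributions[key]
            if d.family in ("bernoulli",):
                _check_prob(d.params["p"], f"distributions.{key}.p")
            elif d.family == "point":
                _check_prob(d.params["value"], f"distributions.{key}.value")
        expected_p = set(_default_probabilities())
        if set(self.probabilities) != expected_p:
            raise ParameterError(
                f"probabilities must have keys {sorted(expected_p)}, got {sorted(self.probabilities)}")
        for key, p in self.probabilities.items():
            _check_prob(p, f"probabilities.{key}")
        self.new_incidence_risk.validate("risks.new_incidence")
        self.contralateral_risk.validate("risks.contralateral")
        self.costs.validate()
        self.asis_shares.validate()
        self.engine.validate()
        return self

    # --- probabilities the engine consumes -------------------------------
    @property
    def p_counseling(self) -> float:
        return self.distributions["counseling_uptake"].mean()

    @property
    def p_testing(self) -> float:
        """Testing uptake conditional on counseling (sequential Bernoulli gates)."""
        return self.distributions["testing_uptake"].mean()

    def residual_gland_annual_hazard(self) -> float:
        """Constant annual hazard equivalent to the lifetime residual-gland risk.

        Solves 1 - (1 - h)^horizon = lifetime probability.
        """
        p = self.probabilities["residual_gland_carcinoma"]
        return 1.0 - (1.0 - p) ** (1.0 / self.engine.horizon_years)

    # --- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "distributions": {
                k: {"family": d.family, **d.params} for k, d in self.distributions.items()
            },
            "probabilities": dict(self.probabilities),
            "risks": {
                "new_incidence": [list(b) for b in self.new_incidence_risk.brackets],
                "contralateral": [list(b) for b in self.contralateral_risk.brackets],
            },
            "costs": dataclasses.asdict(self.costs),
            "asis_shares": dataclasses.asdict(self.asis_shares),
            "engine": dataclasses.asdict(self.engine),
        }

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self.to_dict() == other.to_dict()


def default_parameters() -> ParameterSet:
    """The published defaults (Tables of probabilities, risks and tariffs)."""
    return ParameterSet().validate()


def _dist_from_dict(key: str, d: dict) -> DistributionSpec:
    d = dict(d)
    family = d.pop("family", None)
    if family is None:
        raise ParameterError(f"distributions.{key}: missing 'family'")
    return DistributionSpec(family, {k: float(v) for k, v in d.items()})


def load_parameters(source=None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a YAML document.

    ``source`` may be None (pure defaults), a mapping, a YAML string, a path to
    a ``params.yaml`` file, or an open file object.  Any key absent from the
    document keeps its default.  Risk tables may be given inline as bracket
    lists or as ``{csv: <path>}`` references.
    """
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read()) or {}
    else:
        text = str(source)
        p = Path(text)
        is_path = text.endswith((".yaml", ".yml")) or p.is_file()
        doc = yaml.safe_load(p.read_text() if is_path else text) or {}
    if not isinstance(doc, dict):
        raise ParameterError("configuration document must be a mapping")

    ps = ParameterSet()
    for key, spec in (doc.get("distributions") or {}).items():
        if key not in ps.distributions:
            raise ParameterError(f"distributions.{key}: unknown distribution name")
        ps.distributions[key] = _dist_from_dict(key, spec)
    for key, val in (doc.get("probabilities") or {}).items():
        if key not in ps.probabilities:
            raise ParameterError(f"probabilities.{key}: unknown probability name")
        ps.probabilities[key] = float(val)
    risks = doc.get("risks") or {}
    for key, attr in (("new_incidence", "new_incidence_risk"), ("contralateral", "contralateral_risk")):
        if key in risks:
            spec = risks[key]
            if isinstance(spec, dict) and "csv" in spec:
                table = AgeRiskTable.from_csv(spec["csv"])
            else:
                table = AgeRiskTable([(int(lo), int(hi), float(p)) for lo, hi, p in spec])
            setattr(ps, attr, table)
    for section, obj in (("costs", ps.costs), ("asis_shares", ps.asis_shares), ("engine", ps.engine)):
        for key, val in (doc.get(section) or {}).items():
            if not hasattr(obj, key):
                raise ParameterError(f"{section}.{key}: unknown key")
            current = getattr(obj, key)
            setattr(obj, key, type(current)(val) if not isinstance(current, str) else str(val))
    return ps.validate()


def save_parameters(params: ParameterSet, path=None) -> str:
    """Serialise to YAML; round-trips through :func:`load_parameters`."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class ScenarioSpec:
    """A named experiment: parameter overrides applied on top of a base set.

    ``overrides`` maps dotted parameter paths (e.g.
    ``distributions.counseling_uptake``) to replacement values;
    distribution-valued targets accept a plain number, meaning a point mass.
    """

    name: str
    overrides: dict[str, object] = field(default_factory=dict)
    age_sweep_values: list[float] | None = None

    KNOWN = ("baseline", "scenario1", "scenario2", "scenario2_age_sweep", "scenario3")


def _apply_override(ps: ParameterSet, path: str, value) -> None:
    parts = path.split(".")
    obj = ps
    attr_map = {"risks.new_incidence": "new_incidence_risk", "risks.contralateral": "contralateral_risk"}
    if path in attr_map:
        setattr(ps, attr_map[path], AgeRiskTable([(int(a), int(b), float(p)) for a, b, p in value]))
        return
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ParameterError(f"scenario override {path!r}: no such parameter")
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ParameterError(f"scenario override {path!r}: no such parameter")
        if isinstance(obj[leaf], DistributionSpec) and isinstance(value, (int, float)):
            obj[leaf] = DistributionSpec.point(value)
        elif isinstance(obj[leaf], DistributionSpec) and isinstance(value, dict):
            obj[leaf] = _dist_from_dict(leaf, value)
        else:
            obj[leaf] = value
    else:
        if not hasattr(obj, leaf):
            raise ParameterError(f"scenario override {path!r}: no such parameter")
        setattr(obj, leaf, value)


def apply_scenario(base: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Return a new ParameterSet with the scenario applied; ``base`` is untouched."""
    if spec.name not in ScenarioSpec.KNOWN:
        raise ParameterError(f"unknown scenario name {spec.name!r}")
    ps = base.copy()
    if spec.name in ("scenario1", "scenario2", "scenario2_age_sweep", "scenario3"):
        ps.distributions["counseling_uptake"] = DistributionSpec.point(1.0)
    if spec.name in ("scenario2", "scenario2_age_sweep", "scenario3"):
        ps.distributions["testing_uptake"] = DistributionSpec.point(1.0)
    for path, value in spec.overrides.items():
        _apply_override(ps, path, value)
    return ps.validate()
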