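"""Static templates for the ten diagnostic-therapeutic paths.

Path numbering follows the decision tree for a BRCA-mutated breast-cancer
patient:

=====  ==========================================================================
0      no genetic counseling and/or no BRCA test; standard care
10     quadrantectomy before the test result, no preference (aggregate of 11/12)
11     quadrantectomy + intensive radiological follow-up (pre-test)
12     quadrantectomy + completion bilateral mastectomy + ultrasound (pre-test)
20     mastectomy before the test result, no preference (aggregate of 21/22)
21     unilateral curative mastectomy + intensive follow-up (pre-test)
22     unilateral mastectomy + contralateral prophylactic mastectomy (pre-test)
30     surgery after the test result, no preference (aggregate of 31/32)
31     unilateral curative mastectomy + intensive follow-up (post-test)
32     bilateral mastectomy + ultrasound follow-up (post-test)
=====  ==========================================================================

Paths 11/21/31 keep breast tissue under surveillance (intensive follow-up) and
therefore carry active cancer hazards; 12/22/32 are risk-reducing and drop to
ultrasound follow-up.  The pre-test variants 12 and 22 bill two operations at
year 0 (index surgery before the result, prophylactic completion after), while
32 is a single bilateral operation -- the cost asymmetry between operating
before and after the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ParameterSet

__all__ = ["PathTemplate", "path_template", "admissible_paths",
           "LEAF_PATHS", "AGGREGATE_PATHS", "ALL_PATHS", "aggregate_shares"]

LEAF_PATHS = (11, 12, 21, 22, 31, 32)
AGGREGATE_PATHS = (10, 20, 30)
ALL_PATHS = (0, 10, 11, 12, 20, 21, 22, 30, 31, 32)

#: surgery kind -> (cost key without complications, complication variant key,
#: whether the operation includes reconstruction)
SURGERY_KINDS = {
    "quadrantectomy": ("quadrantectomy", "quadrantectomy_with_complications", False),
    "mastectomy": ("mastectomy", "mastectomy_with_complications", True),
    "bilateral_mastectomy": ("bilateral_mastectomy", "bilateral_mastectomy_with_complications", True),
}


@dataclass(frozen=True)
class PathTemplate:
    path_id: int | str
    is_aggregate: bool = False
    sub_paths: tuple = ()  # (child path_id, ...); shares come from the parameter set
    initial_surgeries: tuple[str, ...] = ()
    followup_regime: str = "none"  # intensive | ultrasound | none
    intact_breasts: int = 0  # breast sides still under surveillance after year 0
    contralateral_breast_present: bool = False
    reconstruction_present: bool = False
    radiotherapy_key: str = "none"  # after_quadrantectomy | after_mastectomy | none
    post_prophylactic: bool = False  # residual/ectopic glandular tissue risk active
    includes_counseling: bool = True
    includes_test: bool = True


_LEAVES = {
    11: PathTemplate(11, initial_surgeries=("quadrantectomy",), followup_regime="intensive",
                     intact_breasts=2, contralateral_breast_present=True,
                     radiotherapy_key="after_quadrantectomy"),
    12: PathTemplate(12, initial_surgeries=("quadrantectomy", "bilateral_mastectomy"),
                     followup_regime="ultrasound", intact_breasts=0,
                     reconstruction_present=True, radiotherapy_key="after_quadrantectomy",
                     post_prophylactic=True),
    21: PathTemplate(21, initial_surgeries=("mastectomy",), followup_regime="intensive",
                     intact_breasts=1, contralateral_breast_present=True,
                     reconstruction_present=True, radiotherapy_key="after_mastectomy"),
    22: PathTemplate(22, initial_surgeries=("mastectomy", "mastectomy"),
                     followup_regime="ultrasound", intact_breasts=0,
                     reconstruction_present=True, radiotherapy_key="after_mastectomy",
                     post_prophylactic=True),
    31: PathTemplate(31, initial_surgeries=("mastectomy",), followup_regime="intensive",
                     intact_breasts=1, contralateral_breast_present=True,
                     reconstruction_present=True, radiotherapy_key="after_mastectomy"),
    32: PathTemplate(32, initial_surgeries=("bilateral_mastectomy",),
                     followup_regime="ultrasound", intact_breasts=0,
                     reconstruction_present=True, radiotherapy_key="after_mastectomy",
                     post_prophylactic=True),
}

# Path 0 standard care: no counseling/test, surgery per the historical
# quadrantectomy/mastectomy split, standard (ultrasound) follow-up, all hazards
# active.  Internal leaf variants "0q"/"0m" carry the two surgical options.
_PATH0_VARIANTS = {
    "0q": PathTemplate("0q", initial_surgeries=("quadrantectomy",), followup_regime="ultrasound",
                       intact_breasts=2, contralateral_breast_present=True,
                       radiotherapy_key="after_quadrantectomy",
                       includes_counseling=False, includes_test=False),
    "0m": PathTemplate("0m", initial_surgeries=("mastectomy",), followup_regime="ultrasound",
                       intact_breasts=1, contralateral_breast_present=True,
                       reconstruction_present=True, radiotherapy_key="after_mastectomy",
                       includes_counseling=False, includes_test=False),
}

_AGGREGATES = {
    0: PathTemplate(0, is_aggregate=True, sub_paths=("0q", "0m"),
                    includes_counseling=False, includes_test=False),
    10: PathTemplate(10, is_aggregate=True, sub_paths=(11, 12)),
    20: PathTemplate(20, is_aggregate=True, sub_paths=(21, 22)),
    30: PathTemplate(30, is_aggregate=True, sub_paths=(31, 32)),
}

_ALL = {**_LEAVES, **_PATH0_VARIANTS, **_AGGREGATES}


def path_template(path_id) -> PathTemplate:
    try:
        return _ALL[path_id]
    except KeyError:
        raise KeyError(f"unknown path id {path_id!r}") from None


def aggregate_shares(path_id: int, params: ParameterSet) -> dict:
    """Conditional child shares of an aggregate node under the given parameters."""
    if path_id == 0:
        return {"0q": params.asis_shares.quadrantectomy_first,
                "0m": params.asis_shares.mastectomy_first}
    return params.asis_shares.node_shares(path_id)


def admissible_paths(patient) -> list[int]:
    """Paths a patient can be optimised over.

    Untested patients have no decision to make: only Path 0 is open, and it is
    never optimal-selectable (the model reports zero savings for them).  Tested
    patients choose among the six leaf strategies; the aggregate nodes exist on
    the reporting side only.
    """
    if not patient.tested:
        return [0]
    return list(LEAF_PATHS) + list(AGGREGATE_PATHS)
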