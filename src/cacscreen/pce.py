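"""Pooled cohort equations (PCE): 10-year ASCVD risk and guideline categories.

The PCE are sex- and race-specific proportional-hazards equations that
estimate 10-year risk of a first hard atherosclerotic cardiovascular
event from age, total and HDL cholesterol, systolic blood pressure (with
separate coefficients for treated and untreated pressure), smoking and
diabetes status.  There are four equation groups: White/other and Black,
by sex; Chinese and Hispanic participants are scored with the White/other
equations, which is the convention of the source equations.

Risk maps to the four guideline categories at the conventional cut
points: low (<5%), borderline (5 to <7.5%), intermediate (7.5 to <20%)
and high (>=20%), each interval closed on the left.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PceRisk",
    "PceCoefficients",
    "PceInputError",
    "load_default_coefficients",
    "compute_pce_risk",
    "classify_pce_category",
    "score_cohort",
    "CATEGORY_LEVELS",
]

CATEGORY_LEVELS = ["low", "borderline", "intermediate", "high"]

#: Category thresholds on the probability scale (closed on the left).
THRESHOLD_BORDERLINE = 0.05
THRESHOLD_INTERMEDIATE = 0.075
THRESHOLD_HIGH = 0.20

#: Race levels scored with the White/other equations.
_WHITE_EQUATION_RACES = {"white", "chinese", "hispanic"}

_VALID_AGE_RANGE = (40.0, 79.0)


class PceInputError(ValueError):
    """Raised for inputs outside the equations' validated domain."""


@dataclass(frozen=True)
class PceRisk:
    probability: float
    category: str


class PceCoefficients:
    """Coefficient tables for the four sex x race-group equations.

    Loaded from a structured YAML file so the transcription is auditable;
    ``checksum`` is the SHA-256 of the source file.
    """

    def __init__(self, groups: dict, checksum: str | None = None):
        expected = {"white_male", "black_male", "white_female", "black_female"}
        if set(groups) != expected:
            raise ValueError(f"expected equation groups {sorted(expected)}, got {sorted(groups)}")
        for g, spec in groups.items():
            if not (0.0 < spec["s10"] < 1.0):
                raise ValueError(f"{g}: baseline survival s10 must be in (0,1)")
        self.groups = groups
        self.checksum = checksum

    @classmethod
    def from_yaml_text(cls, text: str) -> "PceCoefficients":
        doc = yaml.safe_load(text)
        checksum = hashlib.sha256(text.encode()).hexdigest()
        return cls(doc["groups"], checksum=checksum)


def load_default_coefficients() -> PceCoefficients:
    """Load the packaged PCE coefficient file."""
    text = (
        resources.files("cacscreen").joinpath("data/pce_coefficients.yaml").read_text()
    )
    return PceCoefficients.from_yaml_text(text)


def _equation_group(sex: str, race: str) -> str:
    if sex not in ("male", "female"):
        raise PceInputError(f"sex must be 'male' or 'female', got {sex!r}")
    if race == "black":
        return f"black_{sex}"
    if race in _WHITE_EQUATION_RACES:
        return f"white_{sex}"
    raise PceInputError(f"race {race!r} cannot be mapped to an equation group")


def _linear_predictor(
    coefs: dict,
    age: float,
    total_chol: float,
    hdl_chol: float,
    sbp: float,
    treated_bp: bool,
    smoker: bool,
    diabetes: bool,
) -> float:
    c = coefs.get
    ln_age = math.log(age)
    ln_tc = math.log(total_chol)
    ln_hdl = math.log(hdl_chol)
    ln_sbp = math.log(sbp)
    lp = (
        c("ln_age", 0.0) * ln_age
        + c("ln_age_sq", 0.0) * ln_age**2
        + c("ln_tc", 0.0) * ln_tc
        + c("ln_age_x_ln_tc", 0.0) * ln_age * ln_tc
        + c("ln_hdl", 0.0) * ln_hdl
        + c("ln_age_x_ln_hdl", 0.0) * ln_age * ln_hdl
    )
    if treated_bp:
        lp += c("ln_sbp_treated", 0.0) * ln_sbp
        lp += c("ln_age_x_ln_sbp_treated", 0.0) * ln_age * ln_sbp
    else:
        lp += c("ln_sbp_untreated", 0.0) * ln_sbp
        lp += c("ln_age_x_ln_sbp_untreated", 0.0) * ln_age * ln_sbp
    if smoker:
        lp += c("smoker", 0.0) + c("ln_age_x_smoker", 0.0) * ln_age
    if diabetes:
        lp += c("diabetes", 0.0)
    return lp


def compute_pce_risk(
    participant,
    coeffs: PceCoefficients | None = None,
    *,
    diabetes: bool = False,
) -> PceRisk:
    """Compute 10-year ASCVD risk and its guideline category for one person.

    ``participant`` is any mapping (or pandas row) with fields ``age``,
    ``sex``, ``race``, ``total_chol``, ``hdl_chol``, ``sbp``,
    ``antihypertensive_med`` and ``current_smoker``.  The study
    population excludes diabetes, so the diabetes term defaults to 0.
    """
    coeffs = coeffs or load_default_coefficients()
    age = float(participant["age"])
    tc = float(participant["total_chol"])
    hdl = float(participant["hdl_chol"])
    sbp = float(participant["sbp"])
    if not (_VALID_AGE_RANGE[0] <= age <= _VALID_AGE_RANGE[1]):
        raise PceInputError(
            f"age {age} outside the equations' validated range {_VALID_AGE_RANGE}"
        )
    if min(tc, hdl, sbp) <= 0:
        raise PceInputError("total_chol, hdl_chol and sbp must be strictly positive")

    group = _equation_group(str(participant["sex"]), str(participant["race"]))
    spec = coeffs.groups[group]
    lp = _linear_predictor(
        spec["coefficients"],
        age,
        tc,
        hdl,
        sbp,
        bool(participant["antihypertensive_med"]),
        bool(participant["current_smoker"]),
        diabetes,
    )
    prob = 1.0 - spec["s10"] ** math.exp(lp - spec["mean_lp"])
    prob = min(max(prob, 1e-12), 1.0 - 1e-12)
    return PceRisk(probability=prob, category=classify_pce_category(prob))


def classify_pce_category(probability: float) -> str:
    """Map a 10-year risk probability to its guideline category.

    Intervals are closed on the left: [0, 5%) low, [5%, 7.5%) borderline,
    [7.5%, 20%) intermediate, [20%, 100%] high.
    """
    p = float(probability)
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise PceInputError(f"probability must lie in [0, 1], got {probability}")
    if p < THRESHOLD_BORDERLINE:
        return "low"
    if p < THRESHOLD_INTERMEDIATE:
        return "borderline"
    if p < THRESHOLD_HIGH:
        return "intermediate"
    return "high"


def score_cohort(
    cohort: pd.DataFrame, coeffs: PceCoefficients | None = None
) -> pd.DataFrame:
    """Append ``pce_probability`` and ``pce_category`` columns to a cohort.

    Returns a copy; the input is not modified.
    """
    coeffs = coeffs or load_default_coefficients()
    probs = np.empty(len(cohort))
    for i, (_, row) in enumerate(cohort.iterrows()):
        probs[i] = compute_pce_risk(row, coeffs).probability
    out = cohort.copy()
    out["pce_probability"] = probs
    out["pce_category"] = [classify_pce_category(p) for p in probs]
    return out
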