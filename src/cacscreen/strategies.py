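"""Screening strategies: who is visited, CT-scanned, and treatment eligible.

Three policy families are simulated on a scored cohort:

* **Guideline (PCE +/- CAC)** — everyone attends a health-care visit (the
  pooled cohort equations need labs and vitals); participants at
  intermediate PCE risk (7.5 to <20%) receive a CT scan, and treatment
  eligibility goes to the high-risk category (>=20%) plus intermediate
  participants with CACS >= 100.  Low and borderline categories are
  never scanned or treated under this simplified rule.
* **Resource-matched self-report** — participants are ranked by the
  self-report model's predicted probability of a high CAC score; the top
  ``n_scans`` are scanned (these are the only health-care contacts), the
  scanned are re-ranked by their measured CACS, and the top ``n_treat``
  of that re-ranking are treatment eligible.  With the caps set to the
  guideline strategy's scan and treatment counts, the two policies spend
  identical imaging and treatment resources.
* **Fixed-threshold self-report** — real-world variants with an absolute
  probability cutoff for scanning and an absolute CACS cutoff (strict
  inequalities) for treatment; conservative / intermediate / liberal
  presets span screening appetites.

All rankings are fully deterministic: descending primary key, descending
secondary key, then ascending participant id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pce import CATEGORY_LEVELS

__all__ = [
    "StrategyOutcome",
    "StrategyParameterError",
    "guideline_strategy",
    "selfreport_benchmarked_strategy",
    "fixed_threshold_strategy",
    "age_sex_adjusted_guideline_strategy",
    "FIXED_THRESHOLD_PRESETS",
    "GUIDELINE_CAC_TREAT_THRESHOLD",
]

#: CACS (Agatston units) at or above which an intermediate-risk
#: participant becomes treatment eligible under the guideline rule.
GUIDELINE_CAC_TREAT_THRESHOLD = 100.0

#: Fixed-threshold presets: (probability cutoff for CT, CACS cutoff for
#: treatment), both strict inequalities.  The intermediate preset is the
#: recommended clinical operating point (>18% predicted risk of CACS>=100,
#: treat everyone scanned with CACS>15); the conservative and liberal
#: presets bracket it within the studied >15-20% / >0-20 AU ranges.
FIXED_THRESHOLD_PRESETS = {
    "conservative": (0.20, 20.0),
    "intermediate": (0.18, 15.0),
    "liberal": (0.15, 0.0),
}


class StrategyParameterError(ValueError):
    """Raised for invalid strategy parameters (caps, cutoffs)."""


@dataclass
class StrategyOutcome:
    """Per-participant flags and aggregate resource counts for one strategy."""

    strategy: str
    params: dict
    flags: pd.DataFrame = field(repr=False)  # id, visited, scanned, treatment_eligible

    @property
    def n_visits(self) -> int:
        return int(self.flags["visited"].sum())

    @property
    def n_scans(self) -> int:
        return int(self.flags["scanned"].sum())

    @property
    def n_treated(self) -> int:
        return int(self.flags["treatment_eligible"].sum())

    @property
    def treated(self) -> pd.Series:
        return self.flags["treatment_eligible"]

    def resource_summary(self, cohort_size: int | None = None) -> dict:
        n = cohort_size if cohort_size is not None else len(self.flags)
        return {
            "strategy": self.strategy,
            "params": self.params,
            "cohort_size": n,
            "n_visits": self.n_visits,
            "n_scans": self.n_scans,
            "n_treated": self.n_treated,
            "pct_visits": 100.0 * self.n_visits / n,
            "pct_scans": 100.0 * self.n_scans / n,
            "pct_treated": 100.0 * self.n_treated / n,
        }


def _check_scored(cohort: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")


def _outcome(cohort, strategy, params, visited, scanned, treated) -> StrategyOutcome:
    flags = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "visited": np.asarray(visited, dtype=bool),
            "scanned": np.asarray(scanned, dtype=bool),
            "treatment_eligible": np.asarray(treated, dtype=bool),
        }
    )
    return StrategyOutcome(strategy=strategy, params=params, flags=flags)


def guideline_strategy(cohort: pd.DataFrame) -> StrategyOutcome:
    """Simplified PCE/CACS guideline policy.

    Requires ``pce_category`` and ``cacs`` columns.  Everyone is visited;
    only the intermediate category is scanned; treatment eligibility is
    high risk, or intermediate risk with CACS >= 100.
    """
    _check_scored(cohort, ["id", "pce_category", "cacs"])
    cat = cohort["pce_category"]
    bad = set(cat.unique()) - set(CATEGORY_LEVELS)
    if bad or cat.isna().any():
        raise ValueError(f"invalid PCE categories present: {sorted(map(str, bad))}")
    intermediate = (cat == "intermediate").to_numpy()
    high = (cat == "high").to_numpy()
    cacs = cohort["cacs"].to_numpy(dtype=float)
    visited = np.ones(len(cohort), dtype=bool)
    scanned = intermediate
    treated = high | (intermediate & (cacs >= GUIDELINE_CAC_TREAT_THRESHOLD))
    return _outcome(
        cohort,
        "guideline",
        {"cac_treat_threshold": GUIDELINE_CAC_TREAT_THRESHOLD},
        visited,
        scanned,
        treated,
    )


def _rank_order(primary, secondary, ids) -> np.ndarray:
    """Indices sorted by descending primary, descending secondary, ascending id."""
    df = pd.DataFrame({"p": primary, "s": secondary, "id": ids})
    return (
        df.sort_values(["p", "s", "id"], ascending=[False, False, True], kind="mergesort")
        .index.to_numpy()
    )


def selfreport_benchmarked_strategy(
    cohort: pd.DataFrame, n_scans: int, n_treat: int
) -> StrategyOutcome:
    """Self-report policy benchmarked to fixed scan and treatment counts.

    Requires a ``selfreport_probability`` column (honest, out-of-fold
    predictions) and ``cacs``.  The top ``n_scans`` by predicted
    probability are scanned and visited; among the scanned, the top
    ``n_treat`` by measured CACS are treatment eligible.  Treatment uses
    no information other than CACS rank within the scanned set.
    """
    _check_scored(cohort, ["id", "selfreport_probability", "cacs"])
    n = len(cohort)
    if not (0 <= n_treat <= n_scans <= n):
        raise StrategyParameterError(
            f"need 0 <= n_treat ({n_treat}) <= n_scans ({n_scans}) <= cohort size ({n})"
        )
    prob = cohort["selfreport_probability"].to_numpy(dtype=float)
    if np.isnan(prob).any():
        raise ValueError("selfreport_probability contains missing values")
    cacs = cohort["cacs"].to_numpy(dtype=float)
    ids = cohort["id"].to_numpy()

    scan_order = _rank_order(prob, np.zeros(n), ids)
    scanned_idx = scan_order[:n_scans]
    scanned = np.zeros(n, dtype=bool)
    scanned[scanned_idx] = True

    treat_order = _rank_order(cacs[scanned_idx], prob[scanned_idx], ids[scanned_idx])
    treated_idx = scanned_idx[treat_order[:n_treat]]
    treated = np.zeros(n, dtype=bool)
    treated[treated_idx] = True

    return _outcome(
        cohort,
        "selfreport-benchmarked",
        {"n_scans": n_scans, "n_treat": n_treat},
        scanned,
        scanned,
        treated,
    )


def fixed_threshold_strategy(
    cohort: pd.DataFrame, prob_cutoff: float, cacs_cutoff: float, *, label: str | None = None
) -> StrategyOutcome:
    """Self-report policy with absolute cutoffs (both strict inequalities).

    Scan if predicted probability > ``prob_cutoff``; treat scanned
    participants with CACS > ``cacs_cutoff``.
    """
    _check_scored(cohort, ["id", "selfreport_probability", "cacs"])
    if not (0.0 <= prob_cutoff <= 1.0):
        raise StrategyParameterError(f"prob_cutoff must lie in [0, 1], got {prob_cutoff}")
    if cacs_cutoff < 0:
        raise StrategyParameterError(f"cacs_cutoff must be >= 0, got {cacs_cutoff}")
    prob = cohort["selfreport_probability"].to_numpy(dtype=float)
    cacs = cohort["cacs"].to_numpy(dtype=float)
    scanned = prob > prob_cutoff
    treated = scanned & (cacs > cacs_cutoff)
    return _outcome(
        cohort,
        label or "fixed-threshold",
        {"prob_cutoff": prob_cutoff, "cacs_cutoff": cacs_cutoff},
        scanned,
        scanned,
        treated,
    )


def age_sex_adjusted_guideline_strategy(
    cohort: pd.DataFrame, percentile: float = 75.0, *, min_stratum: int = 10
) -> StrategyOutcome:
    """Guideline policy with a relative (age/sex-adjusted) CACS rule.

    As :func:`guideline_strategy`, except an intermediate-risk participant
    is treatment eligible only if CACS > 0 **and** CACS is at or above the
    given empirical percentile of CACS within their sex x age-decade
    stratum.  Strata smaller than ``min_stratum`` fall back to the
    sex-only stratum.
    """
    _check_scored(cohort, ["id", "pce_category", "cacs", "sex", "age"])
    if not (0.0 < percentile < 100.0):
        raise StrategyParameterError(f"percentile must lie in (0, 100), got {percentile}")
    cat = cohort["pce_category"]
    intermediate = (cat == "intermediate").to_numpy()
    high = (cat == "high").to_numpy()
    cacs = cohort["cacs"].to_numpy(dtype=float)
    decade = (cohort["age"].to_numpy(dtype=float) // 10).astype(int)
    sex = cohort["sex"].to_numpy()

    cutoff = np.empty(len(cohort))
    strata = pd.DataFrame({"sex": sex, "decade": decade})
    for (s, d), idx in strata.groupby(["sex", "decade"]).groups.items():
        idx = np.asarray(idx)
        pool = idx if len(idx) >= min_stratum else np.flatnonzero(sex == s)
        cutoff[idx] = np.percentile(cacs[pool], percentile)

    visited = np.ones(len(cohort), dtype=bool)
    scanned = intermediate
    treated = high | (intermediate & (cacs > 0) & (cacs >= cutoff))
    return _outcome(
        cohort,
        "guideline-age-sex-adjusted",
        {"percentile": percentile},
        visited,
        scanned,
        treated,
    )
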