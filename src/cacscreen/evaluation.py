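"""Strategy evaluation: event capture, paired comparison, discrimination.

The headline comparison measure is **event capture**: of all 10-year
events in the cohort, what fraction occurred in participants the
strategy deemed treatment eligible?  Two strategies that spend the same
resources are compared with McNemar's test on the paired eligibility of
the event-positive participants (each person with an event is classified
eligible/ineligible under both strategies; the discordant counts b and c
carry the information).  Discrimination of the underlying risk model is
summarised by the rank-based AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .strategies import StrategyOutcome
from .synthetic_cohort import ENDPOINT_COLUMNS

__all__ = [
    "McNemarResult",
    "EvaluationReport",
    "event_capture",
    "mcnemar_compare",
    "treated_event_rate",
    "auc",
    "endpoint_sweep",
]

#: Below this discordant-pair total the exact binomial test replaces the
#: continuity-corrected chi-square approximation.
EXACT_FALLBACK_THRESHOLD = 25


def _aligned_bool(v, name, n=None) -> np.ndarray:
    a = np.asarray(v, dtype=bool)
    if n is not None and a.size != n:
        raise ValueError(f"{name} has length {a.size}, expected {n}")
    return a


def event_capture(outcome: StrategyOutcome, events) -> tuple[int, int, float]:
    """Events captured by a strategy's treatment-eligible set.

    Returns ``(captured, total, fraction_percent)`` where the fraction is
    ``100 * captured / total``.  ``total`` of zero yields a NaN fraction.
    """
    treated = outcome.treated.to_numpy()
    ev = _aligned_bool(events, "events", treated.size)
    captured = int((treated & ev).sum())
    total = int(ev.sum())
    fraction = 100.0 * captured / total if total else float("nan")
    return captured, total, fraction


@dataclass
class McNemarResult:
    b: int  # events eligible under A only
    c: int  # events eligible under B only
    statistic: float
    p_value: float
    method: str
    no_discordance: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def mcnemar_compare(elig_a, elig_b, events, *, method: str = "auto") -> McNemarResult:
    """McNemar's test on paired treatment eligibility among event cases.

    The pairing unit is the event-positive participant: ``b`` counts
    events eligible only under strategy A, ``c`` only under B.  With
    ``method="auto"`` the continuity-corrected chi-square test is used,
    falling back to the exact binomial test when ``b + c < 25``; the
    exact or corrected method can also be forced.
    """
    a = _aligned_bool(elig_a, "elig_a")
    b_ = _aligned_bool(elig_b, "elig_b", a.size)
    ev = _aligned_bool(events, "events", a.size)
    if method not in ("auto", "exact", "corrected"):
        raise ValueError(f"unknown method {method!r}")

    a_ev, b_ev = a[ev], b_[ev]
    b_count = int((a_ev & ~b_ev).sum())
    c_count = int((~a_ev & b_ev).sum())
    if b_count + c_count == 0:
        return McNemarResult(0, 0, 0.0, 1.0, "no-discordance", no_discordance=True)

    use_exact = method == "exact" or (
        method == "auto" and b_count + c_count < EXACT_FALLBACK_THRESHOLD
    )
    table = [
        [int((a_ev & b_ev).sum()), b_count],
        [c_count, int((~a_ev & ~b_ev).sum())],
    ]
    res = _sm_mcnemar(table, exact=use_exact, correction=True)
    return McNemarResult(
        b=b_count,
        c=c_count,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact-binomial" if use_exact else "chi2-corrected",
    )


def treated_event_rate(outcome: StrategyOutcome, events) -> float | None:
    """10-year event rate (percent) within the treatment-eligible group.

    ``None`` when nobody is treatment eligible (the rate is undefined).
    """
    treated = outcome.treated.to_numpy()
    ev = _aligned_bool(events, "events", treated.size)
    n_treated = int(treated.sum())
    if n_treated == 0:
        return None
    return 100.0 * int((treated & ev).sum()) / n_treated


def auc(probabilities, labels) -> float:
    """Rank-based (concordance) AUC with ties counted half.

    Raises if only one class is present, where the AUC is undefined.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC is undefined with a single class")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


@dataclass
class EvaluationReport:
    """Evaluation of one strategy on one endpoint set."""

    strategy: str
    endpoint: str
    events_total: int
    events_captured: int
    capture_fraction: float  # percent
    treated_event_rate: float | None  # percent
    resources: dict
    mcnemar: dict | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def endpoint_sweep(
    outcomes: dict[str, StrategyOutcome],
    cohort: pd.DataFrame,
    *,
    reference: str | None = None,
    endpoints: list[str] | None = None,
) -> list[EvaluationReport]:
    """Evaluate every strategy on every endpoint set.

    Eligibility never depends on the outcome, so each strategy's treated
    set is identical across endpoint sets; only the capture numbers
    change.  When ``reference`` names one of the strategies, every other
    strategy is compared to it with McNemar's test on each endpoint.
    """
    endpoints = endpoints or ENDPOINT_COLUMNS
    missing = [e for e in endpoints if e not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing endpoint columns: {missing}")
    n = len(cohort)
    reports = []
    for ep in endpoints:
        ev = cohort[ep].to_numpy(dtype=bool)
        for name, outcome in outcomes.items():
            captured, total, fraction = event_capture(outcome, ev)
            mc = None
            if reference is not None and name != reference:
                mc = mcnemar_compare(
                    outcomes[name].treated, outcomes[reference].treated, ev
                ).to_dict()
            reports.append(
                EvaluationReport(
                    strategy=name,
                    endpoint=ep,
                    events_total=total,
                    events_captured=captured,
                    capture_fraction=fraction,
                    treated_event_rate=treated_event_rate(outcome, ev),
                    resources=outcome.resource_summary(n),
                    mcnemar=mc,
                )
            )
    return reports
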