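"""End-to-end orchestration of the screening-strategy comparison.

``run_pipeline`` chains every stage on one synthetic cohort: generation,
PCE scoring, self-report model training (honest out-of-fold
predictions), the guideline strategy, the resource-matched self-report
strategy, the three fixed-threshold presets, and the endpoint sweep.
One global seed deterministically derives every stage seed, so a config
reproduces its report byte for byte.

``verify_printed_arithmetic`` recomputes the count/percent pairs printed
in the published analysis of the emulated cohort from their raw counts —
a transcription-level integrity check that needs no data access.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import cac_model, evaluation, pce, strategies
from .synthetic_cohort import GeneratorConfig, apply_exclusions, generate_cohort, write_cohort_csv

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "verify_printed_arithmetic",
    "load_printed_cases",
    "PRINTED_TOLERANCE_PP",
]

logger = logging.getLogger("cacscreen")

#: Tolerance (percentage points) when comparing recomputed to printed
#: percentages, absorbing half-up vs truncation rounding in the source.
PRINTED_TOLERANCE_PP = 0.1


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    The single ``seed`` deterministically spawns the generator and model
    seeds; ``generator`` overrides (other than n and seed) pass through
    to :class:`GeneratorConfig`.
    """

    seed: int = 20250321
    n: int = 4564
    cac_threshold: float = 100.0
    fixed_presets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(strategies.FIXED_THRESHOLD_PRESETS)
    )
    endpoints: list[str] | None = None
    generator_overrides: dict = field(default_factory=dict)
    report_decimals: int = 1

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        gen, model = ss.spawn(2)
        return {
            "generator": int(gen.generate_state(1)[0] % (2**31)),
            "model": int(model.generate_state(1)[0] % (2**31)),
        }


def run_pipeline(config: PipelineConfig | None = None, *, out_dir=None) -> dict:
    """Run the full comparison and return a report bundle.

    The bundle holds the scored cohort, the fitted model, every strategy
    outcome, and the per-endpoint evaluation reports with the guideline
    strategy as the McNemar reference.  With ``out_dir`` set, the cohort
    CSV, report JSON and a manifest (seeds, config, package version) are
    written there.
    """
    cfg = config or PipelineConfig()
    seeds = cfg.stage_seeds()

    logger.info("stage=simulate n=%d seed=%d", cfg.n, seeds["generator"])
    gen_cfg = GeneratorConfig(n=cfg.n, seed=seeds["generator"], **cfg.generator_overrides)
    cohort = generate_cohort(gen_cfg)

    logger.info("stage=pce")
    scored = pce.score_cohort(cohort)

    logger.info("stage=train threshold=%g seed=%d", cfg.cac_threshold, seeds["model"])
    model = cac_model.train_cac_model(
        scored, threshold=cfg.cac_threshold, seed=seeds["model"]
    )
    # honest predictions: out-of-fold, never scored by a model that saw
    # the participant's CAC label
    scored["selfreport_probability"] = model.cv_probability

    logger.info("stage=strategies")
    guideline = strategies.guideline_strategy(scored)
    benchmarked = strategies.selfreport_benchmarked_strategy(
        scored, n_scans=guideline.n_scans, n_treat=guideline.n_treated
    )
    outcomes = {"guideline": guideline, "selfreport-benchmarked": benchmarked}
    for name, (p_cut, c_cut) in cfg.fixed_presets.items():
        outcomes[f"fixed-{name}"] = strategies.fixed_threshold_strategy(
            scored, p_cut, c_cut, label=f"fixed-{name}"
        )

    logger.info("stage=evaluate")
    reports = evaluation.endpoint_sweep(
        outcomes, scored, reference="guideline", endpoints=cfg.endpoints
    )

    bundle = {
        "config": cfg,
        "seeds": seeds,
        "cohort": scored,
        "model": model,
        "outcomes": outcomes,
        "reports": reports,
        "report_json": _report_json(cfg, seeds, model, reports),
    }
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _round_floats(obj, decimals):
    if isinstance(obj, float):
        return round(obj, decimals + 2)
    if isinstance(obj, dict):
        return {k: _round_floats(v, decimals) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, decimals) for v in obj]
    return obj


def _report_json(cfg, seeds, model, reports) -> dict:
    return _round_floats(
        {
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "n": cfg.n,
            "cac_threshold": cfg.cac_threshold,
            "model": {
                "cv_auc": model.cv_auc,
                "importances_pct": model.importances.to_dict(),
            },
            "evaluations": [r.to_dict() for r in reports],
        },
        cfg.report_decimals,
    )


def _write_bundle(bundle, out_dir) -> None:
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(bundle["cohort"].drop(columns=["pce_probability", "pce_category", "selfreport_probability"]), out / "cohort.csv")
    bundle["cohort"][["id", "pce_probability", "pce_category", "selfreport_probability"]].to_csv(
        out / "risk_scores.csv", index=False
    )
    for name, oc in bundle["outcomes"].items():
        oc.flags.assign(**{c: oc.flags[c].astype(int) for c in ("visited", "scanned", "treatment_eligible")}).to_csv(
            out / f"outcome_{name}.csv", index=False
        )
    with open(out / "report.json", "w") as fh:
        json.dump(bundle["report_json"], fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "seed": bundle["config"].seed,
                "stage_seeds": bundle["seeds"],
                "n": bundle["config"].n,
                "pce_coefficients_sha256": pce.load_default_coefficients().checksum,
            },
            fh,
            indent=2,
        )


# ---------------------------------------------------------------------------
# printed-arithmetic verification
# ---------------------------------------------------------------------------

def load_printed_cases() -> dict:
    """Load the bundled transcription of the published count/percent pairs."""
    text = resources.files("cacscreen").joinpath("data/printed_results.yaml").read_text()
    return yaml.safe_load(text)


def _round_half_up(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return np.floor(x * factor + 0.5) / factor


def verify_printed_arithmetic(cases: list[dict] | None = None) -> pd.DataFrame:
    """Recompute each printed percent from its raw counts.

    Each case's ``100 * numerator / denominator`` is rounded half-up to
    the printed precision and compared to the printed value with a
    +-0.1 pp tolerance.  Returns one row per case with the recomputed
    value, the discrepancy and a pass flag; cases that pass only through
    the tolerance carry a ``rounding-note``.
    """
    if cases is None:
        cases = load_printed_cases()["cases"]
    rows = []
    for case in cases:
        num, den = case["numerator"], case["denominator"]
        if den == 0:
            raise ValueError(f"case {case['description']!r} has zero denominator")
        printed_str = str(case["printed"])
        decimals = len(printed_str.split(".")[1]) if "." in printed_str else 0
        printed = float(printed_str)
        exact = 100.0 * num / den
        recomputed = _round_half_up(exact, decimals)
        diff = abs(recomputed - printed)
        rows.append(
            {
                "description": case["description"],
                "numerator": num,
                "denominator": den,
                "printed": printed,
                "exact_pct": exact,
                "recomputed": recomputed,
                "diff_pp": diff,
                "passed": diff <= PRINTED_TOLERANCE_PP + 1e-12,
                "note": "rounding-note" if 0 < diff <= PRINTED_TOLERANCE_PP + 1e-12 else "",
            }
        )
    return pd.DataFrame(rows)


def verify_exclusion_flow(flow: dict | None = None) -> bool:
    """Check the published inclusion flow: initial minus exclusions = final."""
    if flow is None:
        flow = load_printed_cases()["exclusion_flow"]
    final = apply_exclusions(flow["initial"], flow["exclusions"])
    return final == flow["final"]
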