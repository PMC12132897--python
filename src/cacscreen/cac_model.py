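"""Self-report risk model: boosted stumps predicting a high CAC score.

The model estimates, from ten self-report factors only (never blood
pressure, lipids, or the CAC score itself), the probability that a
participant's Agatston coronary artery calcium score meets a threshold
(default 100; a secondary analysis uses >0).  It is a gradient-boosted
ensemble of depth-one regression trees fit to the Bernoulli deviance:
100 trees, shrinkage 0.1, bag fraction 0.5, no early stopping.  With
depth-one trees the ensemble is additive over features, so the fitted
score decomposes into one partial function per feature and the
relative-influence importances (normalised to sum to 100%) are directly
interpretable.

Out-of-fold predictions from seeded 5-fold cross-validation are stored
with the fitted model so that downstream ranking never scores a
participant with a model that saw their CAC label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .synthetic_cohort import RACE_LEVELS, SELF_REPORT_FACTORS

__all__ = [
    "CacRiskModel",
    "FeatureContractError",
    "train_cac_model",
    "predict_cac_risk",
    "split_half_check",
    "calibration_curve",
]

_HYPERPARAMS = dict(
    n_estimators=100,
    learning_rate=0.1,
    max_depth=1,
    subsample=0.5,
    loss="log_loss",
)


class FeatureContractError(ValueError):
    """Raised when non-self-report features are offered to the trainer."""


def _encode_features(cohort: pd.DataFrame) -> pd.DataFrame:
    """Encode the ten self-report factors as a numeric design matrix.

    Sex and booleans become 0/1 indicators; race is one-hot encoded over
    its four levels so depth-one stumps can split on each indicator.
    """
    missing = [f for f in SELF_REPORT_FACTORS if f not in cohort.columns]
    if missing:
        raise FeatureContractError(f"cohort is missing self-report factors: {missing}")
    X = pd.DataFrame(index=cohort.index)
    X["age"] = cohort["age"].astype(float)
    X["male"] = (cohort["sex"] == "male").astype(float)
    for r in RACE_LEVELS:
        X[f"race_{r}"] = (cohort["race"] == r).astype(float)
    for col in (
        "body_weight",
        "weight_at_20",
        "height",
        "pack_years",
        "smoking_duration",
    ):
        X[col] = cohort[col].astype(float)
    for col in ("antihypertensive_med", "family_history_mi"):
        X[col] = cohort[col].astype(float)
    return X


@dataclass
class CacRiskModel:
    """A fitted boosted-stump ensemble with its cross-validation record."""

    estimator: GradientBoostingClassifier
    threshold: float
    feature_names: list[str]
    seed: int
    cv_fold: np.ndarray = field(repr=False)
    cv_probability: np.ndarray = field(repr=False)
    cv_auc: float = float("nan")

    @property
    def importances(self) -> pd.Series:
        """Relative influence per feature, in percent (sums to 100)."""
        imp = self.estimator.feature_importances_
        return pd.Series(100.0 * imp / imp.sum(), index=self.feature_names)

    def decision_scores(self, cohort: pd.DataFrame) -> np.ndarray:
        """Raw additive score (log-odds scale) before the sigmoid."""
        X = _encode_features(cohort)[self.feature_names]
        return self.estimator.decision_function(X.to_numpy())


def train_cac_model(
    cohort: pd.DataFrame,
    threshold: float = 100.0,
    seed: int = 0,
    *,
    features: list[str] | None = None,
    n_folds: int = 5,
) -> CacRiskModel:
    """Train the self-report model for the label ``cacs >= threshold``.

    A full-data ensemble is fitted for deployment, and seeded,
    label-stratified 5-fold cross-validation stores one honest
    out-of-fold probability per participant for downstream ranking.

    ``features``, if given, must be a subset of the ten self-report
    factors; clinic-only measurements (blood pressure, lipids) and the
    CAC score itself are rejected.

    Raises
    ------
    ValueError
        If the binary label has a single class.
    FeatureContractError
        If a required self-report factor is missing or a non-self-report
        feature is requested.
    """
    if features is not None:
        forbidden = sorted(set(features) - set(SELF_REPORT_FACTORS))
        if forbidden:
            raise FeatureContractError(
                f"non-self-report features are not allowed: {forbidden}"
            )
    X = _encode_features(cohort)
    y = (cohort["cacs"].to_numpy(dtype=float) >= threshold).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"label cacs >= {threshold} has a single class; cannot train"
        )

    est = GradientBoostingClassifier(random_state=seed, **_HYPERPARAMS)
    est.fit(X.to_numpy(), y)

    folds = np.empty(len(y), dtype=int)
    oof = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        fold_est = GradientBoostingClassifier(random_state=seed + 1 + k, **_HYPERPARAMS)
        fold_est.fit(X.to_numpy()[tr], y[tr])
        oof[te] = fold_est.predict_proba(X.to_numpy()[te])[:, 1]
        folds[te] = k
    cv_auc = float(roc_auc_score(y, oof))

    return CacRiskModel(
        estimator=est,
        threshold=float(threshold),
        feature_names=list(X.columns),
        seed=seed,
        cv_fold=folds,
        cv_probability=oof,
        cv_auc=cv_auc,
    )


def predict_cac_risk(model: CacRiskModel, cohort: pd.DataFrame) -> np.ndarray:
    """Predicted probability of a high CAC score, one value per row.

    Deterministic given the fitted model; an empty cohort yields an
    empty array.
    """
    if len(cohort) == 0:
        return np.empty(0, dtype=float)
    X = _encode_features(cohort)[model.feature_names]
    return model.estimator.predict_proba(X.to_numpy())[:, 1]


def model_to_artifact(model: CacRiskModel) -> dict:
    """Serialise a fitted ensemble to a transparent stump list.

    Each stump records its feature, split point and left/right raw leaf
    values; together with the initial log-odds score they reproduce the
    additive decision function exactly (see :func:`score_from_artifact`),
    so the artifact is both a portable model file and an audit of what
    the ensemble learned.
    """
    est = model.estimator
    stumps = []
    for stage in est.estimators_[:, 0]:
        t = stage.tree_
        if t.node_count == 1:  # degenerate stage: constant adjustment
            stumps.append(
                {"feature": None, "split": None, "left": float(t.value[0, 0, 0]),
                 "right": float(t.value[0, 0, 0])}
            )
        else:
            stumps.append(
                {
                    "feature": model.feature_names[int(t.feature[0])],
                    "split": float(t.threshold[0]),
                    "left": float(t.value[1, 0, 0]),
                    "right": float(t.value[2, 0, 0]),
                }
            )
    # recover the initial raw score from one reference prediction
    x0 = np.zeros((1, len(model.feature_names)))
    raw0 = float(est.decision_function(x0)[0])
    contrib0 = sum(
        est.learning_rate * (s["left"] if (s["feature"] is None or 0.0 <= s["split"]) else s["right"])
        for s in stumps
    )
    return {
        "model": "boosted-stumps",
        "threshold": model.threshold,
        "learning_rate": float(est.learning_rate),
        "init_raw_score": raw0 - contrib0,
        "feature_names": model.feature_names,
        "stumps": stumps,
    }


def score_from_artifact(artifact: dict, cohort: pd.DataFrame) -> np.ndarray:
    """Predicted probabilities from a serialised stump list (no estimator).

    Reconstructs the additive raw score ``init + lr * sum(stumps)`` and
    applies the logistic link; agrees with the originating estimator's
    ``predict_proba`` to machine precision.
    """
    X = _encode_features(cohort)[artifact["feature_names"]].to_numpy()
    cols = {name: i for i, name in enumerate(artifact["feature_names"])}
    raw = np.full(len(X), artifact["init_raw_score"])
    lr = artifact["learning_rate"]
    for s in artifact["stumps"]:
        if s["feature"] is None:
            raw += lr * s["left"]
        else:
            x = X[:, cols[s["feature"]]]
            raw += lr * np.where(x <= s["split"], s["left"], s["right"])
    return 1.0 / (1.0 + np.exp(-raw))


def split_half_check(
    cohort: pd.DataFrame, threshold: float = 100.0, seed: int = 0
) -> tuple[float, float]:
    """Overfitting diagnostic: split-half AUC vs 5-fold CV AUC.

    One model is trained on a random half of the cohort and scored on the
    other half; the companion number is the out-of-fold AUC of the
    cross-validated model on the full cohort.  Similar values indicate
    the ensemble is not overtrained.

    Returns ``(auc_half, auc_cv)``.
    """
    if len(cohort) < 200:
        raise ValueError(f"cohort too small for a split-half check ({len(cohort)} < 200)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(cohort))
    half = len(cohort) // 2
    train_part = cohort.iloc[idx[:half]]
    test_part = cohort.iloc[idx[half:]]
    y_test = (test_part["cacs"].to_numpy(dtype=float) >= threshold).astype(int)

    half_model = train_cac_model(train_part, threshold=threshold, seed=seed)
    p_test = predict_cac_risk(half_model, test_part)
    auc_half = float(roc_auc_score(y_test, p_test))

    cv_model = train_cac_model(cohort, threshold=threshold, seed=seed)
    return auc_half, cv_model.cv_auc


def calibration_curve(
    probabilities, labels, n_bins: int = 10
) -> pd.DataFrame:
    """Reliability curve: observed event fraction per predicted-risk bin.

    Bins are quantiles of the predicted probabilities (deciles by
    default), so each non-empty bin holds a comparable number of
    participants.  Returns a frame with ``mean_predicted``,
    ``observed_fraction`` and ``n`` per bin.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    if p.size != y.size:
        raise ValueError(f"length mismatch: {p.size} probabilities vs {y.size} labels")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    # rank-based binning handles heavily tied probabilities gracefully
    order = pd.Series(p).rank(method="first")
    bins = pd.qcut(order, q=n_bins, labels=False, duplicates="drop")
    df = pd.DataFrame({"bin": bins, "p": p, "y": y})
    g = df.groupby("bin", observed=True)
    return pd.DataFrame(
        {
            "mean_predicted": g["p"].mean(),
            "observed_fraction": g["y"].mean(),
            "n": g.size(),
        }
    ).reset_index(drop=True)
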