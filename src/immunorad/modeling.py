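"""Per-subset logistic models, LOOCV, feature significance, and
group prediction.

One binary logistic model per immune subset, with the subset's selected
radiomic features as predictors and the low/high enrichment level as
the response. A vanishingly small L2 ridge (eps = 1e-6) keeps the fit
defined on separable leave-one-out folds without materially shrinking
the coefficients. Predicted probabilities are thresholded at 0.5 into a
level quadruple and mapped to a phenotype group through the rule table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.linear_model import LogisticRegression

from .enrichment import HIGH, LOW
from .expression import SUBSETS
from .phenotype import RULE_MAPPED, ImmunophenotypeLabel, map_levels_to_group

log = logging.getLogger(__name__)

#: Default L2 penalty weight (sklearn's 1/C) applied on the
#: standardized-feature scale. A unit ridge keeps separable
#: leave-one-out folds well-defined AND stops the fit from pinning its
#: boundary on mislabelled training points, which a vanishing ridge
#: does whenever the selected features are numerous enough to separate
#: the cohort. Set to ~1e-6 for an effectively unpenalized fit.
DEFAULT_RIDGE = 1.0


@dataclass
class SubsetModel:
    subset: str
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    n_train: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("one coefficient per feature required")
        if not (np.all(np.isfinite(self.coefficients))
                and np.isfinite(self.intercept)):
            raise ValueError("non-finite model parameters")

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        x = features[self.feature_names].to_numpy(float)
        eta = x @ self.coefficients + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=features.index)

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "features": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "n_train": self.n_train,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubsetModel":
        return cls(d["subset"], d["features"], np.asarray(d["coefficients"]),
                   d["intercept"], d["n_train"], d.get("seed", 0))


@dataclass
class LoocvResult:
    subset: str
    accuracy: float
    auc: float
    predictions: pd.DataFrame  # columns: probability, predicted, truth
    n_skipped_folds: int = 0


def _binary_labels(labels: pd.Series) -> np.ndarray:
    if set(labels.unique()) <= {LOW, HIGH}:
        return (labels == HIGH).astype(int).to_numpy()
    return labels.astype(int).to_numpy()


def fit_subset_model(features: pd.DataFrame, labels: pd.Series,
                     subset: str = "CTL", seed: int = 0,
                     ridge: float = DEFAULT_RIDGE) -> SubsetModel:
    """Ridge-penalized logistic fit (penalty weight ``ridge``, L2).

    Features are standardized internally (the ridge acts on the
    standardized scale, so the solution is invariant to feature units)
    and coefficients are mapped back to the raw scale.
    """
    y = _binary_labels(labels.loc[features.index])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, p = features.shape
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: coefficients may be unstable")
    x = features.to_numpy(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    # Newton iterations converge fast even on separable folds, where the
    # tiny ridge bounds the optimum but first-order solvers crawl to it.
    clf = LogisticRegression(
        penalty="l2", C=1.0 / ridge, solver="newton-cholesky",
        max_iter=200, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable folds: benign non-convergence
        clf.fit((x - mu) / sd, y)
    coef = clf.coef_[0] / sd
    intercept = float(clf.intercept_[0] - np.sum(clf.coef_[0] * mu / sd))
    return SubsetModel(subset, list(features.columns), coef,
                       intercept, n_train=n, seed=seed)


def _rank_auc(probs: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney (concordant-pair) AUC over held-out probabilities."""
    pos = probs[truth == 1]
    neg = probs[truth == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def loocv(features: pd.DataFrame, labels: pd.Series,
          subset: str = "CTL", seed: int = 0,
          ridge: float = DEFAULT_RIDGE) -> LoocvResult:
    """Leave-one-out evaluation: n refits, accuracy and rank AUC."""
    n = len(features)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    y = _binary_labels(labels.loc[features.index])
    probs = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        train = np.ones(n, bool)
        train[i] = False
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {i}: single-class training labels, skipped")
            skipped += 1
            continue
        model = fit_subset_model(features.iloc[train], labels.iloc[train],
                                 subset=subset, seed=seed, ridge=ridge)
        probs[i] = model.predict_proba(features.iloc[[i]]).iloc[0]
    ok = ~np.isnan(probs)
    pred = (probs[ok] >= 0.5).astype(int)
    accuracy = float((pred == y[ok]).mean())
    auc = _rank_auc(probs[ok], y[ok])
    table = pd.DataFrame(
        {"probability": probs, "predicted": np.where(np.isnan(probs), -1,
                                                     (probs >= 0.5)),
         "truth": y}, index=features.index)
    return LoocvResult(subset, accuracy, auc, table, skipped)


def feature_significance(model: SubsetModel, features: pd.DataFrame,
                         labels: pd.Series) -> pd.DataFrame:
    """Likelihood-ratio chi-squared (1 df) and importance ratio per feature.

    The LR statistic compares the full fit against a refit with the
    feature dropped. The importance ratio is the feature's standardized
    |coefficient| share of the model total (ratios sum to 1).
    """
    y = _binary_labels(labels.loc[features.index])
    x_full = features[model.feature_names]

    def _llf(cols: list[str]) -> float:
        if cols:
            m = fit_subset_model(features[cols], labels, model.subset)
            p = m.predict_proba(features).to_numpy()
        else:
            p = np.full(len(y), y.mean())
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

    ll_full = _llf(model.feature_names)
    std = x_full.std(axis=0).to_numpy()
    weights = np.abs(model.coefficients * std)
    total = weights.sum()
    ratios = weights / total if total > 0 else np.full_like(weights,
                                                            1.0 / len(weights))
    rows = []
    for i, name in enumerate(model.feature_names):
        rest = [f for f in model.feature_names if f != name]
        stat = max(0.0, 2.0 * (ll_full - _llf(rest)))
        rows.append({"feature": name, "chi2": stat,
                     "p_value": float(chi2.sf(stat, df=1)),
                     "importance_ratio": float(ratios[i])})
    return pd.DataFrame(rows).set_index("feature")


def predict_levels(models: dict[str, SubsetModel],
                   features: pd.DataFrame,
                   threshold: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample subset probabilities and thresholded levels."""
    missing = [s for s in SUBSETS if s not in models]
    if missing:
        raise ValueError(f"missing model(s) for {missing}")
    probs = pd.DataFrame(index=features.index, columns=list(SUBSETS),
                         dtype=float)
    for subset in SUBSETS:
        model = models[subset]
        absent = [f for f in model.feature_names if f not in features.columns]
        if absent:
            raise ValueError(f"{subset}: feature(s) missing: {absent[:3]}")
        probs[subset] = model.predict_proba(features)
    levels = probs.map(lambda p: HIGH if p >= threshold else LOW)
    return probs, levels


def predict_groups(models: dict[str, SubsetModel],
                   features: pd.DataFrame,
                   threshold: float = 0.5) -> list[ImmunophenotypeLabel]:
    """Threshold the four subset probabilities and map to G1–G5."""
    complete = features.dropna(axis=0)
    dropped = set(features.index) - set(complete.index)
    for sid in sorted(dropped):
        log.warning("sample %s skipped: missing feature value(s)", sid)
    _, levels = predict_levels(models, complete, threshold)
    out = []
    for sid in complete.index:
        quad = tuple(levels.loc[sid, s] for s in SUBSETS)
        group, rule = map_levels_to_group(quad)
        out.append(ImmunophenotypeLabel(str(sid), group, RULE_MAPPED, rule))
    return out


def write_models(models: dict[str, SubsetModel], path) -> None:
    payload = {s: m.to_dict() for s, m in models.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_models(path) -> dict[str, SubsetModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return {s: SubsetModel.from_dict(d) for s, d in payload.items()}
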