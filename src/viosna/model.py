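"""Logistic validation of the network patterns.

The 12 key diagnosis/trauma indicators selected by the network analysis,
plus demographics (age group, residence, nationality), predict whether a
woman belongs to the WVV group. The workflow mirrors the study design:
proportional WVV-stratified 75/25 split, maximum-likelihood logistic fit
with Wald intervals, and stratified 10-fold cross-validated AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelSpec",
    "ModelError",
    "LogisticModel",
    "AurocEstimate",
    "stratified_split",
    "design_matrix",
    "fit_logistic",
    "cross_validated_auroc",
    "predict_probability",
    "ViolenceRiskModel",
]

#: The 12 key diagnoses/traumas entering the predictive model, in reporting
#: order, followed by the demographic terms and their reference levels.
DEFAULT_PREDICTORS = (
    "infectious",
    "symptoms_ill_defined",
    "other_diagnoses",
    "psychoses",
    "alcohol_substance_abuse",
    "circulatory",
    "pregnancy_related",
    "genitourinary",
    "respiratory",
    "trauma_road",
    "trauma_other",
    "repeated_aggression",
)

AGE_DUMMIES = {"age_25_34": "25-34", "age_35_54": "35-54", "age_55_70": "55-70"}


class ModelError(RuntimeError):
    """Logistic fit failed (separation or non-convergence)."""


@dataclass
class ModelSpec:
    """Predictor set and reference levels.

    References: age 15–24, residence outside Rome, foreign nationality.
    ``missing_nationality='level'`` adds an own dummy for a missing
    nationality class when present in the data.
    """

    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    include_demographics: bool = True
    missing_nationality: str = "level"
    outcome: str = "wvv"


def design_matrix(histories: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (with constant) and outcome vector for a history table."""
    cols = {}
    for term in spec.predictors:
        cols[term] = histories[term].astype(float).to_numpy()
    if spec.include_demographics:
        age = histories["age_group"].astype(str).to_numpy()
        for dummy, level in AGE_DUMMIES.items():
            cols[dummy] = (age == level).astype(float)
        cols["residence_metro"] = (
            histories["residence"].astype(str).to_numpy() == "metro_rome"
        ).astype(float)
        nat = histories["nationality"].astype(str).to_numpy()
        cols["nationality_italian"] = (nat == "italian").astype(float)
        if spec.missing_nationality == "level" and (nat == "missing").any():
            cols["nationality_missing"] = (nat == "missing").astype(float)
    X = pd.DataFrame(cols, index=histories.index)
    X.insert(0, "const", 1.0)
    y = histories[spec.outcome].astype(int).to_numpy()
    return X, y


def stratified_split(histories: pd.DataFrame, dev_fraction: float = 0.75,
                     seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportional WVV-stratified split into development and validation.

    The overall validation size is ``floor((1 − f) · N)``, apportioned to the
    strata by largest remainder (which reproduces a 93,519 / 31,172 split of
    124,691 women with 580 WVV at f = 0.75); the development set is the
    complement. Seeded and deterministic.
    """
    if not 0.0 < dev_fraction <= 1.0:
        raise ValueError("dev_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_val_total = int(np.floor((1.0 - dev_fraction) * len(histories)))
    strata = [np.flatnonzero(histories["wvv"].to_numpy() == s) for s in (True, False)]
    exact = [(1.0 - dev_fraction) * len(s) for s in strata]
    take = [int(np.floor(e)) for e in exact]
    short = n_val_total - sum(take)
    for i in sorted(range(len(strata)), key=lambda i: -(exact[i] - take[i]))[:short]:
        take[i] += 1
    val_rows: list[int] = []
    for idx, t in zip(strata, take):
        if t > 0:
            val_rows.extend(rng.choice(idx, size=t, replace=False).tolist())
    val_mask = np.zeros(len(histories), dtype=bool)
    val_mask[val_rows] = True
    return histories.iloc[~val_mask].copy(), histories.iloc[val_mask].copy()


@dataclass
class LogisticModel:
    """Fitted coefficient table with odds ratios and Wald 95% intervals."""

    table: pd.DataFrame  # index = term; columns coef, se, or, ci_low, ci_high, p
    intercept: float
    n: int
    converged: bool
    spec: ModelSpec = field(default_factory=ModelSpec)

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "const"]

    def coefficient(self, term: str) -> float:
        if term == "const":
            return self.intercept
        if term not in self.table.index:
            raise KeyError(f"unknown model term: {term!r}")
        return float(self.table.loc[term, "coef"])

    def write(self, outdir) -> None:
        import json
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.rename_axis("term").to_csv(out / "model.csv")
        payload = {
            "intercept": self.intercept,
            "n": self.n,
            "converged": self.converged,
            "terms": {
                t: {c: float(self.table.loc[t, c]) for c in self.table.columns}
                for t in self.table.index
            },
        }
        (out / "model.json").write_text(json.dumps(payload, indent=1))


def fit_logistic(histories: pd.DataFrame, spec: ModelSpec | None = None) -> LogisticModel:
    """Maximum-likelihood logistic regression of WVV status.

    Raises :class:`ModelError` on separation or non-convergence, naming the
    term with the most extreme coefficient.
    """
    spec = spec or ModelSpec()
    X, y = design_matrix(histories, spec)
    if y.min() == y.max():
        raise ModelError("outcome has a single class")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ModelError(f"logistic fit failed: {exc}") from exc
    params = res.params
    if not res.mle_retvals.get("converged", False) or not np.isfinite(params).all():
        worst = params.abs().idxmax()
        raise ModelError(f"logistic fit did not converge (offending term: {worst})")
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "coef": params,
        "se": res.bse,
        "or": np.exp(params),
        "ci_low": np.exp(ci[0]),
        "ci_high": np.exp(ci[1]),
        "p": res.pvalues,
    })
    return LogisticModel(table=table, intercept=float(params["const"]),
                         n=len(y), converged=True, spec=spec)


def predict_probability(model: LogisticModel, profile: dict) -> float:
    """Inverse-logit of the linear predictor for one covariate profile.

    ``profile`` must supply a value (0/1 or bool) for every non-constant
    model term.
    """
    eta = model.intercept
    for term in model.terms:
        if term not in profile:
            raise KeyError(f"profile is missing model term {term!r}")
        eta += model.coefficient(term) * float(profile[term])
    return float(expit(eta))


@dataclass
class AurocEstimate:
    """Cross-validated AUROC: point estimate, Wald CI over folds, per-fold values."""

    estimate: float
    ci_low: float
    ci_high: float
    per_fold: list[float]


def auroc(y_true, scores) -> float:
    """Area under the ROC curve, rank (Mann–Whitney) formulation with ties
    counted one half."""
    y_true = np.asarray(y_true)
    if y_true.min() == y_true.max():
        raise ValueError("AUROC requires both outcome classes")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def cross_validated_auroc(histories: pd.DataFrame, spec: ModelSpec | None = None,
                          k: int = 10, seed: int | None = None) -> AurocEstimate:
    """Stratified k-fold cross-validated AUROC on a history table.

    Folds are balanced in WVV cases; each fold is scored by a model fitted on
    the other k−1 folds. The interval is mean ± 1.96·SE over folds (a
    reporting convention).
    """
    spec = spec or ModelSpec()
    y_all = histories[spec.outcome].astype(int).to_numpy()
    if y_all.sum() < k:
        raise ValueError(f"need at least {k} WVV cases for {k}-fold stratification")
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for train, test in folds.split(histories, y_all):
        model = fit_logistic(histories.iloc[train], spec)
        X_test, y_test = design_matrix(histories.iloc[test], spec)
        X_test = X_test.reindex(columns=model.table.index, fill_value=0.0)
        scores = expit(X_test.to_numpy() @ model.table["coef"].to_numpy())
        per_fold.append(auroc(y_test, scores))
    arr = np.array(per_fold)
    se = arr.std(ddof=1) / np.sqrt(k)
    return AurocEstimate(float(arr.mean()), float(arr.mean() - 1.96 * se),
                         float(arr.mean() + 1.96 * se), per_fold)


class ViolenceRiskModel(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper for the WVV logistic risk model.

    ``fit(X)`` takes a history table (outcome read from the ``wvv`` column,
    or pass ``y`` explicitly). Fitted attributes: ``model_``
    (:class:`LogisticModel`), ``summary_`` (coefficient table), ``coef_``,
    ``intercept_``, ``classes_``.
    """

    def __init__(self, predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
                 include_demographics: bool = True,
                 missing_nationality: str = "level"):
        self.predictors = predictors
        self.include_demographics = include_demographics
        self.missing_nationality = missing_nationality

    def _spec(self) -> ModelSpec:
        return ModelSpec(predictors=tuple(self.predictors),
                         include_demographics=self.include_demographics,
                         missing_nationality=self.missing_nationality)

    def fit(self, X: pd.DataFrame, y=None):
        data = X.copy()
        if y is not None:
            data = data.assign(wvv=np.asarray(y).astype(int))
        self.model_ = fit_logistic(data, self._spec())
        self.summary_ = self.model_.table
        self.intercept_ = self.model_.intercept
        self.coef_ = self.model_.table.drop(index="const")["coef"].to_numpy()
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "model_")
        data = X if "wvv" in X.columns else X.assign(wvv=0)
        D, _ = design_matrix(data, self._spec())
        D = D.reindex(columns=self.model_.table.index, fill_value=0.0)
        p = expit(D.to_numpy() @ self.model_.table["coef"].to_numpy())
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return logit(p)
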