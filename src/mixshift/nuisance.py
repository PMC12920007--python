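"""Nuisance estimation: outcome regression and shift density ratios.

Two nuisance functions drive the shift TMLE:

* the outcome regression ``Qbar(A, W) = E[Y | A, W]``, fitted by discrete
  cross-validated selection over a roster of learners ("discrete super
  learner": the roster member with the smallest V-fold CV loss is refit
  on all training rows);
* the clever covariate ``H_delta(A, W) = g0(A - delta | W) / g0(A | W)``,
  the density ratio between the shifted and observed exposure laws,
  estimated either by probabilistic classification on an augmented
  two-copy dataset or by direct conditional-density modelling.

Ratios are truncated to a positivity ceiling (default 50) because large
ratios signal shifted exposures leaving the support of the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (logit used by tmle)
from scipy.stats import gaussian_kde
from sklearn.base import clone
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression, RidgeCV
from sklearn.metrics import log_loss, mean_squared_error
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .data import MixtureDataset, ShiftSpec, apply_shift

__all__ = [
    "OutcomeModel",
    "RatioModel",
    "fit_outcome_regression",
    "fit_ratio_classifier",
    "fit_conditional_density",
    "fit_ratio",
    "clever_covariate",
    "default_regressors",
    "default_classifiers",
    "DEFAULT_Q_ROSTER",
    "DEFAULT_RATIO_ROSTER",
    "FAST_Q_ROSTER",
    "FAST_RATIO_ROSTER",
]

# Documented default rosters: intercept-only, main-terms GLM, random forest,
# gradient boosting.  The "fast" rosters (used by the simulation study) swap
# the tree ensembles for a degree-2 polynomial model so replicate grids run
# at desk scale.
DEFAULT_Q_ROSTER = ("mean", "glm", "rf", "gbm")
DEFAULT_RATIO_ROSTER = ("logit", "rf", "gbm")
FAST_Q_ROSTER = ("mean", "glm", "poly2")
FAST_RATIO_ROSTER = ("logit2",)

PROB_BOUNDS = (1e-4, 1.0 - 1e-4)
CLASSIFIER_PROB_BOUNDS = (1e-6, 1.0 - 1e-6)
DEFAULT_RATIO_CEILING = 50.0
DEFAULT_RATIO_FLOOR = 1e-6


def default_regressors(seed: int | None = None) -> dict[str, object]:
    return {
        "mean": DummyRegressor(strategy="mean"),
        "glm": LinearRegression(),
        "poly2": make_pipeline(
            PolynomialFeatures(degree=2, include_bias=False),
            StandardScaler(),
            RidgeCV(alphas=np.logspace(-3, 3, 13)),
        ),
        "rf": RandomForestRegressor(
            n_estimators=200, min_samples_leaf=5, random_state=seed, n_jobs=1
        ),
        "gbm": HistGradientBoostingRegressor(random_state=seed),
    }


def default_classifiers(seed: int | None = None) -> dict[str, object]:
    return {
        "mean": DummyClassifier(strategy="prior"),
        "logit": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000)
        ),
        "logit2": make_pipeline(
            PolynomialFeatures(degree=2, include_bias=False),
            StandardScaler(),
            LogisticRegression(max_iter=2000),
        ),
        "rf": RandomForestClassifier(
            n_estimators=200, min_samples_leaf=10, random_state=seed, n_jobs=1
        ),
        "gbm": HistGradientBoostingClassifier(random_state=seed),
    }


def _resolve_roster(
    roster: Sequence[str] | Mapping[str, object] | None,
    registry: Mapping[str, object],
    default: Sequence[str],
) -> dict[str, object]:
    if roster is None:
        roster = default
    if isinstance(roster, Mapping):
        return dict(roster)
    out: dict[str, object] = {}
    for name in roster:
        if name not in registry:
            raise KeyError(f"unknown learner {name!r}")
        out[name] = registry[name]
    return out


def _design(dataset: MixtureDataset, A: np.ndarray | None = None) -> np.ndarray:
    A = dataset.A if A is None else A
    return np.column_stack([dataset.W, A])


@dataclass
class OutcomeModel:
    """Cross-validated discrete selection for E[Y | A, W].

    Predictions on the unit-interval scale are bounded away from 0 and 1
    so the logistic fluctuation's offset is finite.  For a continuous
    outcome the scaling constants extend the observed range by a 10%
    margin on each side; for a binary outcome they are (0, 1).
    """

    estimator: object
    learner_name: str
    cv_losses: dict[str, float]
    y_lo: float
    y_hi: float
    binary: bool
    confounder_names: tuple[str, ...] = ()
    exposure_names: tuple[str, ...] = ()

    def predict(self, W: np.ndarray, A: np.ndarray) -> np.ndarray:
        """Natural-scale prediction (unbounded)."""
        X = np.column_stack([W, A])
        if self.binary:
            return self.estimator.predict_proba(X)[:, 1]
        return np.asarray(self.estimator.predict(X), dtype=float)

    # -- outcome scaling -------------------------------------------------
    def scale01(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_lo) / (self.y_hi - self.y_lo)

    def unscale(self, y01: np.ndarray) -> np.ndarray:
        return self.y_lo + (self.y_hi - self.y_lo) * np.asarray(y01, dtype=float)

    def predict01(self, W: np.ndarray, A: np.ndarray) -> np.ndarray:
        """Prediction mapped to [0,1] and bounded into (0, 1)."""
        p = self.scale01(self.predict(W, A))
        return np.clip(p, *PROB_BOUNDS)


def fit_outcome_regression(
    train: MixtureDataset,
    roster: Sequence[str] | Mapping[str, object] | None = None,
    v_folds: int = 3,
    seed: int | None = None,
) -> OutcomeModel:
    """Discrete super learner for the outcome regression.

    The roster member with the smallest V-fold cross-validated loss
    (squared error for continuous Y, log loss for binary Y) is refit on
    the full training set.
    """
    y = train.Y
    if np.var(y) == 0:
        raise ValueError("degenerate outcome: zero variance")
    if train.n < 2 * v_folds:
        raise ValueError(f"need at least {2 * v_folds} rows for {v_folds}-fold CV")
    registry = (
        default_classifiers(seed) if train.binary_outcome else default_regressors(seed)
    )
    learners = _resolve_roster(roster, registry, FAST_Q_ROSTER)
    X = _design(train)

    losses: dict[str, float] = {}
    if len(learners) == 1:
        (name,) = learners
        losses[name] = float("nan")
        best = name
    else:
        kf = KFold(n_splits=v_folds, shuffle=True, random_state=seed)
        splits = list(kf.split(X))
        for name, est in learners.items():
            fold_losses = []
            for tr, te in splits:
                model = clone(est).fit(X[tr], y[tr])
                if train.binary_outcome:
                    p = np.clip(model.predict_proba(X[te])[:, 1], 1e-12, 1 - 1e-12)
                    fold_losses.append(log_loss(y[te], p, labels=[0.0, 1.0]))
                else:
                    fold_losses.append(mean_squared_error(y[te], model.predict(X[te])))
            losses[name] = float(np.mean(fold_losses))
        best = min(losses, key=losses.get)

    fitted = clone(learners[best]).fit(X, y)
    if train.binary_outcome:
        y_lo, y_hi = 0.0, 1.0
    else:
        rng_y = float(np.max(y) - np.min(y))
        margin = 0.1 * rng_y
        y_lo, y_hi = float(np.min(y) - margin), float(np.max(y) + margin)
    return OutcomeModel(
        estimator=fitted,
        learner_name=best,
        cv_losses=losses,
        y_lo=y_lo,
        y_hi=y_hi,
        binary=train.binary_outcome,
        confounder_names=train.confounder_names,
        exposure_names=train.exposure_names,
    )


@dataclass
class RatioModel:
    """Fitted estimator of the shift density ratio for one ShiftSpec.

    ``predict_ratio(W, A)`` evaluates g(A - delta | W) / g(A | W) at the
    supplied exposure values, truncated into [floor, ceiling].
    """

    method: str  # {"classifier", "direct-density"}
    spec: ShiftSpec
    ceiling: float = DEFAULT_RATIO_CEILING
    floor: float = DEFAULT_RATIO_FLOOR
    classifier: object | None = None
    learner_name: str | None = None
    exposure_names: tuple[str, ...] = ()
    # direct-density components: per target, (location regressor, kde)
    density_components: dict[str, tuple[object, object]] = field(default_factory=dict)
    max_ratio_: float | None = None

    def raw_ratio(self, W: np.ndarray, A: np.ndarray) -> np.ndarray:
        if self.method == "classifier":
            X = np.column_stack([W, A])
            p = self.classifier.predict_proba(X)[:, 1]
            p = np.clip(p, *CLASSIFIER_PROB_BOUNDS)
            return p / (1.0 - p)
        ratio = np.ones(A.shape[0])
        for name, (reg, kde) in self.density_components.items():
            j = self.exposure_names.index(name)
            delta = self.spec.delta_for(name)
            resid = A[:, j] - reg.predict(W)
            num = kde(resid - delta)
            den = np.maximum(kde(resid), 1e-300)
            ratio = ratio * (num / den)
        return ratio

    def predict_ratio(self, W: np.ndarray, A: np.ndarray) -> np.ndarray:
        return np.clip(self.raw_ratio(W, A), self.floor, self.ceiling)

    def with_spec(self, spec: ShiftSpec) -> "RatioModel":
        """Re-point a direct-density model at a new shift (no refit needed)."""
        if self.method != "direct-density":
            raise ValueError("only direct-density models can be re-pointed")
        return dataclasses.replace(self, spec=spec, max_ratio_=None)


def fit_ratio_classifier(
    train: MixtureDataset,
    spec: ShiftSpec,
    roster: Sequence[str] | Mapping[str, object] | None = None,
    seed: int | None = None,
    ceiling: float = DEFAULT_RATIO_CEILING,
    floor: float = DEFAULT_RATIO_FLOOR,
) -> RatioModel:
    """Density-ratio estimation recast as binary classification.

    Each observation contributes two rows to an augmented dataset: the
    observed exposures labelled 0 and the post-intervention exposures
    (A + delta) labelled 1.  With balanced copies, the fitted odds
    p/(1-p) of a calibrated classifier equal g(a - delta | w)/g(a | w).
    A joint shift is handled by one classifier on the jointly shifted
    copies, respecting exposure dependence.
    """
    spec.validate_for(train)
    A_shift = apply_shift(train, spec, "post-intervention")
    X = np.vstack([_design(train), _design(train, A_shift)])
    xi = np.concatenate([np.zeros(train.n), np.ones(train.n)])

    learners = _resolve_roster(roster, default_classifiers(seed), FAST_RATIO_ROSTER)
    if len(learners) == 1:
        (best,) = learners
    else:
        kf = KFold(n_splits=3, shuffle=True, random_state=seed)
        losses = {}
        for name, est in learners.items():
            fold_losses = []
            for tr, te in kf.split(X):
                model = clone(est).fit(X[tr], xi[tr])
                p = np.clip(model.predict_proba(X[te])[:, 1], 1e-12, 1 - 1e-12)
                fold_losses.append(log_loss(xi[te], p, labels=[0.0, 1.0]))
            losses[name] = float(np.mean(fold_losses))
        best = min(losses, key=losses.get)
    fitted = clone(learners[best]).fit(X, xi)
    return RatioModel(
        method="classifier",
        spec=spec,
        ceiling=ceiling,
        floor=floor,
        classifier=fitted,
        learner_name=best,
        exposure_names=train.exposure_names,
    )


def fit_conditional_density(
    train: MixtureDataset,
    spec: ShiftSpec,
    seed: int | None = None,
    ceiling: float = DEFAULT_RATIO_CEILING,
    floor: float = DEFAULT_RATIO_FLOOR,
) -> RatioModel:
    """Direct conditional-density model for the shift ratio.

    Default estimator: a homoscedastic location model per target exposure
    (linear regression of A on W) with a Gaussian kernel density on the
    residuals (Silverman bandwidth).  Multi-target specs evaluate the
    product of per-exposure ratios.
    """
    spec.validate_for(train)
    components: dict[str, tuple[object, object]] = {}
    for name in spec.targets:
        a = train.exposure(name)
        reg = LinearRegression().fit(train.W, a)
        resid = a - reg.predict(train.W)
        if np.var(resid) < 1e-12:
            raise ValueError(f"zero residual variance for exposure {name!r}")
        kde = gaussian_kde(resid, bw_method="silverman")
        components[name] = (reg, kde)
    return RatioModel(
        method="direct-density",
        spec=spec,
        ceiling=ceiling,
        floor=floor,
        density_components=components,
        exposure_names=train.exposure_names,
    )


def fit_ratio(
    train: MixtureDataset,
    spec: ShiftSpec,
    method: str = "classifier",
    roster: Sequence[str] | Mapping[str, object] | None = None,
    seed: int | None = None,
    ceiling: float = DEFAULT_RATIO_CEILING,
    floor: float = DEFAULT_RATIO_FLOOR,
) -> RatioModel:
    """Dispatch to the configured density-ratio estimator."""
    if method == "classifier":
        return fit_ratio_classifier(train, spec, roster, seed, ceiling, floor)
    if method in ("direct", "direct-density"):
        return fit_conditional_density(train, spec, seed, ceiling, floor)
    raise ValueError(f"unknown density method {method!r}")


def clever_covariate(
    model: RatioModel, dataset: MixtureDataset, spec: ShiftSpec | None = None
) -> np.ndarray:
    """Evaluate H_delta on the observed rows of ``dataset``.

    Returns the truncated positive ratio vector and records the maximum
    (pre-truncation) ratio on the model for positivity diagnostics.
    """
    if spec is not None and spec.as_mapping() != model.spec.as_mapping():
        raise ValueError("ratio model was trained for a different shift spec")
    raw = model.raw_ratio(dataset.W, dataset.A)
    model.max_ratio_ = float(np.max(raw))
    return np.clip(raw, model.floor, model.ceiling)
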