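"""Stacked ensemble regression for the production metrics (TRY).

Six base learners — support-vector regression, elastic net, random forest,
gradient-boosted trees (XGBoost), k-nearest neighbours and a dense neural
network (5 hidden layers of 100 units with batch norm and dropout) — are
grid-searched with five-fold cross-validation; their out-of-fold (OOF)
predictions form the meta-feature matrix on which a gradient-boosted-tree
meta-regressor is trained. Using OOF predictions (not in-sample refits)
keeps the meta-learner from rewarding overfit base learners, and CV folds
are always scored on un-augmented rows: target-jitter augmentation, when
enabled, is applied inside each training fold only.

One stacked model is trained per metric (titer, rate or yield); rows whose
target is missing are dropped for that metric. Evaluation reports the test
coefficient of determination R² = 1 - SSE/SST (about the test mean) and
the Pearson correlation r, optionally also on per-product max-scaled
values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold, ParameterGrid
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .mlp import DenseDropoutRegressor
from .preprocess import AugmentationParams, LeakageAudit, augment

logger = logging.getLogger(__name__)

__all__ = [
    "RegressorSpec",
    "default_specs",
    "StackedTRYRegressor",
    "EvaluationReport",
    "evaluate",
    "fit_stacked",
    "ablation_cobra",
    "learning_curve",
]


@dataclass(frozen=True)
class RegressorSpec:
    """A base learner kind, its hyperparameter grid and a fixed seed."""

    name: str
    estimator: BaseEstimator
    grid: Mapping[str, Sequence] = dc_field(default_factory=dict)

    def candidates(self):
        return list(ParameterGrid(dict(self.grid))) if self.grid else [{}]


def default_specs(seed: int = 0, nn_epochs: int = 60) -> list[RegressorSpec]:
    """The six base learners with compact default grids."""
    return [
        RegressorSpec("svr", SVR(), {"C": [1.0, 10.0], "gamma": ["scale"]}),
        RegressorSpec("elastic_net", ElasticNet(max_iter=5000, random_state=seed),
                      {"alpha": [0.01, 0.1], "l1_ratio": [0.5]}),
        RegressorSpec("random_forest",
                      RandomForestRegressor(n_estimators=80, max_features=0.3,
                                            random_state=seed, n_jobs=1),
                      {"max_depth": [None, 8]}),
        RegressorSpec("gradient_boosted_trees",
                      XGBRegressor(n_estimators=300, learning_rate=0.07,
                                   random_state=seed, n_jobs=1, verbosity=0),
                      {"max_depth": [3, 6]}),
        RegressorSpec("knn", KNeighborsRegressor(), {"n_neighbors": [5, 15]}),
        RegressorSpec("neural_network",
                      DenseDropoutRegressor(epochs=nn_epochs, batch_size=128,
                                            random_state=seed), {}),
    ]


@dataclass
class EvaluationReport:
    """Held-out metrics for one target."""

    target: str
    n_test: int
    r2: float
    pearson_r: float
    r2_scaled: float | None = None
    pearson_r_scaled: float | None = None
    per_learner: dict = dc_field(default_factory=dict)
    cv_r2_mean: float | None = None
    cv_r2_sd: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _safe_r2(y_true, y_pred) -> float:
    """R² = 1 - SSE/SST; defined as 0 for a constant truth (logged)."""
    y_true = np.asarray(y_true, dtype=float)
    if np.allclose(y_true, y_true[0]):
        logger.info("constant target in scoring; R² reported as 0 by convention")
        return 0.0
    return float(r2_score(y_true, y_pred))


def _pearson(y_true, y_pred) -> float:
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return float("nan")
    return float(stats.pearsonr(np.asarray(y_true, float), np.asarray(y_pred, float))[0])


class _YScaledRegressor(BaseEstimator):
    """Standardise the target around each fit (undone at prediction).

    The production metrics live on very different scales (titers of order
    10 g/L, rates of order 0.1 g/L/h); scale-sensitive learners (the SVR's
    epsilon tube, elastic-net penalties) need a unit-variance target to
    behave comparably across metrics.
    """

    def __init__(self, inner: BaseEstimator):
        self.inner = inner

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self._mu = float(y.mean())
        self._sd = float(y.std()) or 1.0
        self.inner_ = clone(self.inner)
        self.inner_.fit(X, (y - self._mu) / self._sd)
        return self

    def predict(self, X):
        return self.inner_.predict(X) * self._sd + self._mu


class StackedTRYRegressor(RegressorMixin, BaseEstimator):
    """Grid-searched base learners + gradient-boosted-tree meta-regressor.

    Parameters
    ----------
    specs : base-learner specifications (>= 2 required); defaults to the
        six-learner set of :func:`default_specs`.
    n_folds : folds for both the per-learner grid search and the OOF
        meta-features.
    augmentation : optional target-jitter parameters applied inside each
        training fold (validation parts stay un-augmented).
    random_state : seed controlling folds, learners and augmentation.
    audit : optional :class:`LeakageAudit` to which consumed ids are logged.

    Fitted attributes: ``base_learners_`` (surviving fitted learners),
    ``meta_learner_``, ``oof_predictions_``, ``cv_results_``,
    ``best_params_``, ``cv_r2_mean_`` / ``cv_r2_sd_`` (score of the stack's
    OOF predictions per fold).
    """

    def __init__(self, specs: Sequence[RegressorSpec] | None = None,
                 n_folds: int = 5,
                 augmentation: AugmentationParams | None = None,
                 random_state: int = 0,
                 audit: LeakageAudit | None = None):
        self.specs = specs
        self.n_folds = n_folds
        self.augmentation = augmentation
        self.random_state = random_state
        self.audit = audit

    def _fold_fit_predict(self, est, X, y, tr, va):
        Xtr, ytr = X.iloc[tr], y.iloc[tr]
        if self.augmentation is not None and self.augmentation.n > 0:
            df = Xtr.copy()
            df["__target__"] = ytr.values
            aug = augment(df, self.augmentation, target_columns=["__target__"])
            Xtr = aug.drop(columns=["__target__", "source_record_id"])
            ytr = aug["__target__"]
        model = _YScaledRegressor(est)
        model.fit(Xtr.values, ytr.values)
        return model.predict(X.iloc[va].values)

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        keep = y.notna()
        X, y = X.loc[keep], y.loc[keep]
        specs = list(self.specs) if self.specs is not None \
            else default_specs(self.random_state)
        if len(specs) < 2:
            raise ValueError("the stack requires at least 2 base learners")
        if self.audit is not None:
            self.audit.record("stack_fit", X.index)

        folds = list(KFold(self.n_folds, shuffle=True,
                           random_state=self.random_state).split(X))
        self.base_learners_ = {}
        self.best_params_ = {}
        self.cv_results_ = []
        oof_cols = {}
        for spec in specs:
            best = None
            try:
                for params in spec.candidates():
                    est = clone(spec.estimator).set_params(**params)
                    oof = np.full(len(y), np.nan)
                    for tr, va in folds:
                        oof[va] = self._fold_fit_predict(est, X, y, tr, va)
                    fold_scores = [_safe_r2(y.iloc[va], oof[va]) for _, va in folds]
                    score = float(np.mean(fold_scores))
                    self.cv_results_.append({"learner": spec.name, **params,
                                             "cv_r2": score})
                    if best is None or score > best[0]:
                        best = (score, params, oof)
            except Exception as exc:  # noqa: BLE001 - a diverging learner leaves the stack
                warnings.warn(f"base learner {spec.name} failed and is excluded: {exc}")
                continue
            score, params, oof = best
            est = clone(spec.estimator).set_params(**params)
            final = self._fit_full(est, X, y)
            self.base_learners_[spec.name] = final
            self.best_params_[spec.name] = params
            oof_cols[spec.name] = oof
        if len(self.base_learners_) < 2:
            raise RuntimeError("fewer than 2 base learners survived fitting")

        self.oof_predictions_ = pd.DataFrame(oof_cols, index=X.index)
        # the gradient-boosted-tree meta-regressor is grid-searched like the
        # base learners, on the same folds over the OOF matrix
        Z = self.oof_predictions_.values
        base = dict(learning_rate=0.1, random_state=self.random_state,
                    n_jobs=1, verbosity=0)
        meta_grid = [dict(max_depth=d, n_estimators=n, **base)
                     for d in (1, 2, 3) for n in (50, 200)]
        best_meta = None
        for params in meta_grid:
            fold_scores = []
            for tr, va in folds:
                mm = XGBRegressor(**params)
                mm.fit(Z[tr], y.values[tr])
                fold_scores.append(_safe_r2(y.iloc[va], mm.predict(Z[va])))
            mean = float(np.mean(fold_scores))
            if best_meta is None or mean > best_meta[0]:
                best_meta = (mean, float(np.std(fold_scores)), params)
        self.cv_r2_mean_, self.cv_r2_sd_, meta_params = best_meta
        self.best_params_["meta"] = {k: meta_params[k]
                                     for k in ("max_depth", "n_estimators")}
        self.meta_learner_ = XGBRegressor(**meta_params)
        self.meta_learner_.fit(Z, y.values)
        self.train_index_ = X.index
        return self

    def _fit_full(self, est, X, y):
        Xf, yf = X, y
        if self.augmentation is not None and self.augmentation.n > 0:
            df = X.copy()
            df["__target__"] = y.values
            aug = augment(df, self.augmentation, target_columns=["__target__"])
            Xf = aug.drop(columns=["__target__", "source_record_id"])
            yf = aug["__target__"]
        model = _YScaledRegressor(est)
        model.fit(Xf.values, yf.values)
        return model

    def _meta_features(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        if len(X) == 0:
            return np.empty((0, len(self.base_learners_)))
        return np.column_stack([m.predict(X.values)
                                for m in self.base_learners_.values()])

    def predict(self, X) -> np.ndarray:
        Z = self._meta_features(X)
        if len(Z) == 0:
            return np.array([])
        return self.meta_learner_.predict(Z)

    def base_predictions(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return pd.DataFrame(self._meta_features(X), index=X.index,
                            columns=list(self.base_learners_))


def fit_stacked(X, y, target: str = "titer",
                specs: Sequence[RegressorSpec] | None = None,
                folds: int = 5, augmentation: AugmentationParams | None = None,
                random_state: int = 0,
                audit: LeakageAudit | None = None) -> StackedTRYRegressor:
    """Functional wrapper over :class:`StackedTRYRegressor`."""
    model = StackedTRYRegressor(specs=specs, n_folds=folds,
                                augmentation=augmentation,
                                random_state=random_state, audit=audit)
    model.fit(X, y)
    model.target_ = target
    return model


def evaluate(model, X_test, y_test, target: str = "titer",
             products: pd.Series | None = None,
             per_product_scaling: bool = False) -> EvaluationReport:
    """Held-out R² and Pearson r; fewer than 3 test rows -> undefined (NaN).

    With ``per_product_scaling`` the metrics are additionally computed on
    values divided by each product's maximum observed target, which puts
    products with very different absolute scales on a comparable footing.
    """
    y_test = pd.Series(np.asarray(y_test, dtype=float), index=pd.DataFrame(X_test).index)
    keep = y_test.notna()
    X_test, y_test = pd.DataFrame(X_test).loc[keep], y_test.loc[keep]
    if len(y_test) < 3:
        return EvaluationReport(target=target, n_test=len(y_test),
                                r2=float("nan"), pearson_r=float("nan"))
    pred = np.asarray(model.predict(X_test), dtype=float)
    rep = EvaluationReport(target=target, n_test=len(y_test),
                           r2=_safe_r2(y_test, pred), pearson_r=_pearson(y_test, pred))
    if per_product_scaling:
        if products is None:
            raise ValueError("per_product_scaling requires a products series")
        prods = pd.Series(products).loc[y_test.index]
        scale = y_test.groupby(prods).transform("max").replace(0.0, 1.0)
        rep.r2_scaled = _safe_r2(y_test / scale, pred / scale)
        rep.pearson_r_scaled = _pearson(y_test / scale, pred / scale)
    if hasattr(model, "base_learners_"):
        rep.per_learner = {name: _safe_r2(y_test, m.predict(X_test.values))
                           for name, m in model.base_learners_.items()}
        rep.cv_r2_mean = getattr(model, "cv_r2_mean_", None)
        rep.cv_r2_sd = getattr(model, "cv_r2_sd_", None)
    return rep


def ablation_cobra(X_train: pd.DataFrame, y_train, X_test: pd.DataFrame, y_test,
                   cobra_columns: Sequence[str], target: str = "titer",
                   specs: Sequence[RegressorSpec] | None = None,
                   augmentation: AugmentationParams | None = None,
                   n_components: int = 40,
                   random_state: int = 0) -> dict:
    """Paired with/without-flux-features scores under identical seeds/folds.

    ``cobra_columns`` name the flux-derived columns in the un-projected
    feature matrix. Each arm gets its own standardise+PCA transform (fitted
    on its training columns) followed by an identically seeded stack, so the
    score difference isolates the constraint-based features.
    """
    from .preprocess import FrozenTransform  # local: avoids import cycle at module load

    cobra_columns = list(cobra_columns)
    missing = set(cobra_columns) - set(X_train.columns)
    if missing:
        raise ValueError(f"cobra feature columns absent from matrix: {sorted(missing)}")
    out = {}
    for label, drop in (("with_cobra", False), ("without_cobra", True)):
        Xtr = X_train.drop(columns=cobra_columns) if drop else X_train
        Xte = X_test.drop(columns=cobra_columns) if drop else X_test
        ft = FrozenTransform(n_components).fit(Xtr)
        Xtr, Xte = ft.transform(Xtr), ft.transform(Xte)
        model = fit_stacked(Xtr, y_train, target=target, specs=specs,
                            augmentation=augmentation, random_state=random_state)
        rep = evaluate(model, Xte, y_test, target=target)
        out[label] = {"test_r2": rep.r2, "test_pearson_r": rep.pearson_r,
                      "cv_r2": model.cv_r2_mean_}
    out["delta_test_r2"] = out["with_cobra"]["test_r2"] - out["without_cobra"]["test_r2"]
    out["delta_cv_r2"] = out["with_cobra"]["cv_r2"] - out["without_cobra"]["cv_r2"]
    return out


def learning_curve(X, y, train_sizes: Sequence[int],
                   specs: Sequence[RegressorSpec] | None = None,
                   n_repeats: int = 3, n_folds: int = 5,
                   augmentation: AugmentationParams | None = None,
                   random_state: int = 0) -> pd.DataFrame:
    """Training and CV R² of the stack as a function of training-set size.

    For each size, ``n_repeats`` seeded subsamples are drawn; the stack is
    fitted on each and scored in-sample (training R²) and by its OOF CV
    score. Returns one row per size with means and standard deviations.
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    keep = y.notna()
    X, y = X.loc[keep], y.loc[keep]
    rows = []
    for size in train_sizes:
        if size > len(y):
            raise ValueError(f"train size {size} exceeds available rows {len(y)}")
        tr_scores, cv_scores, fold_sds = [], [], []
        for rep in range(n_repeats):
            if size == len(y):  # full set: identical to a standard CV run
                idx = np.arange(len(y))
            else:
                rng = np.random.default_rng(random_state + 1000 * rep + size)
                idx = rng.choice(len(y), size=size, replace=False)
            Xs, ys = X.iloc[idx], y.iloc[idx]
            model = StackedTRYRegressor(specs=specs, n_folds=n_folds,
                                        augmentation=augmentation,
                                        random_state=random_state + rep)
            model.fit(Xs, ys)
            tr_scores.append(_safe_r2(ys, model.predict(Xs)))
            cv_scores.append(model.cv_r2_mean_)
            fold_sds.append(model.cv_r2_sd_)
        rows.append({"train_size": int(size),
                     "train_r2_mean": float(np.mean(tr_scores)),
                     "train_r2_sd": float(np.std(tr_scores)),
                     "cv_r2_mean": float(np.mean(cv_scores)),
                     "cv_r2_sd": float(np.std(cv_scores)),
                     "cv_fold_sd_mean": float(np.mean(fold_sds))})
    return pd.DataFrame(rows)
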