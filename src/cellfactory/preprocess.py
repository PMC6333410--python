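"""Leakage-safe splitting, frozen standardise+PCA transform, TRY jitter.

The held-out test split (10% by default) is fixed before any fitting:
standardisation statistics and the PCA basis are learned on training rows
only, and augmentation never touches test rows. Augmentation replicates
each training record n times, jittering only the reported production
metrics (titer, rate, yield) by an independent multiplicative
Uniform(1 - t/100, 1 + t/100) draw per copy — a hard +/- t% bound — while
the input features are copied verbatim. The tuned values from the n in
10..90, t in 0.1%..1% grid are n = 50 and t = 0.1%. A :class:`LeakageAudit`
records which record ids every fitting step consumed so the guarantee is
checkable per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

__all__ = [
    "AugmentationParams",
    "SplitSpec",
    "split_ids",
    "FrozenTransform",
    "augment",
    "grid_search_augmentation",
    "LeakageAudit",
]

TARGET_COLUMNS = ("titer", "rate", "yield_1", "yield_2", "yield_3")


@dataclass(frozen=True)
class AugmentationParams:
    """Replicates per record (n) and jitter half-width (t, % of value)."""

    n: int = 50
    t: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0.0 <= self.t <= 100.0:
            raise ValueError("t must be in [0, 100] percent")


@dataclass
class SplitSpec:
    """Test fraction, fold count and the realised record assignment."""

    test_fraction: float = 0.1
    n_folds: int = 5
    seed: int = 0
    assignment: dict = field(default_factory=dict)  # record id -> "train" | "test"

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")

    @property
    def train_ids(self) -> list:
        return [i for i, a in self.assignment.items() if a == "train"]

    @property
    def test_ids(self) -> list:
        return [i for i, a in self.assignment.items() if a == "test"]


def split_ids(ids: Sequence, test_fraction: float = 0.1, n_folds: int = 5,
              seed: int = 0) -> SplitSpec:
    """Deterministic random split of record ids into train and test."""
    ids = list(ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 records to split")
    spec = SplitSpec(test_fraction=test_fraction, n_folds=n_folds, seed=seed)
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(ids)))
    test = set(rng.permutation(len(ids))[:n_test])
    spec.assignment = {rid: ("test" if i in test else "train")
                       for i, rid in enumerate(ids)}
    return spec


class FrozenTransform(TransformerMixin, BaseEstimator):
    """Standardise (training mean/sd) then project on <= 40 PCA components.

    Fitting rows define the column statistics and the PCA basis; applying
    the frozen transform to new rows uses those statistics unchanged, so
    test rows never influence the projection. Inverting the transform on
    training rows reproduces them (within retained rank) to 1e-8.
    """

    def __init__(self, n_components: int = 40):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X).astype(float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit the transform")
        self.columns_ = list(X.columns)
        self.means_ = X.mean()
        sds = X.std(ddof=0)
        self.sds_ = sds.where(sds > 1e-12, 1.0)  # constant columns pass through centred
        Xs = ((X - self.means_) / self.sds_).values
        rank = min(Xs.shape)
        k = min(self.n_components, rank)
        self._pca = PCA(n_components=k, svd_solver="full")
        self._pca.fit(Xs)
        self.n_components_ = k
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).astype(float)[self.columns_]
        Xs = ((X - self.means_) / self.sds_).values
        Z = self._pca.transform(Xs)
        return pd.DataFrame(Z, index=X.index,
                            columns=[f"pc{i + 1}" for i in range(Z.shape[1])])

    def inverse_transform(self, Z) -> pd.DataFrame:
        Xs = self._pca.inverse_transform(np.asarray(Z))
        X = Xs * self.sds_.values + self.means_.values
        idx = Z.index if isinstance(Z, pd.DataFrame) else None
        return pd.DataFrame(X, columns=self.columns_, index=idx)


def augment(frame: pd.DataFrame, params: AugmentationParams,
            target_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Append n jittered copies of every row (originals kept first).

    ``frame`` holds features plus target columns indexed by record id.
    Non-null targets in each copy are multiplied by independent
    Uniform(1 - t/100, 1 + t/100) draws; features are copied verbatim.
    Output length is ``len(frame) * (n + 1)`` with a ``source_record_id``
    provenance column.
    """
    if target_columns is None:
        target_columns = [c for c in TARGET_COLUMNS if c in frame.columns]
    missing = set(target_columns) - set(frame.columns)
    if missing:
        raise ValueError(f"target columns not in frame: {sorted(missing)}")
    rng = np.random.default_rng(params.seed)
    lo, hi = 1.0 - params.t / 100.0, 1.0 + params.t / 100.0

    out = frame.copy()
    out.insert(len(out.columns), "source_record_id", out.index)
    copies = []
    for k in range(params.n):
        c = frame.copy()
        for col in target_columns:
            factors = rng.uniform(lo, hi, size=len(c))
            c[col] = c[col] * factors  # NaN stays NaN
        c["source_record_id"] = c.index
        c.index = [f"{rid}#aug{k + 1}" for rid in frame.index]
        copies.append(c)
    return pd.concat([out] + copies, axis=0)


def grid_search_augmentation(X: pd.DataFrame, y: pd.Series,
                             n_grid: Sequence[int], t_grid: Sequence[float],
                             model_factory: Callable[[], BaseEstimator],
                             n_folds: int = 5, seed: int = 0,
                             ) -> tuple[AugmentationParams, pd.DataFrame]:
    """Tune (n, t) by cross-validated R² of the supplied model.

    Each grid cell augments the training part of every fold (jittered
    targets, duplicated features) and scores on the fold's untouched
    validation part. Ties break toward smaller n, then smaller t; a model
    failure marks the cell failed (NaN) and the search continues.
    """
    if len(n_grid) == 0 or len(t_grid) == 0:
        raise ValueError("grids must be non-empty")
    mask = y.notna()
    X, y = X.loc[mask], y.loc[mask]
    folds = list(KFold(n_folds, shuffle=True, random_state=seed).split(X))
    rows = []
    for n in n_grid:
        for t in t_grid:
            params = AugmentationParams(n=int(n), t=float(t), seed=seed)
            scores = []
            try:
                for tr, va in folds:
                    df = X.iloc[tr].copy()
                    df["__target__"] = y.iloc[tr]
                    aug = augment(df, params, target_columns=["__target__"])
                    model = model_factory()
                    model.fit(aug.drop(columns=["__target__", "source_record_id"]),
                              aug["__target__"])
                    scores.append(r2_score(y.iloc[va], model.predict(X.iloc[va])))
                rows.append({"n": int(n), "t": float(t),
                             "cv_r2": float(np.mean(scores)),
                             "cv_r2_sd": float(np.std(scores)), "failed": False})
            except Exception as exc:  # noqa: BLE001 - cell failure must not kill the search
                rows.append({"n": int(n), "t": float(t), "cv_r2": np.nan,
                             "cv_r2_sd": np.nan, "failed": True})
    table = pd.DataFrame(rows)
    ok = table[~table.failed]
    if ok.empty:
        raise RuntimeError("every augmentation grid cell failed")
    best = ok.sort_values(["cv_r2", "n", "t"],
                          ascending=[False, True, True]).iloc[0]
    return AugmentationParams(n=int(best.n), t=float(best.t), seed=seed), table


class LeakageAudit:
    """Per-run ledger of which record ids each pipeline stage consumed."""

    def __init__(self):
        self.usage: dict[str, set] = {}

    def record(self, stage: str, ids) -> None:
        self.usage.setdefault(stage, set()).update(
            str(i).split("#aug")[0] for i in ids)

    def violations(self, test_ids) -> dict[str, set]:
        test = {str(i) for i in test_ids}
        return {stage: used & test for stage, used in self.usage.items()
                if used & test}

    def assert_clean(self, test_ids) -> None:
        bad = self.violations(test_ids)
        if bad:
            raise AssertionError(f"test records leaked into fitting stages: {bad}")
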