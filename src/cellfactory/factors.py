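"""Influential-factor ranking via MCA (categorical) and PCA (continuous).

Multiple correspondence analysis is correspondence analysis of the complete
indicator matrix Z of a categorical table: with grand total N, P = Z/N, row
and column masses r and c, the matrix of standardised residuals

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

is decomposed by SVD; principal coordinates are the mass-scaled singular
vectors scaled by the singular values, eigenvalues are squared singular
values, and the contribution of category j to component s is
mass_j * coord_{js}^2 / eigenvalue_s (so contributions to each component sum
to one). Total inertia of an indicator MCA with J categories over Q
variables is J/Q - 1.

PCA operates on column-standardised continuous features (sklearn backend);
per-feature contributions are the squared unit loadings. Both estimators
expose the same :class:`ComponentDecomposition` for downstream ranking, and
:func:`factor_report` turns a decomposition into the contribution ranking
and the record-level overlay (component coordinates + titer quartile bin)
used to visualise where high-titer designs cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA

logger = logging.getLogger(__name__)

__all__ = ["ComponentDecomposition", "MCA", "PCAFactors", "mca", "pca",
           "factor_report", "discretize_quartiles"]


@dataclass
class ComponentDecomposition:
    """Eigenvalues, coordinates and per-feature contributions."""

    method: str                      # "MCA" | "PCA"
    eigenvalues: np.ndarray          # descending, >= 0
    explained_inertia: np.ndarray    # eigenvalue / total inertia
    total_inertia: float
    row_coordinates: pd.DataFrame    # records x components (principal)
    column_coordinates: pd.DataFrame # categories/features x components
    contributions: pd.DataFrame      # categories/features x components, cols sum to 1

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _comp_cols(k: int) -> list[str]:
    return [f"comp{i + 1}" for i in range(k)]


class MCA(TransformerMixin, BaseEstimator):
    """Indicator-matrix multiple correspondence analysis.

    The canonical variant: complete disjunctive coding, no Burt matrix, no
    eigenvalue correction. Constant columns (zero inertia) are dropped with
    a warning. Requires at least two categorical variables, each category
    observed at least once.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X).astype(str)
        nunique = X.nunique()
        constant = list(nunique[nunique <= 1].index)
        if constant:
            warnings.warn(f"dropping constant categorical variables: {constant}")
            X = X.drop(columns=constant)
        if X.shape[1] < 2:
            raise ValueError("MCA needs >= 2 non-constant categorical variables")
        self.variables_ = list(X.columns)
        Z = pd.get_dummies(X, prefix_sep="=").astype(float)
        self.categories_ = list(Z.columns)
        self._fit_ca(Z)
        self.Q_ = X.shape[1]
        self.J_ = Z.shape[1]
        return self

    def _fit_ca(self, Z: pd.DataFrame):
        N = Z.values.sum()
        P = Z.values / N
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, s, Vt = np.linalg.svd(S, full_matrices=False)
        pos = s > 1e-12
        U, s, Vt = U[:, pos], s[pos], Vt[pos]
        k = min(self.n_components, len(s))
        self.singular_values_ = s
        self.eigenvalues_ = s**2
        self.total_inertia_ = float(np.sum(s**2))
        self.row_masses_ = r
        self.col_masses_ = c
        # principal coordinates
        F = (U[:, :k] * s[:k]) / np.sqrt(r)[:, None]
        G = (Vt[:k].T * s[:k]) / np.sqrt(c)[:, None]
        self.row_coordinates_ = pd.DataFrame(F, index=Z.index, columns=_comp_cols(k))
        self.column_coordinates_ = pd.DataFrame(G, index=Z.columns, columns=_comp_cols(k))
        contrib = c[:, None] * G**2 / (s[:k] ** 2)[None, :]
        self.contributions_ = pd.DataFrame(contrib, index=Z.columns, columns=_comp_cols(k))
        self._G_std = Vt[:k].T / np.sqrt(c)[:, None]  # standard col coords for projection

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project (possibly new) records as supplementary row profiles."""
        X = pd.DataFrame(X).astype(str)[self.variables_]
        Z = pd.get_dummies(X, prefix_sep="=").reindex(columns=self.categories_,
                                                      fill_value=0.0).astype(float)
        profiles = Z.values / Z.values.sum(axis=1, keepdims=True)
        F = (profiles - self.col_masses_) @ self._G_std
        return pd.DataFrame(F, index=X.index, columns=self.row_coordinates_.columns)

    def variable_contributions(self) -> pd.DataFrame:
        """Category contributions aggregated to their source variable."""
        owner = [cat.split("=", 1)[0] for cat in self.contributions_.index]
        return self.contributions_.groupby(owner).sum()

    def decomposition(self) -> ComponentDecomposition:
        return ComponentDecomposition(
            method="MCA",
            eigenvalues=self.eigenvalues_[: self.row_coordinates_.shape[1]],
            explained_inertia=self.eigenvalues_[: self.row_coordinates_.shape[1]]
            / self.total_inertia_,
            total_inertia=self.total_inertia_,
            row_coordinates=self.row_coordinates_,
            column_coordinates=self.column_coordinates_,
            contributions=self.contributions_,
        )


class PCAFactors(TransformerMixin, BaseEstimator):
    """Standardised PCA with per-feature component contributions.

    Columns are centred and scaled to unit variance before the SVD;
    zero-variance columns are dropped with a warning. Contributions of
    feature j to component s are the squared unit-loading entries, which sum
    to one per component.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X).astype(float)
        sd = X.std(ddof=0)
        dead = list(sd[sd <= 1e-12].index)
        if dead:
            warnings.warn(f"dropping zero-variance columns: {dead}")
            X = X.drop(columns=dead)
        if X.shape[1] < 2:
            raise ValueError("PCA needs >= 2 non-constant columns")
        self.columns_ = list(X.columns)
        self.means_ = X.mean()
        self.sds_ = X.std(ddof=0)
        Xs = (X - self.means_) / self.sds_
        k = min(self.n_components, min(Xs.shape) - 0)
        self._pca = _SkPCA(n_components=k, svd_solver="full")
        scores = self._pca.fit_transform(Xs.values)
        if self.n_components > len(self._pca.explained_variance_):
            logger.info("rank caps components at %d (requested %d)",
                        len(self._pca.explained_variance_), self.n_components)
        cols = _comp_cols(scores.shape[1])
        self.eigenvalues_ = self._pca.explained_variance_
        # total variance on the same (ddof=1) scale as the eigenvalues
        self.total_inertia_ = float(np.sum(Xs.values.var(axis=0, ddof=1)))
        self.row_coordinates_ = pd.DataFrame(scores, index=X.index, columns=cols)
        loadings = self._pca.components_.T  # unit eigenvectors
        self.column_coordinates_ = pd.DataFrame(
            loadings * np.sqrt(self._pca.explained_variance_), index=X.columns, columns=cols)
        self.contributions_ = pd.DataFrame(loadings**2, index=X.columns, columns=cols)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).astype(float)[self.columns_]
        Xs = (X - self.means_) / self.sds_
        return pd.DataFrame(self._pca.transform(Xs.values), index=X.index,
                            columns=self.row_coordinates_.columns)

    def decomposition(self) -> ComponentDecomposition:
        ev = np.asarray(self.eigenvalues_)
        return ComponentDecomposition(
            method="PCA", eigenvalues=ev, explained_inertia=ev / self.total_inertia_,
            total_inertia=self.total_inertia_,
            row_coordinates=self.row_coordinates_,
            column_coordinates=self.column_coordinates_,
            contributions=self.contributions_,
        )


def mca(X: pd.DataFrame, n_components: int = 2) -> ComponentDecomposition:
    """Fit-and-summarise wrapper over :class:`MCA`."""
    return MCA(n_components=n_components).fit(X).decomposition()


def pca(X: pd.DataFrame, n_components: int = 2) -> ComponentDecomposition:
    """Fit-and-summarise wrapper over :class:`PCAFactors`."""
    return PCAFactors(n_components=n_components).fit(X).decomposition()


def discretize_quartiles(values: pd.Series) -> pd.Series:
    """Quartile bins 1 (lowest) .. 4 (highest); degenerate input -> one bin."""
    values = pd.Series(values)
    try:
        bins = pd.qcut(values, 4, labels=False, duplicates="drop")
    except ValueError:  # fewer than 2 distinct edges
        return pd.Series(1, index=values.index)
    if bins.isna().all():
        return pd.Series(1, index=values.index)
    return (bins + 1).astype(int)


def factor_report(dec: ComponentDecomposition, titers: pd.Series,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contribution ranking for components 1-2 and the titer overlay table.

    Returns ``(ranking, overlay)``: ranking lists each feature's
    contribution to components 1 and 2 sorted by component-2 then
    component-1 contribution (the axis along which high titers cluster);
    overlay gives each record's first two coordinates plus its titer
    quartile bin for plotting.
    """
    if dec.n_components < 2:
        raise ValueError("decomposition needs >= 2 components for a factor report")
    contrib = dec.contributions[["comp1", "comp2"]]
    ranking = contrib.sort_values(["comp2", "comp1"], ascending=False).reset_index()
    ranking.columns = ["feature", "contribution_comp1", "contribution_comp2"]
    ranking.insert(1, "rank", np.arange(1, len(ranking) + 1))

    titers = pd.Series(titers).reindex(dec.row_coordinates.index)
    overlay = pd.DataFrame({
        "comp1": dec.row_coordinates["comp1"],
        "comp2": dec.row_coordinates["comp2"],
        "titer": titers,
        "titer_bin": discretize_quartiles(titers),
    })
    return ranking, overlay
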