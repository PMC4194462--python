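"""Multivariate comparison of many networks.

The characterization rows of g networks form a g x t matrix (t = 8 graph
variables).  Columns are z-scored and a PCA of the correlation matrix
summarises the networks in a low-dimensional component space; K-means over
the retained component scores groups similar networks, with the number of
clusters chosen from the Bayesian Information Criterion curve

    BIC(k) = n ln(W_k / n) + k ln(n)

(W_k: total within-cluster sum of squares) by the elbow heuristic (largest
second difference), with plain BIC minimisation available as an
alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NetworkPCA",
    "KMeansBIC",
    "PCAResult",
    "ClusteringResult",
    "pca",
    "kmeans_bic",
    "cross_tab",
    "variable_size_correlation",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    explained_variance_pct: np.ndarray
    scores: pd.DataFrame               # networks x components
    variable_correlations: pd.DataFrame  # variables x components (correlation circle)
    column_means: pd.Series
    column_sds: pd.Series


@dataclass
class ClusteringResult:
    bic: pd.Series          # indexed by k = 1..k_max
    chosen_k: int
    chosen_k_min_bic: int
    assignments: np.ndarray  # cluster ids in 1..k
    seed: int | None
    n_starts: int


class NetworkPCA(TransformerMixin, BaseEstimator):
    """PCA of a characterization matrix on the correlation scale.

    Columns are standardized (sample sd) before the eigendecomposition, so
    variables with incommensurate scales contribute equally.  Zero-variance
    columns are dropped with a warning.

    Attributes (after fit): ``eigenvalues_``, ``explained_variance_pct_``,
    ``components_`` (eigenvectors, columns = components),
    ``variable_correlations_`` (correlation circle), ``mean_``, ``scale_``,
    ``feature_names_in_``.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, y=None):
        T = pd.DataFrame(X).copy()
        if T.isna().any().any():
            raise ValueError("characterization matrix has missing cells")
        if T.shape[0] < 3:
            raise ValueError("PCA needs at least 3 networks")
        if self.standardize:
            sds = T.std(axis=0, ddof=1)
            dead = sds.index[(sds == 0) | sds.isna()]
            if len(dead):
                warnings.warn(f"dropping zero-variance columns: {list(dead)}")
                T = T.drop(columns=dead)
                sds = sds.drop(dead)
            self.mean_ = T.mean(axis=0)
            self.scale_ = sds
        else:
            self.mean_ = T.mean(axis=0)
            self.scale_ = pd.Series(1.0, index=T.columns)
        Z = (T - self.mean_) / self.scale_
        corr = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
        corr = np.atleast_2d(corr)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # deterministic sign: largest-magnitude loading positive
        for j in range(evecs.shape[1]):
            i = int(np.argmax(np.abs(evecs[:, j])))
            if evecs[i, j] < 0:
                evecs[:, j] = -evecs[:, j]
        self.feature_names_in_ = np.asarray(T.columns)
        self.eigenvalues_ = evals
        self.explained_variance_pct_ = 100.0 * evals / evals.sum()
        self.components_ = evecs
        with np.errstate(invalid="ignore"):
            corr_circle = evecs * np.sqrt(evals)
        self.variable_correlations_ = pd.DataFrame(
            np.clip(corr_circle, -1.0, 1.0), index=T.columns,
            columns=[f"PC{j + 1}" for j in range(len(evals))])
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        T = pd.DataFrame(X)[self.feature_names_in_]
        Z = (T - self.mean_) / self.scale_
        scores = Z.to_numpy() @ self.components_
        return pd.DataFrame(scores, index=T.index,
                            columns=[f"PC{j + 1}" for j in range(scores.shape[1])])


class KMeansBIC(ClusterMixin, BaseEstimator):
    """Seeded best-of-n-starts K-means over k = 1..k_max with BIC selection.

    ``selection="elbow"`` picks the k with the largest positive second
    difference of the BIC curve; ``selection="min"`` picks the BIC minimum.

    Attributes (after fit): ``bic_`` (Series over k), ``k_``, ``k_min_bic_``,
    ``labels_`` (1-based cluster ids for the chosen k).
    """

    def __init__(self, k_max: int = 10, n_starts: int = 100,
                 selection: str = "elbow", random_state: int | None = None):
        self.k_max = k_max
        self.n_starts = n_starts
        self.selection = selection
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(pd.DataFrame(X), dtype=float)
        n = X.shape[0]
        if self.k_max >= n:
            raise ValueError("k_max must be smaller than the number of networks")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        rng = np.random.default_rng(self.random_state)
        bic = {}
        labels = {}
        for k in range(1, self.k_max + 1):
            if k == 1:
                W = float(((X - X.mean(axis=0)) ** 2).sum())
                labels[k] = np.zeros(n, dtype=int)
            else:
                km = KMeans(n_clusters=k, n_init=self.n_starts,
                            random_state=int(rng.integers(2 ** 31)))
                labels[k] = km.fit_predict(X)
                W = float(km.inertia_)
            W = max(W, np.finfo(float).tiny)
            bic[k] = n * np.log(W / n) + k * np.log(n)
        self.bic_ = pd.Series(bic, name="BIC")
        self.k_min_bic_ = int(self.bic_.idxmin())
        self.k_ = self._elbow() if self.selection == "elbow" else self.k_min_bic_
        self.labels_ = labels[self.k_] + 1
        self._all_labels = {k: v + 1 for k, v in labels.items()}
        return self

    def _elbow(self) -> int:
        b = self.bic_.to_numpy()
        if len(b) < 3:
            return self.k_min_bic_
        second = b[:-2] - 2 * b[1:-1] + b[2:]  # indexed by k = 2..k_max-1
        return int(np.argmax(second) + 2)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def pca(T: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """Functional wrapper over :class:`NetworkPCA`."""
    est = NetworkPCA(standardize=standardize).fit(T)
    return PCAResult(
        eigenvalues=est.eigenvalues_,
        explained_variance_pct=est.explained_variance_pct_,
        scores=est.transform(T),
        variable_correlations=est.variable_correlations_,
        column_means=est.mean_,
        column_sds=est.scale_,
    )


def kmeans_bic(scores: pd.DataFrame, k_max: int, n_starts: int = 100,
               seed: int | None = None, selection: str = "elbow") -> ClusteringResult:
    """Functional wrapper over :class:`KMeansBIC`."""
    est = KMeansBIC(k_max=k_max, n_starts=n_starts, selection=selection,
                    random_state=seed).fit(scores)
    return ClusteringResult(bic=est.bic_, chosen_k=est.k_,
                            chosen_k_min_bic=est.k_min_bic_,
                            assignments=est.labels_, seed=seed,
                            n_starts=n_starts)


def cross_tab(assignments, groups) -> pd.DataFrame:
    """Cluster x group contingency table."""
    a = pd.Series(list(assignments), name="cluster")
    g = pd.Series(list(groups), name="group")
    if len(a) != len(g):
        raise ValueError("assignments and groups differ in length")
    return pd.crosstab(a, g)


def variable_size_correlation(T: pd.DataFrame, sizes) -> pd.Series:
    """Pearson correlation of each characterization variable with network size."""
    s = np.asarray(sizes, dtype=float)
    if len(s) != len(T):
        raise ValueError("sizes length does not match matrix rows")
    out = {}
    for col in T.columns:
        x = T[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(s) == 0:
            warnings.warn(f"zero variance for {col!r}; correlation set to 0")
            out[col] = 0.0
        else:
            out[col] = float(np.corrcoef(x, s)[0, 1])
    return pd.Series(out, name="size_correlation")
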