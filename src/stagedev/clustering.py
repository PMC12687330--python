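"""Soft clustering of developmental expression profiles.

Gene profiles over the embryonic stage axis are standardized to z-scores
(per-gene mean 0, sd 1) and clustered with fuzzy c-means, which assigns each
gene a graded membership in [0, 1] to every cluster (rows summing to 1).
Genes are attached to a cluster for reporting/enrichment only when their
membership reaches a threshold (0.7 by default, inclusive), which makes the
procedure robust to noisy profiles without discarding them from the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


@dataclass
class FuzzyClustering:
    """Gene x cluster membership matrix plus centroids over the stage axis."""

    membership: pd.DataFrame
    centroids: pd.DataFrame
    m: float
    n_iter: int
    converged: bool
    objective_history: list[float]


def standardize(expr: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-score rows (mean 0, sd 1); zero-variance rows are dropped.

    Returns the standardized matrix and the list of excluded (constant) genes.
    The sd uses ``ddof=1`` (sample sd), the convention of the R tooling this
    mirrors.
    """
    if expr.shape[1] < 2:
        raise ValueError("standardization needs at least 2 stages")
    x = expr.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    keep = sd[:, 0] > 0
    excluded = list(expr.index[~keep])
    z = (x[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns), excluded


def select_fuzzifier(n_genes: int, n_stages: int,
                     clamp: tuple[float, float] = (1.05, 4.0)) -> float:
    """Data-driven fuzzifier m for expression profiles.

    Uses the dimensionality-based estimate of Schwaemmle & Jensen (2010),

        m = 1 + (1418/N + 22.05) D^-2
              + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134),

    with N genes and D stages, clamped to ``clamp``.  Always > 1.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    n, d = float(n_genes), float(n_stages)
    m = 1.0 + (1418.0 / n + 22.05) * d ** -2.0 \
        + (12.33 / n + 0.243) * d ** (-0.0406 * math.log(n) - 0.1134)
    return float(min(max(m, clamp[0]), clamp[1]))


class FuzzyCMeans(BaseEstimator):
    """Fuzzy c-means soft clustering (Bezdek alternating optimization).

    Minimizes  sum_ij u_ij^m ||x_i - c_j||^2  subject to each membership row
    summing to 1, by alternating centroid and membership updates:

        c_j = sum_i u_ij^m x_i / sum_i u_ij^m
        u_ij = 1 / sum_k (d_ij / d_ik)^(2 / (m - 1))

    A point coinciding with a centroid receives membership 1 there.
    Memberships are initialized uniformly at random (rows normalized) from a
    seeded generator, so identical seeds give identical clusterings.

    Parameters
    ----------
    n_clusters : int
        Number of clusters c (>= 1).
    m : float
        Fuzzifier, > 1.  Larger m gives softer memberships.
    tol : float
        Convergence threshold on max |delta u| between iterations.
    max_iter : int
        Iteration cap.
    random_state : int
        Seed for the membership initialization.
    """

    def __init__(self, n_clusters: int = 2, m: float = 1.25, tol: float = 1e-6,
                 max_iter: int = 1000, random_state: int = 0):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, _ = x.shape
        c = self.n_clusters
        if c < 1:
            raise ValueError("n_clusters must be >= 1")
        if c > n:
            raise ValueError(f"n_clusters={c} exceeds number of rows {n}")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        rng = np.random.default_rng(self.random_state)
        if c == 1:
            u = np.ones((n, 1))
            centers = (x.mean(axis=0, keepdims=True))
            d2 = ((x - centers) ** 2).sum(axis=1, keepdims=True)
            self.membership_ = u
            self.cluster_centers_ = centers
            self.n_iter_ = 0
            self.converged_ = True
            self.objective_history_ = [float(d2.sum())]
            return self
        u = rng.uniform(size=(n, c))
        u /= u.sum(axis=1, keepdims=True)
        history: list[float] = []
        converged = False
        n_iter = 0
        centers = np.zeros((c, x.shape[1]))
        for n_iter in range(1, self.max_iter + 1):
            um = u ** self.m
            centers = (um.T @ x) / um.sum(axis=0)[:, None]
            # squared distances genes x clusters
            d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            u_new = np.empty_like(u)
            zero = d2 <= 1e-300
            any_zero = zero.any(axis=1)
            with np.errstate(divide="ignore", over="ignore"):
                inv = d2 ** (-1.0 / (self.m - 1.0))
            u_new[~any_zero] = inv[~any_zero] / inv[~any_zero].sum(axis=1, keepdims=True)
            if any_zero.any():
                u_new[any_zero] = 0.0
                first_zero = zero.argmax(axis=1)
                u_new[any_zero, first_zero[any_zero]] = 1.0
            history.append(float(((u_new ** self.m) * d2).sum()))
            delta = np.abs(u_new - u).max()
            u = u_new
            if delta < self.tol:
                converged = True
                break
        self.membership_ = u
        self.cluster_centers_ = centers
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.objective_history_ = history
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).membership_.argmax(axis=1)

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        d2 = ((x[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def fuzzy_cmeans(z_matrix: pd.DataFrame, c: int, m: float | None = None,
                 tol: float = 1e-6, max_iter: int = 1000,
                 seed: int = 0) -> FuzzyClustering:
    """Cluster standardized profiles; functional wrapper over :class:`FuzzyCMeans`."""
    if m is None:
        m = select_fuzzifier(z_matrix.shape[0], z_matrix.shape[1])
    est = FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter,
                      random_state=seed).fit(z_matrix.to_numpy(dtype=float))
    clusters = [f"cluster{j}" for j in range(c)]
    return FuzzyClustering(
        membership=pd.DataFrame(est.membership_, index=z_matrix.index,
                                columns=clusters),
        centroids=pd.DataFrame(est.cluster_centers_, index=clusters,
                               columns=z_matrix.columns),
        m=m,
        n_iter=est.n_iter_,
        converged=est.converged_,
        objective_history=est.objective_history_,
    )


def filter_by_membership(clustering: FuzzyClustering,
                         threshold: float = 0.7) -> dict[str, list[str]]:
    """Per-cluster gene lists at membership >= threshold (inclusive).

    With any threshold > 0.5 the lists are pairwise disjoint because
    membership rows sum to 1.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    u = clustering.membership
    return {
        cl: list(u.index[u[cl] >= threshold]) for cl in u.columns
    }
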