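"""Spatial PCA on haplogroup frequencies with global/local permutation tests.

Ordinary PCA maximizes the variance of scores; spatial PCA maximizes the
product of variance and spatial autocorrelation (Moran's I) over a
connection network, so positive eigenvalues capture global (cline-like)
structure and negative ones local (neighbor-contrast) structure.

With centered frequency matrix X (populations x haplogroups) and
symmetrized weights Omega = (W + W')/2, the axes are eigenvectors of
C = X' Omega X / sum(W); each eigenvalue equals var(score) x I(score)
exactly, which is the defining identity checked in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial import QhullError

from .amova import geographic_distance
from .core import FrequencyTable, PopulationMeta


@dataclass
class SpatialWeights:
    labels: list[str]
    W: np.ndarray
    scheme: str
    row_standardized: bool = False

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if (W < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.allclose(np.diag(W), 0):
            raise ValueError("weight diagonal must be zero")
        self.W = W

    def row_standardize(self) -> "SpatialWeights":
        W = self.W.copy()
        sums = W.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        W[nz] = W[nz] / sums[nz]
        return SpatialWeights(self.labels, W, self.scheme, True)

    def symmetric(self) -> np.ndarray:
        return (self.W + self.W.T) / 2.0


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray          # signed, sorted descending
    scores: np.ndarray               # populations x axes
    loadings: np.ndarray             # haplogroups x axes
    axis_variance: np.ndarray
    axis_morans_i: np.ndarray
    population_labels: list[str]
    haplogroup_labels: list[str]


def build_weights(metas: Sequence[PopulationMeta], scheme: str = "delaunay",
                  k: int = 3, power: float = 1.0) -> SpatialWeights:
    """Connection network from great-circle geography.

    ``delaunay`` (default) triangulates the (lon, lat) plane; ``knn`` links
    each population to its k nearest neighbors (symmetrized); and
    ``inverse_distance`` weights every pair by 1/d^power.
    """
    labels = [m.population_id for m in metas]
    coords = np.array([[m.longitude, m.latitude] for m in metas])
    n = len(metas)
    seen: dict[tuple, str] = {}
    for m in metas:
        key = (round(m.longitude, 9), round(m.latitude, 9))
        if key in seen:
            raise ValueError(
                f"duplicate coordinates for {seen[key]} and {m.population_id}")
        seen[key] = m.population_id
    W = np.zeros((n, n))
    if scheme == "delaunay":
        if n < 3:
            warnings.warn("fewer than 3 populations: falling back to the "
                          "complete graph")
            W = 1.0 - np.eye(n)
            return SpatialWeights(labels, W, "complete")
        try:
            tri = Delaunay(coords)
        except QhullError:
            # (near-)collinear sites: joggle into general position
            tri = Delaunay(coords, qhull_options="QJ")
        for simplex in tri.simplices:
            for i in range(3):
                a, b = simplex[i], simplex[(i + 1) % 3]
                W[a, b] = W[b, a] = 1.0
    elif scheme == "knn":
        tree = cKDTree(coords)
        _, idx = tree.query(coords, k=min(k + 1, n))
        for i in range(n):
            for j in np.atleast_1d(idx[i])[1:]:
                W[i, j] = W[j, i] = 1.0
    elif scheme == "inverse_distance":
        for i in range(n):
            for j in range(i + 1, n):
                d = geographic_distance(metas[i], metas[j])
                W[i, j] = W[j, i] = 1.0 / d ** power
    elif scheme == "complete":
        W = 1.0 - np.eye(n)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return SpatialWeights(labels, W, scheme)


def morans_i(x: Sequence[float], weights: SpatialWeights) -> float:
    """Moran's I = (n / sum W) * (xc' W xc) / (xc' xc), xc centered."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("constant vector: Moran's I undefined")
    W = weights.W
    return float(len(x) / W.sum() * (xc @ W @ xc) / denom)


def spca(table: FrequencyTable, weights: SpatialWeights,
         n_axes: int | None = None, scale: bool = False) -> SpcaResult:
    """Spatial principal components of population haplogroup frequencies.

    Columns of the frequency matrix are centered (optionally scaled); the
    eigenvalues of X' Omega X / sum(W) are signed, sorted descending, and
    each equals variance x Moran's I of its score.  Axis signs are fixed by
    making the largest-|loading| haplogroup positive.
    """
    if table.counts.shape[0] < 3:
        raise ValueError("sPCA needs >= 3 populations")
    if table.populations != weights.labels:
        raise ValueError("table rows and weight labels must match in order")
    X = table.frequencies().to_numpy()
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        X[:, keep] = X[:, keep] / sd[keep]
    if not np.any(np.abs(X) > 1e-12):
        n_hg = X.shape[1]
        k = n_axes or min(X.shape)
        zeros = np.zeros(k)
        return SpcaResult(zeros, np.zeros((X.shape[0], k)),
                          np.zeros((n_hg, k)), zeros.copy(), zeros.copy(),
                          table.populations, table.haplogroups)
    omega = weights.symmetric()
    wsum = weights.W.sum()
    C = X.T @ omega @ X / wsum
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if n_axes is not None:
        evals, evecs = evals[:n_axes], evecs[:, :n_axes]
    # reproducible axis signs
    for a in range(evecs.shape[1]):
        lead = np.argmax(np.abs(evecs[:, a]))
        if evecs[lead, a] < 0:
            evecs[:, a] = -evecs[:, a]
    scores = X @ evecs
    n = X.shape[0]
    variances = scores.var(axis=0, ddof=0)
    morans = np.array([
        morans_i(scores[:, a], SpatialWeights(weights.labels, omega,
                                              "symmetrized"))
        if variances[a] > 1e-15 else 0.0
        for a in range(scores.shape[1])
    ])
    return SpcaResult(evals, scores, evecs, variances, morans,
                      table.populations, table.haplogroups)


def _moran_eigenbasis(weights: SpatialWeights):
    """Eigenvectors of the doubly centered symmetrized weight matrix and
    their Moran values."""
    omega = weights.symmetric()
    n = omega.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    M = H @ omega @ H
    _, U = np.linalg.eigh(M)
    sym = SpatialWeights(weights.labels, omega, "symmetrized")
    morans = np.full(U.shape[1], np.nan)
    for k in range(U.shape[1]):
        u = U[:, k]
        if np.std(u) > 1e-12:
            morans[k] = morans_i(u, sym)
    return U, morans


def _gl_statistic(Xs: np.ndarray, U: np.ndarray, sel: np.ndarray) -> float:
    """Mean over variables of the squared projections onto the selected
    Moran eigenvectors (columns of Xs unit-normalized)."""
    stat = 0.0
    p = Xs.shape[1]
    for j in range(p):
        x = Xs[:, j]
        norm = np.linalg.norm(x)
        if norm == 0:
            continue
        proj = U[:, sel].T @ (x / norm)
        stat += float(proj @ proj)
    return stat / p


def spca_global_local_test(table: FrequencyTable, weights: SpatialWeights,
                           side: str = "global", n_perm: int = 999,
                           seed: int = 0) -> tuple[float, float]:
    """Permutation test for global (positive-Moran) or local
    (negative-Moran) spatial structure in the frequency table.

    The statistic sums, over Moran-eigenvector components of the requested
    sign and over variables, the squared projections of the centered,
    scaled data (averaged over variables); the null redistributes
    population rows over coordinates.  p = (1 + #{perm >= obs})/(n_perm+1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if side not in {"global", "local"}:
        raise ValueError("side must be 'global' or 'local'")
    X = table.frequencies().to_numpy()
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    U, morans = _moran_eigenbasis(weights)
    sel = (morans > 0) if side == "global" else (morans < 0)
    sel &= ~np.isnan(morans)
    if not sel.any():
        raise ValueError(f"no {side} Moran eigenvectors for this network")
    obs = _gl_statistic(X, U, sel)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        if _gl_statistic(X[perm], U, sel) >= obs - 1e-12:
            hits += 1
    return obs, (1 + hits) / (n_perm + 1)
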