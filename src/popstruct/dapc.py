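"""Gaussian-mixture cluster detection and DAPC membership probabilities.

Two steps mirror the admixture-like barplot workflow: populations embedded
in principal coordinates of a genetic distance matrix are clustered with
Gaussian mixture models selected by BIC, and discriminant analysis of
principal components (DAPC) then yields, for every population, a posterior
probability of membership in each cluster.  Intermediate (admixed)
populations show split memberships; well-differentiated ones are assigned
almost entirely to a single cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.mixture import GaussianMixture

from .amova import DistanceMatrix

#: covariance families tried during mixture selection
MIXTURE_MODELS = ("spherical", "diag", "full")


def pcoa_embedding(dist: DistanceMatrix, n_dims: int = 3) -> np.ndarray:
    """Principal-coordinate (classical MDS) embedding of a distance matrix."""
    from skbio.stats.ordination import pcoa as _pcoa
    from skbio import DistanceMatrix as _SkbioDM

    res = _pcoa(_SkbioDM(dist.values, ids=dist.labels), method="eigh",
                number_of_dimensions=min(n_dims, len(dist.labels) - 1))
    return res.samples.to_numpy()


def gaussian_mixture_bic(points: np.ndarray, k_range: Sequence[int] = (1, 2, 3, 4),
                         model_set: Sequence[str] = MIXTURE_MODELS,
                         seed: int = 0) -> tuple[int, np.ndarray]:
    """Fit Gaussian mixtures over k and covariance families; pick by BIC.

    Returns the best k and the hard assignment of each point.  The full
    covariance model is skipped with a warning when n <= d.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    best = None
    for cov in model_set:
        if cov == "full" and n <= d:
            warnings.warn("n <= d: skipping full-covariance mixtures")
            continue
        for k in k_range:
            if k > n:
                continue
            gm = GaussianMixture(n_components=k, covariance_type=cov,
                                 n_init=5, random_state=seed,
                                 reg_covar=1e-6)
            try:
                gm.fit(points)
            except ValueError:
                continue
            bic = gm.bic(points)
            if best is None or bic < best[0]:
                best = (bic, k, gm)
    if best is None:
        raise ValueError("no mixture model could be fitted")
    _, k, gm = best
    return k, gm.predict(points)


@dataclass
class DapcModel:
    n_pcs_retained: int
    group_labels: list[str]
    group_means: np.ndarray          # groups x discriminant axes
    pooled_variances: np.ndarray     # per-axis pooled within-group variance
    _feature_mean: np.ndarray
    _feature_scale: np.ndarray
    _pca_components: np.ndarray      # n_pcs x n_features
    _lda_scalings: np.ndarray        # n_pcs x n_axes
    _lda_xbar: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.group_means.shape[1]

    def transform(self, features: np.ndarray) -> np.ndarray:
        X = (np.asarray(features, dtype=float) - self._feature_mean)
        X = X / self._feature_scale
        pcs = X @ self._pca_components.T
        return (pcs - self._lda_xbar) @ self._lda_scalings


def default_n_pcs(features: np.ndarray, threshold: float = 0.9) -> int:
    """Smallest PC count explaining >= 90% variance, capped at n/3."""
    X = np.asarray(features, dtype=float)
    X = X - X.mean(axis=0)
    n = X.shape[0]
    pca = PCA()
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, threshold) + 1)
    return max(1, min(k, max(1, n // 3)))


def dapc_fit(features: np.ndarray, groups: Sequence[str],
             n_pcs: int | None = None, scale: bool = True) -> DapcModel:
    """Center/scale, retain principal components, then find linear
    discriminant axes maximizing between/within group variance.

    A singular within-group scatter is ridge-regularized by the LDA
    shrinkage path; groups of size 1 in multi-group designs trigger a
    warning (their within-group variance is undefined).
    """
    X = np.asarray(features, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("DAPC needs >= 2 groups")
    sizes = {g: int((groups == g).sum()) for g in labels}
    if len(labels) > 2 and min(sizes.values()) == 1:
        warnings.warn(f"groups of size 1 in design: "
                      f"{[g for g, s in sizes.items() if s == 1]}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0) if scale else np.ones(X.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd
    rank = np.linalg.matrix_rank(Xs)
    if n_pcs is None:
        n_pcs = default_n_pcs(Xs)
    if not 1 <= n_pcs <= rank:
        raise ValueError(f"n_pcs must be in [1, rank={rank}]")
    pca = PCA(n_components=n_pcs)
    pcs = pca.fit_transform(Xs)
    n_axes = min(len(labels) - 1, n_pcs)
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=None,
                                     n_components=n_axes)
    try:
        lda.fit(pcs, groups)
    except np.linalg.LinAlgError:
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-6,
                                         n_components=n_axes)
        lda.fit(pcs, groups)
    scalings = lda.scalings_[:, :n_axes]
    xbar = pcs.mean(axis=0)
    da = (pcs - xbar) @ scalings
    means = np.vstack([da[groups == g].mean(axis=0) for g in labels])
    resid = da - means[[labels.index(g) for g in groups]]
    dof = max(1, len(groups) - len(labels))
    pooled = (resid ** 2).sum(axis=0) / dof
    pooled = np.where(pooled > 1e-12, pooled, 1e-12)
    return DapcModel(
        n_pcs_retained=n_pcs,
        group_labels=labels,
        group_means=means,
        pooled_variances=pooled,
        _feature_mean=mean,
        _feature_scale=sd,
        _pca_components=pca.components_,
        _lda_scalings=scalings,
        _lda_xbar=xbar,
    )


def dapc_membership(model: DapcModel, features: np.ndarray,
                    row_labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Posterior membership probabilities (equal priors, pooled
    per-axis Gaussian densities in discriminant space); rows sum to 1."""
    da = model.transform(features)
    log_dens = np.empty((da.shape[0], len(model.group_labels)))
    for g, mu in enumerate(model.group_means):
        z2 = ((da - mu) ** 2 / model.pooled_variances).sum(axis=1)
        log_dens[:, g] = -0.5 * z2
    log_post = log_dens - logsumexp(log_dens, axis=1, keepdims=True)
    post = np.exp(log_post)
    return pd.DataFrame(post, columns=model.group_labels, index=row_labels)


def save_membership_barplot(membership: pd.DataFrame, path: str) -> None:
    """Minimal stacked-bar export of a membership table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = membership.plot(kind="bar", stacked=True, width=0.9,
                         colormap="Greys", edgecolor="black", figsize=(8, 3))
    ax.set_ylabel("membership probability")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
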