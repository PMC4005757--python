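"""mY admixture-coefficient estimation with bootstrap dispersion.

A hybrid population is modeled as a mixture of k parental populations.  The
molecular (mY-style) moment estimator writes the mean pairwise molecular
diversity between the hybrid and each parental as a linear combination of
parental-parental diversities:

    J(h, P_j) = sum_i m_i * J(P_i, P_j),      sum_i m_i = 1,

with J(x, y) = x' D y for frequency vectors x, y and a between-haplogroup
distance matrix D.  The coefficients solve this system by least squares
under the sum-to-one constraint.  The default distance mode is the identity
(0/1) matrix, i.e. pure haplogroup-frequency information; a molecular D can
be supplied.  Weights are not clamped: values outside [0, 1] are reported
raw and flagged, because clamping hides model misfit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

CONDITION_LIMIT = 1e10


class IllConditionedError(ValueError):
    def __init__(self, cond: float):
        super().__init__(
            f"parental diversity system is ill-conditioned "
            f"(condition number {cond:.3g}); parental profiles are too "
            f"similar for stable admixture estimation")
        self.condition_number = cond


@dataclass(frozen=True)
class AdmixtureResult:
    parental_labels: tuple[str, ...]
    weights: np.ndarray
    bootstrap_sd: np.ndarray | None
    bootstrap_mean: np.ndarray | None
    n_bootstrap: int
    distance_mode: str
    out_of_range: bool

    def __post_init__(self):
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise AssertionError("weights must sum to 1")


def _frequencies(counts: Sequence[float]) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    tot = v.sum()
    if tot <= 0:
        raise ValueError("empty count vector")
    return v / tot


def my_estimate(hybrid: Sequence[float], parentals: Sequence[Sequence[float]],
                hg_distance: np.ndarray | None = None,
                labels: Sequence[str] | None = None) -> AdmixtureResult:
    """Point estimate of parental contributions to a hybrid population.

    ``hybrid`` and each parental are haplogroup count (or frequency)
    vectors over a shared label set; ``hg_distance`` is an optional
    symmetric between-haplogroup distance matrix (identity 0/1 mismatch by
    default).
    """
    P = np.vstack([_frequencies(p) for p in parentals])
    k, n_hg = P.shape
    if k < 2:
        raise ValueError("need at least 2 parental populations")
    h = _frequencies(hybrid)
    if h.shape[0] != n_hg:
        raise ValueError("hybrid and parentals must share the label set")
    if hg_distance is None:
        D = 1.0 - np.eye(n_hg)
        mode = "identity"
    else:
        D = np.asarray(hg_distance, dtype=float)
        if D.shape != (n_hg, n_hg) or not np.allclose(D, D.T):
            raise ValueError("hg_distance must be a symmetric matrix over "
                             "the haplogroup labels")
        mode = "custom"
    A = P @ D @ P.T                    # parental-parental diversities
    b = P @ D @ h                      # hybrid-parental diversities
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise IllConditionedError(cond)
    # least squares of A m = b under 1'm = 1 (KKT system)
    G = A.T @ A
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * G
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * A.T @ b, [1.0]])
    sol = np.linalg.solve(kkt, rhs)
    m = sol[:k]
    m = m + (1.0 - m.sum()) / k        # absorb residual rounding
    out_of_range = bool((m < -1e-9).any() or (m > 1 + 1e-9).any())
    if out_of_range:
        warnings.warn("admixture weights outside [0, 1]; reported raw")
    return AdmixtureResult(
        parental_labels=tuple(labels) if labels is not None
        else tuple(f"parental_{i}" for i in range(k)),
        weights=m,
        bootstrap_sd=None,
        bootstrap_mean=None,
        n_bootstrap=0,
        distance_mode=mode,
        out_of_range=out_of_range,
    )


def _counts_from_haplogroups(calls: Sequence[str],
                             label_order: Sequence[str]) -> np.ndarray:
    idx = {hg: i for i, hg in enumerate(label_order)}
    out = np.zeros(len(label_order))
    for c in calls:
        out[idx[c]] += 1
    return out


def my_bootstrap(hybrid_calls: Sequence[str],
                 parental_calls: Sequence[Sequence[str]],
                 n_boot: int = 10_000, seed: int = 0,
                 parental_subsample: int | None = 50,
                 hg_distance: np.ndarray | None = None,
                 labels: Sequence[str] | None = None) -> AdmixtureResult:
    """Bootstrap the mY estimate over individuals.

    Each replicate resamples individuals with replacement within every
    population; parental groups are optionally first subsampled to a fixed
    size (default 50) to equalize sampling variance across sources.
    Reports the full-data point estimate plus bootstrap mean and SD.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap SDs")
    label_order = sorted(
        set(hybrid_calls).union(*[set(p) for p in parental_calls]))
    hybrid_counts = _counts_from_haplogroups(hybrid_calls, label_order)
    parental_counts = [
        _counts_from_haplogroups(p, label_order) for p in parental_calls]
    point = my_estimate(hybrid_counts, parental_counts,
                        hg_distance=hg_distance, labels=labels)
    rng = np.random.default_rng(seed)
    hybrid_arr = np.asarray(hybrid_calls)
    parental_arrs = [np.asarray(p) for p in parental_calls]
    draws = []
    for _ in range(n_boot):
        hb = rng.choice(hybrid_arr, size=len(hybrid_arr), replace=True)
        pbs = []
        for arr in parental_arrs:
            pool = arr
            if parental_subsample is not None and len(arr) > parental_subsample:
                pool = rng.choice(arr, size=parental_subsample, replace=False)
            pbs.append(rng.choice(pool, size=len(pool), replace=True))
        try:
            rep = my_estimate(
                _counts_from_haplogroups(hb, label_order),
                [_counts_from_haplogroups(p, label_order) for p in pbs],
                hg_distance=hg_distance, labels=labels)
        except IllConditionedError:
            continue
        draws.append(rep.weights)
    draws = np.array(draws)
    return AdmixtureResult(
        parental_labels=point.parental_labels,
        weights=point.weights,
        bootstrap_sd=draws.std(axis=0, ddof=1) if len(draws) > 1 else
        np.zeros_like(point.weights),
        bootstrap_mean=draws.mean(axis=0) if len(draws) else point.weights,
        n_bootstrap=len(draws),
        distance_mode=point.distance_mode,
        out_of_range=point.out_of_range,
    )
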