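"""Distance matrices, hierarchical AMOVA with permutation tests, Mantel.

The analysis of molecular variance decomposes the total sum of squared
inter-individual molecular distances into hierarchical components (among
groups, among populations within groups, within populations) and expresses
them as Phi-statistics (Phi_ST, Phi_SC, Phi_CT).  Significance comes from
permutation: individuals among populations for Phi_ST, individuals among
populations within groups for Phi_SC, whole populations among groups for
Phi_CT.

Squared-distance conventions per marker type:

* haplogroup calls — 0/1 mismatch ("frequencies only" AMOVA);
* HVS variant sets — number of pairwise token differences;
* STR profiles — sum over loci of squared repeat-count differences
  (the Rst-style metric).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import IndividualRecord, PopulationMeta

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric labeled distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "custom"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str = "custom") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


@dataclass(frozen=True)
class AmovaResult:
    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    pct_among_groups: float
    pct_among_pops: float
    pct_within: float
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    p_phi_st: float | None
    p_phi_sc: float | None
    p_phi_ct: float | None
    n_permutations: int
    negative_component_floored: bool


# ---------------------------------------------------------------------------
# squared molecular distances
# ---------------------------------------------------------------------------

def _pair_d2(a: IndividualRecord, b: IndividualRecord, kind: str) -> float:
    if kind == "haplogroup":
        ha = a.y_haplogroup or a.mt_haplogroup
        hb = b.y_haplogroup or b.mt_haplogroup
        return 0.0 if ha == hb else 1.0
    if kind == "hvs":
        return float(len(a.hvs_variants ^ b.hvs_variants))
    if kind == "str":
        loci = set(a.str_profile) & set(b.str_profile)
        if not loci:
            raise ValueError("no shared STR loci")
        return float(sum((a.str_profile[l] - b.str_profile[l]) ** 2
                         for l in loci))
    raise ValueError(f"unknown distance kind {kind!r}")


def squared_distance_matrix(records: Sequence[IndividualRecord],
                            kind: str) -> np.ndarray:
    """Individual x individual squared molecular distances."""
    n = len(records)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2[i, j] = d2[j, i] = _pair_d2(records[i], records[j], kind)
    return d2


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _ss_within_sets(d2: np.ndarray, sets: list[np.ndarray]) -> float:
    """sum over sets of (sum of pairwise d2 within set) / set size."""
    total = 0.0
    for idx in sets:
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / 2.0 / len(idx)
    return total


def _amova_components(d2: np.ndarray, pop_codes: np.ndarray,
                      group_codes: np.ndarray | None):
    """Variance components from squared distances (expected-mean-square
    equations of the standard hierarchical decomposition)."""
    n = len(pop_codes)
    pops = np.unique(pop_codes)
    pop_sets = [np.flatnonzero(pop_codes == p) for p in pops]
    sizes = np.array([len(s) for s in pop_sets], dtype=float)
    ss_total = d2.sum() / 2.0 / n
    ss_wp = _ss_within_sets(d2, pop_sets)

    if group_codes is None:
        df_ap, df_wp = len(pops) - 1, n - len(pops)
        if df_ap < 1 or df_wp < 1:
            raise ValueError("need >=2 populations each with >=2 members")
        sigma_c = (ss_wp) / df_wp
        ms_ap = (ss_total - ss_wp) / df_ap
        n_c = (n - np.sum(sizes ** 2) / n) / df_ap
        sigma_b = (ms_ap - sigma_c) / n_c
        return 0.0, sigma_b, sigma_c

    groups = np.unique(group_codes)
    g_of_pop = {}
    for p, s in zip(pops, pop_sets):
        gset = np.unique(group_codes[s])
        if len(gset) != 1:
            raise ValueError(f"population {p} spans multiple groups")
        g_of_pop[p] = gset[0]
    group_sets = [np.flatnonzero(group_codes == g) for g in groups]
    G, P = len(groups), len(pops)
    if G < 2 or P <= G:
        raise ValueError("3-level design needs >=2 groups and more "
                         "populations than groups")
    ss_within_groups = _ss_within_sets(d2, group_sets)
    ss_ag = ss_total - ss_within_groups
    ss_apwg = ss_within_groups - ss_wp
    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    sigma_c = ss_wp / df_wp
    ms_ap = ss_apwg / df_ap
    ms_ag = ss_ag / df_ag
    group_n = np.array([len(s) for s in group_sets], dtype=float)
    sum_np2_by_group = np.array(
        [sum(len(s) ** 2 for p, s in zip(pops, pop_sets)
             if g_of_pop[p] == g) / len(gs)
         for g, gs in zip(groups, group_sets)]
    )
    n1 = (n - sum_np2_by_group.sum()) / df_ap
    n2 = (sum_np2_by_group.sum() - np.sum(sizes ** 2) / n) / df_ag
    n3 = (n - np.sum(group_n ** 2) / n) / df_ag
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def _phi_stats(sigma_a, sigma_b, sigma_c, three_level):
    total = sigma_a + sigma_b + sigma_c
    if total <= 0:
        return 0.0, None, None
    phi_st = (sigma_a + sigma_b) / total
    if not three_level:
        return phi_st, None, None
    phi_ct = sigma_a / total
    denom = sigma_b + sigma_c
    phi_sc = sigma_b / denom if denom > 0 else 0.0
    return phi_st, phi_sc, phi_ct


def amova(d2: np.ndarray, populations: Sequence[str],
          groups: Sequence[str] | None = None, n_perm: int = 10_000,
          seed: int = 0) -> AmovaResult:
    """Hierarchical AMOVA on a squared-distance matrix.

    ``populations`` (and optionally ``groups``) assign each individual (row
    of ``d2``) to the design.  Permutation p-values use the scheme
    appropriate to each Phi statistic; set ``n_perm=0`` to skip them.
    """
    d2 = np.asarray(d2, dtype=float)
    pop_codes = np.asarray(populations)
    singletons = [p for p in np.unique(pop_codes)
                  if (pop_codes == p).sum() < 2]
    if singletons:
        raise ValueError(f"populations of size 1 in design: {singletons}")
    group_codes = np.asarray(groups) if groups is not None else None
    three = group_codes is not None

    sigma_a, sigma_b, sigma_c = _amova_components(d2, pop_codes, group_codes)
    phi_st, phi_sc, phi_ct = _phi_stats(sigma_a, sigma_b, sigma_c, three)

    raw = np.array([sigma_a, sigma_b, sigma_c])
    floored = bool((raw < 0).any())
    nonneg = np.clip(raw, 0.0, None)
    pct = 100.0 * nonneg / nonneg.sum() if nonneg.sum() > 0 else \
        np.array([0.0, 0.0, 100.0])

    p_st = p_sc = p_ct = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        # Phi_ST: permute individuals among populations
        hits_st = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pop_codes))
            a, b, c = _amova_components(d2, pop_codes[perm],
                                        group_codes[perm] if three else None)
            st, _, _ = _phi_stats(a, b, c, three)
            if st >= phi_st - 1e-12:
                hits_st += 1
        p_st = (1 + hits_st) / (n_perm + 1)
        if three:
            pops = np.unique(pop_codes)
            pop_group = {p: group_codes[pop_codes == p][0] for p in pops}
            # Phi_CT: permute whole populations among groups
            hits_ct = 0
            glabels = np.array([pop_group[p] for p in pops])
            for _ in range(n_perm):
                gperm = rng.permutation(glabels)
                new_groups = np.empty(len(pop_codes), dtype=glabels.dtype)
                for p, g in zip(pops, gperm):
                    new_groups[pop_codes == p] = g
                try:
                    a, b, c = _amova_components(d2, pop_codes, new_groups)
                except ValueError:
                    continue
                _, _, ct = _phi_stats(a, b, c, True)
                if ct is not None and ct >= phi_ct - 1e-12:
                    hits_ct += 1
            p_ct = (1 + hits_ct) / (n_perm + 1)
            # Phi_SC: permute individuals among populations within groups
            hits_sc = 0
            group_sets = [np.flatnonzero(group_codes == g)
                          for g in np.unique(group_codes)]
            for _ in range(n_perm):
                new_pops = pop_codes.copy()
                for idx in group_sets:
                    new_pops[idx] = pop_codes[idx][rng.permutation(len(idx))]
                a, b, c = _amova_components(d2, new_pops, group_codes)
                _, sc, _ = _phi_stats(a, b, c, True)
                if sc is not None and sc >= phi_sc - 1e-12:
                    hits_sc += 1
            p_sc = (1 + hits_sc) / (n_perm + 1)

    return AmovaResult(
        sigma_among_groups=float(sigma_a),
        sigma_among_pops=float(sigma_b),
        sigma_within=float(sigma_c),
        pct_among_groups=float(pct[0]),
        pct_among_pops=float(pct[1]),
        pct_within=float(pct[2]),
        phi_st=float(phi_st),
        phi_sc=None if phi_sc is None else float(phi_sc),
        phi_ct=None if phi_ct is None else float(phi_ct),
        p_phi_st=p_st,
        p_phi_sc=p_sc,
        p_phi_ct=p_ct,
        n_permutations=n_perm,
        negative_component_floored=floored,
    )


def molecular_distance(records_a: Sequence[IndividualRecord],
                       records_b: Sequence[IndividualRecord],
                       kind: str) -> float:
    """Pairwise population distance: AMOVA Phi_ST on the pooled individuals.

    ``kind='hvs'`` gives the sequence Phi_ST, ``kind='str'`` the Rst
    analogue, ``kind='haplogroup'`` the frequency (0/1 mismatch) form.
    Negative estimates are truncated to 0.
    """
    if not records_a or not records_b:
        raise ValueError("empty population")
    pooled = list(records_a) + list(records_b)
    pops = ["A"] * len(records_a) + ["B"] * len(records_b)
    d2 = squared_distance_matrix(pooled, kind)
    res = amova(d2, pops, n_perm=0)
    return max(0.0, res.phi_st)


def pairwise_phist_matrix(records: Sequence[IndividualRecord],
                          kind: str) -> DistanceMatrix:
    """Population x population Phi_ST (or Rst-mode) matrix."""
    by_pop: dict[str, list[IndividualRecord]] = {}
    for r in records:
        by_pop.setdefault(r.population_id, []).append(r)
    labels = sorted(by_pop)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = molecular_distance(
                by_pop[labels[i]], by_pop[labels[j]], kind)
    return DistanceMatrix(labels, mat,
                          kind="r_st" if kind == "str" else "phi_st")


# ---------------------------------------------------------------------------
# Reynolds / geographic distances
# ---------------------------------------------------------------------------

def reynolds_theta(p: Sequence[float], q: Sequence[float],
                   n1: int, n2: int, corrected: bool = True) -> float:
    """Coancestry estimate theta between two populations, treating the
    haplogroup system as one multi-allelic locus.

    ``corrected`` uses the sample-size-corrected drift (moment) estimator
    (Reynolds/Weir-Cockerham form for haploid counts); otherwise the plain
    sum((p-q)^2)/2 / (1 - sum(p*q)) form.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("frequency vectors must share the label set")
    if not corrected:
        denom = 1.0 - float(np.sum(p * q))
        if denom <= 0:
            return 1.0
        return float(np.sum((p - q) ** 2) / 2.0 / denom)
    n1, n2 = float(n1), float(n2)
    N = n1 + n2
    pbar = (n1 * p + n2 * q) / N
    msb = (n1 * np.sum((p - pbar) ** 2) + n2 * np.sum((q - pbar) ** 2))  # df=1
    msw = (n1 * np.sum(p * (1 - p)) + n2 * np.sum(q * (1 - q))) / (N - 2.0)
    nc = N - (n1 ** 2 + n2 ** 2) / N
    denom = msb + (nc - 1.0) * msw
    if denom <= 0:
        return 0.0
    return float((msb - msw) / denom)


def reynolds_distance(p: Sequence[float], q: Sequence[float],
                      n1: int, n2: int, corrected: bool = True) -> float:
    """Reynolds drift distance D = -ln(1 - theta); theta clamped to [0, 1)."""
    theta = reynolds_theta(p, q, n1, n2, corrected)
    theta = min(max(theta, 0.0), 1.0)
    if theta >= 1.0:
        return float("inf")
    return -math.log(1.0 - theta)


def reynolds_matrix(table, corrected: bool = True) -> DistanceMatrix:
    """Population x population Reynolds distances from a FrequencyTable."""
    freqs = table.frequencies().to_numpy()
    totals = table.row_totals.to_numpy()
    labels = table.populations
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = reynolds_distance(
                freqs[i], freqs[j], totals[i], totals[j], corrected)
    return DistanceMatrix(labels, mat, kind="reynolds")


def geographic_distance(a: PopulationMeta, b: PopulationMeta) -> float:
    """Great-circle distance in km (spherical Earth, R = 6371 km)."""
    la1, lo1, la2, lo2 = map(math.radians,
                             (a.latitude, a.longitude, b.latitude, b.longitude))
    s = (math.sin((la2 - la1) / 2) ** 2
         + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def geographic_matrix(metas: Sequence[PopulationMeta]) -> DistanceMatrix:
    labels = [m.population_id for m in metas]
    n = len(metas)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = geographic_distance(metas[i], metas[j])
    return DistanceMatrix(labels, mat, kind="geographic")


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel(mat1: DistanceMatrix, mat2: DistanceMatrix,
           n_perm: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over upper-triangle entries; p is the
    one-sided (upper) permutation p-value from joint row/column permutations
    of the second matrix, with resolution 1/(n_perm+1).
    """
    if mat1.labels != mat2.labels:
        raise ValueError("matrices must share labels in the same order")
    x = mat1.values
    y = mat2.values
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    xv = x[iu]
    if np.std(xv) == 0 or np.std(y[iu]) == 0:
        raise ValueError("constant distance matrix: r undefined")
    r_obs = float(np.corrcoef(xv, y[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y[np.ix_(perm, perm)][iu]
        if np.std(yp) == 0:
            continue
        if np.corrcoef(xv, yp)[0, 1] >= r_obs - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (n_perm + 1)
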