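"""Distance matrices, hierarchical AMOVA, Mantel correlation."""

import math

import numpy as np
import pytest

from popstruct.amova import (
    DistanceMatrix,
    amova,
    geographic_distance,
    mantel,
    molecular_distance,
    reynolds_distance,
    reynolds_theta,
    squared_distance_matrix,
)
from popstruct.core import IndividualRecord, PopulationMeta
from popstruct.simulate import StarSimSpec, simulate_star_str

from conftest import FOUNDER8, RATES8


def _hg_records(assignments):
    return [IndividualRecord(f"i{k}", pop, y_haplogroup=hg)
            for k, (pop, hg) in enumerate(assignments)]


# ---------------------------------------------------------------------------
# brute-force oracle: direct sum-of-squares decomposition
# ---------------------------------------------------------------------------

def _brute_force_components(d2, pops, groups=None):
    """Independent variance-component computation from explicit SS loops."""
    n = len(pops)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    pop_ids = sorted(set(pops))
    ss_wp = 0.0
    for p in pop_ids:
        idx = [i for i in range(n) if pops[i] == p]
        ss_wp += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    sizes = {p: pops.count(p) for p in pop_ids}
    if groups is None:
        P = len(pop_ids)
        sigma_c = ss_wp / (n - P)
        nc = (n - sum(s ** 2 for s in sizes.values()) / n) / (P - 1)
        sigma_b = ((ss_total - ss_wp) / (P - 1) - sigma_c) / nc
        return 0.0, sigma_b, sigma_c
    group_of = {p: groups[pops.index(p)] for p in pop_ids}
    g_ids = sorted(set(groups))
    G, P = len(g_ids), len(pop_ids)
    ss_wg = 0.0
    for g in g_ids:
        idx = [i for i in range(n) if groups[i] == g]
        ss_wg += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    sigma_c = ss_wp / (n - P)
    sum_np2_by_g = sum(
        sum(sizes[p] ** 2 for p in pop_ids if group_of[p] == g)
        / sum(sizes[p] for p in pop_ids if group_of[p] == g)
        for g in g_ids)
    gsizes = {g: sum(sizes[p] for p in pop_ids if group_of[p] == g)
              for g in g_ids}
    n1 = (n - sum_np2_by_g) / (P - G)
    n2 = (sum_np2_by_g - sum(s ** 2 for s in sizes.values()) / n) / (G - 1)
    n3 = (n - sum(s ** 2 for s in gsizes.values()) / n) / (G - 1)
    sigma_b = ((ss_wg - ss_wp) / (P - G) - sigma_c) / n1
    sigma_a = ((ss_total - ss_wg) / (G - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


class TestAmova:
    def test_components_match_brute_force_two_level(self, rng):
        recs = simulate_star_str(
            StarSimSpec(12, 60.0, FOUNDER8, RATES8, seed=5))
        d2 = squared_distance_matrix(recs, "str")
        pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        res = amova(d2, pops, n_perm=0)
        _, sb, sc = _brute_force_components(d2, pops)
        assert res.sigma_among_pops == pytest.approx(sb, abs=1e-10)
        assert res.sigma_within == pytest.approx(sc, abs=1e-10)

    def test_components_match_brute_force_three_level(self):
        rng = np.random.default_rng(17)
        n = 18
        pops = (["A"] * 4 + ["B"] * 5 + ["C"] * 4 + ["D"] * 5)
        groups = ["G1"] * 9 + ["G2"] * 9
        pts = rng.normal(size=n)
        pts[9:] += 1.5
        d2 = (pts[:, None] - pts[None, :]) ** 2
        res = amova(d2, pops, groups, n_perm=0)
        sa, sb, sc = _brute_force_components(d2, pops, groups)
        assert res.sigma_among_groups == pytest.approx(sa, abs=1e-10)
        assert res.sigma_among_pops == pytest.approx(sb, abs=1e-10)
        assert res.sigma_within == pytest.approx(sc, abs=1e-10)
        total = sa + sb + sc
        assert res.phi_st == pytest.approx((sa + sb) / total, abs=1e-12)
        assert res.phi_ct == pytest.approx(sa / total, abs=1e-12)

    def test_percentages_sum_to_100(self):
        recs = _hg_records([("A", "H1")] * 4 + [("A", "H2")]
                           + [("B", "H2")] * 4 + [("B", "H1")])
        d2 = squared_distance_matrix(recs, "haplogroup")
        res = amova(d2, [r.population_id for r in recs], n_perm=0)
        assert (res.pct_among_groups + res.pct_among_pops
                + res.pct_within) == pytest.approx(100.0)

    def test_fixed_differences_give_phi_st_one(self):
        recs = _hg_records([("A", "H1")] * 14 + [("B", "H2")] * 14)
        d2 = squared_distance_matrix(recs, "haplogroup")
        res = amova(d2, [r.population_id for r in recs], n_perm=99, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_phi_st <= 1 / (99 + 1) + 1e-12

    def test_single_pool_gives_phi_st_near_zero(self, rng):
        # two samples of one panmictic pool: Phi_ST fluctuates around 0
        hgs = ["H1", "H2", "H3"]
        phis = []
        for _ in range(5):
            calls = rng.choice(hgs, size=200, p=[0.5, 0.3, 0.2])
            recs = _hg_records([("A" if k < 100 else "B", hg)
                                for k, hg in enumerate(calls)])
            d2 = squared_distance_matrix(recs, "haplogroup")
            phis.append(amova(d2, [r.population_id for r in recs],
                              n_perm=0).phi_st)
        assert abs(np.mean(phis)) < 0.02

    def test_population_of_size_one_rejected(self):
        recs = _hg_records([("A", "H1"), ("A", "H2"), ("B", "H1")])
        d2 = squared_distance_matrix(recs, "haplogroup")
        with pytest.raises(ValueError, match="B"):
            amova(d2, [r.population_id for r in recs], n_perm=0)

    def test_phi_st_increases_with_divergence(self):
        # island-style check: deeper split -> larger Phi_ST
        phis = []
        for offset in (0, 2, 6):
            a = simulate_star_str(StarSimSpec(
                15, 80.0, FOUNDER8, RATES8, seed=1, population_id="A"))
            b = simulate_star_str(StarSimSpec(
                15, 80.0, {l: v + offset for l, v in FOUNDER8.items()},
                RATES8, seed=2, population_id="B"))
            d2 = squared_distance_matrix(a + b, "str")
            phis.append(amova(d2, ["A"] * 15 + ["B"] * 15, n_perm=0).phi_st)
        assert phis[0] < phis[1] < phis[2]


class TestMolecularDistance:
    def test_identical_populations_zero(self):
        recs = _hg_records([("A", "H1"), ("A", "H2")] * 3)
        assert molecular_distance(recs, recs, "haplogroup") == 0.0

    def test_fixed_single_site_difference_gives_one(self):
        a = [IndividualRecord(f"a{k}", "A",
                              hvs_variants=frozenset({"16224C"}))
             for k in range(4)]
        b = [IndividualRecord(f"b{k}", "B",
                              hvs_variants=frozenset({"16311C"}))
             for k in range(4)]
        assert molecular_distance(a, b, "hvs") == pytest.approx(1.0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            molecular_distance([], _hg_records([("B", "H1")] * 2),
                               "haplogroup")


def _reynolds_oracle(p, q, n1, n2):
    """Independent transcription of the haploid moment estimator."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    N = n1 + n2
    pbar = (n1 * p + n2 * q) / N
    msb = n1 * ((p - pbar) ** 2).sum() + n2 * ((q - pbar) ** 2).sum()
    msw = (n1 * (p * (1 - p)).sum() + n2 * (q * (1 - q)).sum()) / (N - 2)
    nc = N - (n1 ** 2 + n2 ** 2) / N
    theta = (msb - msw) / (msb + (nc - 1) * msw)
    return -math.log(1 - min(max(theta, 0.0), 1 - 1e-15))


class TestReynolds:
    def test_equal_frequencies_give_zero(self):
        p = [0.5, 0.3, 0.2]
        assert reynolds_distance(p, p, 100, 100) == pytest.approx(0.0)

    def test_disjoint_fixed_classes_diverge(self):
        d = reynolds_distance([1, 0], [0, 1], 10_000, 10_000)
        assert d > 5.0

    def test_matches_independent_formula(self):
        p, q = [0.6, 0.3, 0.1], [0.2, 0.5, 0.3]
        assert reynolds_distance(p, q, 100, 100) == pytest.approx(
            _reynolds_oracle(p, q, 100, 100), rel=1e-12)

    def test_uncorrected_variant(self):
        p, q = [0.6, 0.4], [0.4, 0.6]
        theta = reynolds_theta(p, q, 50, 50, corrected=False)
        expected = ((0.2 ** 2) * 2 / 2) / (1 - (0.6 * 0.4 + 0.4 * 0.6))
        assert theta == pytest.approx(expected)


class TestGeographic:
    def _meta(self, lat, lon, pid="X"):
        return PopulationMeta(pid, "G", lat, lon, 10)

    def test_same_point(self):
        m = self._meta(37.5, 14.0)
        assert geographic_distance(m, m) == 0.0

    def test_pole_to_pole(self):
        d = geographic_distance(self._meta(90, 0), self._meta(-90, 0))
        assert d == pytest.approx(math.pi * 6371, rel=1e-9)

    def test_quarter_meridian(self):
        d = geographic_distance(self._meta(0, 0), self._meta(0, 90))
        assert d == pytest.approx(6371 * math.pi / 2, rel=1e-9)


class TestMantel:
    def _random_matrix(self, rng, n=8):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return DistanceMatrix([f"P{i}" for i in range(n)], a)

    def test_affine_relation_gives_r_one_minimal_p(self, rng):
        m1 = self._random_matrix(rng)
        m2 = DistanceMatrix(m1.labels, 2.0 * m1.values)
        r, p = mantel(m1, m2, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_hand_computed_pearson_on_toy(self):
        v1 = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6],
                       [3, 5, 6, 0]], float)
        v2 = np.array([[0, 2, 1, 5], [2, 0, 3, 4], [1, 3, 0, 8],
                       [5, 4, 8, 0]], float)
        labels = list("ABCD")
        r, _ = mantel(DistanceMatrix(labels, v1), DistanceMatrix(labels, v2),
                      n_perm=99, seed=0)
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 5, 3, 4, 8]
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_null_p_values_approximately_uniform(self, rng):
        from scipy import stats
        pvals = [mantel(self._random_matrix(rng), self._random_matrix(rng),
                        n_perm=99, seed=rep)[1] for rep in range(100)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_p_granularity(self, rng):
        m1 = self._random_matrix(rng)
        m2 = self._random_matrix(rng)
        _, p = mantel(m1, m2, n_perm=99, seed=1)
        assert round(p * 100, 9) == int(round(p * 100))

    def test_constant_matrix_rejected(self):
        labels = list("ABC")
        const = DistanceMatrix(labels, np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError):
            mantel(const, const, n_perm=99)
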