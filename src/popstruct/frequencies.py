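"""Haplogroup counting, diversity indices, and enrichment tests.

Haplogroup frequencies are estimated by direct counting.  Gene diversity is
Nei's unbiased estimator H = n/(n-1) * (1 - sum p_i^2) with its standard
sampling variance; haplotype diversity applies the same estimator with the
full multi-locus STR profile (or full HVS variant set) as the haplotype
unit.  Enrichment of single lineages in a focal group of populations is
tested with 2x2 Fisher exact tests, an overall Monte-Carlo r x c exact
test, and Bonferroni-corrected chi-square tests for pairwise group
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import FrequencyTable, IndividualRecord


@dataclass(frozen=True)
class DiversityResult:
    population_id: str
    gene_diversity: float
    gene_diversity_se: float
    n: int
    n_haplotypes: int | None = None
    haplotype_diversity: float | None = None


def count_haplogroups(records: Sequence[IndividualRecord],
                      system: str = "Y") -> tuple[FrequencyTable, int]:
    """Direct-count populations x haplogroups table.

    Records without a call for the requested system ("Y" or "MT") are
    excluded; the second return value is that drop tally.
    """
    if system not in {"Y", "MT"}:
        raise ValueError("system must be 'Y' or 'MT'")
    attr = "y_haplogroup" if system == "Y" else "mt_haplogroup"
    kept = [(r.population_id, getattr(r, attr)) for r in records
            if getattr(r, attr) is not None]
    dropped = len(records) - len(kept)
    if not kept:
        return FrequencyTable(pd.DataFrame(dtype=np.int64)), dropped
    df = pd.DataFrame(kept, columns=["population_id", "haplogroup"])
    table = pd.crosstab(df["population_id"], df["haplogroup"])
    table.index.name = None
    table.columns.name = None
    return FrequencyTable(table), dropped


def gene_diversity(counts: Iterable[int]) -> tuple[float, float]:
    """Nei's unbiased gene diversity and its standard error.

    H = n/(n-1) * (1 - sum p_i^2); the variance is Nei (1987) eq. 8.12.
    """
    counts = np.asarray([c for c in counts if c > 0], dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("gene diversity needs n >= 2")
    p = counts / n
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    h = n / (n - 1.0) * (1.0 - s2)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (s3 - s2 ** 2) + s2 - s2 ** 2
    )
    return h, math.sqrt(max(var, 0.0))


def _haplotype_key(record: IndividualRecord) -> tuple | None:
    if record.str_profile is not None:
        return tuple(sorted(record.str_profile.items()))
    if record.hvs_variants is not None:
        return tuple(sorted(record.hvs_variants))
    return None


def haplotype_sharing(records: Sequence[IndividualRecord]) -> tuple[int, int]:
    """(number of distinct haplotypes, largest multiplicity)."""
    keys = [_haplotype_key(r) for r in records]
    keys = [k for k in keys if k is not None]
    if not keys:
        return 0, 0
    counts = pd.Series(keys).value_counts()
    return int(len(counts)), int(counts.max())


def diversity_by_population(records: Sequence[IndividualRecord],
                            system: str = "Y") -> list[DiversityResult]:
    """Per-population gene diversity (haplogroups) and haplotype diversity."""
    table, _ = count_haplogroups(records, system)
    results = []
    for pop in table.populations:
        counts = table.counts.loc[pop]
        h, se = gene_diversity(counts)
        pop_records = [r for r in records if r.population_id == pop]
        keys = [_haplotype_key(r) for r in pop_records]
        keys = [k for k in keys if k is not None]
        hap_div = None
        n_hap = None
        if len(keys) >= 2:
            hap_counts = pd.Series(keys).value_counts().to_numpy()
            n_hap = int(len(hap_counts))
            hap_div = gene_diversity(hap_counts)[0]
        results.append(
            DiversityResult(
                population_id=pop,
                gene_diversity=h,
                gene_diversity_se=se,
                n=int(counts.sum()),
                n_haplotypes=n_hap,
                haplotype_diversity=hap_div,
            )
        )
    return results


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray) -> float:
    """log P of an r x c table under the fixed-margins (Fisher) null."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def fisher_rxc_montecarlo(table: np.ndarray, n_mc: int = 100_000,
                          seed: int = 0) -> float:
    """Monte-Carlo r x c Fisher exact test (fixed margins).

    Null tables are generated by permuting column category labels against
    row labels; the test statistic is the table probability, with
    p = (1 + #{P(sim) <= P(obs)}) / (n_mc + 1).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.sum() == 0:
        return 1.0
    r, c = table.shape
    obs_lp = _log_table_prob(table)
    rows = np.repeat(np.arange(r), table.sum(axis=1))
    cols = np.repeat(np.arange(c), table.sum(axis=0))
    rng = np.random.default_rng(seed)
    hits = 0
    flat_rows = rows * c  # precomputed row offsets
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        sim = np.bincount(flat_rows + perm, minlength=r * c).reshape(r, c)
        if _log_table_prob(sim) <= obs_lp + 1e-12:
            hits += 1
    return (1 + hits) / (n_mc + 1)


@dataclass(frozen=True)
class EnrichmentResult:
    haplogroup: str
    focal_count: int
    rest_count: int
    odds_ratio: float
    p_value: float
    direction: str  # "over" / "under" / "none"


def fisher_enrichment(table: FrequencyTable, focal_group: Iterable[str],
                      n_mc: int = 100_000, seed: int = 0,
                      ) -> tuple[list[EnrichmentResult], float]:
    """Per-haplogroup 2x2 Fisher tests of a focal population group vs the
    rest, plus a global Monte-Carlo r x c exact p-value.

    Each 2x2 table is (focal vs rest) x (haplogroup vs all others); the
    direction is read off the odds ratio.  Zero-margin haplogroups get
    p = 1 by convention.
    """
    focal = set(focal_group)
    pops = set(table.populations)
    if not focal or not focal < pops:
        raise ValueError("focal group must be a non-empty strict subset "
                         "of the table's populations")
    rest = pops - focal
    fc = table.counts.loc[sorted(focal)].sum(axis=0)
    rc = table.counts.loc[sorted(rest)].sum(axis=0)
    f_tot, r_tot = int(fc.sum()), int(rc.sum())
    results = []
    for hg in table.haplogroups:
        a, b = int(fc[hg]), f_tot - int(fc[hg])
        c_, d = int(rc[hg]), r_tot - int(rc[hg])
        if a + c_ == 0 or b + d == 0 or a + b == 0 or c_ + d == 0:
            results.append(EnrichmentResult(hg, a, c_, float("nan"), 1.0, "none"))
            continue
        odds, p = stats.fisher_exact([[a, b], [c_, d]])
        direction = "over" if odds > 1 else ("under" if odds < 1 else "none")
        results.append(EnrichmentResult(hg, a, c_, float(odds), float(p),
                                        direction))
    global_table = np.vstack([fc.to_numpy(), rc.to_numpy()])
    global_p = fisher_rxc_montecarlo(global_table, n_mc=n_mc, seed=seed)
    return results, global_p


def pairwise_chisq_bonferroni(counts_a: pd.Series, counts_b: pd.Series,
                              n_tests: int, min_focal: int = 10,
                              ) -> pd.DataFrame:
    """Per-lineage 2x2 chi-square tests between two composition vectors.

    Lineages with a focal (``counts_a``) count below ``min_focal`` are
    excluded (age/enrichment comparisons are restricted to lineages with an
    absolute frequency of at least 10 individuals).  Raw p-values are
    multiplied by ``n_tests`` and capped at 1.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count vectors must share the same haplogroup labels")
    tot_a, tot_b = int(counts_a.sum()), int(counts_b.sum())
    rows = []
    for hg in counts_a.index:
        a = int(counts_a[hg])
        if a < min_focal:
            continue
        b = int(counts_b[hg])
        table = np.array([[a, tot_a - a], [b, tot_b - b]])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            p_raw = 1.0
            chi2 = 0.0
        else:
            chi2, p_raw, _, _ = stats.chi2_contingency(table, correction=True)
        rows.append({
            "haplogroup": hg,
            "count_a": a,
            "count_b": b,
            "chi2": float(chi2),
            "p_raw": float(p_raw),
            "p_adjusted": min(1.0, float(p_raw) * n_tests),
        })
    return pd.DataFrame(rows,
                        columns=["haplogroup", "count_a", "count_b", "chi2",
                                 "p_raw", "p_adjusted"])
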