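"""Synthetic-data generators with the statistical structure the pipeline assumes.

Four generators cover the four data regimes the estimators rely on:

* ``simulate_star_str`` — Y-STR haplotypes evolved under a single-step
  stepwise mutation model (SMM) on a star genealogy of known age.  On a star
  genealogy the expected per-locus sample variance of repeat counts is
  exactly ``mu_l * t``, which is the identity the variance/SD dating
  estimator inverts; a simple Kingman-coalescent option is provided for
  robustness experiments.
* ``simulate_hvs`` — HVS-I sequences carrying a known root variant set plus
  Poisson-distributed private mutations (finite sites: recurrent hits are
  possible, as in real control-region data).
* ``simulate_cline_frequencies`` — per-population multinomial haplogroup
  counts whose expected frequencies follow a logit-linear longitudinal
  cline, the stand-in for NW-SE Mediterranean frequency gradients.
* ``simulate_admixed`` — a hybrid population drawn from a known mixture of
  parental frequency profiles (the tri-hybrid admixture truth).

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    HVS_WINDOW,
    RCRS_LENGTH,
    FrequencyTable,
    IndividualRecord,
    PopulationMeta,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class StarSimSpec:
    """Star-genealogy SMM simulation settings.

    ``tmrca_generations`` is the true age t; each of ``n_lineages``
    descends independently from ``founder_profile`` for t generations, and
    per locus the number of mutations is Poisson(mu_l * t), each step +-1
    repeat with equal probability.
    """

    n_lineages: int
    tmrca_generations: float
    founder_profile: Mapping[str, int]
    locus_rates: Mapping[str, float]
    seed: int
    population_id: str = "sim"

    def __post_init__(self):
        if self.n_lineages < 2:
            raise ValueError("n_lineages must be >= 2")
        if self.tmrca_generations < 0:
            raise ValueError("tmrca_generations must be >= 0")
        for locus, rate in self.locus_rates.items():
            if rate <= 0:
                raise ValueError(f"rate for {locus} must be > 0")
        missing = set(self.locus_rates) - set(self.founder_profile)
        if missing:
            raise ValueError(f"founder profile missing loci {sorted(missing)}")


@dataclass(frozen=True)
class ClineSimSpec:
    """Logit-linear haplogroup cline over sampled populations."""

    n_populations: int
    haplogroup_labels: Sequence[str]
    baseline_frequencies: Sequence[float]
    cline_slope_per_degree: Sequence[float]
    coordinates: Sequence[tuple[float, float]]  # (lat, lon)
    sample_sizes: Sequence[int]
    seed: int
    group_labels: Sequence[str] | None = None

    def __post_init__(self):
        base = np.asarray(self.baseline_frequencies, dtype=float)
        if base.min() <= 0 or abs(base.sum() - 1.0) > 1e-9:
            raise ValueError("baseline frequencies must be a strictly "
                             "positive simplex vector")
        if len(self.coordinates) != self.n_populations:
            raise ValueError("need one coordinate pair per population")
        if len(self.sample_sizes) != self.n_populations:
            raise ValueError("need one sample size per population")
        if len(self.cline_slope_per_degree) != len(self.haplogroup_labels):
            raise ValueError("need one slope per haplogroup")


def _mutate_profile(profile: dict[str, int], rates: Mapping[str, float],
                    t: float, rng: np.random.Generator) -> dict[str, int]:
    out = dict(profile)
    for locus, mu in rates.items():
        k = rng.poisson(mu * t)
        if k:
            steps = rng.choice((-1, 1), size=k).sum()
            out[locus] = max(1, out[locus] + int(steps))  # repeats stay positive
    return out


def simulate_star_str(spec: StarSimSpec) -> list[IndividualRecord]:
    """Evolve ``n_lineages`` STR haplotypes on a star genealogy of known age."""
    rng = np.random.default_rng(spec.seed)
    records = []
    founder = dict(spec.founder_profile)
    for i in range(spec.n_lineages):
        profile = _mutate_profile(founder, spec.locus_rates,
                                  spec.tmrca_generations, rng)
        records.append(
            IndividualRecord(
                individual_id=f"{spec.population_id}_{i:04d}",
                population_id=spec.population_id,
                y_haplogroup="SIM",
                str_profile=profile,
            )
        )
    return records


def simulate_coalescent_str(spec: StarSimSpec) -> list[IndividualRecord]:
    """As :func:`simulate_star_str` but on a Kingman coalescent genealogy.

    Coalescence times are rescaled so the root sits at exactly
    ``tmrca_generations``; branch-specific SMM mutations then accumulate
    along each lineage's root-to-tip path.  Useful for probing the
    star-assumption sensitivity of the dating estimator.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lineages
    # Kingman merge times (units of generations), rescaled to the target age
    times = np.cumsum([rng.exponential(2.0 / (k * (k - 1)))
                       for k in range(n, 1, -1)])
    times *= spec.tmrca_generations / times[-1]
    nodes: list[dict] = [{"depth": 0.0, "tips": [i]} for i in range(n)]
    active = list(range(n))
    deltas = [dict.fromkeys(spec.locus_rates, 0) for _ in range(n)]
    for depth in times:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = nodes[active[i]], nodes[active[j]]
        # mutations on each child branch are shared by every tip of the clade
        for child in (a, b):
            dt = depth - child["depth"]
            for locus, mu in spec.locus_rates.items():
                k = rng.poisson(mu * dt)
                if k:
                    step = int(rng.choice((-1, 1), size=k).sum())
                    for tip in child["tips"]:
                        deltas[tip][locus] += step
        nodes.append({"depth": depth, "tips": a["tips"] + b["tips"]})
        active = [x for k_, x in enumerate(active) if k_ not in (i, j)]
        active.append(len(nodes) - 1)
    profiles = [
        {locus: max(1, count + d.get(locus, 0))
         for locus, count in spec.founder_profile.items()}
        for d in deltas
    ]
    return [
        IndividualRecord(
            individual_id=f"{spec.population_id}_{i:04d}",
            population_id=spec.population_id,
            y_haplogroup="SIM",
            str_profile=profiles[i],
        )
        for i in range(n)
    ]


def _hvs_positions() -> np.ndarray:
    start, end = HVS_WINDOW
    return np.concatenate([np.arange(start, RCRS_LENGTH + 1),
                           np.arange(1, end + 1)])


def simulate_hvs(n: int, root_variants: frozenset[str] | set[str],
                 rate_years_per_mutation: float, age_years: float,
                 seed: int, population_id: str = "sim",
                 mt_haplogroup: str = "SIM") -> list[IndividualRecord]:
    """Sequences = root variant set + Poisson(age/rate) private mutations.

    Private mutations hit uniformly drawn window positions (finite sites, so
    a site may be struck twice and tokens can collide, as with real
    recurrent control-region mutation).
    """
    if age_years < 0:
        raise ValueError("age_years must be >= 0")
    if rate_years_per_mutation <= 0:
        raise ValueError("rate_years_per_mutation must be > 0")
    rng = np.random.default_rng(seed)
    positions = _hvs_positions()
    root = frozenset(root_variants)
    lam = age_years / rate_years_per_mutation
    records = []
    for i in range(n):
        k = rng.poisson(lam)
        tokens = set(root)
        for pos, base in zip(rng.choice(positions, size=k),
                             rng.choice(_BASES, size=k)):
            tokens.add(f"{pos}{base}")
        records.append(
            IndividualRecord(
                individual_id=f"{population_id}_{i:04d}",
                population_id=population_id,
                mt_haplogroup=mt_haplogroup,
                hvs_variants=frozenset(tokens),
            )
        )
    return records


def simulate_cline_frequencies(
    spec: ClineSimSpec,
) -> tuple[FrequencyTable, list[PopulationMeta]]:
    """Multinomial haplogroup counts along a longitudinal logit cline.

    Expected frequencies per population are
    ``softmax(log(baseline) + slope * longitude)``.
    """
    rng = np.random.default_rng(spec.seed)
    base = np.asarray(spec.baseline_frequencies, dtype=float)
    slopes = np.asarray(spec.cline_slope_per_degree, dtype=float)
    rows, metas = [], []
    for p in range(spec.n_populations):
        lat, lon = spec.coordinates[p]
        eta = np.log(base) + slopes * lon
        probs = np.exp(eta - eta.max())
        probs /= probs.sum()
        counts = rng.multinomial(spec.sample_sizes[p], probs)
        rows.append(counts)
        metas.append(
            PopulationMeta(
                population_id=f"P{p:02d}",
                group_label=(spec.group_labels[p] if spec.group_labels
                             else "ALL"),
                latitude=lat,
                longitude=lon,
                sample_size=int(spec.sample_sizes[p]),
            )
        )
    table = FrequencyTable(
        pd.DataFrame(rows, index=[m.population_id for m in metas],
                     columns=list(spec.haplogroup_labels))
    )
    return table, metas


def expected_cline_frequencies(spec: ClineSimSpec) -> pd.DataFrame:
    """Noise-free expectation of :func:`simulate_cline_frequencies`."""
    base = np.asarray(spec.baseline_frequencies, dtype=float)
    slopes = np.asarray(spec.cline_slope_per_degree, dtype=float)
    rows = []
    for lat, lon in spec.coordinates:
        eta = np.log(base) + slopes * lon
        probs = np.exp(eta - eta.max())
        rows.append(probs / probs.sum())
    return pd.DataFrame(rows, columns=list(spec.haplogroup_labels))


def simulate_mixture_panel(profile: Sequence[float], n_per_cluster: int = 10,
                           jitter: float = 0.06, n_mixed: int = 3,
                           mixed_sample_size: int = 500_000,
                           seed: int = 0):
    """Two-cluster frequency panel with exactly intermediate admixed
    populations, for membership-probability demonstrations.

    Cluster ``a`` populations are the ``profile`` plus uniform(+-jitter)
    population-level heterogeneity (renormalized); cluster ``b`` mirrors
    each cluster-``a`` profile (reversed component order), so the two
    clusters are exactly symmetric about the 50/50 mixture.  Mixed
    populations are deeply sampled multinomial draws from that exact
    half-mixture.  Within-cluster spread is dominated by the jitter, i.e.
    by real between-population heterogeneity rather than sampling noise,
    as in regional haplogroup data.

    Returns ``(pure_features, pure_labels, mixed_features)``.
    """
    rng = np.random.default_rng(seed)
    profile = np.asarray(profile, dtype=float)
    rows = []
    for _ in range(n_per_cluster):
        jit = profile + rng.uniform(-jitter, jitter, size=len(profile))
        jit = np.clip(jit, 0.02, None)
        rows.append(jit / jit.sum())
    rows += [row[::-1] for row in rows]
    labels = ["a"] * n_per_cluster + ["b"] * n_per_cluster
    mix_prof = 0.5 * profile + 0.5 * profile[::-1]
    mixed = [rng.multinomial(mixed_sample_size, mix_prof) / mixed_sample_size
             for _ in range(n_mixed)]
    return np.vstack(rows), labels, np.vstack(mixed)


def simulate_admixed(parental_freqs: Sequence[Sequence[float]],
                     weights: Sequence[float], n: int, seed: int) -> np.ndarray:
    """Hybrid haplogroup counts ~ multinomial(n, sum_i w_i * parental_i)."""
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    P = np.asarray(parental_freqs, dtype=float)
    if P.ndim != 2 or P.shape[0] != len(weights):
        raise ValueError("need one parental frequency vector per weight")
    mix = weights @ P
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, mix / mix.sum())
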