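"""TMRCA estimation for Y-STR haplotype clusters and mtDNA HVS-I lineages.

Y-chromosome ages use a within-haplogroup STR-variance (SD) estimator: per
dating locus l, the accumulated age in generations is the sample variance
of repeat counts divided by the locus mutation rate (the star-genealogy
single-step SMM identity E[var] = mu*t); the haplogroup age is the mean
over the 8-locus dating panel, its SE the across-locus standard deviation
over sqrt(L), and years are generations times the generation time.  Before
estimation, outlier haplotypes far from the modal haplotype are removed
(mean squared repeat distance above Q3 + 3*IQR).

mtDNA ages use the rho statistic: the mean number of variant differences
between each sequence and the root haplotype, converted to years by a
linear HVS-I clock calibration (years per mutation), with the star-like
SE = sqrt(rho/n) on the rho scale.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ClockConfig, IndividualRecord

logger = logging.getLogger(__name__)

MIN_DATING_SAMPLE = 10  # lineages below this absolute frequency are not dated


@dataclass(frozen=True)
class TmrcaEstimate:
    haplogroup: str
    n_samples: int
    estimate_years: float
    se_years: float
    estimate_generations: float | None = None
    se_generations: float | None = None
    loci_used: tuple[str, ...] | None = None
    region_used: str | None = None
    n_outliers_removed: int = 0
    rho: float | None = None

    @property
    def ci95_years(self) -> tuple[float, float]:
        return (self.estimate_years - 1.96 * self.se_years,
                self.estimate_years + 1.96 * self.se_years)


@dataclass(frozen=True)
class ModalHaplotype:
    """Per-locus modal repeat counts (Y) or a root variant set (mt)."""
    profile: dict[str, int] | None = None
    root_variants: frozenset[str] | None = None


def modal_haplotype(records: Sequence[IndividualRecord],
                    loci: Sequence[str] | None = None) -> ModalHaplotype:
    """Per-locus mode of repeat counts; ties break toward the smaller allele."""
    if not records:
        raise ValueError("empty haplogroup")
    if loci is None:
        loci = sorted(set.intersection(
            *[set(r.str_profile) for r in records if r.str_profile]))
    profile = {}
    for locus in loci:
        counts = Counter(r.str_profile[locus] for r in records
                         if r.str_profile and locus in r.str_profile)
        if not counts:
            raise ValueError(f"no observations at locus {locus}")
        top = max(counts.values())
        allele = min(a for a, c in counts.items() if c == top)
        if sum(1 for c in counts.values() if c == top) > 1:
            logger.info("modal tie at %s resolved toward smaller allele %d",
                        locus, allele)
        profile[locus] = allele
    return ModalHaplotype(profile=dict(profile))


def flag_outliers(records: Sequence[IndividualRecord], modal: ModalHaplotype,
                  loci: Sequence[str] | None = None,
                  ) -> tuple[list[IndividualRecord], int]:
    """Drop haplotypes whose mean squared repeat distance to the modal
    haplotype exceeds Q3 + 3*IQR; inactive (with a warning) for n < 8."""
    if modal.profile is None:
        raise ValueError("modal haplotype has no STR profile")
    loci = list(loci) if loci is not None else sorted(modal.profile)
    if len(records) < 8:
        warnings.warn("n < 8: outlier screen skipped")
        return list(records), 0
    scores = np.array([
        np.mean([(r.str_profile[l] - modal.profile[l]) ** 2 for l in loci])
        for r in records
    ])
    q1, q3 = np.percentile(scores, [25, 75])
    cut = q3 + 3.0 * (q3 - q1)
    keep = [r for r, s in zip(records, scores) if s <= cut]
    return keep, len(records) - len(keep)


def tmrca_ystr(records: Sequence[IndividualRecord], clock: ClockConfig,
               haplogroup: str = "", remove_outliers: bool = True,
               ) -> TmrcaEstimate:
    """Within-haplogroup STR-variance age estimate.

    Requires the configured 8-locus dating panel in every profile and at
    least 10 haplotypes after outlier removal.
    """
    loci = clock.dating_loci
    if not loci:
        raise ValueError("clock config defines no dating loci")
    for r in records:
        missing = [l for l in loci if not r.str_profile or l not in r.str_profile]
        if missing:
            raise ValueError(
                f"{r.individual_id} lacks dating loci {missing}")
    n_removed = 0
    kept = list(records)
    if remove_outliers and records:
        modal = modal_haplotype(records, loci)
        kept, n_removed = flag_outliers(records, modal, loci)
    if len(kept) < MIN_DATING_SAMPLE:
        raise ValueError(
            f"only {len(kept)} haplotypes after outlier removal; dating "
            f"requires an absolute frequency of at least {MIN_DATING_SAMPLE}")
    ages = []
    for locus in loci:
        repeats = np.array([r.str_profile[locus] for r in kept], dtype=float)
        ages.append(np.var(repeats, ddof=1) / clock.locus_rates[locus])
    ages = np.array(ages)
    est_gen = float(ages.mean())
    se_gen = float(ages.std(ddof=1) / np.sqrt(len(ages)))
    return TmrcaEstimate(
        haplogroup=haplogroup,
        n_samples=len(kept),
        estimate_generations=est_gen,
        se_generations=se_gen,
        estimate_years=clock.generation_years * est_gen,
        se_years=clock.generation_years * se_gen,
        loci_used=tuple(loci),
        n_outliers_removed=n_removed,
    )


def rho_statistic(records: Sequence[IndividualRecord],
                  root: ModalHaplotype) -> tuple[float, float]:
    """rho = mean symmetric-difference count to the root variant set;
    SE = sqrt(rho/n) under the star assumption."""
    if not records:
        raise ValueError("empty haplogroup")
    if root.root_variants is None:
        raise ValueError("root haplotype has no variant set")
    diffs = [len((r.hvs_variants or frozenset()) ^ root.root_variants)
             for r in records]
    rho = float(np.mean(diffs))
    return rho, float(np.sqrt(rho / len(records)))


def modal_root(records: Sequence[IndividualRecord],
               min_fraction: float = 0.5) -> ModalHaplotype:
    """Fallback root for rho: variants carried by a majority of sequences."""
    if not records:
        raise ValueError("empty haplogroup")
    counts = Counter(t for r in records for t in (r.hvs_variants or frozenset()))
    n = len(records)
    return ModalHaplotype(root_variants=frozenset(
        t for t, c in counts.items() if c / n > min_fraction))


def tmrca_mtdna(rho: float, se_rho: float, clock: ClockConfig,
                haplogroup: str = "", n_samples: int = 0) -> TmrcaEstimate:
    """Linear-clock conversion of rho to years (HVS-I calibration)."""
    rate = clock.hvs_rate_years_per_mutation
    if rate is None or rate <= 0:
        raise ValueError("clock config must supply a positive "
                         "hvs_rate_years_per_mutation")
    logger.info("HVS-I calibration: %.1f years per mutation", rate)
    return TmrcaEstimate(
        haplogroup=haplogroup,
        n_samples=n_samples,
        estimate_years=rho * rate,
        se_years=se_rho * rate,
        region_used="HVS-I",
        rho=rho,
    )


def date_haplogroups_ystr(records: Sequence[IndividualRecord],
                          clock: ClockConfig,
                          min_n: int = MIN_DATING_SAMPLE,
                          ) -> list[TmrcaEstimate]:
    """Date every Y haplogroup with at least ``min_n`` carriers."""
    by_hg: dict[str, list[IndividualRecord]] = {}
    for r in records:
        if r.y_haplogroup and r.str_profile:
            by_hg.setdefault(r.y_haplogroup, []).append(r)
    out = []
    for hg in sorted(by_hg):
        if len(by_hg[hg]) < min_n:
            continue
        try:
            out.append(tmrca_ystr(by_hg[hg], clock, haplogroup=hg))
        except ValueError as exc:
            logger.warning("skipping %s: %s", hg, exc)
    return out
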