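"""Y-STR variance dating and mtDNA rho-statistic dating."""

import numpy as np
import pytest

from popstruct.core import ClockConfig, IndividualRecord
from popstruct.datasets import ssi_y_haplogroup_ages
from popstruct.dating import (
    ModalHaplotype,
    flag_outliers,
    modal_haplotype,
    modal_root,
    rho_statistic,
    tmrca_mtdna,
    tmrca_ystr,
)
from popstruct.simulate import StarSimSpec, simulate_hvs, simulate_star_str

from conftest import FOUNDER8, RATES8


def _str_records(profiles, pop="P"):
    return [IndividualRecord(f"i{k}", pop, y_haplogroup="HG",
                             str_profile=dict(p))
            for k, p in enumerate(profiles)]


class TestModalHaplotype:
    def test_identical_profiles_return_that_profile(self):
        recs = _str_records([FOUNDER8] * 4)
        assert modal_haplotype(recs).profile == FOUNDER8

    def test_tie_breaks_toward_smaller_allele(self):
        profiles = [{"DYS19": 13}] * 3 + [{"DYS19": 14}] * 3
        assert modal_haplotype(_str_records(profiles)).profile == {"DYS19": 13}

    def test_matches_brute_force_mode(self):
        profiles = [{"DYS19": 14, "DYS390": 24}, {"DYS19": 14, "DYS390": 23},
                    {"DYS19": 15, "DYS390": 24}, {"DYS19": 14, "DYS390": 24},
                    {"DYS19": 16, "DYS390": 25}]
        modal = modal_haplotype(_str_records(profiles)).profile
        for locus in ("DYS19", "DYS390"):
            counts = {}
            for p in profiles:
                counts[p[locus]] = counts.get(p[locus], 0) + 1
            best = max(counts.values())
            assert modal[locus] == min(a for a, c in counts.items()
                                       if c == best)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            modal_haplotype([])


class TestFlagOutliers:
    def test_distant_haplotype_removed(self):
        core = [dict(FOUNDER8) for _ in range(11)]
        far = {l: v + 10 for l, v in FOUNDER8.items()}
        recs = _str_records(core + [far])
        modal = modal_haplotype(recs)
        kept, n_removed = flag_outliers(recs, modal)
        assert n_removed == 1
        assert all(r.str_profile != far for r in kept)

    def test_homogeneous_cluster_untouched(self):
        recs = _str_records([FOUNDER8] * 10)
        _, n_removed = flag_outliers(recs, modal_haplotype(recs))
        assert n_removed == 0

    def test_small_sample_skipped_with_warning(self):
        recs = _str_records([FOUNDER8] * 5)
        with pytest.warns(UserWarning, match="n < 8"):
            kept, n_removed = flag_outliers(recs, modal_haplotype(recs))
        assert n_removed == 0 and len(kept) == 5


class TestTmrcaYstr:
    def test_monomorphic_cluster_dates_to_zero(self, clock8):
        recs = _str_records([FOUNDER8] * 12)
        est = tmrca_ystr(recs, clock8)
        assert est.estimate_generations == 0.0
        assert est.estimate_years == 0.0

    def test_year_conversion_is_exact(self, clock8):
        recs = simulate_star_str(
            StarSimSpec(50, 120.0, FOUNDER8, RATES8, seed=2))
        est = tmrca_ystr(recs, clock8)
        assert est.estimate_years == pytest.approx(
            clock8.generation_years * est.estimate_generations, abs=1e-12)

    def test_invariant_under_repeat_shift(self, clock8):
        recs = simulate_star_str(
            StarSimSpec(40, 100.0, FOUNDER8, RATES8, seed=3))
        shifted = _str_records(
            [{l: v + 5 for l, v in r.str_profile.items()} for r in recs])
        a = tmrca_ystr(recs, clock8, remove_outliers=False)
        b = tmrca_ystr(shifted, clock8, remove_outliers=False)
        assert a.estimate_generations == pytest.approx(b.estimate_generations)

    def test_minimum_sample_rule_enforced(self, clock8):
        recs = _str_records([FOUNDER8] * 9)
        with pytest.raises(ValueError, match="at least 10"):
            tmrca_ystr(recs, clock8)

    def test_missing_dating_locus_rejected(self, clock8):
        bad = {l: v for l, v in FOUNDER8.items() if l != "DYS392"}
        with pytest.raises(ValueError, match="DYS392"):
            tmrca_ystr(_str_records([bad] * 12), clock8)

    def test_star_simulation_recovery_unbiased(self, clock8):
        # pure estimator (no outlier screen) on its own model: <5% bias
        truth = 160.0
        ests = [
            tmrca_ystr(
                simulate_star_str(StarSimSpec(200, truth, FOUNDER8, RATES8,
                                              seed=rep)),
                clock8, remove_outliers=False).estimate_generations
            for rep in range(60)
        ]
        assert abs(np.mean(ests) - truth) / truth < 0.05

    def test_se_tracks_replicate_dispersion(self, clock8):
        ests = [
            tmrca_ystr(
                simulate_star_str(StarSimSpec(200, 160.0, FOUNDER8, RATES8,
                                              seed=rep)),
                clock8, remove_outliers=False)
            for rep in range(60)
        ]
        empirical_sd = np.std([e.estimate_generations for e in ests], ddof=1)
        mean_se = np.mean([e.se_generations for e in ests])
        assert 0.5 < mean_se / empirical_sd < 2.0


class TestPublishedTableConversion:
    def test_tmrca_equals_generation_time_times_sd(self, clock8):
        """The printed year-scale ages are the generation-scale SD estimates
        converted with a 25-year generation time (+-2 y rounding)."""
        table = ssi_y_haplogroup_ages()
        for row in table.itertuples():
            assert abs(clock8.generation_years * row.sd_generations
                       - row.tmrca_ybp) <= 2.0
            assert abs(clock8.generation_years * row.se_generations
                       - row.se_ybp) <= 2.0


class TestRho:
    ROOT = ModalHaplotype(root_variants=frozenset({"16224C", "16311C"}))

    def _recs(self, variant_sets):
        return [IndividualRecord(f"i{k}", "P", mt_haplogroup="H",
                                 hvs_variants=frozenset(v))
                for k, v in enumerate(variant_sets)]

    def test_sequences_equal_to_root_give_zero(self):
        recs = self._recs([self.ROOT.root_variants] * 6)
        rho, se = rho_statistic(recs, self.ROOT)
        assert rho == 0.0 and se == 0.0

    def test_one_private_variant_each_gives_one(self):
        sets = [self.ROOT.root_variants | {f"1600{i}A"} for i in range(2, 8)]
        rho, _ = rho_statistic(self._recs(sets), self.ROOT)
        assert rho == 1.0

    def test_simulated_poisson_mean_recovered(self):
        recs = simulate_hvs(1000, self.ROOT.root_variants, 8000.0, 16000.0,
                            seed=9)
        rho, se = rho_statistic(recs, self.ROOT)
        assert abs(rho - 2.0) < 3 * se

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rho_statistic([], self.ROOT)

    def test_modal_root_recovers_shared_variants(self):
        recs = simulate_hvs(200, frozenset({"16126C", "16294T"}), 10000.0,
                            5000.0, seed=4)
        root = modal_root(recs)
        assert root.root_variants == frozenset({"16126C", "16294T"})


class TestTmrcaMtdna:
    def test_zero_rho_gives_zero_age(self, clock8):
        est = tmrca_mtdna(0.0, 0.0, clock8)
        assert est.estimate_years == 0.0

    def test_linear_clock(self):
        clock = ClockConfig(locus_rates={"DYS19": 0.001},
                            hvs_rate_years_per_mutation=10_000.0)
        est = tmrca_mtdna(2.0, 0.1, clock)
        assert est.estimate_years == 20_000.0
        assert est.se_years == 1_000.0

    def test_missing_calibration_rejected(self):
        clock = ClockConfig(locus_rates={"DYS19": 0.001})
        with pytest.raises(ValueError):
            tmrca_mtdna(1.0, 0.1, clock)

    def test_round_trip_with_simulated_age(self, clock8):
        truth = 16_000.0
        recs = simulate_hvs(400, frozenset({"16224C"}),
                            clock8.hvs_rate_years_per_mutation, truth, seed=6)
        root = ModalHaplotype(root_variants=frozenset({"16224C"}))
        rho, se = rho_statistic(recs, root)
        est = tmrca_mtdna(rho, se, clock8, n_samples=400)
        assert abs(est.estimate_years - truth) < 3 * est.se_years
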