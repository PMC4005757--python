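"""Whole-study orchestration: one config, deterministic seeded stages,
TSV outputs and a run log.

Stage order mirrors the analysis workflow the package implements:
frequencies -> diversity -> AMOVA / Fisher (regional structure) ->
distances + Mantel -> sPCA + global/local tests -> clustering/DAPC ->
enrichment -> TMRCA dating -> admixture.  Every stage is independently
re-runnable through the library API; the pipeline records seeds,
permutation counts and statistical decisions in ``run_log.yaml``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .amova import (
    amova as run_amova,
    geographic_matrix,
    mantel as run_mantel,
    reynolds_matrix,
    squared_distance_matrix,
)
from . import dapc as dapc_mod
from . import dating as dating_mod
from . import frequencies as freq_mod
from . import spca as spca_mod
from .admixture import my_bootstrap
from .core import (
    ClockConfig,
    HaplogroupTree,
    IndividualRecord,
    collapse_haplogroups,
    read_genotype_table,
    read_population_meta,
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single user seed."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    genotypes: str
    metadata: str
    output_dir: str
    seed: int = 0
    marker_system: str = "Y"
    tree: str | None = None
    clock: str | None = None
    groupings: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    admixture: dict | None = None   # {"hybrid": group, "parentals": [groups]}
    n_perm_amova: int = 999
    n_perm_mantel: int = 10_000
    n_perm_spca: int = 999
    n_mc_fisher: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        perms = doc.pop("n_perm", {})
        return cls(
            **doc,
            n_perm_amova=perms.get("amova", 999),
            n_perm_mantel=perms.get("mantel", 10_000),
            n_perm_spca=perms.get("spca", 999),
            n_mc_fisher=perms.get("fisher", 10_000),
        )


def _validate(config: PipelineConfig, records, metas) -> None:
    pop_ids = {m.population_id for m in metas}
    rec_pops = {r.population_id for r in records}
    unknown = rec_pops - pop_ids
    if unknown:
        raise ValueError(f"records reference populations without metadata: "
                         f"{sorted(unknown)}")
    for scheme, groups in config.groupings.items():
        for g, pops in groups.items():
            bad = set(pops) - pop_ids
            if bad:
                raise ValueError(
                    f"grouping {scheme!r}/{g!r} references unknown "
                    f"populations {sorted(bad)}")


def subset_comparison(records: Sequence[IndividualRecord],
                      subset_ids: Sequence[str], system: str = "Y",
                      n_mc: int = 10_000, seed: int = 0) -> float:
    """Global exact-test p for haplogroup composition of a subset of
    individuals against its complement (e.g. a surname-selected subsample
    versus the full dataset)."""
    subset = set(subset_ids)
    all_ids = {r.individual_id for r in records}
    if not subset or subset == all_ids:
        raise ValueError("subset must be non-empty and a strict subset")
    bad = subset - all_ids
    if bad:
        raise ValueError(f"subset ids not in data: {sorted(bad)}")
    attr = "y_haplogroup" if system == "Y" else "mt_haplogroup"
    calls = [(r.individual_id in subset, getattr(r, attr)) for r in records
             if getattr(r, attr) is not None]
    df = pd.DataFrame(calls, columns=["in_subset", "haplogroup"])
    table = pd.crosstab(df["in_subset"], df["haplogroup"]).to_numpy()
    return freq_mod.fisher_rxc_montecarlo(table, n_mc=n_mc, seed=seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a summary dict (also logged)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}
    summary: dict = {}

    def run_stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # halt with stage name; keep partial output
            raise PipelineStageError(name, exc) from exc
        log["stages"][name] = {"seed": stage_seed(config.seed, name)}
        return result

    records = read_genotype_table(config.genotypes)
    metas = read_population_meta(config.metadata)
    run_stage("validate", lambda: _validate(config, records, metas))

    tree = HaplogroupTree.from_config(config.tree) if config.tree else None
    clock = ClockConfig.from_config(config.clock) if config.clock else None

    # --- frequencies -------------------------------------------------------
    def stage_freqs():
        table, dropped = freq_mod.count_haplogroups(records,
                                                    config.marker_system)
        if tree is not None:
            table = collapse_haplogroups(table, tree)
        table.to_tsv(out / "haplogroup_counts.tsv")
        table.percentages().to_csv(out / "haplogroup_percent.tsv", sep="\t")
        log["stages"].setdefault("frequencies", {})["records_dropped"] = dropped
        return table

    table = run_stage("frequencies", stage_freqs)
    summary["n_populations"] = len(table.populations)
    summary["n_haplogroups"] = len(table.haplogroups)

    # --- diversity ---------------------------------------------------------
    def stage_diversity():
        res = freq_mod.diversity_by_population(records, config.marker_system)
        pd.DataFrame([r.__dict__ for r in res]).to_csv(
            out / "diversity.tsv", sep="\t", index=False)
        return res

    run_stage("diversity", stage_diversity)

    # --- AMOVA + Fisher per grouping scheme --------------------------------
    def stage_amova():
        rows = []
        d2 = squared_distance_matrix(
            records, "haplogroup" if config.marker_system == "Y" else "haplogroup")
        pops = [r.population_id for r in records]
        for scheme, groups in config.groupings.items():
            pop_to_group = {p: g for g, ps in groups.items() for p in ps}
            keep = [i for i, p in enumerate(pops) if p in pop_to_group]
            sub = d2[np.ix_(keep, keep)]
            sub_pops = [pops[i] for i in keep]
            sub_groups = [pop_to_group[p] for p in sub_pops]
            res = run_amova(sub, sub_pops, sub_groups,
                                  n_perm=config.n_perm_amova,
                                  seed=stage_seed(config.seed, f"amova:{scheme}"))
            rows.append({"scheme": scheme, **res.__dict__})
            gp = freq_mod.fisher_enrichment(
                table, [p for p in groups[next(iter(groups))]],
                n_mc=config.n_mc_fisher,
                seed=stage_seed(config.seed, f"fisher:{scheme}"))[1]
            rows[-1]["fisher_global_p"] = gp
        if rows:
            pd.DataFrame(rows).to_csv(out / "amova.tsv", sep="\t", index=False)
        return rows

    amova_rows = run_stage("amova", stage_amova)
    if amova_rows:
        summary["amova"] = {r["scheme"]: r["phi_ct"] for r in amova_rows}

    # --- distances + Mantel ------------------------------------------------
    def stage_mantel():
        gen = reynolds_matrix(table)
        meta_map = {m.population_id: m for m in metas}
        geo = geographic_matrix([meta_map[p] for p in gen.labels])
        gen.to_tsv(out / "reynolds_distances.tsv")
        geo.to_tsv(out / "geographic_distances.tsv")
        r, p = run_mantel(gen, geo, n_perm=config.n_perm_mantel,
                                seed=stage_seed(config.seed, "mantel"))
        log["stages"].setdefault("mantel", {}).update(
            {"n_perm": config.n_perm_mantel})
        return {"r": r, "p": p}

    summary["mantel"] = run_stage("mantel", stage_mantel)

    # --- sPCA --------------------------------------------------------------
    def stage_spca():
        meta_map = {m.population_id: m for m in metas}
        ordered = [meta_map[p] for p in table.populations]
        weights = spca_mod.build_weights(ordered, scheme="delaunay")
        res = spca_mod.spca(table, weights)
        pd.DataFrame(res.scores, index=res.population_labels).to_csv(
            out / "spca_scores.tsv", sep="\t")
        pd.DataFrame(res.loadings, index=res.haplogroup_labels).to_csv(
            out / "spca_loadings.tsv", sep="\t")
        stat, p = spca_mod.spca_global_local_test(
            table, weights, "global", n_perm=config.n_perm_spca,
            seed=stage_seed(config.seed, "spca_global"))
        lstat, lp = spca_mod.spca_global_local_test(
            table, weights, "local", n_perm=config.n_perm_spca,
            seed=stage_seed(config.seed, "spca_local"))
        log["stages"].setdefault("spca", {})["network"] = "delaunay"
        return {"global_stat": stat, "global_p": p,
                "local_stat": lstat, "local_p": lp,
                "eigenvalues": res.eigenvalues.tolist()}

    summary["spca"] = run_stage("spca", stage_spca)

    # --- clustering + DAPC membership --------------------------------------
    def stage_dapc():
        gen = reynolds_matrix(table)
        coords = dapc_mod.pcoa_embedding(gen, n_dims=3)
        k, assign = dapc_mod.gaussian_mixture_bic(
            coords, k_range=range(1, min(6, len(gen.labels))),
            seed=stage_seed(config.seed, "cluster"))
        if k < 2:
            pd.DataFrame({"population_id": gen.labels,
                          "cluster": assign}).to_csv(
                out / "membership.tsv", sep="\t", index=False)
            return {"best_k": k}
        model = dapc_mod.dapc_fit(coords, [str(a) for a in assign])
        membership = dapc_mod.dapc_membership(model, coords,
                                              row_labels=gen.labels)
        membership.to_csv(out / "membership.tsv", sep="\t")
        return {"best_k": k}

    summary["clusters"] = run_stage("dapc", stage_dapc)

    # --- dating ------------------------------------------------------------
    if clock is not None and clock.dating_loci:
        def stage_dating():
            ests = dating_mod.date_haplogroups_ystr(records, clock)
            pd.DataFrame([
                {"haplogroup": e.haplogroup, "n": e.n_samples,
                 "sd_generations": e.estimate_generations,
                 "se_generations": e.se_generations,
                 "tmrca_ybp": e.estimate_years, "se_ybp": e.se_years,
                 "outliers_removed": e.n_outliers_removed}
                for e in ests
            ]).to_csv(out / "tmrca_y.tsv", sep="\t", index=False)
            return {e.haplogroup: e.estimate_years for e in ests}

        summary["tmrca_y"] = run_stage("dating", stage_dating)

    # --- admixture ---------------------------------------------------------
    if config.admixture:
        def stage_admix():
            spec = config.admixture
            group_of = {}
            for scheme in config.groupings.values():
                for g, pops in scheme.items():
                    for p in pops:
                        group_of.setdefault(p, g)
            attr = "y_haplogroup" if config.marker_system == "Y" else "mt_haplogroup"
            def calls_for(group):
                pops = {p for p, g in group_of.items() if g == group}
                return [getattr(r, attr) for r in records
                        if r.population_id in pops and getattr(r, attr)]
            res = my_bootstrap(
                calls_for(spec["hybrid"]),
                [calls_for(g) for g in spec["parentals"]],
                n_boot=spec.get("n_boot", 1000),
                seed=stage_seed(config.seed, "admixture"),
                labels=spec["parentals"])
            pd.DataFrame({
                "parental": res.parental_labels,
                "weight": res.weights,
                "bootstrap_sd": res.bootstrap_sd,
            }).to_csv(out / "admixture.tsv", sep="\t", index=False)
            return dict(zip(res.parental_labels, res.weights.tolist()))

        summary["admixture"] = run_stage("admixture", stage_admix)

    log["summary"] = _to_plain(summary)
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return summary


def _to_plain(obj):
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
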