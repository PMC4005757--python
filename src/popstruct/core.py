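"""Domain types, file readers/writers, and marker-level normalization rules.

The package works on uniparentally inherited markers: Y-chromosome SNP
haplogroups with multi-locus Y-STR repeat profiles, and mtDNA control-region
(HVS-I/HVS-II) haplotypes expressed as variant tokens relative to the rCRS.
Everything downstream (diversity, AMOVA, sPCA, DAPC, dating, admixture)
consumes the containers defined here.

Conventions
-----------
* mtDNA coordinates are 1-based on the circular 16,569-bp rCRS.
* Missing values are written with an explicit sentinel token (``NA``), never
  an empty string.
* The Yfiler loci DYS385a/DYS385b are excluded from every analysis profile
  (the multiplex cannot resolve which allele is a and which is b); DYS389b is
  a derived locus, DYS389II minus DYS389I.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

RCRS_LENGTH = 16569
HVS_WINDOW = (15975, 155)  # 750 bp spanning the origin
MISSING = "NA"
#: loci never admitted to an analysis profile
EXCLUDED_STR_LOCI = frozenset({"DYS385a", "DYS385b", "DYS385A", "DYS385B"})


class SchemaError(ValueError):
    """A required column is absent or a config file is malformed."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""


class MappingError(KeyError):
    """A haplogroup label cannot be resolved in the tree."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndividualRecord:
    """One sampled chromosome/genome.

    ``str_profile`` maps locus name to an integer repeat count;
    ``hvs_variants`` is a frozenset of tokens such as ``"16224C"`` (position +
    derived base, rCRS-relative).  Either marker system may be missing.
    """

    individual_id: str
    population_id: str
    y_haplogroup: str | None = None
    str_profile: Mapping[str, int] | None = None
    mt_haplogroup: str | None = None
    hvs_variants: frozenset[str] | None = None

    def __post_init__(self):
        if self.str_profile is not None:
            for locus, count in self.str_profile.items():
                if locus in EXCLUDED_STR_LOCI:
                    raise ValueError(
                        f"locus {locus} is excluded from analysis profiles"
                    )
                if not (isinstance(count, (int, np.integer)) and count > 0):
                    raise ValueError(
                        f"repeat count for {locus} must be a positive integer,"
                        f" got {count!r}"
                    )
            object.__setattr__(self, "str_profile", dict(self.str_profile))
        if self.hvs_variants is not None:
            for token in self.hvs_variants:
                pos = variant_position(token)
                if not _in_hvs_window(pos):
                    raise ValueError(
                        f"variant {token} lies outside the HVS window "
                        f"{HVS_WINDOW[0]}..{HVS_WINDOW[1]}"
                    )
            object.__setattr__(self, "hvs_variants", frozenset(self.hvs_variants))


@dataclass(frozen=True)
class PopulationMeta:
    """Sampling-location metadata (decimal degrees, WGS84)."""

    population_id: str
    group_label: str
    latitude: float
    longitude: float
    sample_size: int

    def __post_init__(self):
        if not abs(self.latitude) <= 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not abs(self.longitude) <= 180:
            raise ValueError(f"longitude {self.longitude} out of range")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


class HaplogroupTree:
    """Rooted haplogroup forest with a designated reduced comparison level.

    Cross-study comparison requires concatenating sub-haplogroups to a common
    resolution (e.g. 21 paternal / 16 maternal lineages); ``reduce_label``
    walks each observed label up to its unique reduced-level ancestor.
    """

    def __init__(self, parent: Mapping[str, str], reduced_level: Iterable[str]):
        self.parent = dict(parent)
        self.reduced_level = set(reduced_level)
        # cycle guard
        for node in self.parent:
            seen = {node}
            cur = node
            while cur in self.parent:
                cur = self.parent[cur]
                if cur in seen:
                    raise SchemaError(f"cycle in haplogroup tree at {cur}")
                seen.add(cur)

    @classmethod
    def from_config(cls, path: str | Path) -> "HaplogroupTree":
        doc = yaml.safe_load(Path(path).read_text())
        try:
            return cls(doc["parent"], doc["reduced_level"])
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"tree config {path} missing {exc}") from exc

    def reduce_label(self, label: str) -> str:
        cur = label
        while True:
            if cur in self.reduced_level:
                return cur
            if cur not in self.parent:
                raise MappingError(
                    f"haplogroup {label!r} has no reduced-level ancestor"
                )
            cur = self.parent[cur]


@dataclass
class ClockConfig:
    """Mutation-rate/clock settings for lineage dating.

    ``locus_rates`` are per-locus Y-STR mutation rates (mutations/locus/
    generation); ``dating_loci`` is the ordered 8-locus panel used for
    variance dating (markers chosen for the longest duration of linearity
    with time); ``hvs_rate_years_per_mutation`` is the HVS-I clock
    calibration (years per observed mutation) and has no default.
    """

    locus_rates: dict[str, float]
    generation_years: float = 25.0
    hvs_rate_years_per_mutation: float | None = None
    dating_loci: tuple[str, ...] = ()

    def __post_init__(self):
        if self.generation_years <= 0:
            raise ValueError("generation_years must be > 0")
        for locus, rate in self.locus_rates.items():
            if rate <= 0:
                raise ValueError(f"rate for {locus} must be > 0")
        if self.hvs_rate_years_per_mutation is not None and (
            self.hvs_rate_years_per_mutation <= 0
        ):
            raise ValueError("hvs_rate_years_per_mutation must be > 0")
        missing = [l for l in self.dating_loci if l not in self.locus_rates]
        if missing:
            raise ValueError(f"dating loci without a rate: {missing}")
        self.dating_loci = tuple(self.dating_loci)

    @classmethod
    def from_config(cls, path: str | Path) -> "ClockConfig":
        doc = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                locus_rates={k: float(v) for k, v in doc["locus_rates"].items()},
                generation_years=float(doc.get("generation_years", 25.0)),
                hvs_rate_years_per_mutation=(
                    float(doc["hvs_rate_years_per_mutation"])
                    if doc.get("hvs_rate_years_per_mutation") is not None
                    else None
                ),
                dating_loci=tuple(doc.get("dating_loci", ())),
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"clock config {path} malformed: {exc}") from exc


@dataclass
class FrequencyTable:
    """Populations x haplogroups count matrix.

    Wraps a pandas DataFrame of non-negative integer counts; rows are
    population ids, columns haplogroup labels.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        counts = self.counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative count in frequency table")
        self.counts = counts

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def haplogroups(self) -> list[str]:
        return list(self.counts.columns)

    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.row_totals, axis=0)

    def percentages(self, decimals: int = 1) -> pd.DataFrame:
        """Reporting view: 100*count/row_total, rounded."""
        return (100.0 * self.frequencies()).round(decimals)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="population_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


# ---------------------------------------------------------------------------
# marker-level rules
# ---------------------------------------------------------------------------

def variant_position(token: str) -> int:
    """Position of an rCRS-relative variant token such as ``16224C``."""
    digits = "".join(ch for ch in token if ch.isdigit())
    if not digits:
        raise ParseError(f"variant token {token!r} has no position")
    return int(digits)


def _in_hvs_window(pos: int) -> bool:
    start, end = HVS_WINDOW
    return start <= pos <= RCRS_LENGTH or 1 <= pos <= end


def circular_region_length(start: int, end: int, genome_length: int = RCRS_LENGTH) -> int:
    """Inclusive length of the clockwise arc start..end on a circular genome.

    The HVS sequencing window 15975..155 on the 16,569-bp rCRS wraps through
    the origin and spans 750 bp.
    """
    for pos in (start, end):
        if not 1 <= pos <= genome_length:
            raise ValueError(f"position {pos} outside [1..{genome_length}]")
    if start <= end:
        return end - start + 1
    return (genome_length - start + 1) + end


def derive_dys389b(record: IndividualRecord) -> IndividualRecord:
    """Replace DYS389II by the derived locus DYS389b = DYS389II - DYS389I.

    DYS389II is amplified as a nested fragment containing DYS389I, so the
    independent repeat stretch is their difference; DYS389I is retained.
    """
    profile = record.str_profile
    if profile is None or not {"DYS389I", "DYS389II"} <= set(profile):
        raise ValueError("both DYS389I and DYS389II required")
    b = profile["DYS389II"] - profile["DYS389I"]
    if b < 0:
        raise ValueError(
            f"DYS389II ({profile['DYS389II']}) < DYS389I ({profile['DYS389I']})"
        )
    if b == 0:
        warnings.warn(
            f"{record.individual_id}: DYS389b = 0 is suspicious", stacklevel=2
        )
    new_profile = {k: v for k, v in profile.items() if k != "DYS389II"}
    # a zero repeat count is invalid in IndividualRecord; keep 0 only via flag
    if b > 0:
        new_profile["DYS389b"] = b
        return replace(record, str_profile=new_profile)
    rec = replace(record, str_profile=new_profile)
    object.__setattr__(rec, "str_profile", {**new_profile, "DYS389b": 0})
    return rec


def collapse_haplogroups(table: FrequencyTable, tree: HaplogroupTree) -> FrequencyTable:
    """Sum counts into reduced-level ancestor lineages; row totals preserved."""
    mapping = {}
    for label in table.haplogroups:
        mapping[label] = tree.reduce_label(label)  # raises MappingError
    collapsed = table.counts.T.groupby(
        table.counts.columns.map(mapping)
    ).sum().T
    out = FrequencyTable(collapsed)
    if not (out.row_totals == table.row_totals).all():
        raise AssertionError("collapse changed row totals")  # pragma: no cover
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {"individual_id", "population_id"}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_genotype_table(path: str | Path, marker_system: str = "BOTH") -> list[IndividualRecord]:
    """Read a delimited genotype table into validated records.

    One row per individual.  Recognized columns: ``individual_id``,
    ``population_id``, ``y_haplogroup``, ``mt_haplogroup``, ``hvs_variants``
    (semicolon- or space-separated tokens), plus any number of Y-STR locus
    columns (integer repeat counts).  DYS385a/b columns are dropped from the
    analysis profile with a logged warning.  Missing cells hold ``NA``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str).fillna(MISSING)
    missing_cols = _REQUIRED_COLUMNS - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {sorted(missing_cols)}")

    known = {"individual_id", "population_id", "y_haplogroup", "mt_haplogroup",
             "hvs_variants"}
    locus_cols = [c for c in df.columns if c not in known]
    excluded = [c for c in locus_cols if c in EXCLUDED_STR_LOCI]
    if excluded:
        logger.warning("excluding loci %s from analysis profiles", excluded)
        locus_cols = [c for c in locus_cols if c not in EXCLUDED_STR_LOCI]

    records: list[IndividualRecord] = []
    for idx, row in df.iterrows():
        profile: dict[str, int] = {}
        for locus in locus_cols:
            cell = row[locus].strip()
            if cell == MISSING or cell == "":
                continue
            try:
                profile[locus] = int(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: row {idx} locus {locus}: non-integer repeat "
                    f"{cell!r}"
                ) from exc
        hvs = None
        if "hvs_variants" in df.columns and row["hvs_variants"] != MISSING:
            tokens = row["hvs_variants"].replace(";", " ").split()
            hvs = frozenset(tokens)
        records.append(
            IndividualRecord(
                individual_id=row["individual_id"],
                population_id=row["population_id"],
                y_haplogroup=(
                    row["y_haplogroup"]
                    if "y_haplogroup" in df.columns and row["y_haplogroup"] != MISSING
                    else None
                ),
                str_profile=profile or None,
                mt_haplogroup=(
                    row["mt_haplogroup"]
                    if "mt_haplogroup" in df.columns and row["mt_haplogroup"] != MISSING
                    else None
                ),
                hvs_variants=hvs,
            )
        )
    return records


def write_genotype_table(records: Sequence[IndividualRecord], path: str | Path) -> None:
    """Write records to a delimited table; exact round-trip with the reader."""
    path = Path(path)
    loci = sorted({l for r in records if r.str_profile for l in r.str_profile})
    rows = []
    for r in records:
        row = {
            "individual_id": r.individual_id,
            "population_id": r.population_id,
            "y_haplogroup": r.y_haplogroup if r.y_haplogroup else MISSING,
            "mt_haplogroup": r.mt_haplogroup if r.mt_haplogroup else MISSING,
            "hvs_variants": (
                ";".join(sorted(r.hvs_variants)) if r.hvs_variants else MISSING
            ),
        }
        for locus in loci:
            row[locus] = (
                str(r.str_profile[locus])
                if r.str_profile and locus in r.str_profile
                else MISSING
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_population_meta(path: str | Path) -> list[PopulationMeta]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    needed = {"population_id", "group_label", "latitude", "longitude", "sample_size"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return [
        PopulationMeta(
            population_id=str(r.population_id),
            group_label=str(r.group_label),
            latitude=float(r.latitude),
            longitude=float(r.longitude),
            sample_size=int(r.sample_size),
        )
        for r in df.itertuples()
    ]


def write_population_meta(metas: Sequence[PopulationMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "population_id": m.population_id,
                "group_label": m.group_label,
                "latitude": m.latitude,
                "longitude": m.longitude,
                "sample_size": m.sample_size,
            }
            for m in metas
        ]
    ).to_csv(path, sep=_sep_for(Path(path)), index=False)
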