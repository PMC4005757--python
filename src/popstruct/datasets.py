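"""Bundled example tables and configs."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .core import ClockConfig, HaplogroupTree


def _data_path(name: str) -> Path:
    return Path(resources.files("popstruct").joinpath("data", name))


def ssi_y_haplogroup_ages() -> pd.DataFrame:
    """Published Y-haplogroup dating table for the Sicily/Southern-Italy
    survey the package's workflow mirrors: per haplogroup, carrier count,
    frequency (%), the STR-variance (SD) age and SE in generations, and the
    corresponding TMRCA and SE in years before present.

    Used as worked-example input for frequency and year-conversion
    arithmetic; no raw genotypes accompany it.
    """
    return pd.read_csv(_data_path("ssi_y_haplogroup_ages.tsv"), sep="\t")


def example_clock() -> ClockConfig:
    """Editable placeholder clock config (see comments in the YAML)."""
    return ClockConfig.from_config(_data_path("clock_example.yaml"))


def example_y_tree() -> HaplogroupTree:
    """Editable example Y haplogroup tree with a reduced comparison level."""
    return HaplogroupTree.from_config(_data_path("y_tree_example.yaml"))
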