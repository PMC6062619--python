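"""Packaged study tables: the published sample-level ancestry profiles, the
uniparental haplogroup counts, sample-to-period-group sizes, and the group
mean percentages printed in the results narrative."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .haplogroups import HaplogroupTable, read_haplogroup_table

__all__ = [
    "ANCESTRY_COLUMNS",
    "load_sample_profiles",
    "load_haplogroup_table",
    "load_sample_groups",
    "load_group_means",
]

#: ancestry column order used by the published sample-profile table
ANCESTRY_COLUMNS = [
    "Northern Asian", "West-Central African", "Omotic", "Northern European",
    "Japanese", "Eastern African", "Kalash", "Northern African",
    "Sino-Tibetan", "Circumpolar", "Amerindian", "Southern Asian",
    "Western Asian", "Central African", "Southeastern Asian", "South Indian",
    "Southern European", "Southern African", "Oceanian", "Western African",
    "Arabian",
]


def _data_path(name: str):
    return resources.files("paleoproj.data").joinpath(name)


def load_sample_profiles() -> pd.DataFrame:
    """Published sparsified ancestry proportions for the 49 samples."""
    with resources.as_file(_data_path("table1_profiles.csv")) as path:
        df = pd.read_csv(path)
    return df


def load_haplogroup_table() -> HaplogroupTable:
    """Published Y and mitochondrial haplogroup counts for the 49 samples."""
    with resources.as_file(_data_path("table2_haplogroups.csv")) as path:
        return read_haplogroup_table(path)


def load_sample_groups() -> pd.DataFrame:
    """Sample -> period group mapping with individual counts."""
    with resources.as_file(_data_path("sample_groups.csv")) as path:
        return pd.read_csv(path)


def load_group_means() -> pd.DataFrame:
    """Group-level mean ancestry percentages as printed in the results
    narrative (long format: group, ancestry, percent)."""
    with resources.as_file(_data_path("results_group_means.csv")) as path:
        return pd.read_csv(path)
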