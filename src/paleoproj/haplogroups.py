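"""Y-chromosome and mitochondrial haplogroup composition by period group.

Haplogroup labels are matched by plain, case-sensitive string prefix: the
prefix "H" counts "H", "H5", and "HV"; "R" counts "R1a", "R1b", and "R1".
Parenthetical exclusion notation such as "K(xLT)" is not parsed -- it is a
plain label that matches prefix "K".  Prefix matching, not phylogenetic
containment, is the tabulation rule throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "HaplogroupRecord",
    "HaplogroupTable",
    "CompositionResult",
    "read_haplogroup_table",
    "haplogroup_composition",
]

Y = "Y"
MT = "MT"
_COLUMNS = ["group", "sample", "locus", "haplogroup", "count"]


@dataclass(frozen=True)
class HaplogroupRecord:
    """Count of one haplogroup at one locus in one sample."""

    group: str
    sample: str
    locus: str
    haplogroup: str
    count: int

    def __post_init__(self) -> None:
        if self.locus not in (Y, MT):
            raise ValueError(f"locus must be Y or MT, got {self.locus!r}")
        if self.count < 1:
            raise ValueError(f"count must be positive, got {self.count}")
        if not self.haplogroup or self.haplogroup.upper() == "NA":
            raise ValueError(
                "missing haplogroup data is represented by absent records, "
                f"not a record named {self.haplogroup!r}"
            )


@dataclass
class HaplogroupTable:
    """Collection of haplogroup records with unique (group, sample, locus,
    haplogroup) keys."""

    records: list[HaplogroupRecord]

    def __post_init__(self) -> None:
        keys = [(r.group, r.sample, r.locus, r.haplogroup) for r in self.records]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate haplogroup record key {dup}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=_COLUMNS)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return list(seen)


@dataclass(frozen=True)
class CompositionResult:
    """Matched and total lineage counts for one selection and prefix set."""

    matched: int
    total: int

    @property
    def percent(self) -> float:
        return 100.0 * self.matched / self.total

    @property
    def percent_rounded(self) -> float:
        """Percentage rounded to 1 decimal, the display convention."""
        return round(self.percent, 1)


def read_haplogroup_table(path) -> HaplogroupTable:
    """Read a haplogroup CSV with columns group, sample, locus, haplogroup,
    count.  Rows whose haplogroup is NA/empty are dropped (no data)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"haplogroup table {path} lacks columns {missing}")
    records = []
    for idx, row in df.iterrows():
        hap = row["haplogroup"]
        if pd.isna(hap) or str(hap).strip().upper() in ("", "NA"):
            continue
        try:
            records.append(
                HaplogroupRecord(
                    group=str(row["group"]),
                    sample=str(row["sample"]),
                    locus=str(row["locus"]),
                    haplogroup=str(hap),
                    count=int(row["count"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {idx + 2}: {exc}") from exc
    return HaplogroupTable(records=records)


def _select(table: HaplogroupTable, locus: str,
            groups=None, samples=None) -> list[HaplogroupRecord]:
    recs = [r for r in table.records if r.locus == locus]
    if groups is not None:
        wanted = {groups} if isinstance(groups, str) else set(groups)
        recs = [r for r in recs if r.group in wanted]
    if samples is not None:
        wanted = {samples} if isinstance(samples, str) else set(samples)
        recs = [r for r in recs if r.sample in wanted]
    return recs


def haplogroup_composition(table: HaplogroupTable, locus: str,
                           prefixes: list[str],
                           groups=None, samples=None) -> CompositionResult:
    """Fraction of lineages whose haplogroup starts with any given prefix.

    ``groups`` and/or ``samples`` restrict the selection (samples are
    interpreted within the selected groups, since sample names recur across
    period groups).  A record is counted once if any prefix matches.
    """
    recs = _select(table, locus, groups=groups, samples=samples)
    if not recs:
        raise ValueError(
            f"selection matches no records (locus={locus}, groups={groups}, "
            f"samples={samples})"
        )
    total = sum(r.count for r in recs)
    if total == 0:
        raise ValueError("selection has zero total count")
    matched = sum(
        r.count for r in recs
        if any(r.haplogroup.startswith(p) for p in prefixes)
    )
    return CompositionResult(matched=matched, total=total)
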