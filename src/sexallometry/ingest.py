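"""Reading, validating, cleaning and partitioning long-format phenotyping tables.

The expected input is a delimited text file (CSV or TSV, autodetected by
extension) with one row per animal x trait measurement.  Arbitrary source
headers are supported through a column map (``{canonical_name: source_header}``),
which can also be loaded from a YAML file.

Cleaning applies three rules: rows with missing or non-positive body weight
are removed, rows with a trait value of exactly zero are removed (log-scale
modelling requires ratio-scale positive values), and duplicated specimen IDs
within a trait are reduced to their first occurrence.  Every removal is
counted in a :class:`CleaningReport` so the process is auditable, and
cleaning is idempotent.

Interval-scale traits (which legitimately contain non-positive values, e.g.
temperature differences) are shifted onto the ratio scale before modelling;
the applied offset is recorded in the dataset's provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    CANONICAL_COLUMNS,
    MANDATORY_COLUMNS,
    ConstantTraitError,
    EmptyTraitError,
    TraitDataset,
)

logger = logging.getLogger(__name__)

_SEX_TOKENS = {"female": "female", "f": "female", "male": "male", "m": "male"}


@dataclass
class RowProblem:
    """One rejected or unparseable input row."""

    row_number: int  # 1-based data row number (header excluded)
    reason: str


@dataclass
class CleaningReport:
    """Counts of rows removed per cleaning rule."""

    n_input: int = 0
    missing_weight: int = 0
    nonpositive_weight: int = 0
    zero_value: int = 0
    missing_value: int = 0
    duplicate: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.missing_weight
            + self.nonpositive_weight
            + self.zero_value
            + self.missing_value
            + self.duplicate
        )

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_removed"] = self.n_removed
        d["n_kept"] = self.n_kept
        return d


@dataclass
class TraitGroupMap:
    """Mapping from trait name to correlated-trait group, with the assumed
    within-group correlation ``r`` used when merging p-values (default 0.8)."""

    groups: dict[str, str]
    r: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.r < 1.0):
            raise ValueError(f"inter-trait correlation r must be in [0, 1), got {self.r}")

    def group_of(self, trait_name: str) -> str:
        return self.groups[trait_name]

    def traits_in(self, group_id: str) -> list[str]:
        return sorted(t for t, g in self.groups.items() if g == group_id)

    @classmethod
    def from_csv(cls, path: str | Path, r: float = 0.8) -> "TraitGroupMap":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("group map must have two columns: trait_name, group_id")
        tcol, gcol = df.columns[:2]
        return cls(groups=dict(zip(df[tcol].astype(str), df[gcol].astype(str))), r=r)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"trait_name": list(self.groups), "group_id": list(self.groups.values())}
        ).to_csv(path, index=False)


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a ``{canonical_name: source_header}`` map from YAML."""
    with open(path) as fh:
        cmap = yaml.safe_load(fh)
    if not isinstance(cmap, Mapping):
        raise ValueError("column map YAML must be a mapping")
    return dict(cmap)


def _canonical_sex(token: object) -> str | None:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    return _SEX_TOKENS.get(str(token).strip().lower())


def read_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[RowProblem]]:
    """Read a delimited measurement table into canonical long format.

    Parameters
    ----------
    path : path
        CSV or TSV file (delimiter autodetected by extension; ``.tsv`` and
        ``.txt`` are read as tab-separated).
    column_map : mapping, optional
        ``{canonical_name: source_header}``; canonical names missing from the
        map are looked up verbatim.

    Returns
    -------
    records : pandas.DataFrame
        Valid rows, canonical columns.
    problems : list of RowProblem
        Rejected rows with 1-based data row numbers and reasons (unknown sex
        token, unparseable weight or trait value).

    Raises
    ------
    ValueError
        If the file is empty or a mandatory column is absent.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    if df.empty and df.columns.size == 0:
        raise ValueError(f"empty input file: {path}")

    column_map = dict(column_map or {})
    rename: dict[str, str] = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
    df = df.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mandatory column(s) missing from {path.name}: {missing}")
    if df.empty:
        raise ValueError(f"input file has a header but no data rows: {path}")

    for c in CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = pd.NA

    problems: list[RowProblem] = []
    keep = np.ones(len(df), dtype=bool)

    sexes = df["sex"].map(_canonical_sex)
    for i in np.flatnonzero(sexes.isna().to_numpy()):
        problems.append(RowProblem(int(i) + 1, f"unknown sex token {df['sex'].iloc[i]!r}"))
        keep[i] = False
    df["sex"] = sexes

    for col in ("weight", "trait_value"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        for i in np.flatnonzero(bad.to_numpy() & keep):
            problems.append(RowProblem(int(i) + 1, f"unparseable {col}: {df[col].iloc[i]!r}"))
            keep[i] = False
        df[col] = parsed

    df["weight_age_days"] = pd.to_numeric(df["weight_age_days"], errors="coerce")

    for problem in problems:
        logger.warning("row %d rejected: %s", problem.row_number, problem.reason)

    out = df.loc[keep, CANONICAL_COLUMNS].reset_index(drop=True)
    return out, problems


def clean_dataset(
    records: pd.DataFrame,
    trait_name: str | None = None,
    functional_group: str | None = None,
) -> tuple[TraitDataset, CleaningReport]:
    """Apply the cleaning rules to the records of one trait.

    Rules, applied in order: drop rows with missing body weight; drop rows
    with non-positive body weight; drop rows with missing trait value; drop
    rows with a trait value of exactly zero; keep the first occurrence of each
    duplicated specimen ID.  The report accounts for every removed row, so
    ``n_input == n_kept + n_removed`` always holds and the operation is
    idempotent.

    Raises
    ------
    EmptyTraitError
        If no rows survive (the trait is skipped, not fatal to a run).
    """
    if records.empty:
        raise EmptyTraitError("no input rows")
    names = records["trait_name"].dropna().unique()
    if trait_name is None:
        if len(names) != 1:
            raise ValueError(f"records span {len(names)} traits; pass trait_name")
        trait_name = str(names[0])

    report = CleaningReport(n_input=len(records))
    df = records

    m = df["weight"].isna()
    report.missing_weight = int(m.sum())
    df = df[~m]

    m = df["weight"] <= 0
    report.nonpositive_weight = int(m.sum())
    df = df[~m]

    m = df["trait_value"].isna()
    report.missing_value = int(m.sum())
    df = df[~m]

    m = df["trait_value"] == 0
    report.zero_value = int(m.sum())
    df = df[~m]

    dup = df["animal_id"].duplicated(keep="first")
    report.duplicate = int(dup.sum())
    df = df[~dup].reset_index(drop=True)

    if df.empty:
        raise EmptyTraitError(f"all rows of trait {trait_name!r} removed by cleaning")

    if functional_group is None:
        fg = df["functional_group"].dropna().unique()
        functional_group = str(fg[0]) if len(fg) else "unknown"

    ds = TraitDataset(
        trait_name=trait_name,
        functional_group=functional_group,
        data=df,
        provenance={"cleaning": report.to_dict()},
    )
    return ds, report


def adjust_interval_trait(
    ds: TraitDataset, quantum: float = 1.0
) -> TraitDataset:
    """Shift an interval-scale trait onto the ratio scale.

    Interval-scale traits can take non-positive values, which a log-scale
    power-law model cannot accept.  The rule is an additive shift placing the
    minimum at ``+quantum`` (one measurement-unit quantum, default 1.0):
    ``offset = quantum - min(value)`` whenever ``min(value) <= 0``.  The
    offset is recorded in the dataset's provenance; all-positive traits are
    returned unchanged.

    Raises
    ------
    ConstantTraitError
        If the trait has zero variance (no allometric relationship can be
        estimated; the trait is skipped).
    """
    values = ds.data["trait_value"].to_numpy(dtype=float)
    if np.ptp(values) == 0:
        raise ConstantTraitError(f"trait {ds.trait_name!r} is constant")
    vmin = values.min()
    if vmin > 0:
        return ds
    offset = quantum - vmin
    out = ds.data.copy()
    out["trait_value"] = values + offset
    provenance = dict(ds.provenance)
    provenance["interval_offset"] = float(offset)
    return TraitDataset(ds.trait_name, ds.functional_group, out, provenance)


def partition_by_trait(records: pd.DataFrame) -> list[TraitDataset]:
    """Split cleaned records into one :class:`TraitDataset` per trait.

    The result is sorted by trait name (deterministic ordering) and forms a
    partition: datasets are disjoint and their sizes sum to the input size.
    Traits emptied by cleaning are skipped with a logged reason.
    """
    out: list[TraitDataset] = []
    if records.empty:
        return out
    for trait_name in sorted(records["trait_name"].dropna().unique()):
        sub = records[records["trait_name"] == trait_name].reset_index(drop=True)
        try:
            ds, _ = clean_dataset(sub, trait_name=str(trait_name))
        except EmptyTraitError as exc:
            logger.info("trait %r skipped: %s", trait_name, exc)
            continue
        out.append(ds)
    return out


def write_trait_table(ds: TraitDataset, path: str | Path) -> None:
    """Write one cleaned per-trait table as TSV."""
    ds.data.to_csv(path, sep="\t", index=False)
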