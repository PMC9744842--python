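"""Core containers for per-trait phenotyping data.

A measurement table is a :class:`pandas.DataFrame` in canonical long format,
one row per animal x trait, with the columns in :data:`CANONICAL_COLUMNS`.
:class:`TraitDataset` wraps the rows belonging to a single trait together
with the counts the downstream models need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Canonical column names of a measurement table (long format, one row per
#: animal x trait measurement).
CANONICAL_COLUMNS = [
    "animal_id",
    "sex",
    "weight",
    "weight_age_days",
    "trait_name",
    "trait_value",
    "batch",
    "metadata_group",
    "substrain",
    "centre",
    "procedure_name",
    "functional_group",
]

#: Columns that must be present and non-null for a row to be usable.
MANDATORY_COLUMNS = [
    "animal_id",
    "sex",
    "weight",
    "trait_name",
    "trait_value",
    "batch",
    "metadata_group",
    "substrain",
]

#: The nine functional groupings used for mouse phenotyping traits.
FUNCTIONAL_GROUPS = [
    "behaviour",
    "eye",
    "hearing",
    "heart",
    "haematology",
    "immunology",
    "metabolism",
    "morphology",
    "physiology",
]

SEXES = ("female", "male")


class SexAllometryError(Exception):
    """Base class for typed signals raised by this package."""


class EmptyTraitError(SexAllometryError):
    """All rows of a trait were removed by cleaning; the trait is skipped."""


class ConstantTraitError(SexAllometryError):
    """Trait has zero variance; it cannot be adjusted or modelled."""


class SingleSexError(SexAllometryError):
    """Only one sex present; the sex-contrast model is undefined."""


class NotConvergedError(SexAllometryError):
    """An operation that requires a converged fit received a failed one."""


@dataclass
class TraitDataset:
    """Cleaned measurements for one phenotypic trait.

    Attributes
    ----------
    trait_name : str
        Trait identifier (IMPReSS-style parameter name).
    functional_group : str
        One of the nine functional groupings (behaviour, eye, ...).
    data : pandas.DataFrame
        Rows for this trait in canonical long format.
    provenance : dict
        Audit trail: cleaning counts, interval-scale offsets, generator
        parameters for synthetic data, etc.
    """

    trait_name: str
    functional_group: str
    data: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.data["trait_name"].unique()
        if len(names) > 1:
            raise ValueError(f"mixed trait names in one dataset: {list(names)}")

    @property
    def n_female(self) -> int:
        return int((self.data["sex"] == "female").sum())

    @property
    def n_male(self) -> int:
        return int((self.data["sex"] == "male").sum())

    @property
    def n_total(self) -> int:
        return len(self.data)

    @property
    def n_batches(self) -> int:
        return self.data["batch"].nunique()

    @property
    def n_metadata_groups(self) -> int:
        return self.data["metadata_group"].nunique()

    @property
    def n_substrains(self) -> int:
        return self.data["substrain"].nunique()

    def sex_mask(self, sex: str) -> np.ndarray:
        return (self.data["sex"] == sex).to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TraitDataset({self.trait_name!r}, group={self.functional_group!r}, "
            f"n={self.n_total} [{self.n_female}F/{self.n_male}M], "
            f"batches={self.n_batches}, mg={self.n_metadata_groups}, "
            f"substrains={self.n_substrains})"
        )


def empty_measurement_frame() -> pd.DataFrame:
    """An empty measurement table with the canonical columns."""
    return pd.DataFrame({c: pd.Series(dtype=object) for c in CANONICAL_COLUMNS})
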