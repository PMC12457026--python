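"""Core data container for the clonal factorial design.

The universal input of every analysis stage is a tidy per-individual table
with one row per animal: clone identity, dietary treatment (AA / CA / CC,
maternal diet then offspring diet; A = high-quality algae, C = low-quality
cyanobacteria), generation (G2 = maternal, G3 = offspring), age at
measurement in hours, eye size and body size in mm, and reproductive output
(offspring count summed over the first three clutches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("AA", "CA", "CC")
GENERATIONS = ("G2", "G3")

#: canonical column order of the on-disk schema
COLUMNS = (
    "clone_id",
    "treatment",
    "generation",
    "age_h",
    "eye_mm",
    "body_mm",
    "repro_count",
)

#: analysis trait name -> dataframe column
TRAIT_COLUMNS = {
    "eye_size": "eye_mm",
    "body_size": "body_mm",
    "reproduction": "repro_count",
}

#: traits whose model includes the age covariate
MORPHOLOGICAL_TRAITS = ("eye_size", "body_size")

#: measurement age the design targets (hours); age is centred here
DESIGN_AGE_H = 132.0

#: the six observed treatment x generation cells (no A->C arm exists)
CELLS = tuple((t, g) for t in TREATMENTS for g in GENERATIONS)


class ValidationError(ValueError):
    """Raised when a dataset or configuration violates the design schema."""


@dataclass
class TraitDataset:
    """Per-individual trait records of the clonal factorial design.

    Wraps a :class:`pandas.DataFrame` with the canonical columns and
    guarantees the treatment/generation factors are drawn from the design's
    allowed sets.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"dataset is missing columns: {missing}")
        bad_t = set(self.df["treatment"].unique()) - set(TREATMENTS)
        if bad_t:
            raise ValidationError(f"unknown treatment labels: {sorted(bad_t)}")
        bad_g = set(self.df["generation"].unique()) - set(GENERATIONS)
        if bad_g:
            raise ValidationError(f"unknown generation labels: {sorted(bad_g)}")
        if self.df.index.has_duplicates:
            raise ValidationError("duplicated individual identifiers in index")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitDataset):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def n_clones(self) -> int:
        return self.df["clone_id"].nunique()

    def design_summary(self) -> pd.DataFrame:
        """Record counts per clone x treatment x generation cell."""
        return (
            self.df.groupby(["clone_id", "treatment", "generation"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )

    def cell_counts(self) -> pd.Series:
        """Record counts per treatment x generation cell."""
        return self.df.groupby(["treatment", "generation"], observed=True).size()

    def trait_values(self, trait: str) -> pd.Series:
        col = TRAIT_COLUMNS.get(trait)
        if col is None:
            raise KeyError(f"unknown trait {trait!r}; expected one of {list(TRAIT_COLUMNS)}")
        return self.df[col]

    def complete_cases(self, trait: str) -> "TraitDataset":
        """Trait-wise complete-case subset (drops rows missing the trait,
        and missing age for morphological traits)."""
        col = TRAIT_COLUMNS[trait]
        mask = self.df[col].notna()
        if trait in MORPHOLOGICAL_TRAITS:
            mask &= self.df["age_h"].notna()
        return TraitDataset(self.df.loc[mask].copy())


def cell_label(treatment: str, generation: str) -> str:
    """Human-readable cell name, e.g. ``'AA G3'``."""
    return f"{treatment} {generation}"
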