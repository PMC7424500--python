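"""Core data containers shared by every pipeline stage.

An :class:`ExpressionMatrix` is a genes-by-samples table tagged with the
scale of its values; :class:`SampleMetadata` assigns each sample to a
(group, week) cell; :class:`GeneSet` is an ordered, de-duplicated list of
gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SCALE_RAW",
    "SCALE_NORMALIZED",
    "SCALE_LOG2",
    "GROUPS",
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSet",
]

SCALE_RAW = "raw"
SCALE_NORMALIZED = "normalized"
SCALE_LOG2 = "log2"
_SCALES = (SCALE_RAW, SCALE_NORMALIZED, SCALE_LOG2)

GROUPS = ("control", "treated")


@dataclass
class ExpressionMatrix:
    """Genes (rows) by samples (columns) numeric table.

    Parameters
    ----------
    data
        DataFrame with unique gene (or probe) ids as index and unique
        sample ids as columns.
    scale
        One of ``"raw"``, ``"normalized"`` or ``"log2"``.  Raw values must
        be strictly positive.
    """

    data: pd.DataFrame
    scale: str = SCALE_LOG2

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:10]}")
        if not self.data.columns.is_unique:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:10]}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == SCALE_RAW and (values <= 0).any():
            rows, cols = np.nonzero(values <= 0)
            gene = self.data.index[rows[0]]
            sample = self.data.columns[cols[0]]
            raise ValueError(
                f"raw-intensity matrix must be strictly positive; "
                f"offending entry gene={gene!r} sample={sample!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], scale=self.scale)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids), :], scale=self.scale)

    def equals(self, other: "ExpressionMatrix", atol: float = 0.0) -> bool:
        if self.scale != other.scale:
            return False
        if not self.data.index.equals(other.data.index):
            return False
        if not self.data.columns.equals(other.data.columns):
            return False
        return np.allclose(self.data.to_numpy(), other.data.to_numpy(), atol=atol, rtol=0.0)


@dataclass
class SampleMetadata:
    """Per-sample group label and timepoint (weeks).

    The table must have columns ``sample_id``, ``group`` and ``week``;
    groups are restricted to ``control``/``treated``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "week"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dup}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        self.table = self.table.reset_index(drop=True)
        self.table["week"] = self.table["week"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def weeks(self) -> list[int]:
        return sorted(self.table["week"].unique().tolist())

    @property
    def groups(self) -> list[str]:
        present = set(self.table["group"])
        return [g for g in GROUPS if g in present]

    def samples_in_cell(self, group: str, week: int) -> list[str]:
        """Sample ids belonging to one (group, week) cell, in table order."""
        mask = (self.table["group"] == group) & (self.table["week"] == int(week))
        return self.table.loc[mask, "sample_id"].tolist()

    def cells(self) -> Iterator[tuple[str, int, list[str]]]:
        """Yield (group, week, sample_ids) for every non-empty cell."""
        for group in self.groups:
            for week in self.weeks:
                ids = self.samples_in_cell(group, week)
                if ids:
                    yield group, week, ids


@dataclass
class GeneSet:
    """Named, ordered collection of unique gene symbols."""

    genes: list[str] = field(default_factory=list)
    name: str = "gene_set"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        cleaned: list[str] = []
        for g in self.genes:
            g = str(g).strip()
            if not g or g in seen:
                continue
            seen.add(g)
            cleaned.append(g)
        self.genes = cleaned

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def intersect(self, other: "GeneSet") -> "GeneSet":
        mine = other.as_set()
        return GeneSet([g for g in self.genes if g in mine], name=f"{self.name}&{other.name}")
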