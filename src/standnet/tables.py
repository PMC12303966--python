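"""In-memory containers for soil-property and ASV abundance tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eight physicochemical indicators, in canonical column order.
#: Units: SOC, TN, TP g/kg; AN g/kg; AP mg/kg; pH unitless; MWHC %; BD g/cm3.
SOIL_INDICATORS = ["SOC", "TN", "TP", "AN", "AP", "pH", "MWHC", "BD"]

STAND_COLUMN = "stand"


def validate_soil_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a soil-property table (samples x indicators + stand label).

    Expects a DataFrame indexed by sample id with a ``stand`` column and the
    eight indicator columns. Raises ``ValueError`` naming the offending
    column or sample on any violation.
    """
    missing = [c for c in [STAND_COLUMN, *SOIL_INDICATORS] if c not in table.columns]
    if missing:
        raise ValueError(f"soil table missing columns: {missing}")
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    values = table[SOIL_INDICATORS]
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"missing values in indicator columns: {bad}")
    if not np.issubdtype(values.to_numpy().dtype, np.number):
        raise ValueError("non-numeric indicator values")
    if (table["BD"] <= 0).any():
        raise ValueError("BD must be positive")
    if ((table["pH"] <= 0) | (table["pH"] >= 14)).any():
        raise ValueError("pH out of (0, 14)")
    return table


@dataclass
class AbundanceTable:
    """ASV count table for one domain (bacteria or fungi).

    Attributes
    ----------
    counts : pd.DataFrame
        samples x ASVs matrix of non-negative integer counts.
    taxonomy : pd.Series
        Semicolon-delimited rank string per ASV, indexed by ASV id.
    domain : str
        ``"bacteria"`` or ``"fungi"``.
    metadata : pd.DataFrame
        Per-sample metadata (at least a ``stand`` column), indexed like
        ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    domain: str
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in abundance table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate ASV ids in abundance table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            rows, cols = np.where(arr < 0)
            raise ValueError(
                "negative count at sample "
                f"{self.counts.index[rows[0]]!r}, ASV {self.counts.columns[cols[0]]!r}"
            )
        if self.domain not in ("bacteria", "fungi", "combined"):
            raise ValueError(f"unknown domain tag {self.domain!r}")
        self.taxonomy = self.taxonomy.reindex(self.counts.columns).fillna("Unassigned")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.columns

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"all-zero samples: {empty}")
        return self.counts.div(totals, axis=0)

    def stands(self) -> pd.Series:
        if STAND_COLUMN not in self.metadata.columns:
            raise ValueError("abundance table has no stand metadata")
        return self.metadata.loc[self.counts.index, STAND_COLUMN]

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        meta = (
            self.metadata.loc[list(sample_ids)]
            if len(self.metadata)
            else self.metadata
        )
        return AbundanceTable(
            counts=self.counts.loc[list(sample_ids)],
            taxonomy=self.taxonomy,
            domain=self.domain,
            metadata=meta,
        )

    def subset_asvs(self, asv_ids) -> "AbundanceTable":
        return AbundanceTable(
            counts=self.counts[list(asv_ids)],
            taxonomy=self.taxonomy.loc[list(asv_ids)],
            domain=self.domain,
            metadata=self.metadata,
        )


def combine_domains(bacteria: AbundanceTable, fungi: AbundanceTable) -> AbundanceTable:
    """Join bacterial and fungal tables on shared samples for pooled networks.

    ASV ids are assumed disjoint between domains (generator prefixes them
    ``B``/``F``); taxonomy strings are carried through and the per-ASV domain
    is recoverable from a joint taxonomy lookup.
    """
    shared = bacteria.sample_ids.intersection(fungi.sample_ids)
    if len(shared) == 0:
        raise ValueError("no shared samples between domains")
    overlap = bacteria.asv_ids.intersection(fungi.asv_ids)
    if len(overlap) > 0:
        raise ValueError(f"ASV ids shared across domains: {overlap[:5].tolist()}")
    counts = pd.concat(
        [bacteria.counts.loc[shared], fungi.counts.loc[shared]], axis=1
    )
    taxonomy = pd.concat([bacteria.taxonomy, fungi.taxonomy])
    return AbundanceTable(
        counts=counts,
        taxonomy=taxonomy,
        domain="combined",
        metadata=bacteria.metadata.loc[shared]
        if len(bacteria.metadata)
        else bacteria.metadata,
    )


def asv_domains(bacteria: AbundanceTable, fungi: AbundanceTable) -> pd.Series:
    """Per-ASV domain tag for a combined table."""
    return pd.concat(
        [
            pd.Series("bacteria", index=bacteria.asv_ids),
            pd.Series("fungi", index=fungi.asv_ids),
        ]
    )
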