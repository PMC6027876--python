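"""Core in-memory containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`, an entries × markers dosage
matrix on the 0–2 scale (0 = homozygous reference, 2 = homozygous alternate,
NaN = missing). Genotyped inbreds carry integer dosages; projected F1 hybrids
may carry real-valued dosages in [0, 2] (e.g. 0.5 when one parent was called
heterozygous). Marker metadata (chromosome, position, alleles) and entry
metadata (entry type) travel with the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError

#: canonical entry-type labels
ENTRY_TYPES = ("inbred_B", "inbred_R", "hybrid", "control")

MARKER_COLUMNS = ["chrom", "pos", "ref", "alt"]


def population_of(entry_type: str) -> str:
    """Collapse an entry type to its population label (``inbred``/``hybrid``)."""
    if entry_type.startswith("inbred"):
        return "inbred"
    return entry_type


@dataclass
class GenotypeMatrix:
    """Entries × markers dosage matrix with marker and entry metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by entry id with one float column per marker id;
        values in [0, 2] or NaN for missing.
    markers
        DataFrame indexed by marker id with columns ``chrom, pos, ref, alt``
        and optionally ``n_alleles`` (observed allele count, used by the
        multi-allelic filter rule).
    entries
        DataFrame indexed by entry id with a column ``entry_type``.
    """

    dosages: pd.DataFrame
    markers: pd.DataFrame
    entries: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.entries is None:
            self.entries = pd.DataFrame(
                {"entry_type": ["hybrid"] * self.dosages.shape[0]},
                index=self.dosages.index,
            )
        if not self.dosages.columns.equals(self.markers.index):
            # allow construction from any order, but align strictly
            if set(self.dosages.columns) != set(self.markers.index):
                raise AlignmentError("dosage columns and marker index differ")
            self.markers = self.markers.loc[self.dosages.columns]
        if not self.dosages.index.equals(self.entries.index):
            if set(self.dosages.index) != set(self.entries.index):
                raise AlignmentError("dosage rows and entry index differ")
            self.entries = self.entries.loc[self.dosages.index]
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 2)):
                raise DataError("dosage values must lie in [0, 2] or be missing")
        if self.markers.duplicated(subset=["chrom", "pos"]).any():
            raise DataError("marker positions must be unique per chromosome")

    # -- basic introspection ------------------------------------------------

    @property
    def n_entries(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def entry_ids(self) -> pd.Index:
        return self.dosages.index

    def values(self) -> np.ndarray:
        return self.dosages.to_numpy(dtype=float)

    def missing_rate(self) -> float:
        return float(self.dosages.isna().to_numpy().mean())

    def populations(self) -> pd.Series:
        return self.entries["entry_type"].map(population_of)

    # -- subsetting ---------------------------------------------------------

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        marker_ids = pd.Index(marker_ids)
        missing = marker_ids.difference(self.markers.index)
        if len(missing):
            raise AlignmentError(f"unknown markers: {list(missing[:5])}")
        return GenotypeMatrix(
            self.dosages.loc[:, marker_ids],
            self.markers.loc[marker_ids],
            self.entries.copy(),
        )

    def subset_entries(self, entry_ids) -> "GenotypeMatrix":
        entry_ids = pd.Index(entry_ids)
        missing = entry_ids.difference(self.entries.index)
        if len(missing):
            raise AlignmentError(f"unknown entries: {list(missing[:5])}")
        return GenotypeMatrix(
            self.dosages.loc[entry_ids],
            self.markers.copy(),
            self.entries.loc[entry_ids],
        )

    @staticmethod
    def concat_entries(a: "GenotypeMatrix", b: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack two matrices that share an identical marker set."""
        if not a.marker_ids.equals(b.marker_ids):
            raise AlignmentError("marker sets differ; cannot stack entries")
        if len(a.entry_ids.intersection(b.entry_ids)):
            raise DataError("duplicate entry ids across matrices")
        return GenotypeMatrix(
            pd.concat([a.dosages, b.dosages]),
            a.markers.copy(),
            pd.concat([a.entries, b.entries]),
        )


class CrossPlan:
    """A table of planned single crosses: (hybrid_id, female_id, male_id).

    Females are A/B-lines, males are R-lines. Hybrid ids must be unique and
    no (female, male) pair may repeat.
    """

    COLUMNS = ["hybrid_id", "female_id", "male_id"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise DataError(f"cross plan missing columns: {missing}")
        table = table[self.COLUMNS].reset_index(drop=True)
        if table["hybrid_id"].duplicated().any():
            raise DataError("duplicate hybrid_id in cross plan")
        if table.duplicated(subset=["female_id", "male_id"]).any():
            raise DataError("duplicate (female, male) pair in cross plan")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def hybrid_ids(self) -> pd.Index:
        return pd.Index(self.table["hybrid_id"])

    def parents_of(self, hybrid_id: str) -> tuple[str, str]:
        row = self.table.loc[self.table["hybrid_id"] == hybrid_id]
        if row.empty:
            raise AlignmentError(f"unknown hybrid id: {hybrid_id}")
        return str(row["female_id"].iloc[0]), str(row["male_id"].iloc[0])

    def offspring_of(self, parent_id: str) -> pd.Index:
        mask = (self.table["female_id"] == parent_id) | (
            self.table["male_id"] == parent_id
        )
        return pd.Index(self.table.loc[mask, "hybrid_id"])

    @classmethod
    def full_factorial(cls, female_ids, male_ids) -> "CrossPlan":
        """Every possible female × male cross (e.g. 192 × 192 → 36,864)."""
        rows = [
            (f"{f}x{m}", f, m)
            for f in female_ids
            for m in male_ids
        ]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    @classmethod
    def from_csv(cls, path) -> "CrossPlan":
        return cls(pd.read_csv(path, comment="#", dtype=str))

    def to_csv(self, path, seed=None) -> None:
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            self.table.to_csv(fh, index=False)
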