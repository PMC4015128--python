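"""Sample-by-metabolite abundance tables.

The central container is :class:`MetaboliteTable`: an ``n_samples x
n_metabolites`` matrix of abundances (arbitrary units, ``NaN`` marking
below-detection / missing cells) with unique sample and metabolite
identifiers and optional per-sample group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetaboliteTable", "read_abundance_table", "write_abundance_table"]


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundance matrix.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_metabolites)
        Abundances; ``NaN`` encodes a missing cell.
    sample_ids, metabolite_ids : sequences of str
        Unique row / column identifiers matching the matrix shape.
    group_labels : sequence, optional
        One categorical label per sample (e.g. ``"control"`` /
        ``"fasted"``) for two-group comparisons.
    """

    values: np.ndarray
    sample_ids: list[str]
    metabolite_ids: list[str]
    group_labels: list | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x metabolites matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("at least 2 samples are required")
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.metabolite_ids) != p:
            raise ValueError(
                f"{len(self.metabolite_ids)} metabolite ids for {p} matrix columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(self.metabolite_ids)) != p:
            raise ValueError("metabolite ids must be unique")
        if self.group_labels is not None:
            self.group_labels = list(self.group_labels)
            if len(self.group_labels) != n:
                raise ValueError("one group label per sample is required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(
            self.values.copy(),
            list(self.sample_ids),
            list(self.metabolite_ids),
            None if self.group_labels is None else list(self.group_labels),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Return the matrix as a DataFrame (samples in rows)."""
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.metabolite_ids
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, group_labels=None
    ) -> "MetaboliteTable":
        return cls(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            group_labels,
        )


def read_abundance_table(
    path,
    sep: str = ",",
    orientation: str = "samples-rows",
    group_col: str | None = None,
) -> MetaboliteTable:
    """Read a delimited abundance matrix.

    The first column holds sample IDs and the header row metabolite IDs
    (``orientation="samples-rows"``); pass ``orientation="metabolites-rows"``
    for transposed files.  Empty cells and ``NA`` are read as missing.
    ``group_col`` names an optional non-numeric column with group labels.
    """
    if orientation not in ("samples-rows", "metabolites-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=["NA", "NaN", "na"],
        keep_default_na=True,
    )
    if orientation == "metabolites-rows":
        df = df.T
    labels = None
    if group_col is not None:
        if group_col not in df.columns:
            raise ValueError(f"group column {group_col!r} not found")
        labels = df.pop(group_col).tolist()
    return MetaboliteTable.from_dataframe(df.astype(float), labels)


def write_abundance_table(table: MetaboliteTable, path, sep: str = ",") -> None:
    df = table.to_dataframe()
    if table.group_labels is not None:
        df.insert(0, "group", table.group_labels)
    df.to_csv(path, sep=sep, index_label="sample_id")
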