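"""In-memory containers: protein abundance matrices and cell-mean matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DESIGN_COLUMNS


@dataclass
class AbundanceMatrix:
    """Protein x sample relative abundances with the sample design.

    ``values`` is a DataFrame indexed by protein id with one column per
    sample; missing entries are NaN. ``design`` is indexed by sample id
    with columns condition / day / zone / replicate, aligned with the
    value columns. ``log_scale`` records whether values are log2.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated protein id {dup!r}")
        missing_meta = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing_meta:
            raise ValueError(f"design lacks columns {missing_meta}")
        if list(self.values.columns) != list(self.design.index):
            # tolerate reordering, not mismatch
            if set(self.values.columns) != set(self.design.index):
                extra = set(self.values.columns) - set(self.design.index)
                raise ValueError(
                    f"samples without design metadata: {sorted(extra)[:5]}"
                )
            self.design = self.design.loc[self.values.columns]
        if not self.log_scale:
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy(dtype=float) < 0).any():
                    raise ValueError("raw-scale abundances must be >= 0")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_log2(self) -> "AbundanceMatrix":
        """Log2-transform raw abundances (zeros become missing)."""
        if self.log_scale:
            return self
        vals = self.values.to_numpy(dtype=float).copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(vals > 0, np.log2(np.where(vals > 0, vals, np.nan)), np.nan)
        return AbundanceMatrix(
            pd.DataFrame(vals, index=self.values.index, columns=self.values.columns),
            self.design.copy(),
            log_scale=True,
        )

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.loc[:, list(sample_ids)],
            self.design.loc[list(sample_ids)],
            log_scale=self.log_scale,
        )


@dataclass
class CellMeanMatrix:
    """Protein profiles averaged over replicates within each design cell.

    ``values`` columns are a MultiIndex of (condition, day, zone); an
    entry is NaN only when every replicate of that cell was missing.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.values.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 3:
            raise ValueError("cell columns must be a (condition, day, zone) MultiIndex")
        if cols.has_duplicates:
            raise ValueError("duplicated design cell")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> list[tuple[str, str, int]]:
        return [tuple(c) for c in self.values.columns]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def complete(self) -> tuple["CellMeanMatrix", pd.Index]:
        """Drop proteins with any missing cell mean; return them too."""
        mask = self.values.notna().all(axis=1)
        dropped = self.values.index[~mask]
        return CellMeanMatrix(self.values.loc[mask]), dropped


def cell_means(matrix: AbundanceMatrix) -> CellMeanMatrix:
    """Average replicates within each (condition, day, zone) cell.

    The mean is taken over available (non-missing) replicates; a cell
    with no observation for a protein carries NaN.
    """
    design = matrix.design
    keys = pd.MultiIndex.from_frame(design[["condition", "day", "zone"]])
    grouped = matrix.values.T.groupby(keys, sort=False).mean()
    vals = grouped.T
    vals.columns = pd.MultiIndex.from_tuples(
        [tuple(c) for c in vals.columns], names=["condition", "day", "zone"]
    )
    return CellMeanMatrix(vals)
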