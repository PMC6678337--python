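"""Dense expression-matrix container.

The matrix is always oriented genes x cells and is assumed to hold
log-scale, user-normalised values; no transformation is applied anywhere
in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of log-scale expression values.

    Parameters
    ----------
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    values
        Real matrix of shape ``(len(gene_ids), len(cell_ids))``; every
        entry must be finite.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    values: np.ndarray
    _gene_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- container protocol -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_values(self, gene: str) -> np.ndarray:
        """Per-cell values for one gene (view, do not mutate)."""
        return self.values[self._gene_index[gene]]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row-subset in the given gene order; missing genes raise KeyError."""
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=np.asarray(list(genes), dtype=object),
            cell_ids=self.cell_ids.copy(),
            values=self.values[idx].copy(),
        )

    def with_rows(self, new_gene_ids, new_values) -> "ExpressionMatrix":
        """Return a copy with extra gene rows appended."""
        return ExpressionMatrix(
            gene_ids=np.concatenate([self.gene_ids, np.asarray(new_gene_ids, dtype=object)]),
            cell_ids=self.cell_ids.copy(),
            values=np.vstack([self.values, np.atleast_2d(new_values)]),
        )

    # -- pandas interop -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=df.index.to_numpy(dtype=object),
            cell_ids=df.columns.to_numpy(dtype=object),
            values=df.to_numpy(dtype=np.float64),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.gene_ids.copy(), self.cell_ids.copy(), self.values.copy())
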