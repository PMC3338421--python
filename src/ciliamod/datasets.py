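"""Core data containers shared across the pipeline.

Expression matrices are kept as pandas DataFrames with genes in rows and
samples in columns; gene and sample identifiers live on the index/columns.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Module label used for genes not placed in any module.
UNASSIGNED = -1


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


class DataError(ValueError):
    """Raised when an input matrix or table violates a precondition."""


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix from one experiment.

    Parameters
    ----------
    expr : DataFrame
        Numeric matrix, genes in rows (unique ids), samples in columns.
        Values are assumed already normalized and on a log scale.
    tissue : str
        Tissue label of the experiment (e.g. ``"brain"``).
    dataset_id : str
        Unique identifier of the experiment.
    """

    expr: pd.DataFrame
    tissue: str
    dataset_id: str

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            dups = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids in {self.dataset_id}: {dups[:5]}")
        if self.expr.isna().to_numpy().any():
            raise DataError(f"missing values in dataset {self.dataset_id}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.expr.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr.columns

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def drop_zero_variance(self) -> "ExpressionDataset":
        """Return a copy without constant gene rows (logged, not fatal)."""
        values = self.expr.to_numpy(float)
        keep = values.std(axis=1) > 0
        n_drop = int((~keep).sum())
        if n_drop:
            dropped = self.expr.index[~keep].tolist()
            logger.warning(
                "dataset %s: dropping %d zero-variance genes: %s%s",
                self.dataset_id, n_drop, dropped[:5], "..." if n_drop > 5 else "",
            )
        return ExpressionDataset(self.expr.loc[keep], self.tissue, self.dataset_id)


@dataclass
class ModulePartition:
    """Gene -> module assignment. Module ids are non-negative ints;
    ``UNASSIGNED`` (−1) marks genes outside every module."""

    labels: pd.Series  # index = gene ids, values = int module ids

    @property
    def module_ids(self) -> list[int]:
        ids = sorted(int(m) for m in self.labels.unique() if m != UNASSIGNED)
        return ids

    @property
    def module_sizes(self) -> dict[int, int]:
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return {int(m): int(c) for m, c in counts.sort_index().items()}

    def genes_in(self, module_id: int) -> pd.Index:
        return self.labels.index[self.labels == module_id]

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)


@dataclass
class TissueAtlas:
    """Multi-tissue body-atlas expression matrix.

    ``ciliated_tissues`` are tissues whose samples carry motile cilia;
    ``excluded_tissues`` (typically brain) are dropped before per-gene
    specificity testing because cilia presence there is region-dependent.
    """

    expr: pd.DataFrame  # genes x samples
    sample_tissues: pd.Series  # index = sample ids, values = tissue labels
    ciliated_tissues: list[str] = field(default_factory=list)
    excluded_tissues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = self.expr.columns.difference(self.sample_tissues.index)
        if len(missing):
            raise DataError(f"samples without a tissue label: {list(missing)[:5]}")
        self.sample_tissues = self.sample_tissues.loc[self.expr.columns]

    @property
    def tissues(self) -> list[str]:
        return sorted(self.sample_tissues.unique())

    @property
    def ciliated_sample_mask(self) -> np.ndarray:
        return self.sample_tissues.isin(self.ciliated_tissues).to_numpy()

    @property
    def excluded_sample_mask(self) -> np.ndarray:
        return self.sample_tissues.isin(self.excluded_tissues).to_numpy()

    def drop_excluded(self) -> "TissueAtlas":
        keep = ~self.excluded_sample_mask
        return TissueAtlas(
            self.expr.loc[:, keep],
            self.sample_tissues[keep],
            list(self.ciliated_tissues),
            [],
        )
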