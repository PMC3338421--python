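"""Eigengene summarization and genome-scale module expansion.

Each module detected on the seed gene set is summarized by a module
eigengene (ME): the standardized mean of the z-scored profiles of its 10
most intramodularly connected genes.  Module membership (MM, also called
kME) of any gene is the Pearson correlation of its profile with an ME;
genes across the whole genome are then assigned to the module of their
highest MM, or to none when every MM falls below the assignment threshold.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import UNASSIGNED, DataError, ExpressionDataset, ModulePartition
from .network import correlation_matrix, soft_adjacency

logger = logging.getLogger(__name__)


def _as_expr(x) -> pd.DataFrame:
    if isinstance(x, ExpressionDataset):
        return x.expr
    if isinstance(x, pd.DataFrame):
        return x
    return pd.DataFrame(np.asarray(x, float))


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise DataError("zero-variance profile cannot be z-scored")
    return (values - mean) / sd


def intramodular_connectivity(
    adjacency: pd.DataFrame, partition: ModulePartition
) -> pd.Series:
    """Within-module connectivity k_in(i) = Σ_{j∈M(i), j≠i} a_ij.

    Unassigned genes get k_in = 0.
    """
    missing = partition.labels.index.difference(adjacency.index)
    if len(missing):
        raise DataError(f"genes absent from adjacency: {list(missing)[:5]}")
    a = adjacency.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    labels = partition.labels.reindex(adjacency.index).to_numpy()
    k_in = np.zeros(len(a))
    for module in np.unique(labels):
        if module == UNASSIGNED:
            continue
        idx = np.flatnonzero(labels == module)
        k_in[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    return pd.Series(k_in, index=adjacency.index, name="k_in")


def module_eigengene(
    dataset, module_genes, adjacency: pd.DataFrame | None = None, n_hub: int = 10
) -> tuple[pd.Series, list[str]]:
    """ME of a module: standardized mean of its top-``n_hub`` hub profiles.

    Hubs are the module genes with highest intramodular connectivity (all
    genes if the module is smaller than ``n_hub``); ties at the cutoff are
    broken by gene-id order.  Each hub profile is z-scored across samples,
    the profiles are averaged, and the average is re-standardized to mean 0
    and SD 1.  The sign is fixed so hub genes correlate positively with the
    ME on average.

    Returns the ME (one value per sample) and the hub genes used.
    """
    expr = _as_expr(dataset)
    module_genes = [g for g in module_genes]
    if not module_genes:
        raise DataError("empty module has no eigengene")
    sub = expr.loc[module_genes]
    if adjacency is not None and len(module_genes) > n_hub:
        a = adjacency.loc[module_genes, module_genes].to_numpy(float).copy()
        np.fill_diagonal(a, 0.0)
        k_in = pd.Series(a.sum(axis=1), index=module_genes)
        order = sorted(module_genes, key=lambda g: (-k_in[g], g))
        hubs = order[:n_hub]
        if len(module_genes) > n_hub and k_in[order[n_hub - 1]] == k_in[order[n_hub]]:
            logger.info("hub cutoff tie broken by gene id at rank %d", n_hub)
    else:
        hubs = sorted(module_genes)[: min(n_hub, len(module_genes))]
    z = _zscore_rows(sub.loc[hubs].to_numpy(float))
    me = z.mean(axis=0)
    sd = me.std()
    if sd == 0:
        raise DataError("degenerate module: hub average has zero variance")
    me = (me - me.mean()) / sd
    if np.mean([np.corrcoef(row, me)[0, 1] for row in z]) < 0:
        me = -me
    return pd.Series(me, index=expr.columns, name="ME"), hubs


def module_eigengenes(
    dataset, partition: ModulePartition, adjacency: pd.DataFrame, n_hub: int = 10
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """MEs of every module in a partition: DataFrame (modules x samples)."""
    expr = _as_expr(dataset)
    mes, hub_map = {}, {}
    for module in partition.module_ids:
        genes = [g for g in partition.genes_in(module) if g in expr.index]
        me, hubs = module_eigengene(expr, genes, adjacency, n_hub=n_hub)
        mes[module] = me
        hub_map[module] = hubs
    return pd.DataFrame(mes).T, hub_map


def module_membership(dataset, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """MM_gm = Pearson correlation of every gene profile with every ME.

    ``eigengenes`` has modules in rows and samples in columns, aligned with
    the dataset's samples.
    """
    expr = _as_expr(dataset)
    if not expr.columns.equals(eigengenes.columns):
        raise DataError("samples of dataset and eigengenes are not aligned")
    x = _zscore_rows(expr.to_numpy(float))
    e = _zscore_rows(eigengenes.to_numpy(float))
    mm = x @ e.T / x.shape[1]
    mm = np.clip(mm, -1.0, 1.0)
    return pd.DataFrame(mm, index=expr.index, columns=eigengenes.index)


def expand_partition(membership: pd.DataFrame, threshold: float = 0.5) -> ModulePartition:
    """Assign each gene to its argmax-MM module if that MM reaches the
    threshold, else leave it unassigned.  Ties go to the lower module id."""
    cols = sorted(membership.columns)
    mm = membership[cols].to_numpy(float)
    best = mm.argmax(axis=1)  # first (= lowest module id) wins ties
    best_mm = mm[np.arange(len(mm)), best]
    labels = np.where(best_mm >= threshold,
                      np.asarray(cols, dtype=int)[best], UNASSIGNED)
    return ModulePartition(pd.Series(labels, index=membership.index))


class GenomeScaleExpander(BaseEstimator):
    """Genome-scale re-assignment of genes to seed-set modules.

    scikit-learn style: ``fit(X, y)`` takes the seed expression matrix
    ``X`` of shape ``(n_seed_genes, n_samples)`` (DataFrame indexed by gene
    id) and seed module labels ``y``; ``predict(X_full)`` assigns every
    gene of a genome-scale matrix to a module (−1 = unassigned) and
    ``transform(X_full)`` returns the gene-by-module MM matrix.

    Parameters
    ----------
    power : int
        Soft-threshold power used to rebuild the seed adjacency for
        intramodular connectivity ranking.
    n_hub : int
        Hub genes summarized per eigengene.
    mm_threshold : float
        Minimum MM for assignment; below it a gene joins no module.
    """

    def __init__(self, power: int = 6, n_hub: int = 10, mm_threshold: float = 0.5):
        self.power = power
        self.n_hub = n_hub
        self.mm_threshold = mm_threshold

    def fit(self, X, y, adjacency: pd.DataFrame | None = None):
        expr = _as_expr(X)
        labels = pd.Series(np.asarray(y, dtype=int), index=expr.index)
        partition = ModulePartition(labels)
        if adjacency is None:
            corr = correlation_matrix(expr)
            adjacency = soft_adjacency(corr, self.power)
        self.eigengenes_, self.hub_genes_ = module_eigengenes(
            expr, partition, adjacency, n_hub=self.n_hub
        )
        self.sample_ids_ = expr.columns
        return self

    def transform(self, X) -> pd.DataFrame:
        return module_membership(_as_expr(X), self.eigengenes_)

    def predict(self, X) -> np.ndarray:
        mm = self.transform(X)
        return expand_partition(mm, threshold=self.mm_threshold).labels.to_numpy()

    def expand(self, X) -> tuple[ModulePartition, pd.DataFrame]:
        """Partition and MM matrix for a genome-scale expression matrix."""
        mm = self.transform(X)
        return expand_partition(mm, threshold=self.mm_threshold), mm
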