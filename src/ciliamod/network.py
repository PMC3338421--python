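"""Weighted coexpression network construction and module detection.

One network per dataset: Pearson correlations between all gene pairs, a
soft-threshold power chosen by the scale-free topology criterion, an
unsigned weighted adjacency a_ij = |r_ij|^beta, the topological overlap
matrix (TOM), average-linkage clustering of 1 − TOM, and an adaptive
dendrogram cut into modules of at least ``min_size`` genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .datasets import UNASSIGNED, DataError, ExpressionDataset, ModulePartition

logger = logging.getLogger(__name__)


def subsample_genes(dataset: ExpressionDataset, n: int, seed: int) -> ExpressionDataset:
    """Uniform random gene subset without replacement (original row order kept)."""
    if n > dataset.n_genes:
        raise DataError(
            f"requested {n} genes but dataset {dataset.dataset_id} has {dataset.n_genes}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(dataset.n_genes, size=n, replace=False))
    return ExpressionDataset(dataset.expr.iloc[idx], dataset.tissue, dataset.dataset_id)


def correlation_matrix(dataset: ExpressionDataset | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all pairs of gene expression profiles."""
    expr = dataset.expr if isinstance(dataset, ExpressionDataset) else dataset
    values = expr.to_numpy(float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0].tolist()
        raise DataError(f"zero-variance gene(s): {bad[:5]}")
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log-log degree-distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    are dropped; log10(bin frequency) is regressed on log10(mean bin
    connectivity).  The R² is multiplied by −sign(slope) so that a
    scale-free (decreasing) distribution scores positively.
    """
    k = np.asarray(connectivity, float)
    if len(k) < n_bins:
        raise DataError(f"need at least {n_bins} connectivities, got {len(k)}")
    if (k < 0).any():
        raise DataError("negative connectivity")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if counts[b]:
            means[b] = k[which == b].mean()
    ok = (counts > 0) & (means > 0)
    if ok.sum() < 3:
        raise DataError(f"scale-free fit undefined: only {int(ok.sum())} usable bins")
    x = np.log10(means[ok])
    y = np.log10(counts[ok] / len(k))
    fit = linregress(x, y)
    r2 = fit.rvalue**2
    return float(r2 * (-np.sign(fit.slope))) if fit.slope != 0 else float(r2)


def soft_adjacency(corr: pd.DataFrame | np.ndarray, power: int) -> pd.DataFrame | np.ndarray:
    """Unsigned weighted adjacency a_ij = |r_ij|^power, zero diagonal."""
    if power < 1:
        raise DataError("power must be >= 1")
    is_df = isinstance(corr, pd.DataFrame)
    r = corr.to_numpy(float) if is_df else np.asarray(corr, float)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    if is_df:
        return pd.DataFrame(a, index=corr.index, columns=corr.columns)
    return a


def connectivity(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    a = adjacency.to_numpy(float) if isinstance(adjacency, pd.DataFrame) else np.asarray(adjacency, float)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


@dataclass
class SoftPowerResult:
    power: int
    r2: float
    table: pd.DataFrame  # candidate power, signed R², mean connectivity


def choose_soft_power(
    dataset_or_corr,
    candidates=tuple(range(1, 21)),
    r2_threshold: float = 0.8,
    n_bins: int = 10,
    min_mean_k: float = 1.0,
) -> SoftPowerResult:
    """Smallest candidate power whose signed scale-free R² reaches the
    threshold; if none qualifies, the candidate maximizing the R².

    Powers that leave the network with mean connectivity below
    ``min_mean_k`` are excluded (unless all would be): at such powers the
    adjacency is essentially empty and the apparent scale-free fit reflects
    noise, not topology.  Set ``min_mean_k=0`` to disable the guard.
    """
    if not len(candidates):
        raise DataError("no candidate powers")
    corr = dataset_or_corr
    if isinstance(dataset_or_corr, ExpressionDataset):
        corr = correlation_matrix(dataset_or_corr)
    r = corr.to_numpy(float) if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    rows = []
    abs_r = np.abs(r)
    np.fill_diagonal(abs_r, 0.0)
    for beta in candidates:
        k = (abs_r**beta).sum(axis=1)
        try:
            r2 = scale_free_fit(k, n_bins=n_bins)
        except DataError:
            r2 = -np.inf
        rows.append((int(beta), r2, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_k"])
    admissible = table[table.mean_k >= min_mean_k]
    if not len(admissible):
        admissible = table
    qualifying = admissible[admissible.signed_r2 >= r2_threshold]
    row = (qualifying.iloc[0] if len(qualifying)
           else admissible.loc[admissible.signed_r2.idxmax()])
    return SoftPowerResult(int(row.power), float(row.signed_r2), table)


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap TO_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj; diagonal set to 1."""
    is_df = isinstance(adjacency, pd.DataFrame)
    a = adjacency.to_numpy(float) if is_df else np.asarray(adjacency, float)
    a = a.copy()
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise DataError("adjacency must be square and symmetric")
    off = a[~np.eye(len(a), dtype=bool)]
    if len(off) and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
        raise DataError("off-diagonal adjacency must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # diagonal of a is 0, so u=i and u=j terms vanish
    min_k = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (min_k + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    if is_df:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def average_linkage_dendrogram(dissimilarity: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree of a symmetric dissimilarity
    matrix with zero diagonal; scipy linkage-matrix format."""
    d = (dissimilarity.to_numpy(float) if isinstance(dissimilarity, pd.DataFrame)
         else np.asarray(dissimilarity, float))
    if not np.allclose(d, d.T, atol=1e-10):
        raise DataError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise DataError("dissimilarity diagonal must be zero")
    condensed = squareform(d, checks=False)
    return linkage(condensed, method="average")


# ---------------------------------------------------------------------------
# adaptive dendrogram cut
# ---------------------------------------------------------------------------

def dynamic_tree_cut(
    Z: np.ndarray,
    min_size: int = 10,
    deep_split: bool = True,
    cut_frac: float = 0.95,
    gap_frac: float = 0.10,
    gene_ids=None,
) -> ModulePartition:
    """Adaptive cut of an average-linkage dendrogram into modules.

    Two stages.  First, a static cut at ``cut_frac`` of the root height
    separates tight branches (coexpression modules merge low) from the
    high-merging agglomerate of mutually uncorrelated genes; components of
    at least ``min_size`` leaves become candidate modules, the rest is
    unassigned.  If no component qualifies, the tree is treated as one
    undifferentiated cluster and all leaves form a single module (provided
    ``min_size`` allows) — a dendrogram with no height structure carries no
    evidence for more than one module.

    Second, with ``deep_split`` enabled, each candidate module's subtree is
    recursively decomposed: a merge is a real module boundary when both
    branches hold at least ``min_size`` leaves and both are *distinct* —
    their stripped core tops sit more than ``gap_frac`` of the root height
    below the joining height.  (A branch's core top is the height of its
    topmost merge joining two sub-branches of at least ``min_size`` leaves
    each; straggler attachments are stripped so single genes chaining onto
    a branch do not mask the boundary.)  Straggler chains attaching below
    an undivided branch are absorbed into it; stragglers above a divided
    branch are left unassigned.  Disabling ``deep_split`` skips this stage,
    so enabling it can only refine the partition and the module count is
    monotone in the flag.
    """
    Z = np.asarray(Z, float)
    n = len(Z) + 1
    if gene_ids is None:
        gene_ids = pd.RangeIndex(n)
    gene_ids = pd.Index(gene_ids)
    labels = np.full(n, UNASSIGNED, dtype=int)
    if min_size > n or n < 2:
        return ModulePartition(pd.Series(labels, index=gene_ids))

    root_height = float(Z[:, 2].max())
    if root_height <= 0:  # all leaves identical: one module
        labels[:] = 0
        return ModulePartition(pd.Series(labels, index=gene_ids))
    min_gap = gap_frac * root_height
    h_cut = cut_frac * root_height

    left = Z[:, 0].astype(int)
    right = Z[:, 1].astype(int)
    heights = Z[:, 2]

    counts = np.ones(2 * n - 1, dtype=int)
    top_h = np.zeros(2 * n - 1)  # node's own merge height (0 for leaves)
    core_top = np.zeros(2 * n - 1)
    for m in range(n - 1):
        node = n + m
        l, r = left[m], right[m]
        counts[node] = counts[l] + counts[r]
        top_h[node] = heights[m]
        if counts[l] >= min_size and counts[r] >= min_size:
            core_top[node] = heights[m]
        else:  # straggler attachment: core continues through the big branch
            big = l if counts[l] >= counts[r] else r
            core_top[node] = core_top[big]

    def eff_top(v: int) -> float:
        # a branch with no developed core is measured by its own top merge
        return core_top[v] if core_top[v] > 0 else top_h[v]

    def leaves_of(node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                m = v - n
                stack.extend((left[m], right[m]))
        return out

    # --- stage 1: static components below the cut height -------------------
    # component roots: nodes whose own merge is <= h_cut but whose parent
    # merge (if any) is above it
    parent_h = np.full(2 * n - 1, np.inf)
    for m in range(n - 1):
        parent_h[left[m]] = heights[m]
        parent_h[right[m]] = heights[m]
    node_h = np.concatenate([np.zeros(n), heights])
    comp_roots = [v for v in range(2 * n - 1)
                  if node_h[v] <= h_cut < parent_h[v]]

    candidates = [v for v in comp_roots if counts[v] >= min_size]
    unassigned: list[int] = []
    for v in comp_roots:
        if counts[v] < min_size:
            unassigned.extend(leaves_of(v))

    if not candidates:
        # no height structure below the cut: one undifferentiated cluster
        labels[:] = 0
        return ModulePartition(pd.Series(labels, index=gene_ids))

    # --- stage 2: recursive decomposition of each candidate ----------------
    def cut(node: int) -> tuple[list[list[int]], list[int]]:
        """Return (modules as leaf-index lists, unassigned leaf indices)."""
        if node < n or counts[node] < 2 * min_size:
            return [leaves_of(node)], []
        m = node - n
        l, r = left[m], right[m]
        h = heights[m]
        big, small = (l, r) if counts[l] >= counts[r] else (r, l)

        if counts[small] >= min_size:
            distinct = (h - eff_top(l) > min_gap) and (h - eff_top(r) > min_gap)
            if distinct:
                mods_l, un_l = cut(l)
                mods_r, un_r = cut(r)
                return mods_l + mods_r, un_l + un_r
            return [leaves_of(node)], []

        # straggler chain: descend into the big branch and absorb if whole
        mods, un = cut(big)
        stragglers = leaves_of(small)
        if len(mods) == 1 and not un:
            mods[0].extend(stragglers)
            return mods, []
        return mods, un + stragglers

    modules: list[list[int]] = []
    for v in candidates:
        if deep_split:
            mods, un = cut(v)
        else:
            mods, un = [leaves_of(v)], []
        for leaves in mods:
            if len(leaves) >= min_size:
                modules.append(leaves)
            else:
                unassigned.extend(leaves)
        unassigned.extend(un)

    if not modules:  # deep stage dissolved everything: fall back to stage 1
        modules = [leaves_of(v) for v in candidates]

    # deterministic module ids: decreasing size, ties by smallest leaf index
    modules.sort(key=lambda lv: (-len(lv), min(lv)))
    for mid, leaves in enumerate(modules):
        labels[leaves] = mid
    return ModulePartition(pd.Series(labels, index=gene_ids))


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, ClusterMixin  # noqa: E402


class CoexpressionModules(ClusterMixin, BaseEstimator):
    """Weighted coexpression network construction and module detection.

    Follows the scikit-learn clusterer contract: ``fit(X)`` with ``X`` of
    shape ``(n_genes, n_samples)`` (genes are the objects being clustered)
    populates ``labels_`` with module ids (−1 = unassigned).

    Parameters
    ----------
    power_candidates : sequence of int
        Candidate soft-threshold powers.
    r2_threshold : float
        Scale-free topology R² target for power selection.
    n_bins : int
        Connectivity histogram bins for the scale-free fit.
    min_module_size : int
        Smallest reported module.
    deep_split : bool
        Aggressiveness of the adaptive dendrogram cut.

    Attributes
    ----------
    power_ : int
    scale_free_r2_ : float
    corr_, adjacency_, tom_ : ndarray
    connectivity_ : ndarray
    linkage_ : ndarray, scipy linkage matrix of 1 − TOM
    labels_ : ndarray of module ids per gene
    module_sizes_ : dict
    """

    def __init__(self, power_candidates=tuple(range(1, 21)), r2_threshold=0.8,
                 n_bins=10, min_module_size=10, deep_split=True):
        self.power_candidates = power_candidates
        self.r2_threshold = r2_threshold
        self.n_bins = n_bins
        self.min_module_size = min_module_size
        self.deep_split = deep_split

    def fit(self, X, y=None):
        if isinstance(X, ExpressionDataset):
            expr = X.expr
        elif isinstance(X, pd.DataFrame):
            expr = X
        else:
            expr = pd.DataFrame(np.asarray(X, float))
        ds = ExpressionDataset(expr, tissue="", dataset_id="fit")
        corr = correlation_matrix(ds)
        sp = choose_soft_power(corr, candidates=tuple(self.power_candidates),
                               r2_threshold=self.r2_threshold, n_bins=self.n_bins)
        adj = soft_adjacency(corr.to_numpy(), sp.power)
        tom = topological_overlap(adj)
        Z = average_linkage_dendrogram(1.0 - tom)
        partition = dynamic_tree_cut(Z, min_size=self.min_module_size,
                                     deep_split=self.deep_split,
                                     gene_ids=expr.index)
        self.gene_ids_ = expr.index
        self.power_ = sp.power
        self.scale_free_r2_ = sp.r2
        self.power_table_ = sp.table
        self.corr_ = corr.to_numpy()
        self.adjacency_ = adj
        self.connectivity_ = connectivity(adj)
        self.tom_ = tom
        self.linkage_ = Z
        self.partition_ = partition
        self.labels_ = partition.labels.to_numpy()
        self.module_sizes_ = partition.module_sizes
        return self
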