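"""Ciliary-module identification, cross-dataset consensus and novelty.

Per dataset, the ciliary module is the module most significantly enriched
in golden-standard ciliary markers (one-sided Fisher's exact test).  The
consensus signature collects genes that belong to the ciliary module in at
least ``min_tissues`` tissues and at least ``min_datasets`` datasets; its
false-discovery rate is estimated by size-preserving random replacement of
the per-dataset modules.  Signature genes are stratified by prior study
evidence into known (I), previously proposed (II) and novel (III).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datasets import DataError, ModulePartition

logger = logging.getLogger(__name__)


def hypergeometric_enrichment(module_genes, markers, universe) -> float:
    """One-sided Fisher's exact test for marker over-representation.

    p = P(X >= observed overlap) with X ~ Hypergeometric(N=|universe|,
    K=|markers|, n=|module|).
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    module = set(module_genes) & universe
    marker = set(markers) & universe
    overlap = len(module & marker)
    return float(hypergeom.sf(overlap - 1, len(universe), len(marker), len(module)))


def identify_ciliary_module(
    partition: ModulePartition, markers, universe=None, alpha: float = 1e-3
):
    """Module with the smallest marker-enrichment p-value, if below alpha.

    Returns ``(module_id, p, overlap)`` or ``(None, best_p, best_overlap)``
    when no module reaches ``alpha``.  Ties on p go to the larger marker
    overlap, then to the lower module id.
    """
    if universe is None:
        universe = set(partition.labels.index)
    universe = set(universe)
    marker = set(markers) & universe
    best = (None, 1.0, 0)
    for module in partition.module_ids:
        genes = set(partition.genes_in(module)) & universe
        if not genes:
            continue
        p = hypergeometric_enrichment(genes, marker, universe)
        overlap = len(genes & marker)
        if (p, -overlap, module) < (best[1], -best[2], math.inf if best[0] is None else best[0]):
            best = (module, p, overlap)
    module, p, overlap = best
    if p < alpha:
        return module, p, overlap
    return None, p, overlap


def pairwise_module_overlap(
    partition_a: ModulePartition, partition_b: ModulePartition, universe
) -> pd.DataFrame:
    """All module pairs of two partitions: overlap size, percent of the
    smaller module, and Fisher's exact p on the shared universe."""
    universe = set(universe)
    rows = []
    for ma in partition_a.module_ids:
        genes_a = set(partition_a.genes_in(ma)) & universe
        if not genes_a:
            logger.info("module %s of partition A empty on shared universe; skipped", ma)
            continue
        for mb in partition_b.module_ids:
            genes_b = set(partition_b.genes_in(mb)) & universe
            if not genes_b:
                continue
            shared = len(genes_a & genes_b)
            p = float(hypergeom.sf(shared - 1, len(universe), len(genes_b), len(genes_a)))
            rows.append((ma, mb, shared,
                         percent_overlap(shared, min(len(genes_a), len(genes_b))), p))
    return pd.DataFrame(rows, columns=["module_a", "module_b", "n_shared",
                                       "percent_of_smaller", "p_value"])


def percent_overlap(shared: int, total: int) -> int:
    """Integer percentage round(100*shared/total), half away from zero."""
    if total == 0:
        raise DataError("total must be positive")
    if not (0 <= shared <= total):
        raise DataError("shared must lie in [0, total]")
    return int(math.floor(100.0 * shared / total + 0.5))


@dataclass
class MembershipTable:
    """Gene x dataset ciliary-module membership with availability masks."""

    membership: pd.DataFrame  # bool, genes x datasets
    availability: pd.DataFrame  # bool, genes x datasets (gene measured?)
    dataset_tissues: dict[str, str]
    mm_ciliary: pd.DataFrame | None = None  # MM with the ciliary ME, same shape

    def __post_init__(self) -> None:
        unmapped = [d for d in self.membership.columns if d not in self.dataset_tissues]
        if unmapped:
            raise DataError(f"datasets without tissue label: {unmapped}")
        bad = (self.membership & ~self.availability).to_numpy().any()
        if bad:
            raise DataError("membership=True where gene is not available")


@dataclass
class ConsensusSignature:
    genes: list[str]
    support: pd.DataFrame  # per gene: n_datasets, n_tissues
    min_tissues: int
    min_datasets: int
    fdr: float | None = None
    categories: dict[str, str] = field(default_factory=dict)


def build_consensus(
    table: MembershipTable, min_tissues: int = 2, min_datasets: int = 4
) -> ConsensusSignature:
    """Genes in the ciliary module in >= ``min_tissues`` tissues and,
    simultaneously, >= ``min_datasets`` datasets (counting only datasets
    where the gene is measured)."""
    member = table.membership.to_numpy(bool)
    tissues = np.asarray([table.dataset_tissues[d] for d in table.membership.columns])
    n_datasets = member.sum(axis=1)
    tissue_names = np.unique(tissues)
    per_tissue = np.stack([member[:, tissues == t].any(axis=1) for t in tissue_names], axis=1)
    n_tissues = per_tissue.sum(axis=1)
    included = (n_tissues >= min_tissues) & (n_datasets >= min_datasets)
    support = pd.DataFrame(
        {"n_datasets": n_datasets, "n_tissues": n_tissues, "in_signature": included},
        index=table.membership.index,
    )
    genes = support.index[included].tolist()
    return ConsensusSignature(genes, support, min_tissues, min_datasets)


def permutation_fdr(
    module_sizes: dict[str, int],
    universes: dict[str, list],
    dataset_tissues: dict[str, str],
    min_tissues: int = 2,
    min_datasets: int = 4,
    true_size: int | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[float | None, float]:
    """Size-preserving random-replacement FDR of the consensus signature.

    Each iteration replaces the ciliary module of every dataset by a
    uniform random gene set of the same size drawn from that dataset's
    available universe, rebuilds the consensus, and records its size.  The
    FDR is the mean permuted signature size divided by ``true_size``.

    Returns ``(fdr, mean_permuted_size)``; ``fdr`` is None (with a warning)
    when ``true_size`` is 0 or not supplied.
    """
    rng = np.random.default_rng(seed)
    datasets = sorted(module_sizes)
    all_genes = sorted({g for d in datasets for g in universes[d]})
    gene_index = {g: i for i, g in enumerate(all_genes)}
    tissues = np.asarray([dataset_tissues[d] for d in datasets])
    tissue_names = np.unique(tissues)
    universe_idx = {d: np.asarray([gene_index[g] for g in universes[d]]) for d in datasets}

    sizes = np.empty(n_iter, dtype=int)
    member = np.zeros((len(all_genes), len(datasets)), dtype=bool)
    for it in range(n_iter):
        member[:] = False
        for j, d in enumerate(datasets):
            size = min(module_sizes[d], len(universe_idx[d]))
            pick = rng.choice(universe_idx[d], size=size, replace=False)
            member[pick, j] = True
        n_ds = member.sum(axis=1)
        per_tissue = np.stack(
            [member[:, tissues == t].any(axis=1) for t in tissue_names], axis=1
        )
        ok = (per_tissue.sum(axis=1) >= min_tissues) & (n_ds >= min_datasets)
        sizes[it] = int(ok.sum())
    mean_size = float(sizes.mean())
    if not true_size:
        logger.warning("true consensus signature size is 0; FDR undefined (NA)")
        return None, mean_size
    return mean_size / true_size, mean_size


def categorize_novelty(genes, evidence: pd.DataFrame) -> dict[str, str]:
    """Stratify genes by prior study evidence.

    I — high confidence in >=1 study, or medium confidence in >=2 studies;
    II — medium confidence in exactly one study, or low confidence in any
    number of studies; III — no prior evidence.  Genes absent from the
    evidence table are treated as having zero counts (logged).
    """
    if (evidence[["n_high", "n_medium", "n_low"]] < 0).to_numpy().any():
        raise DataError("negative evidence counts")
    out = {}
    missing = []
    for g in genes:
        if g in evidence.index:
            high, medium, low = (int(evidence.at[g, c]) for c in
                                 ("n_high", "n_medium", "n_low"))
        else:
            high = medium = low = 0
            missing.append(g)
        if high >= 1 or medium >= 2:
            out[g] = "I"
        elif medium == 1 or low >= 1:
            out[g] = "II"
        else:
            out[g] = "III"
    if missing:
        logger.info("%d genes absent from evidence table treated as no-evidence: %s%s",
                    len(missing), missing[:5], "..." if len(missing) > 5 else "")
    return out


def localization_summary(
    loc_classes: dict[str, str], categories: dict[str, str]
) -> pd.DataFrame:
    """Counts and integer percentages of localization classes (A/B/C) per
    novelty category, with a Total row.  Row percentages are of the row
    total, rounded half away from zero; empty rows get NA percentages."""
    genes = sorted(set(loc_classes) & set(categories))
    class_names = ["A", "B", "C"]
    cat_names = ["I", "II", "III"]
    rows = {}
    for cat in cat_names + ["total"]:
        sel = [g for g in genes if cat == "total" or categories[g] == cat]
        counts = {c: sum(1 for g in sel if loc_classes[g] == c) for c in class_names}
        total = sum(counts.values())
        row = {}
        for c in class_names:
            row[f"n_{c}"] = counts[c]
            row[f"pct_{c}"] = (percent_overlap(counts[c], total)
                               if total else float("nan"))
        row["n_total"] = total
        rows[cat] = row
    return pd.DataFrame(rows).T
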