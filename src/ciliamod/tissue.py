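"""Tissue ranking and the mean-rank permutation test of ciliated-tissue
up-regulation.

Atlas expression is Z-scored per gene; tissues are ranked by the mean
signature Z.  Per gene, samples are ranked ascending by expression (high
expression = high rank, ties get average ranks); the statistic is the mean
rank of ciliated samples and the upper-tail p-value comes from random
re-draws of the ciliated sample set.  Brain (or any configured tissue) is
excluded beforehand because cilia presence there is region-dependent.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .datasets import DataError, TissueAtlas

logger = logging.getLogger(__name__)


def zscore_by_gene(atlas: TissueAtlas) -> TissueAtlas:
    """Z-score each gene row across retained samples; constant genes are
    dropped with a warning."""
    values = atlas.expr.to_numpy(float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise DataError("all genes constant; cannot Z-score")
    if (~keep).sum():
        logger.warning("dropping %d constant genes before Z-scoring", int((~keep).sum()))
    values = values[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
    return TissueAtlas(
        pd.DataFrame(z, index=atlas.expr.index[keep], columns=atlas.expr.columns),
        atlas.sample_tissues,
        list(atlas.ciliated_tissues),
        list(atlas.excluded_tissues),
    )


def rank_tissues(atlas: TissueAtlas, signature_genes) -> pd.DataFrame:
    """Tissues ordered by mean signature-gene Z over their samples
    (descending).  Excluded tissues are not ranked."""
    genes = [g for g in signature_genes if g in atlas.expr.index]
    if not genes:
        raise DataError("no signature gene present in the atlas")
    keep = ~atlas.excluded_sample_mask
    expr = atlas.expr.loc[genes].loc[:, keep]
    tissues = atlas.sample_tissues[keep]
    means = expr.mean(axis=0).groupby(tissues).mean()
    n_samples = tissues.value_counts()
    out = pd.DataFrame({
        "mean_signature_z": means,
        "n_samples": n_samples.loc[means.index],
        "ciliated": [t in atlas.ciliated_tissues for t in means.index],
    })
    out = out.sort_values("mean_signature_z", ascending=False)
    out.index.name = "tissue"
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def mean_rank_test(
    values,
    ciliated_mask,
    n_perm: int = 10**6,
    seed: int = 0,
    add_one: bool = True,
    _rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation p-value for up-regulation in ciliated samples.

    Samples are ranked ascending (ties -> average ranks); the statistic is
    the mean rank of ciliated samples.  The p-value is the upper-tail
    fraction of ``n_perm`` random re-draws of the ciliated set attaining a
    statistic at least as large, add-one corrected by default:
    p = (1 + #{permuted >= observed}) / (1 + n_perm).

    Returns ``(observed mean rank, p)``.
    """
    values = np.asarray(values, float)
    mask = np.asarray(ciliated_mask, bool)
    n = len(values)
    m = int(mask.sum())
    if m == 0 or n == 0:
        raise DataError("need at least one ciliated and one sample overall")
    ranks = rankdata(values)
    observed = float(ranks[mask].mean())
    if m == n:
        return observed, 1.0
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(2e7) // max(n, 1)))
    done = 0
    tol = 1e-9
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        stats = ranks[idx].mean(axis=1)
        exceed += int((stats >= observed - tol).sum())
        done += b
    if add_one:
        return observed, (exceed + 1) / (n_perm + 1)
    return observed, exceed / n_perm


def mean_rank_test_table(
    atlas: TissueAtlas,
    genes=None,
    n_perm: int = 10**5,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene mean-rank tests over an atlas (excluded samples dropped),
    with BH adjustment.  Independent random substreams per gene keep the
    tests exchangeable and the whole table reproducible from ``seed``."""
    retained = atlas.drop_excluded()
    mask = retained.ciliated_sample_mask
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise DataError("need ciliated and non-ciliated samples after exclusions")
    if genes is None:
        genes = retained.expr.index
    genes = [g for g in genes if g in retained.expr.index]
    streams = np.random.SeedSequence([seed, 77]).spawn(len(genes))
    rows = []
    for g, ss in zip(genes, streams):
        rng = np.random.default_rng(ss)
        stat, p = mean_rank_test(retained.expr.loc[g].to_numpy(), mask,
                                 n_perm=n_perm, _rng=rng)
        rows.append((g, stat, p))
    out = pd.DataFrame(rows, columns=["gene", "mean_rank", "p"]).set_index("gene")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_upregulated(
    results: pd.DataFrame, categories: dict[str, str], alpha: float = 0.05
) -> pd.Series:
    """Percentage of genes significantly up-regulated in ciliated tissues,
    per novelty category (NaN for empty categories)."""
    cats = pd.Series({g: categories.get(g) for g in results.index})
    out = {}
    for cat in sorted({c for c in cats.dropna().unique()}):
        sel = results.loc[cats[cats == cat].index]
        out[cat] = 100.0 * (sel["p_adj"] < alpha).mean() if len(sel) else float("nan")
    sel = results.loc[cats.dropna().index]
    out["all"] = 100.0 * (sel["p_adj"] < alpha).mean() if len(sel) else float("nan")
    return pd.Series(out, name="pct_significant")
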