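"""Hub-based differential coexpression of the ciliary module between tissues.

A gene is a ciliary-module *hub* in a dataset when it belongs to the module
and its module membership reaches ``tau`` (default 0.75).  Candidates for
tissue-restricted coexpression are hubs in more than half of one tissue's
datasets that are module members nowhere else; the MM difference across
tissues is tested by one-way ANOVA on Fisher-transformed MM values, BH
corrected, and validated by expression differences in the body atlas
(focal tissue vs the union of the others, pooled-variance t-test).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DataError, TissueAtlas
from .tissue import bh_adjust

logger = logging.getLogger(__name__)


def call_hubs(
    membership: pd.DataFrame, mm_ciliary: pd.DataFrame, tau: float = 0.75
) -> pd.DataFrame:
    """Hub flag per gene x dataset: module member AND MM_ciliary >= tau."""
    if not membership.index.equals(mm_ciliary.index) or not membership.columns.equals(
        mm_ciliary.columns
    ):
        raise DataError("membership and MM tables are not aligned")
    return membership.astype(bool) & (mm_ciliary >= tau)


def screen_candidates(
    hubs: pd.DataFrame,
    membership: pd.DataFrame,
    availability: pd.DataFrame,
    dataset_tissues: dict[str, str],
) -> pd.DataFrame:
    """Genes that are hubs in a strict majority of one tissue's datasets
    and ciliary-module members in no dataset of any other tissue.

    Availability-masked datasets are excluded from denominators.  Returns a
    DataFrame with the focal tissue and per-tissue hub/membership counts.
    """
    tissues = np.asarray([dataset_tissues[d] for d in hubs.columns])
    tissue_names = sorted(set(tissues))
    if len(tissue_names) < 2:
        raise DataError("need at least two tissues to screen candidates")
    rows = []
    hub_arr = hubs.to_numpy(bool)
    mem_arr = membership.to_numpy(bool)
    avail_arr = availability.to_numpy(bool)
    for i, gene in enumerate(hubs.index):
        for t in tissue_names:
            in_t = tissues == t
            n_avail = int(avail_arr[i, in_t].sum())
            if n_avail == 0:
                continue
            n_hub = int(hub_arr[i, in_t].sum())
            member_elsewhere = bool(mem_arr[i, ~in_t].any())
            if n_hub * 2 > n_avail and not member_elsewhere:
                rows.append((gene, t, n_hub, n_avail))
    return pd.DataFrame(rows, columns=["gene", "focal_tissue", "n_hub_datasets",
                                       "n_available_datasets"])


def fisher_z(r):
    """Fisher transform z = atanh(r); |r| within 1e-15 of 1 is clamped."""
    r = np.asarray(r, float)
    if (np.abs(r) > 1).any():
        raise DataError("correlations must lie in [-1, 1]")
    bound = 1 - 1e-15
    if (np.abs(r) >= bound).any():
        logger.info("clamping %d correlation(s) at |r| = 1 - 1e-15",
                    int((np.abs(r) >= bound).sum()))
    clipped = np.clip(r, -bound, bound)
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def anova_differential(mm_by_tissue: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA on Fisher-transformed MM values grouped
    by tissue.  Returns (F, p); (nan, nan) when the test is undefined."""
    groups = [fisher_z(np.asarray(v, float)) for v in mm_by_tissue.values()
              if len(v) > 0]
    if len(groups) < 2:
        raise DataError("ANOVA needs at least two non-empty groups")
    flat = np.concatenate(groups)
    if len(flat) <= len(groups) or np.allclose(flat, flat[0]):
        if np.allclose(flat, flat[0]):
            return 0.0, 1.0
        logger.warning("ANOVA undefined: no within-group degrees of freedom")
        return float("nan"), float("nan")
    within_var = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within_var == 0:
        means = [g.mean() for g in groups]
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        logger.warning("ANOVA undefined: zero within-group variance")
        return float("nan"), float("nan")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass
class DifferentialCoexpressionResult:
    table: pd.DataFrame  # gene, focal tissue, per-tissue mean MM, F, p, p_adj
    alpha: float


def test_candidates(
    candidates: pd.DataFrame,
    mm_ciliary: pd.DataFrame,
    availability: pd.DataFrame,
    dataset_tissues: dict[str, str],
    alpha: float = 0.05,
) -> DifferentialCoexpressionResult:
    """ANOVA (Fisher-transformed MM across tissues) per candidate, BH over
    the candidate list.  MM values come from every available dataset,
    member or not."""
    tissues = np.asarray([dataset_tissues[d] for d in mm_ciliary.columns])
    tissue_names = sorted(set(tissues))
    rows = []
    for _, cand in candidates.iterrows():
        gene = cand["gene"]
        avail = availability.loc[gene].to_numpy(bool)
        groups = {}
        for t in tissue_names:
            sel = (tissues == t) & avail
            vals = mm_ciliary.loc[gene].to_numpy(float)[sel]
            groups[t] = vals[~np.isnan(vals)]  # datasets with no ciliary module carry no MM
        f, p = anova_differential(groups)
        row = {"gene": gene, "focal_tissue": cand["focal_tissue"], "F": f, "p": p}
        for t in tissue_names:
            row[f"mean_mm_{t}"] = float(np.mean(groups[t])) if len(groups[t]) else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        valid = table["p"].notna()
        table["p_adj"] = np.nan
        if valid.any():
            table.loc[valid, "p_adj"] = bh_adjust(table.loc[valid, "p"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
    return DifferentialCoexpressionResult(table, alpha)


def select_marker_positive_samples(
    atlas: TissueAtlas, markers, tissue: str, n: int = 10
) -> list[str]:
    """The ``n`` samples of ``tissue`` with highest mean marker Z-score
    (ties by sample-id order); all samples with a warning if fewer exist."""
    markers = [g for g in markers if g in atlas.expr.index]
    if not markers:
        raise DataError("no marker present in the atlas")
    in_tissue = atlas.sample_tissues == tissue
    samples = atlas.expr.columns[in_tissue]
    if len(samples) == 0:
        raise DataError(f"atlas has no samples of tissue {tissue!r}")
    expr = atlas.expr.loc[markers, samples].to_numpy(float)
    z = (expr - expr.mean(axis=1, keepdims=True)) / np.where(
        expr.std(axis=1, keepdims=True) == 0, 1.0, expr.std(axis=1, keepdims=True)
    )
    score = pd.Series(z.mean(axis=0), index=samples)
    if len(samples) < n:
        logger.warning("tissue %r has only %d samples (< %d); using all",
                       tissue, len(samples), n)
        n = len(samples)
    # stable sort: descending score, ties by sample id order
    order = score.to_frame("score").assign(_id=np.arange(len(score)))
    order = order.sort_values(["score", "_id"], ascending=[False, True], kind="stable")
    return order.index[:n].tolist()


def validate_tissue_expression(
    atlas: TissueAtlas,
    gene: str,
    focal_samples,
    other_samples,
) -> float:
    """Two-sided pooled-variance t-test of a gene's Z-normalized expression
    in the focal-tissue samples vs the union of the other tissues'."""
    if len(focal_samples) < 2 or len(other_samples) < 2:
        raise DataError("need at least two samples per side")
    x = atlas.expr.loc[gene, list(focal_samples)].to_numpy(float)
    y = atlas.expr.loc[gene, list(other_samples)].to_numpy(float)
    if x.std() == 0 and y.std() == 0:
        return 1.0 if x.mean() == y.mean() else float("nan")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.pvalue)
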