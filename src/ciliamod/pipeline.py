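"""End-to-end orchestration: per-dataset networks, ciliary-module
identification, genome-scale expansion, consensus signature with
permutation FDR, tissue specificity, and differential coexpression.

Every stage draws its randomness from a sub-seed derived from the global
seed by a fixed offset, so changing e.g. the number of FDR iterations does
not perturb network construction.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cons
from . import diffcoexp as dc
from . import io as cio
from . import tissue as ts
from .datasets import UNASSIGNED, DataError, ExpressionDataset, TissueAtlas
from .expansion import GenomeScaleExpander
from .network import CoexpressionModules, subsample_genes
from .simulate import (GeneratorConfig, simulate_body_atlas, simulate_collection,
                       simulate_evidence_table)

logger = logging.getLogger(__name__)

# fixed sub-seed offsets per stage
_SEED_SUBSAMPLE = 11
_SEED_FDR = 23
_SEED_TISSUE = 37


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the conventional defaults."""

    seed_gene_count: int = 4000
    min_module_size: int = 10
    deep_split: bool = True
    r2_threshold: float = 0.8
    power_candidates: tuple[int, ...] = tuple(range(1, 21))
    n_hub: int = 10
    mm_threshold: float = 0.5
    enrichment_alpha: float = 1e-3
    min_tissues: int = 2
    min_datasets: int = 4
    fdr_iterations: int = 1000
    hub_tau: float = 0.75
    n_permutations: int = 10**6
    bh_alpha: float = 0.05
    n_marker_positive: int = 10
    seed: int = 0

    # file-based runs
    dataset_paths: list = field(default_factory=list)  # (path, tissue) pairs
    marker_gmt: str | None = None
    evidence_tsv: str | None = None
    atlas_expr: str | None = None
    atlas_sample_sheet: str | None = None
    ciliated_tissues: list = field(default_factory=list)
    excluded_tissues: list = field(default_factory=list)

    def to_yaml(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.power_candidates = tuple(cfg.power_candidates)
        return cfg


@dataclass
class DatasetResult:
    dataset_id: str
    tissue: str
    n_modules: int
    power: int
    scale_free_r2: float
    ciliary_module: int | None
    ciliary_size: int  # genome-scale size (0 when not detected)
    enrichment_p: float
    marker_overlap: int
    expanded_labels: pd.Series
    mm_ciliary: pd.Series | None
    seed_labels: pd.Series


@dataclass
class RunReport:
    per_dataset: pd.DataFrame
    dataset_results: list[DatasetResult]
    membership: cons.MembershipTable
    signature: cons.ConsensusSignature
    tissue_ranking: pd.DataFrame | None
    specificity: pd.DataFrame | None
    upregulated_pct: pd.Series | None
    diffcoexp: pd.DataFrame
    config: PipelineConfig


def analyze_dataset(
    dataset: ExpressionDataset, markers, config: PipelineConfig
) -> DatasetResult:
    """Stages B-C for one dataset: network, modules, expansion, ciliary id."""
    ds = dataset.drop_zero_variance()
    n_seed = min(config.seed_gene_count, ds.n_genes)
    seed_ds = subsample_genes(ds, n_seed, seed=config.seed + _SEED_SUBSAMPLE)

    net = CoexpressionModules(
        power_candidates=config.power_candidates,
        r2_threshold=config.r2_threshold,
        min_module_size=config.min_module_size,
        deep_split=config.deep_split,
    ).fit(seed_ds)

    expander = GenomeScaleExpander(
        power=net.power_, n_hub=config.n_hub, mm_threshold=config.mm_threshold
    )
    adj = pd.DataFrame(net.adjacency_, index=seed_ds.gene_ids, columns=seed_ds.gene_ids)
    if net.partition_.n_modules == 0:
        logger.warning("dataset %s: no modules detected", ds.dataset_id)
        empty = pd.Series(UNASSIGNED, index=ds.gene_ids)
        return DatasetResult(ds.dataset_id, ds.tissue, 0, net.power_,
                             net.scale_free_r2_, None, 0, 1.0, 0, empty, None,
                             net.partition_.labels)
    expander.fit(seed_ds.expr, net.labels_, adjacency=adj)
    expanded, mm = expander.expand(ds.expr)

    module, p, overlap = cons.identify_ciliary_module(
        expanded, markers, universe=ds.gene_ids, alpha=config.enrichment_alpha
    )
    if module is None:
        logger.info("dataset %s: no ciliary module (best p=%.3g)", ds.dataset_id, p)
        mm_cil = None
        size = 0
    else:
        mm_cil = mm[module]
        size = int((expanded.labels == module).sum())
    return DatasetResult(ds.dataset_id, ds.tissue, expanded.n_modules, net.power_,
                         net.scale_free_r2_, module, size, p, overlap,
                         expanded.labels, mm_cil, net.partition_.labels)


def build_membership(
    results: list[DatasetResult], all_genes: pd.Index
) -> cons.MembershipTable:
    """Gene x dataset membership/availability/MM tables over the union of
    genes; datasets without a ciliary module contribute availability only."""
    ids = [r.dataset_id for r in results]
    member = pd.DataFrame(False, index=all_genes, columns=ids)
    avail = pd.DataFrame(False, index=all_genes, columns=ids)
    mm = pd.DataFrame(np.nan, index=all_genes, columns=ids)
    for r in results:
        avail.loc[r.expanded_labels.index, r.dataset_id] = True
        if r.ciliary_module is not None:
            in_mod = r.expanded_labels.index[r.expanded_labels == r.ciliary_module]
            member.loc[in_mod, r.dataset_id] = True
            mm.loc[r.mm_ciliary.index, r.dataset_id] = r.mm_ciliary
    tissue_map = {r.dataset_id: r.tissue for r in results}
    return cons.MembershipTable(member, avail, tissue_map, mm_ciliary=mm)


def run_collection(
    datasets: list[ExpressionDataset],
    markers,
    evidence: pd.DataFrame | None = None,
    atlas: TissueAtlas | None = None,
    config: PipelineConfig | None = None,
) -> RunReport:
    """Run the full analysis on in-memory inputs."""
    config = config or PipelineConfig()
    markers = list(markers)
    results = [analyze_dataset(ds, markers, config) for ds in datasets]
    per_dataset = pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id, "tissue": r.tissue,
                "n_modules": r.n_modules, "power": r.power,
                "scale_free_r2": r.scale_free_r2,
                "ciliary_module": "-" if r.ciliary_module is None else r.ciliary_module,
                "ciliary_size": r.ciliary_size,
                "enrichment_p": r.enrichment_p,
                "marker_overlap": r.marker_overlap,
            }
            for r in results
        ]
    )

    all_genes = pd.Index(sorted(set().union(*[r.expanded_labels.index for r in results])))
    membership = build_membership(results, all_genes)
    signature = cons.build_consensus(membership, config.min_tissues, config.min_datasets)

    contributing = [r for r in results if r.ciliary_module is not None]
    module_sizes = {r.dataset_id: r.ciliary_size for r in contributing}
    universes = {r.dataset_id: list(r.expanded_labels.index) for r in contributing}
    tissue_map = {r.dataset_id: r.tissue for r in contributing}
    if module_sizes:
        fdr, mean_perm = cons.permutation_fdr(
            module_sizes, universes, tissue_map,
            config.min_tissues, config.min_datasets,
            true_size=len(signature.genes),
            n_iter=config.fdr_iterations, seed=config.seed + _SEED_FDR,
        )
        signature.fdr = fdr
    if evidence is not None:
        signature.categories = cons.categorize_novelty(signature.genes, evidence)

    tissue_ranking = specificity = upregulated = None
    if atlas is not None and signature.genes:
        z_atlas = ts.zscore_by_gene(atlas)
        present = [g for g in signature.genes if g in z_atlas.expr.index]
        tissue_ranking = ts.rank_tissues(z_atlas, present)
        specificity = ts.mean_rank_test_table(
            z_atlas, genes=present, n_perm=config.n_permutations,
            seed=config.seed + _SEED_TISSUE, alpha=config.bh_alpha,
        )
        if signature.categories:
            upregulated = ts.classify_upregulated(
                specificity, signature.categories, alpha=config.bh_alpha
            )

    diffcoexp_table = run_diffcoexp(membership, signature, atlas, markers, config)

    return RunReport(per_dataset, results, membership, signature,
                     tissue_ranking, specificity, upregulated,
                     diffcoexp_table, config)


def run_diffcoexp(
    membership: cons.MembershipTable,
    signature: cons.ConsensusSignature,
    atlas: TissueAtlas | None,
    markers,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Stage H: tissue-restricted hubs, ANOVA, atlas validation."""
    if membership.mm_ciliary is None:
        return pd.DataFrame()
    mm = membership.mm_ciliary.fillna(0.0)
    hubs = dc.call_hubs(membership.membership, mm, tau=config.hub_tau)
    candidates = dc.screen_candidates(
        hubs, membership.membership, membership.availability, membership.dataset_tissues
    )
    if not len(candidates):
        return pd.DataFrame()
    result = dc.test_candidates(
        candidates, membership.mm_ciliary.where(membership.availability),
        membership.availability, membership.dataset_tissues, alpha=config.bh_alpha,
    )
    table = result.table

    if atlas is not None:
        z_atlas = ts.zscore_by_gene(atlas)
        # validation groups: marker-positive samples of each excluded tissue
        # (the ependyma-positive analog), plus all samples of ciliated tissues
        groups = _validation_groups(z_atlas, markers, membership.dataset_tissues,
                                    n=config.n_marker_positive)
        pvals = []
        for _, row in table.iterrows():
            focal = groups.get(row["focal_tissue"])
            if focal is None or row["gene"] not in z_atlas.expr.index:
                pvals.append(np.nan)
                continue
            others = [s for t, ss in groups.items() if t != row["focal_tissue"]
                      for s in ss]
            try:
                p = dc.validate_tissue_expression(z_atlas, row["gene"], focal, others)
            except DataError:
                p = np.nan
            pvals.append(p)
        table["validation_p"] = pvals
        valid = table["validation_p"].notna()
        table["validation_p_adj"] = np.nan
        if valid.any():
            table.loc[valid, "validation_p_adj"] = ts.bh_adjust(
                table.loc[valid, "validation_p"].to_numpy()
            )
        table["validated"] = table["validation_p_adj"] < config.bh_alpha
    return table


def _validation_groups(z_atlas, markers, dataset_tissues, n=10) -> dict[str, list[str]]:
    """Atlas sample groups per collection tissue, for t-test validation."""
    from .simulate import HUB_ATLAS_MAP

    groups: dict[str, list[str]] = {}
    atlas_tissues = set(z_atlas.sample_tissues.unique())
    for tissue in sorted(set(dataset_tissues.values())):
        if tissue in atlas_tissues:
            if tissue in z_atlas.excluded_tissues:
                try:
                    groups[tissue] = dc.select_marker_positive_samples(
                        z_atlas, markers, tissue, n=n
                    )
                except DataError:
                    continue
            else:
                sel = z_atlas.sample_tissues == tissue
                groups[tissue] = z_atlas.expr.columns[sel].tolist()
        else:
            mapped = [t for t in HUB_ATLAS_MAP.get(tissue, ()) if t in atlas_tissues]
            if mapped:
                sel = z_atlas.sample_tissues.isin(mapped)
                groups[tissue] = z_atlas.expr.columns[sel].tolist()
    return groups


def run_pipeline(config: PipelineConfig) -> RunReport:
    """File-based end-to-end run described by a PipelineConfig."""
    if not config.dataset_paths:
        raise DataError("config lists no datasets")
    datasets = []
    for entry in config.dataset_paths:
        path, tissue = entry if isinstance(entry, (list, tuple)) else (entry, "")
        try:
            datasets.append(cio.read_expression_tsv(path, tissue=tissue))
        except Exception as exc:
            raise DataError(f"stage ingest: failed reading {path}: {exc}") from exc
    if not config.marker_gmt:
        raise DataError("config lists no marker GMT")
    marker_sets = cio.read_gmt(config.marker_gmt)
    markers = sorted(set().union(*marker_sets.values()))
    evidence = cio.read_evidence_tsv(config.evidence_tsv) if config.evidence_tsv else None
    atlas = None
    if config.atlas_expr and config.atlas_sample_sheet:
        atlas = cio.read_atlas(config.atlas_expr, config.atlas_sample_sheet,
                               config.ciliated_tissues, config.excluded_tissues)
    return run_collection(datasets, markers, evidence, atlas, config)


def simulate_inputs(gen_config: GeneratorConfig):
    """Generate the full synthetic input bundle (collection, markers,
    evidence, atlas, truth) in memory."""
    datasets, truth = simulate_collection(gen_config)
    atlas, _ = simulate_body_atlas(gen_config)
    evidence = simulate_evidence_table(gen_config)
    return datasets, truth.markers, evidence, atlas, truth


def write_report(report: RunReport, out_dir) -> None:
    """Emit the report as TSVs with fixed column order and LF endings."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_dataset.to_csv(out / "per_dataset.tsv", sep="\t", index=False,
                              lineterminator="\n", float_format="%.6g")
    sig = report.signature.support.copy()
    sig["category"] = [report.signature.categories.get(g, "")
                       for g in sig.index]
    sig.index.name = "gene"
    sig.to_csv(out / "consensus_signature.tsv", sep="\t", lineterminator="\n")
    member = report.membership.membership.astype(int)
    member.index.name = "gene"
    member.to_csv(out / "membership.tsv", sep="\t", lineterminator="\n")
    mm = report.membership.mm_ciliary
    if mm is not None:
        mm.index.name = "gene"
        mm.to_csv(out / "mm_ciliary.tsv", sep="\t", lineterminator="\n",
                  float_format="%.6g")
    if report.tissue_ranking is not None:
        report.tissue_ranking.to_csv(out / "tissue_ranking.tsv", sep="\t",
                                     lineterminator="\n", float_format="%.6g")
    if report.specificity is not None:
        report.specificity.to_csv(out / "tissue_specificity.tsv", sep="\t",
                                  lineterminator="\n", float_format="%.6g")
    report.diffcoexp.to_csv(out / "diffcoexp.tsv", sep="\t", index=False,
                            lineterminator="\n", float_format="%.6g")
    summary = {
        "n_datasets": len(report.dataset_results),
        "n_with_ciliary_module": int(sum(r.ciliary_module is not None
                                         for r in report.dataset_results)),
        "signature_size": len(report.signature.genes),
        "fdr": report.signature.fdr,
        "seed": report.config.seed,
    }
    cio.write_json(summary, out / "summary.json")
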