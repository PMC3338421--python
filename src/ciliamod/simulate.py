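"""Synthetic expression collections with a planted ciliated-cell signature.

The generator emulates the latent structure the coexpression analysis
assumes: in each bulk sample the fraction of ciliated cells varies, so genes
transcribed in ciliated cells rise and fall together.  A planted block of
``signature_size`` genes is driven linearly by a per-sample latent fraction
c_s drawn from a Beta distribution; a subset of those genes is flagged as
known markers.  Independent confounder modules are driven by their own
latent factors, tissue-restricted hub genes load on the ciliary factor only
in datasets of their own tissue, and the remaining genes are pure noise.

Because expression is on a log scale and loadings are specified in units of
the noise standard deviation, the latent fraction is standardized (zero
mean, unit variance) within each dataset before use as the driver; the raw
Beta draws are kept in the ground truth.  With the default
``beta_range=(0.5, 1.5)`` and ``noise_sd=1.0`` this yields within-signature
correlations of roughly 0.2-0.7 — strong coexpression against an
uncorrelated background, as observed for cell-type modules in real tissue
panels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ConfigurationError, ExpressionDataset, TissueAtlas

TISSUE_NAMES = ("brain", "airways", "reproductive")
#: atlas tissues carrying motile cilia (testis via the sperm flagellum)
ATLAS_CILIATED = ("trachea", "bronchus", "lung", "fallopian_tube", "endometrium", "testis")

#: mapping collection tissue -> atlas tissues where that tissue's
#: restricted hubs are up-regulated ("brain" maps to the marker-positive
#: ependyma-like brain samples, handled separately)
HUB_ATLAS_MAP = {
    "airways": ("trachea", "bronchus", "lung"),
    "reproductive": ("fallopian_tube", "endometrium", "testis"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic collection.

    Defaults mirror a 10-dataset, 3-tissue design with 2000 genes and 60
    samples per dataset, a 150-gene planted ciliary signature of which 25
    genes are known markers, 3 independent confounder modules of 100 genes,
    and 3 tissue-restricted hub genes per tissue.
    """

    n_tissues: int = 3
    datasets_per_tissue: tuple[int, ...] = (4, 3, 3)
    n_genes: int = 2000
    n_samples: int = 60
    signature_size: int = 150
    n_markers: int = 25
    n_confounder_modules: int = 3
    confounder_size: int = 100
    beta_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 1.0
    proportion_dist: tuple[float, float] = (2.0, 5.0)  # Beta(a, b) for c_s
    n_tissue_hubs: int = 3
    dropout_rate: float = 0.05
    atlas_tissues: int = 20
    atlas_ciliated: int = 6
    atlas_samples_per_tissue: int = 5
    atlas_brain_samples: int = 15
    n_marker_positive: int = 10
    atlas_effect: float = 2.0
    standardize_factor: bool = True
    novelty_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        def err(name, msg):
            raise ConfigurationError(f"{name}: {msg}")

        for name in ("n_tissues", "n_genes", "n_samples", "signature_size",
                     "n_markers", "confounder_size", "n_tissue_hubs",
                     "atlas_tissues", "atlas_ciliated", "atlas_samples_per_tissue"):
            if getattr(self, name) <= 0:
                err(name, "must be positive")
        if self.n_confounder_modules < 0:
            err("n_confounder_modules", "must be non-negative")
        if self.n_markers > self.signature_size:
            err("n_markers", "markers must be a subset of the planted signature")
        if not (0 < self.beta_range[0] <= self.beta_range[1]):
            err("beta_range", "must be a strictly positive interval")
        if self.noise_sd < 0:
            err("noise_sd", "must be >= 0")
        if min(self.proportion_dist) <= 0:
            err("proportion_dist", "Beta parameters must be positive")
        if not (0 <= self.dropout_rate < 1):
            err("dropout_rate", "must be in [0, 1)")
        if self.n_tissues != len(self.datasets_per_tissue):
            err("datasets_per_tissue", "length must equal n_tissues")
        if any(d <= 0 for d in self.datasets_per_tissue):
            err("datasets_per_tissue", "all counts must be positive")
        if self.atlas_tissues < self.atlas_ciliated + 1:  # +1 for brain
            err("atlas_tissues", "fewer tissues than ciliated tissues plus brain")
        needed = (self.signature_size
                  + self.n_confounder_modules * self.confounder_size
                  + self.n_tissues * self.n_tissue_hubs)
        if self.n_genes < needed + 10:
            err("n_genes", f"too small for the planted structure (need > {needed + 10})")
        if abs(sum(self.novelty_fractions) - 1.0) > 1e-9:
            err("novelty_fractions", "must sum to 1")

    @property
    def n_datasets(self) -> int:
        return sum(self.datasets_per_tissue)

    @property
    def tissue_names(self) -> tuple[str, ...]:
        if self.n_tissues <= len(TISSUE_NAMES):
            return TISSUE_NAMES[: self.n_tissues]
        return TISSUE_NAMES + tuple(
            f"tissue_{i}" for i in range(len(TISSUE_NAMES), self.n_tissues)
        )


@dataclass
class GroundTruth:
    """What was planted, for scoring downstream recovery."""

    planted_signature: list[str]
    markers: list[str]
    tissue_hubs: dict[str, list[str]]
    confounder_modules: list[list[str]]
    latent_fractions: dict[str, np.ndarray] = field(default_factory=dict)
    confounder_factors: dict[str, np.ndarray] = field(default_factory=dict)
    signature_betas: dict[str, pd.Series] = field(default_factory=dict)
    novelty_truth: dict[str, str] = field(default_factory=dict)
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)
    marker_positive_samples: list[str] = field(default_factory=list)


def _gene_layout(config: GeneratorConfig) -> dict:
    """Deterministic gene-id layout of the planted structure."""
    ids = [f"G{i:05d}" for i in range(config.n_genes)]
    pos = 0
    signature = ids[pos: pos + config.signature_size]
    pos += config.signature_size
    markers = signature[: config.n_markers]
    confounders = []
    for _ in range(config.n_confounder_modules):
        confounders.append(ids[pos: pos + config.confounder_size])
        pos += config.confounder_size
    hubs = {}
    for tissue in config.tissue_names:
        hubs[tissue] = ids[pos: pos + config.n_tissue_hubs]
        pos += config.n_tissue_hubs
    return {"ids": ids, "signature": signature, "markers": markers,
            "confounders": confounders, "hubs": hubs}


def _novelty_truth(config: GeneratorConfig, layout: dict) -> dict[str, str]:
    """Category labels: planted genes split I/II/III by novelty_fractions
    (markers always category I); background genes are category III."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 900]))
    truth = {g: "III" for g in layout["ids"]}
    non_marker = [g for g in layout["signature"] if g not in set(layout["markers"])]
    f1, f2, _ = config.novelty_fractions
    n1 = max(0, int(round(f1 * config.signature_size)) - config.n_markers)
    n2 = int(round(f2 * config.signature_size))
    order = rng.permutation(len(non_marker))
    cat1 = [non_marker[i] for i in order[:n1]]
    cat2 = [non_marker[i] for i in order[n1: n1 + n2]]
    for g in layout["markers"] + cat1:
        truth[g] = "I"
    for g in cat2:
        truth[g] = "II"
    return truth


def _base_truth(config: GeneratorConfig) -> tuple[dict, GroundTruth]:
    layout = _gene_layout(config)
    truth = GroundTruth(
        planted_signature=list(layout["signature"]),
        markers=list(layout["markers"]),
        tissue_hubs={t: list(g) for t, g in layout["hubs"].items()},
        confounder_modules=[list(m) for m in layout["confounders"]],
        novelty_truth=_novelty_truth(config, layout),
    )
    return layout, truth


def simulate_dataset(
    config: GeneratorConfig, tissue: str, seed: int
) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate one gene-by-sample dataset for ``tissue``.

    Planted gene g follows x_gs = alpha_g + beta_g * f_s + eps_gs with the
    driver f_s the (standardized) latent ciliated fraction; tissue hubs of
    ``tissue`` load at the top of ``beta_range`` while hubs of other tissues
    have beta = 0; confounder modules are driven by their own independent
    factors; background genes are pure noise.
    """
    layout, truth = _base_truth(config)
    rng = np.random.default_rng(seed)
    n_g, n_s = config.n_genes, config.n_samples
    a, b = config.proportion_dist

    c_raw = rng.beta(a, b, size=n_s)
    driver = c_raw.copy()
    if config.standardize_factor:
        driver = (driver - driver.mean()) / driver.std()

    lo, hi = config.beta_range
    alpha = rng.normal(6.0, 1.0, size=n_g)
    x = alpha[:, None] + rng.normal(0.0, config.noise_sd, size=(n_g, n_s))

    index = pd.Index(layout["ids"], name="gene")
    sig_idx = index.get_indexer(layout["signature"])
    beta_sig = rng.uniform(lo, hi, size=len(sig_idx))
    x[sig_idx] += beta_sig[:, None] * driver[None, :]

    # tissue-restricted hubs: own tissue loads maximally, others not at all
    own = index.get_indexer(layout["hubs"].get(tissue, []))
    if len(own):
        x[own] += hi * driver[None, :]

    conf_factors = []
    for module in layout["confounders"]:
        f_raw = rng.beta(a, b, size=n_s)
        f = f_raw - f_raw.mean()
        # orthogonalize against the ciliary driver so confounders carry no
        # in-sample trace of the ciliated fraction
        d = driver - driver.mean()
        if d.std() > 0:
            f = f - (f @ d) / (d @ d) * d
        if config.standardize_factor and f.std() > 0:
            f = f / f.std()
        conf_factors.append(f)
        idx = index.get_indexer(module)
        beta_m = rng.uniform(lo, hi, size=len(idx))
        x[idx] += beta_m[:, None] * f[None, :]

    samples = [f"S{j:03d}" for j in range(n_s)]
    ds = ExpressionDataset(pd.DataFrame(x, index=index, columns=samples),
                           tissue=tissue, dataset_id=f"{tissue}_{seed}")
    truth.latent_fractions[ds.dataset_id] = c_raw
    truth.confounder_factors[ds.dataset_id] = np.asarray(conf_factors)
    truth.signature_betas[ds.dataset_id] = pd.Series(beta_sig, index=layout["signature"])
    return ds, truth


def simulate_collection(
    config: GeneratorConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Simulate the full multi-tissue collection sharing one planted signature.

    A per-dataset random ``dropout_rate`` fraction of planted genes is
    removed to emulate genes lacking measurements on some platforms.
    """
    _, truth = _base_truth(config)
    root = np.random.SeedSequence([config.seed, 100])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   root.spawn(config.n_datasets)]
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 200]))

    datasets: list[ExpressionDataset] = []
    k = 0
    for tissue, n_ds in zip(config.tissue_names, config.datasets_per_tissue):
        for j in range(n_ds):
            ds, ds_truth = simulate_dataset(config, tissue, child_seeds[k])
            ds = ExpressionDataset(ds.expr, tissue, f"{tissue}_{j}")
            if config.dropout_rate > 0:
                n_drop = int(round(config.dropout_rate * config.signature_size))
                dropped = drop_rng.choice(truth.planted_signature, size=n_drop,
                                          replace=False)
                ds = ExpressionDataset(ds.expr.drop(index=list(dropped)),
                                       tissue, ds.dataset_id)
                truth.dropped_genes[ds.dataset_id] = sorted(dropped)
            key = f"{tissue}_{child_seeds[k]}"
            truth.latent_fractions[ds.dataset_id] = ds_truth.latent_fractions[key]
            truth.confounder_factors[ds.dataset_id] = ds_truth.confounder_factors[key]
            truth.signature_betas[ds.dataset_id] = ds_truth.signature_betas[key]
            datasets.append(ds)
            k += 1
    return datasets, truth


def simulate_body_atlas(config: GeneratorConfig) -> tuple[TissueAtlas, GroundTruth]:
    """Simulate a multi-tissue body atlas with planted ciliated-tissue effects.

    Signature genes are shifted upward by ``atlas_effect`` (in units of the
    per-gene noise SD, i.e. approximately Z units) in the ciliated tissues.
    A brain tissue is included and flagged for exclusion; ``n_marker_positive``
    of its samples get elevated marker expression (an ependyma-positive
    analog) plus the focal-tissue effect for brain-restricted hubs.
    Non-signature, non-hub genes have identical means across tissues.
    """
    layout, truth = _base_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 300]))

    ciliated = list(ATLAS_CILIATED[: config.atlas_ciliated])
    n_other = config.atlas_tissues - config.atlas_ciliated - 1
    tissues = ciliated + ["brain"] + [f"tissue_{i:02d}" for i in range(n_other)]

    sample_ids, sample_tissues = [], []
    for t in tissues:
        n = config.atlas_brain_samples if t == "brain" else config.atlas_samples_per_tissue
        for j in range(n):
            sample_ids.append(f"{t}.{j:02d}")
            sample_tissues.append(t)
    tissue_arr = np.asarray(sample_tissues)
    n_s = len(sample_ids)

    sd = config.noise_sd
    alpha = rng.normal(6.0, 1.0, size=config.n_genes)
    x = alpha[:, None] + rng.normal(0.0, sd, size=(config.n_genes, n_s))

    index = pd.Index(layout["ids"], name="gene")
    delta = config.atlas_effect * sd
    cil_mask = np.isin(tissue_arr, ciliated)
    x[np.ix_(index.get_indexer(layout["signature"]), np.flatnonzero(cil_mask))] += delta

    brain_cols = np.flatnonzero(tissue_arr == "brain")
    mpos = brain_cols[: min(config.n_marker_positive, len(brain_cols))]
    x[np.ix_(index.get_indexer(layout["markers"]), mpos)] += delta
    truth.marker_positive_samples = [sample_ids[j] for j in mpos]

    for tissue, hub_genes in layout["hubs"].items():
        if tissue == "brain":
            cols = mpos
        else:
            mapped = HUB_ATLAS_MAP.get(tissue, ())
            cols = np.flatnonzero(np.isin(tissue_arr, [t for t in mapped if t in tissues]))
        if len(cols):
            x[np.ix_(index.get_indexer(hub_genes), cols)] += delta

    atlas = TissueAtlas(
        pd.DataFrame(x, index=index, columns=sample_ids),
        pd.Series(sample_tissues, index=sample_ids, name="tissue"),
        ciliated_tissues=ciliated,
        excluded_tissues=["brain"],
    )
    return atlas, truth


def simulate_evidence_table(config: GeneratorConfig) -> pd.DataFrame:
    """Per-gene study-evidence counts consistent with the novelty truth.

    Category I genes get high-confidence support in >=1 study or medium
    support in >=2; category II genes get medium support in exactly one
    study or low-confidence support only; category III genes have no
    support at all.
    """
    layout, truth = _base_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 400]))
    rows = []
    for g in layout["ids"]:
        cat = truth.novelty_truth[g]
        if cat == "I":
            if rng.random() < 0.7:
                rows.append((1 + rng.poisson(1.0), rng.poisson(0.5), rng.poisson(0.5)))
            else:
                rows.append((0, 2 + rng.poisson(0.5), rng.poisson(0.5)))
        elif cat == "II":
            if rng.random() < 0.5:
                rows.append((0, 1, rng.poisson(0.5)))
            else:
                rows.append((0, 0, 1 + rng.poisson(0.5)))
        else:
            rows.append((0, 0, 0))
    return pd.DataFrame(rows, index=pd.Index(layout["ids"], name="gene"),
                        columns=["n_high", "n_medium", "n_low"]).astype(int)


def ground_truth(config: GeneratorConfig) -> GroundTruth:
    """The planted structure implied by ``config`` (no expression draws)."""
    return _base_truth(config)[1]


def small_config(**overrides) -> GeneratorConfig:
    """A scaled-down configuration for quick smoke runs."""
    base = dict(n_genes=400, n_samples=40, signature_size=60, n_markers=15,
                n_confounder_modules=2, confounder_size=40,
                datasets_per_tissue=(2, 1, 1), atlas_samples_per_tissue=4,
                atlas_brain_samples=12)
    base.update(overrides)
    return GeneratorConfig(**base)
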