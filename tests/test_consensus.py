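"""Marker enrichment, consensus rules, permutation FDR, novelty, summaries."""
import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from ciliamod import (DataError, MembershipTable, ModulePartition,
                      build_consensus, categorize_novelty,
                      hypergeometric_enrichment, identify_ciliary_module,
                      localization_summary, pairwise_module_overlap,
                      percent_overlap, permutation_fdr)


def enrichment_oracle(n_universe, n_markers, n_module, overlap):
    """Exact hypergeometric upper tail by direct enumeration."""
    total = comb(n_universe, n_module)
    return sum(
        comb(n_markers, k) * comb(n_universe - n_markers, n_module - k)
        for k in range(overlap, min(n_markers, n_module) + 1)
    ) / total


def _sets(n_universe, n_markers, n_module, overlap):
    universe = [f"g{i}" for i in range(n_universe)]
    markers = universe[:n_markers]
    module = markers[:overlap] + universe[n_markers: n_markers + n_module - overlap]
    return module, markers, universe


def test_enrichment_zero_overlap_is_one():
    module, markers, universe = _sets(20, 4, 5, 0)
    assert hypergeometric_enrichment(module, markers, universe) == pytest.approx(1.0)


def test_enrichment_worked_example_496_15504():
    module, markers, universe = _sets(20, 4, 5, 3)
    p = hypergeometric_enrichment(module, markers, universe)
    assert p == pytest.approx(496 / 15504, abs=1e-12)


def test_enrichment_matches_enumeration_oracle():
    for overlap in range(0, 7):
        module, markers, universe = _sets(30, 8, 6, min(overlap, 6))
        p = hypergeometric_enrichment(module, markers, universe)
        assert p == pytest.approx(
            enrichment_oracle(30, 8, 6, min(overlap, 6)), abs=1e-12
        )


def test_enrichment_empty_universe_errors():
    with pytest.raises(DataError):
        hypergeometric_enrichment([], [], [])


def test_identify_ciliary_module_rules():
    genes = [f"g{i}" for i in range(100)]
    labels = pd.Series([0] * 20 + [1] * 20 + [-1] * 60, index=genes)
    part = ModulePartition(labels)
    # no module holds a marker -> NONE
    module, p, _ = identify_ciliary_module(part, ["g99"], genes)
    assert module is None
    # markers concentrated in module 1
    markers = genes[20:30]
    module, p, overlap = identify_ciliary_module(part, markers, genes)
    assert module == 1 and overlap == 10 and p < 1e-3


def test_identify_tie_broken_by_larger_overlap():
    genes = [f"g{i}" for i in range(40)]
    # two modules of equal size; markers split so p ties only if overlaps tie,
    # so give module 1 the larger overlap with a disjoint marker set of its own
    labels = pd.Series([0] * 10 + [1] * 10 + [-1] * 20, index=genes)
    part = ModulePartition(labels)
    markers = genes[0:3] + genes[10:13]  # equal overlap 3 and 3 -> lower id wins
    module, _, _ = identify_ciliary_module(part, markers, genes, alpha=1.0)
    assert module == 0
    # unequal overlaps at equal module size: larger overlap wins
    markers = genes[0:2] + genes[10:14]
    module, _, overlap = identify_ciliary_module(part, markers, genes, alpha=1.0)
    assert module == 1 and overlap == 4


def test_pairwise_module_overlap_extremes():
    genes = [f"g{i}" for i in range(60)]
    la = pd.Series([0] * 20 + [1] * 20 + [-1] * 20, index=genes)
    lb = pd.Series([0] * 20 + [-1] * 20 + [1] * 20, index=genes)
    table = pairwise_module_overlap(ModulePartition(la), ModulePartition(lb), genes)
    identical = table[(table.module_a == 0) & (table.module_b == 0)].iloc[0]
    assert identical.percent_of_smaller == 100
    disjoint = table[(table.module_a == 0) & (table.module_b == 1)].iloc[0]
    assert disjoint.percent_of_smaller == 0
    assert disjoint.p_value == pytest.approx(1.0)
    # p values agree with the shared enrichment oracle
    for _, row in table.iterrows():
        a = set(la.index[la == row.module_a])
        b = set(lb.index[lb == row.module_b])
        assert row.p_value == pytest.approx(
            hypergeometric_enrichment(a, b, genes), abs=1e-12
        )


def test_percent_overlap_errors():
    with pytest.raises(DataError):
        percent_overlap(1, 0)
    with pytest.raises(DataError):
        percent_overlap(5, 3)


def _membership(patterns, tissues):
    """patterns: dict gene -> tuple of 0/1 over datasets."""
    datasets = [f"d{i}" for i in range(len(tissues))]
    member = pd.DataFrame.from_dict(patterns, orient="index", columns=datasets).astype(bool)
    avail = pd.DataFrame(True, index=member.index, columns=datasets)
    return MembershipTable(member, avail, dict(zip(datasets, tissues)))


def test_build_consensus_rules():
    tissues = ["A"] * 4 + ["B"] * 3 + ["C"] * 3
    table = _membership(
        {
            "two_tissues_four_ds": (1, 1, 1, 0, 1, 0, 0, 0, 0, 0),
            "one_tissue_four_ds": (1, 1, 1, 1, 0, 0, 0, 0, 0, 0),
            "two_tissues_three_ds": (1, 1, 0, 0, 1, 0, 0, 0, 0, 0),
        },
        tissues,
    )
    sig = build_consensus(table, min_tissues=2, min_datasets=4)
    assert sig.genes == ["two_tissues_four_ds"]
    assert sig.support.at["one_tissue_four_ds", "n_tissues"] == 1


def test_build_consensus_exhaustive_pattern_oracle():
    """All 2^10 membership patterns for one gene vs direct set logic."""
    tissues = ["A"] * 4 + ["B"] * 3 + ["C"] * 3
    for bits in itertools.product([0, 1], repeat=10):
        table = _membership({"g": bits}, tissues)
        sig = build_consensus(table, min_tissues=2, min_datasets=4)
        n_ds = sum(bits)
        tset = {t for t, b in zip(tissues, bits) if b}
        expected = n_ds >= 4 and len(tset) >= 2
        assert ("g" in sig.genes) == expected, bits


def test_build_consensus_monotone_in_support(rng):
    tissues = ["A"] * 4 + ["B"] * 3 + ["C"] * 3
    for _ in range(50):
        bits = rng.integers(0, 2, size=10)
        table = _membership({"g": tuple(bits)}, tissues)
        before = "g" in build_consensus(table).genes
        if bits.all():
            continue
        j = int(np.flatnonzero(bits == 0)[0])
        bits2 = bits.copy()
        bits2[j] = 1
        after = "g" in build_consensus(_membership({"g": tuple(bits2)}, tissues)).genes
        assert after >= before  # adding support never removes a gene


def test_build_consensus_unmapped_dataset_errors():
    member = pd.DataFrame({"d0": [True]}, index=["g"])
    avail = member.copy()
    with pytest.raises(DataError):
        MembershipTable(member, avail, {})


def test_permutation_fdr_closed_form():
    """Universe 100, module size 10 in each of 4 datasets (2 tissues x 2),
    thresholds (>=2 tissues, >=2 datasets): mean permuted size matches
    100*(1-0.9^2)^2 = 3.61 within 3 Monte-Carlo SE."""
    genes = [f"g{i}" for i in range(100)]
    sizes = {f"d{i}": 10 for i in range(4)}
    universes = {d: genes for d in sizes}
    tissue_map = {"d0": "A", "d1": "A", "d2": "B", "d3": "B"}
    n_iter = 3000
    fdr, mean_size = permutation_fdr(sizes, universes, tissue_map,
                                     min_tissues=2, min_datasets=2,
                                     true_size=100, n_iter=n_iter, seed=5)
    # binomial per gene: p = (1-0.9^2)^2; SE of mean size from per-iter SD
    p = (1 - 0.9**2) ** 2
    sd_iter = np.sqrt(100 * p * (1 - p) * 1.2)  # slight negative dependence; pad
    assert abs(mean_size - 100 * p) <= 3 * sd_iter / np.sqrt(n_iter) + 0.05


def test_permutation_fdr_impossible_threshold_gives_zero():
    genes = [f"g{i}" for i in range(50)]
    sizes = {"d0": 5, "d1": 5}
    universes = {d: genes for d in sizes}
    fdr, mean_size = permutation_fdr(sizes, universes, {"d0": "A", "d1": "B"},
                                     min_tissues=2, min_datasets=3,
                                     true_size=10, n_iter=50, seed=1)
    assert fdr == 0.0 and mean_size == 0.0


def test_permutation_fdr_deterministic_and_na_for_empty_truth():
    genes = [f"g{i}" for i in range(30)]
    sizes = {"d0": 5, "d1": 5, "d2": 5, "d3": 5}
    universes = {d: genes for d in sizes}
    tmap = {"d0": "A", "d1": "A", "d2": "B", "d3": "B"}
    a = permutation_fdr(sizes, universes, tmap, 2, 2, true_size=7, n_iter=100, seed=9)
    b = permutation_fdr(sizes, universes, tmap, 2, 2, true_size=7, n_iter=100, seed=9)
    assert a == b
    fdr, _ = permutation_fdr(sizes, universes, tmap, 2, 2, true_size=0,
                             n_iter=10, seed=0)
    assert fdr is None


def test_fdr_calibrated_against_realized_null():
    """The permutation FDR estimate agrees within a factor of 2 with the
    realized signature rate of independent random-module draws (50 runs)."""
    genes = [f"g{i}" for i in range(100)]
    sizes = {f"d{i}": 10 for i in range(4)}
    universes = {d: genes for d in sizes}
    tmap = {"d0": "A", "d1": "A", "d2": "B", "d3": "B"}
    true_size = 20  # nominal signature size for normalization
    fdr, _ = permutation_fdr(sizes, universes, tmap, 2, 2,
                             true_size=true_size, n_iter=1000, seed=2)
    _, realized_mean = permutation_fdr(sizes, universes, tmap, 2, 2,
                                       true_size=true_size, n_iter=50, seed=999)
    realized = realized_mean / true_size
    assert fdr / 2 <= realized <= fdr * 2


def test_categorize_novelty_rules():
    evidence = pd.DataFrame(
        {"n_high": [1, 0, 0, 0], "n_medium": [0, 2, 1, 0], "n_low": [0, 0, 3, 0]},
        index=["known_high", "known_medium", "proposed", "novel"],
    )
    cats = categorize_novelty(evidence.index, evidence)
    assert cats == {"known_high": "I", "known_medium": "I",
                    "proposed": "II", "novel": "III"}
    # absent gene treated as zero counts
    assert categorize_novelty(["ghost"], evidence)["ghost"] == "III"
    with pytest.raises(DataError):
        categorize_novelty(["x"], pd.DataFrame(
            {"n_high": [-1], "n_medium": [0], "n_low": [0]}, index=["x"]))


def test_localization_summary_printed_percentages():
    """Row percentages reproduce the published localization table from its
    printed counts."""
    loc, cat = {}, {}
    counts = {"I": (76, 34, 26), "II": (13, 8, 13), "III": (20, 5, 23)}
    i = 0
    for c, (na, nb, nc) in counts.items():
        for cls, n in zip("ABC", (na, nb, nc)):
            for _ in range(n):
                loc[f"g{i}"] = cls
                cat[f"g{i}"] = c
                i += 1
    table = localization_summary(loc, cat)
    assert tuple(table.loc["I", ["pct_A", "pct_B", "pct_C"]]) == (56, 25, 19)
    assert tuple(table.loc["II", ["pct_A", "pct_B", "pct_C"]]) == (38, 24, 38)
    assert tuple(table.loc["III", ["pct_A", "pct_B", "pct_C"]]) == (42, 10, 48)
    assert tuple(table.loc["total", ["pct_A", "pct_B", "pct_C"]]) == (50, 22, 28)
    assert table.loc["total", "n_total"] == 218


def test_localization_summary_single_gene_and_empty_rows():
    table = localization_summary({"g": "A"}, {"g": "II"})
    assert tuple(table.loc["II", ["pct_A", "pct_B", "pct_C"]]) == (100, 0, 0)
    assert np.isnan(table.loc["I", "pct_A"])
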