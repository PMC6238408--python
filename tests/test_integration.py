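"""FPKM, bootstrap gene DE, miRNA-target correlation and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirapex.integration import (compute_fpkm, correlate,
                                 diff_expression_genes, enrichment,
                                 expressed_universe, gene_diff_table)

DESIGN = {"a1": "HL", "a2": "HL", "a3": "HL", "b1": "LS", "b2": "LS", "b3": "LS"}


def test_fpkm_direct_formula():
    counts = pd.DataFrame({"s1": [100]}, index=["g"])
    fpkm = compute_fpkm(counts, pd.Series({"g": 1000}),
                        pd.Series({"s1": 10_000_000}))
    assert fpkm.loc["g", "s1"] == 10.0


def test_fpkm_zero_count_is_zero():
    counts = pd.DataFrame({"s1": [0]}, index=["g"])
    fpkm = compute_fpkm(counts, pd.Series({"g": 500}), pd.Series({"s1": 1e6}))
    assert fpkm.loc["g", "s1"] == 0.0


def test_fpkm_halves_when_library_doubles():
    counts = pd.DataFrame({"s1": [100], "s2": [100]}, index=["g"])
    fpkm = compute_fpkm(counts, pd.Series({"g": 1000}),
                        pd.Series({"s1": 1e7, "s2": 2e7}))
    assert fpkm.loc["g", "s1"] == 2 * fpkm.loc["g", "s2"]


def test_fpkm_rejects_zero_length():
    with pytest.raises(ValueError):
        compute_fpkm(pd.DataFrame({"s1": [1]}, index=["g"]),
                     pd.Series({"g": 0}), pd.Series({"s1": 1e6}))


def _fpkm_rows(rows):
    genes = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=genes, columns=list(DESIGN)).astype(float)


def test_identical_replicates_have_zero_probability():
    fpkm = _fpkm_rows([[50, 50, 50, 50, 50, 50]])
    calls = diff_expression_genes(fpkm, DESIGN, ("HL", "LS"), n_boot=200, seed=0)
    assert calls[0].probability == 0.0
    assert calls[0].status == "ns"


def test_tenfold_change_matches_exhaustive_bootstrap():
    """Bootstrap probability equals exhaustive 3^3 x 3^3 enumeration."""
    a, b = [100.0, 98.0, 102.0], [10.0, 9.0, 11.0]
    hits = total = 0
    for ia in itertools.product(range(3), repeat=3):
        for ib in itertools.product(range(3), repeat=3):
            ma = sum(a[i] for i in ia) / 3 + 0.01
            mb = sum(b[i] for i in ib) / 3 + 0.01
            hits += abs(math.log2(ma / mb)) > 1.0
            total += 1
    exact = hits / total
    assert exact == 1.0
    fpkm = _fpkm_rows([a + b])
    calls = diff_expression_genes(fpkm, DESIGN, ("HL", "LS"), n_boot=500, seed=1)
    assert calls[0].probability == pytest.approx(exact)
    assert calls[0].status == "up"
    assert calls[0].log2fc == pytest.approx(math.log2(100.01 / 10.01), abs=0.01)


def test_bootstrap_probability_seeded_reproducible():
    rng = np.random.default_rng(8)
    fpkm = _fpkm_rows(rng.uniform(1, 100, size=(20, 6)))
    c1 = diff_expression_genes(fpkm, DESIGN, ("HL", "LS"), n_boot=300, seed=42)
    c2 = diff_expression_genes(fpkm, DESIGN, ("HL", "LS"), n_boot=300, seed=42)
    assert [c.probability for c in c1] == [c.probability for c in c2]


def test_probability_monotone_in_true_fold_change():
    rng = np.random.default_rng(3)
    noise = rng.normal(1.0, 0.08, size=(3,))
    probs = []
    for fold in (1.5, 3.0, 6.0):
        fpkm = _fpkm_rows([list(100 * fold * noise) + list(100 * noise)])
        calls = diff_expression_genes(fpkm, DESIGN, ("HL", "LS"),
                                      n_boot=400, seed=7)
        probs.append(calls[0].probability)
    assert probs == sorted(probs)


def test_too_few_replicates_rejected():
    fpkm = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a1", "b1"])
    with pytest.raises(ValueError):
        diff_expression_genes(fpkm, {"a1": "HL", "b1": "LS"}, ("HL", "LS"))


def _diff_frame(rows):
    return pd.DataFrame(rows, columns=["feature_id", "condition_a",
                                       "condition_b", "log2fc", "pvalue",
                                       "status"]).rename(
        columns={"feature_id": "feature_id"})


def test_correlate_directions():
    mirna_diff = _diff_frame([["m1", "HL", "LS", 2.0, 1e-5, "up"],
                              ["m2", "HL", "LS", 1.5, 1e-4, "up"]])
    gene_diff = pd.DataFrame([
        {"gene_id": "g1", "condition_a": "HL", "condition_b": "LS",
         "log2fc": -2.0, "probability": 0.95, "status": "down"},
        {"gene_id": "g2", "condition_a": "HL", "condition_b": "LS",
         "log2fc": 1.4, "probability": 0.92, "status": "up"},
        {"gene_id": "g3", "condition_a": "HL", "condition_b": "LS",
         "log2fc": 0.1, "probability": 0.1, "status": "ns"}])
    pairs = correlate(mirna_diff, gene_diff,
                      [("m1", "g1"), ("m2", "g2"), ("m1", "g3"), ("mX", "g1")])
    by = {(p.mirna_id, p.gene_id): p for p in pairs}
    assert by[("m1", "g1")].negative          # miRNA up, target down
    assert not by[("m2", "g2")].negative      # both up: retained, not negative
    assert ("m1", "g3") not in by             # gene not DE: no pair
    assert by[("mX", "g1")].mirna_direction == "flat"
    assert not by[("mX", "g1")].negative


def test_enrichment_closed_form_extreme_draw():
    universe = {f"g{i}" for i in range(20)}
    term_genes = {f"g{i}" for i in range(5)}
    annot = {g: {"T"} for g in term_genes}
    table = enrichment(term_genes, annot, universe)
    expected = 1.0 / math.comb(20, 5)
    assert table.loc[table.term == "T", "pvalue"].iloc[0] == \
        pytest.approx(expected, rel=1e-9)


def test_enrichment_term_covering_universe_is_null():
    universe = {f"g{i}" for i in range(10)}
    annot = {g: {"ALL"} for g in universe}
    table = enrichment({"g0", "g1"}, annot, universe)
    assert table.loc[table.term == "ALL", "pvalue"].iloc[0] == pytest.approx(1.0)


def test_enrichment_matches_bruteforce_on_small_universe():
    """Hypergeometric tail equals enumeration of all draws (n <= 20)."""
    universe = {f"g{i}" for i in range(12)}
    term = {f"g{i}" for i in range(4)}
    annot = {g: {"T"} for g in term}
    targets = {"g0", "g1", "g5", "g6", "g7"}
    k_obs = len(targets & term)
    total = hits = 0
    for combo in itertools.combinations(sorted(universe), len(targets)):
        total += 1
        hits += len(set(combo) & term) >= k_obs
    table = enrichment(targets, annot, universe)
    assert table.pvalue.iloc[0] == pytest.approx(hits / total, rel=1e-9)


def test_enrichment_requires_targets_in_universe():
    with pytest.raises(ValueError):
        enrichment({"gX"}, {}, {"g1"})


def test_enrichment_random_targets_are_calibrated():
    """Random target draws give roughly uniform enrichment p-values."""
    rng = np.random.default_rng(11)
    universe = {f"g{i}" for i in range(60)}
    annot = {f"g{i}": {"T"} for i in range(15)}
    pvals = []
    for _ in range(300):
        targets = set(rng.choice(sorted(universe), size=10, replace=False))
        table = enrichment(targets, annot, universe)
        pvals.append(table.pvalue.iloc[0])
    # discrete conservatism allowed: P(p <= 0.05) must not exceed 0.05 much
    assert np.mean(np.array(pvals) <= 0.05) <= 0.08


def test_expressed_universe_drops_all_zero_genes():
    fpkm = pd.DataFrame({"s1": [0.0, 1.0], "s2": [0.0, 0.0]},
                        index=["dead", "alive"])
    assert expressed_universe(fpkm) == {"alive"}


def test_gene_diff_table_roundtrip():
    fpkm = _fpkm_rows([[100, 98, 102, 10, 9, 11]])
    table = gene_diff_table(diff_expression_genes(fpkm, DESIGN, ("HL", "LS"),
                                                  n_boot=100, seed=0))
    assert set(table.columns) == {"gene_id", "condition_a", "condition_b",
                                  "log2fc", "probability", "status"}
    assert table.status.iloc[0] == "up"
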