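"""Target-gene expression, gene-level DE and miRNA-target integration.

Gene abundance is FPKM (fragments per kilobase per million mapped
reads).  Differential expression follows the fold-change-with-probability
convention: a gene is called when the mean-FPKM fold change between two
treatments exceeds 2 and the bootstrap probability of |log2 FC| > 1
(resampling replicates with replacement) exceeds 0.8.  Differential
miRNAs are crossed with differential validated targets to flag
negatively correlated regulator/target pairs, and target sets are tested
for annotation-term over-representation with a hypergeometric upper tail
and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.01


@dataclass
class GeneDiffCall:
    gene_id: str
    condition_pair: tuple[str, str]
    log2fc: float
    probability: float
    status: str   # "up" | "down" | "ns"


@dataclass
class CorrelationPair:
    mirna_id: str
    gene_id: str
    condition_pair: tuple[str, str]
    mirna_direction: str   # "up" | "down" | "flat"
    gene_direction: str    # "up" | "down"
    negative: bool
    evidence: str = "degradome_validated"


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series,
                 mapped_totals: pd.Series | None = None) -> pd.DataFrame:
    """FPKM = count / (length/1e3 * mapped_reads/1e6), per sample."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive")
    if mapped_totals is None:
        mapped_totals = counts.sum(axis=0)
    mapped_totals = pd.Series(mapped_totals).reindex(counts.columns)
    if (mapped_totals <= 0).any():
        raise ValueError("mapped totals must be positive")
    return counts.div(lengths / 1e3, axis=0).div(mapped_totals / 1e6, axis=1)


def diff_expression_genes(fpkm: pd.DataFrame, design: dict[str, str],
                          pair: tuple[str, str], n_boot: int = 1000,
                          seed: int = 0, min_log2fc: float = 1.0,
                          min_probability: float = 0.8
                          ) -> list[GeneDiffCall]:
    """Bootstrap fold-change calls for one condition pair (A vs B).

    The probability is the fraction of ``n_boot`` replicate resamples
    (with replacement, per group) in which |log2 FC| of group-mean FPKM
    exceeds ``min_log2fc``; a gene is DE when the point fold change and
    the probability both clear their thresholds.
    """
    cond_a, cond_b = pair
    sa = [s for s in fpkm.columns if design.get(s) == cond_a]
    sb = [s for s in fpkm.columns if design.get(s) == cond_b]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("at least 2 replicates per condition are required")
    rng = np.random.default_rng(seed)
    a = fpkm[sa].to_numpy()
    b = fpkm[sb].to_numpy()
    log2fc = np.log2((a.mean(axis=1) + PSEUDOCOUNT)
                     / (b.mean(axis=1) + PSEUDOCOUNT))
    ia = rng.integers(0, len(sa), size=(n_boot, len(sa)))
    ib = rng.integers(0, len(sb), size=(n_boot, len(sb)))
    boot_a = a[:, ia].mean(axis=2)     # genes x n_boot
    boot_b = b[:, ib].mean(axis=2)
    boot_fc = np.log2((boot_a + PSEUDOCOUNT) / (boot_b + PSEUDOCOUNT))
    prob = (np.abs(boot_fc) > min_log2fc).mean(axis=1)
    calls = []
    for i, gid in enumerate(fpkm.index):
        status = "ns"
        if abs(log2fc[i]) > min_log2fc and prob[i] > min_probability:
            status = "up" if log2fc[i] > 0 else "down"
        calls.append(GeneDiffCall(gid, pair, float(log2fc[i]),
                                  float(prob[i]), status))
    return calls


def gene_diff_table(calls: list[GeneDiffCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": c.gene_id, "condition_a": c.condition_pair[0],
        "condition_b": c.condition_pair[1], "log2fc": c.log2fc,
        "probability": c.probability, "status": c.status} for c in calls])


def correlate(mirna_diff: pd.DataFrame, gene_diff: pd.DataFrame,
              validated_targets: list[tuple[str, str]]
              ) -> list[CorrelationPair]:
    """Cross validated miRNA->gene pairs with the two DE tables.

    A pair is emitted per condition pair in which the gene is DE; it is
    negative when the miRNA moves the opposite way.  miRNAs without a
    significant call are labelled "flat" (such pairs are retained but not
    negative).
    """
    m_idx = {(r.feature_id, (r.condition_a, r.condition_b)): r.status
             for r in mirna_diff.itertuples()}
    out = []
    for mirna_id, gene_id in validated_targets:
        sub = gene_diff[(gene_diff.gene_id == gene_id)
                        & (gene_diff.status != "ns")]
        for r in sub.itertuples():
            pair = (r.condition_a, r.condition_b)
            m_dir = m_idx.get((mirna_id, pair), "ns")
            if m_dir == "ns":
                m_dir = "flat"
            negative = {m_dir, r.status} == {"up", "down"}
            out.append(CorrelationPair(mirna_id, gene_id, pair, m_dir,
                                       r.status, negative))
    return out


def enrichment(target_genes: set[str], annotation_map: dict[str, set[str]],
               universe: set[str], alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms.

    ``annotation_map`` maps gene -> set of terms.  For each term with K
    universe genes, p = P[X >= k] drawing |targets| genes from the
    universe.  Benjamini-Hochberg q-values across terms; ``significant``
    marks q < alpha.  Terms absent from the universe are skipped.
    """
    if not target_genes <= universe:
        raise ValueError("target genes must be a subset of the universe")
    term_universe: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    for gene in universe:
        for term in annotation_map.get(gene, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in target_genes:
                term_hits[term] = term_hits.get(term, 0) + 1
    rows = []
    N, n = len(universe), len(target_genes)
    for term in sorted(term_universe):
        K = term_universe[term]
        k = term_hits.get(term, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "universe_count": K, "target_count": k,
                     "pvalue": p})
    df = pd.DataFrame(rows,
                      columns=["term", "universe_count", "target_count",
                               "pvalue"])
    if len(df):
        df["qvalue_bh"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        df["significant"] = df["qvalue_bh"] < alpha
    return df


def expressed_universe(fpkm: pd.DataFrame) -> set[str]:
    """Default enrichment background: genes with FPKM > 0 in >= 1 sample."""
    return set(fpkm.index[(fpkm > 0).any(axis=1)])
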