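"""Mature miRNA quantification, TPM normalisation and differential calls.

Quantification is isomiR-tolerant: a tag counts toward a mature sequence
when an ungapped alignment matches exactly everywhere outside the
terminal 3 nt at each end and carries at most 3 end mismatches plus
overhang nucleotides per end.  Abundances are normalised to tags per
million clean reads (TPM = count / clean_reads * 1e6).  Differential
expression between condition pairs uses the Audic-Claverie exact test on
pooled raw counts with library-size offsets (two-sided), with calls at
|log2 fold change| >= 1 and p < 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .preprocess import SmallRNATag

PSEUDOCOUNT = 0.01


@dataclass
class DiffCall:
    feature_id: str
    condition_pair: tuple[str, str]
    log2fc: float
    pvalue: float
    status: str  # "up" | "down" | "ns"


def _end_match(tag: str, mature: str, shift: int,
               max_end_edits: int = 3) -> bool:
    """Check one ungapped register (mature start at ``shift`` within tag).

    Positions outside the terminal 3 nt of each end of the overlap must
    match exactly; each end's overhang plus terminal mismatches must not
    exceed ``max_end_edits``.
    """
    lo = max(0, shift)
    hi = min(len(tag), shift + len(mature))
    if hi - lo < max(len(mature) - max_end_edits, 1):
        return False
    left_over = lo + max(0, -shift)          # unaligned nt at the 5' ends
    right_over = (len(tag) - hi) + max(0, shift + len(mature) - len(tag))
    left_edits, right_edits = left_over, right_over
    for i in range(lo, hi):
        if tag[i] != mature[i - shift]:
            if i - lo < 3:
                left_edits += 1
            elif hi - 1 - i < 3:
                right_edits += 1
            else:
                return False                  # mismatch in the middle
    return left_edits <= max_end_edits and right_edits <= max_end_edits


def assign_tag(tag: str, matures: list[tuple[str, str]],
               max_shift: int = 3) -> str | None:
    """Best mature for one tag under the isomiR rule, or None.

    Ties are broken by fewest total end edits, then catalog order.
    """
    best: tuple[int, int] | None = None
    best_id = None
    for order, (mid, mature) in enumerate(matures):
        core = mature[3:-3]
        if core and core not in tag:
            continue
        for shift in range(-max_shift, max_shift + 1):
            if _end_match(tag, mature, shift):
                edits = abs(shift) + abs(shift + len(mature) - len(tag))
                key = (edits, order)
                if best is None or key < best:
                    best, best_id = key, mid
                break
    return best_id


def quantify_mirna(tags: list[SmallRNATag],
                   catalog: list[tuple[str, str]],
                   samples: list[str]) -> pd.DataFrame:
    """Raw mature-miRNA count matrix (miRNA x sample).

    ``catalog`` is an ordered list of (mirna_id, mature_sequence).
    Duplicate mature sequences across precursors are counted once, under
    the first catalog entry carrying that sequence.  Each tag contributes
    to at most one mature.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    seen: set[str] = set()
    unique: list[tuple[str, str]] = []
    for mid, seq in catalog:
        key = seq.upper().replace("U", "T")
        if key not in seen:
            seen.add(key)
            unique.append((mid, key))
    counts = pd.DataFrame(0, index=[m for m, _ in unique], columns=samples,
                          dtype=np.int64)
    for tag in tags:
        mid = assign_tag(tag.sequence.upper().replace("U", "T"), unique)
        if mid is not None:
            for s, c in tag.counts.items():
                counts.loc[mid, s] += c
    return counts


def normalize_tpm(counts: pd.DataFrame, clean_reads: dict[str, int]
                  ) -> pd.DataFrame:
    """Tags-per-million: count / total clean reads * 1e6, per sample."""
    totals = pd.Series(clean_reads, dtype=float).reindex(counts.columns)
    if (totals <= 0).any() or totals.isna().any():
        raise ValueError("clean_reads must be positive for every sample")
    return counts / totals * 1e6


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie exact p for pooled counts x (lib n1) vs y (n2).

    The conditional law of y given x under equal per-base rates is negative
    binomial with size x+1 and success probability n1/(n1+n2).  The
    two-sided p doubles the smaller of the two conditional lower tails
    P(Y <= y | x) and P(X <= x | y) (capped at 1), which makes the test
    exactly symmetric under swapping the groups.
    """
    tail_y = nbinom.cdf(y, x + 1, n1 / (n1 + n2))
    tail_x = nbinom.cdf(x, y + 1, n2 / (n1 + n2))
    return float(min(1.0, 2.0 * min(tail_y, tail_x)))


def diff_expression(counts: pd.DataFrame, tpm: pd.DataFrame,
                    design: dict[str, str], pair: tuple[str, str],
                    alpha: float = 1e-3, min_log2fc: float = 1.0
                    ) -> list[DiffCall]:
    """Audic-Claverie differential calls for one condition pair (A vs B).

    log2fc = log2((mean TPM_A + c) / (mean TPM_B + c)) with pseudocount
    c = 0.01; p from pooled raw counts with the pooled library sizes as
    offsets.  Status 'up' means higher in condition A.
    """
    cond_a, cond_b = pair
    sa = [s for s in counts.columns if design.get(s) == cond_a]
    sb = [s for s in counts.columns if design.get(s) == cond_b]
    if not sa or not sb:
        raise ValueError(f"no samples for condition pair {pair}")
    lib = counts.sum(axis=0)
    n1, n2 = float(lib[sa].sum()), float(lib[sb].sum())
    x = counts[sa].sum(axis=1).to_numpy()
    y = counts[sb].sum(axis=1).to_numpy()
    log2fc = np.log2((tpm[sa].mean(axis=1).to_numpy() + PSEUDOCOUNT)
                     / (tpm[sb].mean(axis=1).to_numpy() + PSEUDOCOUNT))
    tail_y = nbinom.cdf(y, x + 1, n1 / (n1 + n2))
    tail_x = nbinom.cdf(x, y + 1, n2 / (n1 + n2))
    pvals = np.minimum(1.0, 2.0 * np.minimum(tail_y, tail_x))
    calls = []
    for i, fid in enumerate(counts.index):
        status = "ns"
        if abs(log2fc[i]) >= min_log2fc and pvals[i] < alpha:
            status = "up" if log2fc[i] > 0 else "down"
        calls.append(DiffCall(fid, pair, float(log2fc[i]), float(pvals[i]), status))
    return calls


def diff_table(calls: list[DiffCall]) -> pd.DataFrame:
    """Flat table of differential calls with a BH-adjusted column.

    The adjusted q-value is reported for reference only; status keeps the
    raw p < alpha convention.
    """
    df = pd.DataFrame([{
        "feature_id": c.feature_id, "condition_a": c.condition_pair[0],
        "condition_b": c.condition_pair[1], "log2fc": c.log2fc,
        "pvalue": c.pvalue, "status": c.status} for c in calls])
    if len(df):
        df["qvalue_bh"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df


ALL_PAIRS = [("HS", "LS"), ("HL", "LL"), ("HL", "HS"),
             ("LL", "LS"), ("HS", "LL"), ("HL", "LS")]


def diff_all_pairs(counts: pd.DataFrame, tpm: pd.DataFrame,
                   design: dict[str, str],
                   pairs: list[tuple[str, str]] = ALL_PAIRS,
                   alpha: float = 1e-3) -> pd.DataFrame:
    frames = [diff_table(diff_expression(counts, tpm, design, pair, alpha=alpha))
              for pair in pairs]
    return pd.concat(frames, ignore_index=True)
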