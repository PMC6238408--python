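"""Plant miRNA target prediction by complementarity penalty scoring.

Each miRNA:target duplex is scored with the standard plant convention:
mismatch 1.0, G:U wobble 0.5, gapped position 2.0, with all penalties
doubled over the functionally critical miRNA positions 2-13 (numbered
from the miRNA 5' end).  Transcripts are scanned on the sense strand by
an exhaustive ungapped pass plus a banded dynamic program allowing up to
two gaps.  Two stringency configurations play the roles of the two
commonly used prediction tools: a strict ungapped pass (cutoff 2.5) and
a permissive gapped pass (cutoff 4.0); their intersection keyed by
(miRNA, transcript) is the consensus prediction set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_SENTINEL = 4
_BIG = 1e6

#: per-position penalty by (miRNA base, target base), both 5'->3'
PENALTY = np.full((5, 5), 1.0)
PENALTY[:, _SENTINEL] = _BIG
PENALTY[_SENTINEL, :] = _BIG
for _m, _t in ((0, 3), (3, 0), (1, 2), (2, 1)):   # Watson-Crick
    PENALTY[_m, _t] = 0.0
PENALTY[2, 3] = PENALTY[3, 2] = 0.5               # G:U wobble

MISMATCH, WOBBLE, GAP_PENALTY = 1.0, 0.5, 2.0
CRITICAL_REGION = (2, 13)   # miRNA positions with doubled penalties


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, _SENTINEL) for c in seq.upper()],
                    dtype=np.int64)


def position_weights(length: int) -> np.ndarray:
    """Penalty multiplier per miRNA position 1..length."""
    w = np.ones(length)
    lo, hi = CRITICAL_REGION
    w[lo - 1:hi] = 2.0
    return w


@dataclass(frozen=True)
class ScanConfig:
    """One stringency configuration of the scanner."""

    name: str
    cutoff: float
    allow_gaps: bool


CONFIG_A = ScanConfig("strict", 2.5, allow_gaps=False)
CONFIG_B = ScanConfig("permissive", 4.0, allow_gaps=True)


@dataclass
class DuplexAlignment:
    """A scored miRNA:target pairing on transcript coordinates."""

    mirna_id: str
    transcript_id: str
    target_start0: int
    target_end0: int
    score: float
    pair_states: list[str] = field(default_factory=list)   # per miRNA position

    def pairing_string(self) -> str:
        glyph = {"match": "|", "GU": "o", "mismatch": ".", "gap": "-"}
        return "".join(glyph[s] for s in self.pair_states)


def _pair_state(m: str, t: str) -> str:
    pm, pt = _CODE.get(m.upper(), _SENTINEL), _CODE.get(t.upper(), _SENTINEL)
    pen = PENALTY[pm, pt]
    return "match" if pen == 0.0 else ("GU" if pen == 0.5 else "mismatch")


def score_duplex(mirna: str, site: str) -> tuple[float, list[str]]:
    """Score an aligned miRNA:site duplex (both 5'->3', '-' for gaps).

    Without gaps the two strings must be equal length; with gaps they are
    aligned strings of equal length.  Aligned column c pairs miRNA column
    c with site column (len-1-c) — the strands are antiparallel.  Returns
    the summed penalty and the per-miRNA-position states.
    """
    if len(mirna) != len(site):
        raise ValueError("aligned miRNA and site strings differ in length")
    if mirna.count("-") + site.count("-") > 2:
        raise ValueError("more than 2 gaps in the alignment")
    score = 0.0
    states: list[str] = []
    pos = 0   # miRNA position of the last consumed miRNA base
    ncols = len(mirna)
    lo, hi = CRITICAL_REGION
    for c in range(ncols):
        m, t = mirna[c], site[ncols - 1 - c]
        if m == "-" and t == "-":
            raise ValueError("double-gap alignment column")
        if m != "-":
            pos += 1
            w = 2.0 if lo <= pos <= hi else 1.0
            if t == "-":
                score += GAP_PENALTY * w
                states.append("gap")
            else:
                st = _pair_state(m, t)
                score += PENALTY[_CODE[m.upper()], _CODE[t.upper()]] * w
                states.append(st)
        else:  # bulged target base, attributed to the next miRNA position
            w = 2.0 if lo <= pos + 1 <= hi else 1.0
            score += GAP_PENALTY * w
    return score, states


def ungapped_scores(mirna_codes: np.ndarray, t_codes: np.ndarray) -> np.ndarray:
    """Penalty of every ungapped site, indexed by site end (exclusive).

    Entry k is the score of the site t[k-L:k] for k in [L, len(t)];
    returned array has length len(t)+1 with +inf for k < L.
    """
    L = len(mirna_codes)
    n = len(t_codes)
    out = np.full(n + 1, np.inf)
    if n < L:
        return out
    w = position_weights(L)
    acc = np.zeros(n - L + 1)
    for p in range(1, L + 1):
        acc += w[p - 1] * PENALTY[mirna_codes[p - 1], t_codes[L - p:n - p + 1]]
    out[L:] = acc
    return out


def ungapped_scores_batch(mirna_matrix: np.ndarray,
                          t_codes: np.ndarray) -> np.ndarray:
    """Ungapped site scores for many same-length miRNAs at once.

    Rows of ``mirna_matrix`` are coded miRNAs; returns (n_mirnas,
    n_sites) where column k is the site ending at position L+k.
    """
    S, L = mirna_matrix.shape
    n = len(t_codes)
    w = position_weights(L)
    acc = np.zeros((S, n - L + 1))
    for p in range(1, L + 1):
        acc += w[p - 1] * PENALTY[mirna_matrix[:, p - 1], :][:, t_codes[L - p:n - p + 1]]
    return acc


def _gapped_scores(mirna_codes: np.ndarray, t_codes: np.ndarray,
                   max_gaps: int = 2) -> dict[int, np.ndarray]:
    """Banded gapped site scores by net length offset d (site len = L+d).

    Returns {d: scores indexed by site end}, minimised over gap counts
    <= max_gaps; |d| <= max_gaps.
    """
    L = len(mirna_codes)
    n = len(t_codes)
    w = position_weights(L)
    pad = L + max_gaps + 1
    tp = np.concatenate([np.full(pad, _SENTINEL, dtype=np.int64), t_codes,
                         np.full(pad, _SENTINEL, dtype=np.int64)])
    n_e = n + 1   # site end positions 0..n
    states = {(d, g): np.full(n_e, _BIG)
              for d in range(-max_gaps, max_gaps + 1)
              for g in range(abs(d), max_gaps + 1)}
    states[(0, 0)] = np.zeros(n_e)
    e_idx = np.arange(n_e)
    for p in range(1, L + 1):
        new = {k: np.full(n_e, _BIG) for k in states}
        for (d, g), prev in states.items():
            # pair/mismatch: consume one miRNA and one target base
            cost = w[p - 1] * PENALTY[mirna_codes[p - 1], tp[e_idx - p - d + pad]]
            cand = prev + cost
            cur = new[(d, g)]
            np.minimum(cur, cand, out=cur)
            # bulged miRNA base: consume miRNA only
            if g + 1 <= max_gaps and (d - 1, g + 1) in new:
                cand = prev + GAP_PENALTY * w[p - 1]
                cur = new[(d - 1, g + 1)]
                np.minimum(cur, cand, out=cur)
        # bulged target base between miRNA positions p and p+1
        wb = w[min(p, L - 1)]
        for d in range(-max_gaps + 1, max_gaps + 1):
            for g in range(abs(d), max_gaps):
                if (d - 1, g) in new:
                    cand = new[(d - 1, g)] + GAP_PENALTY * wb
                    cur = new[(d, g + 1)]
                    np.minimum(cur, cand, out=cur)
        states = new
    best: dict[int, np.ndarray] = {}
    for d in range(-max_gaps, max_gaps + 1):
        arrs = [states[(d, g)] for g in range(abs(d), max_gaps + 1)]
        merged = np.minimum.reduce(arrs)
        merged[e_idx - L - d < 0] = _BIG   # site would start before the transcript
        best[d] = merged
    return best


def _align_site(mirna: str, site: str, max_gaps: int = 2
                ) -> tuple[float, list[str]]:
    """Optimal gapped alignment of one miRNA against one excised site."""
    L, n = len(mirna), len(site)
    w = position_weights(L)
    mc, tc = encode(mirna), encode(site)[::-1]   # walk target 3'->5'
    INF = _BIG
    # dp[p][c][g]: miRNA 1..p aligned against c target bases using g gaps
    dp = np.full((L + 1, n + 1, max_gaps + 1), INF)
    dp[0, 0, 0] = 0.0
    back = {}
    for p in range(L + 1):
        for c in range(n + 1):
            for g in range(max_gaps + 1):
                cur = dp[p, c, g]
                if cur >= INF:
                    continue
                if p < L and c < n:
                    cost = w[p] * PENALTY[mc[p], tc[c]]
                    if cur + cost < dp[p + 1, c + 1, g]:
                        dp[p + 1, c + 1, g] = cur + cost
                        back[(p + 1, c + 1, g)] = (p, c, g, "pair")
                if p < L and g < max_gaps:
                    cost = GAP_PENALTY * w[p]
                    if cur + cost < dp[p + 1, c, g + 1]:
                        dp[p + 1, c, g + 1] = cur + cost
                        back[(p + 1, c, g + 1)] = (p, c, g, "mgap")
                if c < n and g < max_gaps:
                    cost = GAP_PENALTY * w[min(p, L - 1)]
                    if cur + cost < dp[p, c + 1, g + 1]:
                        dp[p, c + 1, g + 1] = cur + cost
                        back[(p, c + 1, g + 1)] = (p, c, g, "tgap")
    g_best = int(np.argmin(dp[L, n, :]))
    score = float(dp[L, n, g_best])
    states: list[str] = []
    p, c, g = L, n, g_best
    while (p, c, g) != (0, 0, 0):
        p2, c2, g2, move = back[(p, c, g)]
        if move == "pair":
            states.append(_pair_state(mirna[p2], site[n - 1 - c2]))
        elif move == "mgap":
            states.append("gap")
        p, c, g = p2, c2, g2
    states.reverse()
    return score, states


def scan_transcripts(mirna_id: str, mirna: str, transcripts: dict[str, str],
                     config: ScanConfig = CONFIG_B,
                     cutoff: float | None = None) -> list[DuplexAlignment]:
    """All sense-strand sites of one miRNA with score <= cutoff.

    Overlapping hits are reduced to the best-scoring one (ties: leftmost).
    """
    cutoff = config.cutoff if cutoff is None else cutoff
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    mc = encode(mirna)
    L = len(mc)
    out: list[DuplexAlignment] = []
    for tid, tseq in transcripts.items():
        tc = encode(tseq)
        hits: list[tuple[int, int, float]] = []   # start, end, score
        if config.allow_gaps:
            for d, scores in _gapped_scores(mc, tc).items():
                for e in np.nonzero(scores <= cutoff)[0]:
                    hits.append((int(e) - L - d, int(e), float(scores[e])))
        else:
            scores = ungapped_scores(mc, tc)
            for e in np.nonzero(scores <= cutoff)[0]:
                hits.append((int(e) - L, int(e), float(scores[e])))
        for s, e, sc in sorted(hits, key=lambda h: (h[2], h[0])):
            if any(s < ke and ks < e for ks, ke, _ in
                   [(a.target_start0, a.target_end0, None) for a in out
                    if a.transcript_id == tid]):
                continue
            site = tseq[s:e]
            if config.allow_gaps:
                score, states = _align_site(mirna, site)
            else:
                score, states = score_duplex(mirna, site)
            out.append(DuplexAlignment(mirna_id, tid, s, e, score, states))
    return sorted(out, key=lambda a: (a.transcript_id, a.target_start0))


def scan_catalog(catalog: list[tuple[str, str]], transcripts: dict[str, str],
                 config: ScanConfig) -> list[DuplexAlignment]:
    out = []
    for mid, mature in catalog:
        out.extend(scan_transcripts(mid, mature, transcripts, config))
    return out


def intersect_predictions(set_a: list[DuplexAlignment],
                          set_b: list[DuplexAlignment]
                          ) -> set[tuple[str, str]]:
    """(miRNA, transcript) pairs present in both prediction sets.

    Site coordinates need not match between the two configurations.
    """
    keys_a = {(a.mirna_id, a.transcript_id) for a in set_a}
    keys_b = {(b.mirna_id, b.transcript_id) for b in set_b}
    return keys_a & keys_b
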