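"""Degradome (PARE) profiles and cleavage-site validation.

Degradome tags are 5' ends of uncapped mRNA fragments; a pile-up of tag
5' ends opposite miRNA positions 10/11 of a predicted site is the
signature of miRNA-guided slicing.  A predicted alignment is validated
when its penalty score is at most 4 and the transcript position opposite
miRNA position 10 or 11 carries degradome signal; events are categorised
by the abundance rank of the cleavage position within the transcript's
profile (CleaveLand-style categories 0-4) and assigned an empirical
p-value from composition-preserving miRNA shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .targets import DuplexAlignment, encode, ungapped_scores_batch

SCORE_MAX = 4.0


@dataclass
class DegradomeProfile:
    """Per-transcript tag 5'-end counts (0-based positions)."""

    transcript_id: str
    end5_counts: np.ndarray

    @property
    def total_tags(self) -> int:
        return int(self.end5_counts.sum())


@dataclass
class CleavageEvent:
    mirna_id: str
    transcript_id: str
    cleavage_pos0: int
    opposite_mirna_pos: int      # 10 or 11
    site_score: float
    abundance: int
    category: int = -1
    pvalue: float = float("nan")
    site: tuple[int, int] = field(default=(0, 0))


def map_degradome(tags: list[tuple[str, str]], transcripts: dict[str, str],
                  min_len: int = 18) -> dict[str, DegradomeProfile]:
    """Exact sense-strand placement of tag 5' ends onto transcripts.

    Multi-hit tags count at every hit.  Returns a profile per transcript
    (all transcripts, including tag-free ones with all-zero profiles).
    """
    profiles = {tid: DegradomeProfile(tid, np.zeros(len(seq), dtype=np.int64))
                for tid, seq in transcripts.items()}
    counts: dict[str, int] = {}
    for _tid, seq in tags:
        if len(seq) >= min_len:
            counts[seq] = counts.get(seq, 0) + 1
    k = min((len(s) for s in counts), default=18)
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in transcripts.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((tid, i))
    for tagseq, n in counts.items():
        for tid, i in index.get(tagseq[:k], ()):
            if transcripts[tid][i:i + len(tagseq)] == tagseq:
                profiles[tid].end5_counts[i] += n
    return profiles


def categorize_event(abundance: int, profile: DegradomeProfile) -> int:
    """CleaveLand-style category of one cleavage position.

    0: unique transcript maximum; 1: tied maximum; 4: a singleton that is
    not the maximum; 2: above the median of non-zero positions but below
    the maximum; 3: at or below that median.
    """
    if abundance <= 0:
        raise ValueError("category undefined for zero abundance")
    counts = profile.end5_counts
    cmax = counts.max()
    if abundance == cmax:
        return 0 if (counts == cmax).sum() == 1 else 1
    if abundance == 1:
        return 4
    med = np.median(counts[counts > 0])
    return 2 if abundance > med else 3


def detect_cleavage(profiles: dict[str, DegradomeProfile],
                    alignments: list[DuplexAlignment],
                    score_max: float = SCORE_MAX) -> list[CleavageEvent]:
    """Cleavage events at predicted sites with position-10/11 signal.

    For each alignment with penalty score <= score_max, the transcript
    positions opposite miRNA positions 10 and 11 are inspected; an event
    is emitted when either carries tag 5' ends (the better-supported of
    the two wins).  Alignments whose opposite positions fall outside the
    transcript are skipped with a warning.
    """
    events: list[CleavageEvent] = []
    for aln in alignments:
        if aln.score > score_max:
            continue
        prof = profiles.get(aln.transcript_id)
        if prof is None:
            continue
        candidates = []
        for opp in (10, 11):
            pos = aln.target_end0 - opp
            if not 0 <= pos < len(prof.end5_counts):
                warnings.warn(
                    f"opposite position {pos} outside {aln.transcript_id}; "
                    f"alignment skipped")
                candidates = []
                break
            candidates.append((int(prof.end5_counts[pos]), opp, pos))
        if not candidates:
            continue
        abundance, opp, pos = max(candidates, key=lambda c: (c[0], -c[1]))
        if abundance <= 0:
            continue
        ev = CleavageEvent(aln.mirna_id, aln.transcript_id, pos, opp,
                           aln.score, abundance,
                           site=(aln.target_start0, aln.target_end0))
        ev.category = categorize_event(abundance, prof)
        events.append(ev)
    return events


def cleavage_pvalue(event: CleavageEvent, profile: DegradomeProfile,
                    mirna: str, transcript_seq: str,
                    n_shuffles: int = 1000, seed: int = 0) -> float:
    """Empirical p of one event from composition-preserving miRNA shuffles.

    Each shuffled miRNA is rescanned (ungapped) over the transcript; a
    shuffle counts as a hit when some site scores at most the event's
    site score with a position-10/11 partner whose tag abundance is at
    least the event's.  p = (1 + hits) / (1 + n_shuffles).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    mc = encode(mirna)
    L = len(mc)
    tc = encode(transcript_seq)
    if len(tc) < L:
        return 1.0
    shuffled = np.stack([rng.permutation(mc) for _ in range(n_shuffles)])
    scores = ungapped_scores_batch(shuffled, tc)   # (n_shuffles, n_sites)
    counts = profile.end5_counts
    n_sites = scores.shape[1]
    ends = np.arange(L, L + n_sites)
    ok = np.zeros(n_sites, dtype=bool)
    for opp in (10, 11):
        pos = ends - opp
        valid = (pos >= 0) & (pos < len(counts))
        hit = np.zeros(n_sites, dtype=bool)
        hit[valid] = counts[pos[valid]] >= event.abundance
        ok |= hit
    hits = int(((scores <= event.site_score) & ok[None, :]).any(axis=1).sum())
    return (1 + hits) / (1 + n_shuffles)


def attach_pvalues(events: list[CleavageEvent],
                   profiles: dict[str, DegradomeProfile],
                   matures: dict[str, str], transcripts: dict[str, str],
                   n_shuffles: int = 1000, seed: int = 0
                   ) -> list[CleavageEvent]:
    """Compute p-values in place for a list of events (seeded per event)."""
    for i, ev in enumerate(events):
        ev.pvalue = cleavage_pvalue(
            ev, profiles[ev.transcript_id], matures[ev.mirna_id],
            transcripts[ev.transcript_id], n_shuffles=n_shuffles,
            seed=seed + i)
    return events


def tplot_data(profile: DegradomeProfile,
               event: CleavageEvent | None = None) -> pd.DataFrame:
    """T-plot series: tag abundance by transcript position.

    Rows are the full profile; the ``highlight`` column marks the
    validated cleavage position (at most one row).
    """
    n = len(profile.end5_counts)
    df = pd.DataFrame({
        "position0": np.arange(n),
        "abundance": profile.end5_counts,
        "highlight": np.zeros(n, dtype=bool),
    })
    if event is not None and 0 <= event.cleavage_pos0 < n:
        df.loc[event.cleavage_pos0, "highlight"] = True
    return df


def events_table(events: list[CleavageEvent]) -> pd.DataFrame:
    """Events as a 1-based TSV-ready table."""
    return pd.DataFrame([{
        "mirna_id": e.mirna_id, "transcript_id": e.transcript_id,
        "cleavage_site_1based": e.cleavage_pos0 + 1,
        "opposite_mirna_pos": e.opposite_mirna_pos,
        "score": e.site_score, "abundance": e.abundance,
        "category": e.category, "pvalue": e.pvalue,
    } for e in events])
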