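"""miRNA discovery: hairpin evaluation of candidate precursor windows.

Flagged tags seed genomic windows that are folded and screened with the
plant miRNA annotation criteria: a single stem-loop structure, the mature
tag confined to one arm, exact 2-nt 3' overhangs of the miRNA/miRNA*
duplex when both arms are sequenced, no large internal loops or bulges in
the mature-spanning duplex, a minimum free energy at or below
-18 kcal/mol, and a dominant-arm read count greater than 5.  Accepted
precursors are matched to known mature families (<=2 substitutions and
<=2 nt total end offset) and named by genome order.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field

from .folding import EnergyModel, DEFAULT_MODEL, fold_hairpin, pair_chain, pair_table
from .preprocess import SmallRNATag
from .util import revcomp

# rejection reason codes, one per criterion
NOT_HAIRPIN = "NOT_HAIRPIN"
MATURE_NOT_IN_ARM = "MATURE_NOT_IN_ARM"
OVERHANG = "OVERHANG"
LARGE_LOOP = "LARGE_LOOP"
MFE_GATE = "MFE_GATE"
MIN_COUNT = "MIN_COUNT"


@dataclass
class CandidateWindow:
    """Oriented genomic window hosting a potential precursor."""

    chrom: str
    start0: int
    end0: int
    strand: str
    seq: str


@dataclass
class HairpinCall:
    """Folded candidate precursor with accept/reject bookkeeping."""

    locus: tuple[str, int, int, str]
    precursor_seq: str
    structure: str
    mfe: float
    mature_5p: str | None
    mature_3p: str | None
    dominant_arm: str
    dominant_count: int
    reasons: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.reasons

    @property
    def mature(self) -> str | None:
        return self.mature_5p if self.dominant_arm == "5p" else self.mature_3p


@dataclass
class MiRNARecord:
    name: str
    family: str
    novelty: str            # "known" | "novel"
    best_match: str | None
    call: HairpinCall


def extract_candidates(tags: list[SmallRNATag], genome: dict[str, str],
                       min_seed_count: int = 6, flank_long: int = 180,
                       flank_short: int = 20) -> list[CandidateWindow]:
    """Two windows per strand-oriented genome hit of each seeding tag.

    Windows span [tag - flank_short, tag + flank_long] and the mirror
    [tag - flank_long, tag + flank_short] in transcription orientation,
    clipped at chromosome edges.  Near-duplicate windows (>=90 % overlap
    on the same chromosome and strand) are dropped.
    """
    raw: list[tuple[str, str, int, int]] = []
    for tag in tags:
        if tag.total < min_seed_count:
            continue
        for chrom, s, e, strand in tag.genome_hits:
            clen = len(genome[chrom])
            for a, b in ((s - flank_short, e + flank_long),
                         (s - flank_long, e + flank_short)):
                raw.append((chrom, strand, max(0, a), min(clen, b)))
    raw = sorted(set(raw))
    kept: list[tuple[str, str, int, int]] = []
    for chrom, strand, s, e in raw:
        dup = False
        for kc, ks, a, b in kept:
            if kc == chrom and ks == strand:
                ov = min(e, b) - max(s, a)
                if ov >= 0.9 * (e - s):
                    dup = True
                    break
        kept.append((chrom, strand, s, e)) if not dup else None
    out = []
    for chrom, strand, s, e in kept:
        seq = genome[chrom][s:e]
        if strand == "-":
            seq = revcomp(seq)
        out.append(CandidateWindow(chrom, s, e, strand, seq))
    return out


def _positions_in_window(window: CandidateWindow,
                         tags: list[SmallRNATag]) -> list[tuple[SmallRNATag, int]]:
    """Window-relative tag placements derived from genome hits."""
    placed = []
    for tag in tags:
        hits = tag.genome_hits or _substring_hits(window, tag)
        for chrom, s, e, strand in hits:
            if (chrom == window.chrom and strand == window.strand
                    and s >= window.start0 and e <= window.end0):
                pos = (s - window.start0 if strand == "+" else window.end0 - e)
                placed.append((tag, pos))
    return placed


def _substring_hits(window: CandidateWindow, tag: SmallRNATag):
    p = window.seq.find(tag.sequence)
    if p < 0:
        return []
    if window.strand == "+":
        return [(window.chrom, window.start0 + p,
                 window.start0 + p + len(tag.sequence), "+")]
    return [(window.chrom, window.end0 - p - len(tag.sequence),
             window.end0 - p, "-")]


def evaluate_precursor(window: CandidateWindow,
                       tags: list[SmallRNATag] | list[tuple[SmallRNATag, int]],
                       model: EnergyModel = DEFAULT_MODEL,
                       mfe_max: float = -18.0, min_count: int = 5,
                       max_bulge: int = 3, max_internal_side: int = 5
                       ) -> HairpinCall:
    """Fold one window and apply the acceptance criteria.

    Rejection is a result, not an error: every failed criterion appends
    its reason code.  ``min_count`` is the exclusive lower bound on the
    summed dominant-arm tag count (the gate is "greater than 5").
    """
    if tags and isinstance(tags[0], SmallRNATag):
        placed = _positions_in_window(window, tags)  # type: ignore[arg-type]
    else:
        placed = list(tags)  # type: ignore[assignment]
    structure, mfe = fold_hairpin(window.seq, model)
    reasons: list[str] = []
    chain = pair_chain(structure)

    def _locus(a: int, b: int) -> tuple[str, int, int, str]:
        if window.strand == "+":
            return (window.chrom, window.start0 + a, window.start0 + b + 1, "+")
        n = len(window.seq)
        return (window.chrom, window.start0 + n - b - 1,
                window.start0 + n - a, "-")

    if not chain:
        reasons.append(NOT_HAIRPIN)
        reasons.append(MFE_GATE)
        return HairpinCall(_locus(0, len(window.seq) - 1), window.seq,
                           structure, mfe, None, None, "5p", 0, reasons)

    outer_i, outer_j = chain[0]
    inner_i, inner_j = chain[-1]
    mid = (inner_i + inner_j + 1) // 2

    # arm assignment of every placed tag; a few nt of slack beyond the
    # hairpin extent admits the unpaired 2-nt 3' overhangs of the duplex
    slack = 4
    arm5: list[tuple[SmallRNATag, int]] = []
    arm3: list[tuple[SmallRNATag, int]] = []
    for tag, pos in placed:
        end = pos + len(tag.sequence)
        if pos >= outer_i - slack and end <= mid:
            arm5.append((tag, pos))
        elif pos >= mid and end <= outer_j + 1 + slack:
            arm3.append((tag, pos))

    def _dominant(arm):
        return max(arm, key=lambda tp: (tp[0].total, tp[0].sequence)) if arm else None

    d5, d3 = _dominant(arm5), _dominant(arm3)
    c5 = sum(t.total for t, _ in arm5)
    c3 = sum(t.total for t, _ in arm3)
    dominant_arm = "5p" if c5 >= c3 else "3p"
    dominant_count = c5 if dominant_arm == "5p" else c3
    dom = d5 if dominant_arm == "5p" else d3

    # (2) most abundant placed tag lies entirely within one arm
    overall = max(placed, key=lambda tp: (tp[0].total, tp[0].sequence),
                  default=None)
    if overall is None or dom is None or overall[0].total > dom[0].total:
        reasons.append(MATURE_NOT_IN_ARM)
        dom = dom or overall
    if dom is None:
        reasons.append(MIN_COUNT)
        return HairpinCall(_locus(outer_i, outer_j),
                           window.seq[outer_i:outer_j + 1],
                           structure[outer_i:outer_j + 1], mfe, None, None,
                           dominant_arm, 0, reasons)

    # Criteria 3-5 are judged on the precursor proper.  When both arms are
    # sequenced the precursor region is anchored by the tag boundaries
    # [5p start, 3p end) and re-folded without flank sequence, which is
    # how the implied miRNA/miRNA* duplex is defined; with one arm only,
    # the window's hairpin extent is used as the precursor.
    if d5 is not None and d3 is not None:
        rs = d5[1]
        re_ = d3[1] + len(d3[0].sequence)
        sub_struct, sub_mfe = fold_hairpin(window.seq[rs:re_], model)
        sub_chain = pair_chain(sub_struct)
        table = pair_table(sub_struct)
        s5, e5 = 0, len(d5[0].sequence)
        s3, e3 = d3[1] - rs, re_ - rs
        if not sub_chain:
            reasons.append(NOT_HAIRPIN)
        # (3) exact 2-nt 3' overhangs on both duplex ends
        if table.get(s5) != e3 - 3 or table.get(s3) != e5 - 3:
            reasons.append(OVERHANG)
    else:
        rs, re_ = outer_i, outer_j + 1
        sub_struct = structure[rs:re_]
        sub_chain = [(a - rs, b - rs) for a, b in chain]
        sub_mfe = mfe

    # (4) loop/bulge size inside the mature-spanning duplex
    ds, de = dom[1] - rs, dom[1] + len(dom[0].sequence) - rs
    for (a, b), (a2, b2) in zip(sub_chain, sub_chain[1:]):
        touches = (min(a2, de - 1) >= max(a, ds)) or (min(b, de - 1) >= max(b2, ds))
        if not touches:
            continue
        n1, n2 = a2 - a - 1, b - b2 - 1
        if (min(n1, n2) == 0 and max(n1, n2) > max_bulge) or \
                (min(n1, n2) > 0 and max(n1, n2) > max_internal_side):
            reasons.append(LARGE_LOOP)
            break

    # (5) MFE gate: accept at or below the threshold
    if not sub_mfe <= mfe_max:
        reasons.append(MFE_GATE)

    # (6) summed dominant-arm copy number strictly greater than min_count
    if not dominant_count > min_count:
        reasons.append(MIN_COUNT)

    return HairpinCall(
        locus=_locus(rs, re_ - 1),
        precursor_seq=window.seq[rs:re_],
        structure=sub_struct,
        mfe=sub_mfe,
        mature_5p=d5[0].sequence if d5 else None,
        mature_3p=d3[0].sequence if d3 else None,
        dominant_arm=dominant_arm,
        dominant_count=dominant_count,
        reasons=reasons,
    )


_FAMILY_RE = re.compile(r"(miR\d+)", re.IGNORECASE)


def classify_known(mature: str, reference: dict[str, str],
                   max_mismatch: int = 2, max_offset: int = 2
                   ) -> tuple[str, str | None]:
    """Match a mature sequence against a known-miRNA reference.

    Known iff some reference mature aligns ungapped with at most
    ``max_mismatch`` substitutions over the overlap and a total end offset
    (5' shift plus length difference at the 3' end) of at most
    ``max_offset`` nt.  Ties: fewest mismatches, then smallest offset,
    then lexicographic reference name.  Returns (family, best_match_name)
    or ("novel", None).
    """
    q = mature.upper().replace("U", "T")
    best: tuple[int, int, str] | None = None
    for name in sorted(reference):
        r = reference[name].upper().replace("U", "T")
        for s in range(-max_offset, max_offset + 1):
            t3 = s + len(q) - len(r)
            offset = abs(s) + abs(t3)
            if offset > max_offset:
                continue
            lo = max(0, s)
            hi = min(len(q), len(r) + s)
            if hi - lo < 10:
                continue
            mism = sum(q[i] != r[i - s] for i in range(lo, hi))
            if mism <= max_mismatch:
                key = (mism, offset, name)
                if best is None or key < best:
                    best = key
    if best is None:
        return "novel", None
    name = best[2]
    m = _FAMILY_RE.search(name)
    return (m.group(1) if m else name), name


def name_mirnas(calls: list[HairpinCall], reference: dict[str, str] | None = None,
                prefix: str = "csa") -> list[MiRNARecord]:
    """Assign family-based names, suffixed alphabetically by genome order.

    Known members of a multi-locus family get suffixes a, b, c ... ordered
    by (chrom, start); single-member families carry no suffix.  Novel
    precursors are serialised as ``{prefix}-novel-mir{n}`` in genome order.
    """
    seen = set()
    for call in calls:
        if call.locus in seen:
            raise ValueError(f"duplicate precursor locus {call.locus}")
        seen.add(call.locus)
    classified = []
    for call in sorted(calls, key=lambda c: (c.locus[0], c.locus[1])):
        family, match = classify_known(call.mature, reference) if reference \
            else ("novel", None)
        classified.append((family, match, call))
    records: list[MiRNARecord] = []
    by_family: dict[str, list] = {}
    novels = []
    for family, match, call in classified:
        if family == "novel":
            novels.append((match, call))
        else:
            by_family.setdefault(family, []).append((match, call))
    for family in sorted(by_family):
        members = by_family[family]
        for i, (match, call) in enumerate(members):
            suffix = chr(ord("a") + i) if len(members) > 1 else ""
            records.append(MiRNARecord(f"{prefix}-{family}{suffix}", family,
                                       "known", match, call))
    for serial, (match, call) in enumerate(novels, start=1):
        records.append(MiRNARecord(f"{prefix}-novel-mir{serial}", "novel",
                                   "novel", match, call))
    return records


def _dedup_calls(calls: list[HairpinCall]) -> list[HairpinCall]:
    """Collapse accepted calls whose precursor loci overlap; keep lowest MFE."""
    kept: list[HairpinCall] = []
    for call in sorted(calls, key=lambda c: (c.mfe, -(c.locus[2] - c.locus[1]))):
        clash = False
        for other in kept:
            if (call.locus[0] == other.locus[0] and call.locus[3] == other.locus[3]
                    and call.locus[1] < other.locus[2]
                    and other.locus[1] < call.locus[2]):
                clash = True
                break
        if not clash:
            kept.append(call)
    return kept


def discover(tags: list[SmallRNATag], genome: dict[str, str],
             reference: dict[str, str] | None = None, prefix: str = "csa",
             min_seed_count: int = 6, mfe_max: float = -18.0,
             min_count: int = 5, model: EnergyModel = DEFAULT_MODEL
             ) -> tuple[list[MiRNARecord], list[HairpinCall]]:
    """Full discovery pass: windows -> hairpin calls -> named catalog.

    Returns the named records for accepted, locus-deduplicated precursors
    and the complete list of hairpin calls (accepted and rejected).
    """
    windows = extract_candidates(tags, genome, min_seed_count=min_seed_count)
    # index tag hits per (chrom, strand) for fast window placement
    by_loc: dict[tuple[str, str], list[tuple[int, int, SmallRNATag]]] = {}
    for tag in tags:
        for chrom, s, e, strand in tag.genome_hits:
            by_loc.setdefault((chrom, strand), []).append((s, e, tag))
    for lst in by_loc.values():
        lst.sort(key=lambda x: x[0])
    calls: list[HairpinCall] = []
    for w in windows:
        lst = by_loc.get((w.chrom, w.strand), [])
        starts = [x[0] for x in lst]
        placed = []
        for i in range(bisect_left(starts, w.start0), len(lst)):
            s, e, tag = lst[i]
            if s >= w.end0:
                break
            if e <= w.end0:
                pos = s - w.start0 if w.strand == "+" else w.end0 - e
                placed.append((tag, pos))
        calls.append(evaluate_precursor(w, placed, model=model, mfe_max=mfe_max,
                                        min_count=min_count))
    accepted = _dedup_calls([c for c in calls if c.accepted])
    return name_mirnas(accepted, reference, prefix=prefix), calls
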