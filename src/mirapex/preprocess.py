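"""Small-RNA read cleaning, tag collapsing and annotation.

Raw adapter-ligated reads are 3'-adapter trimmed, impurity/length
filtered to the 18-30 nt window, collapsed to non-redundant unique tags
with per-sample counts, and annotated against genome features with a
fixed class priority.  Tags in the classes that feed miRNA discovery
(reference-mature matches, intron-derived, exon-antisense and
unannotated) are flagged for the downstream hairpin search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .util import revcomp

#: class priority, highest first; first match across all genome hits wins
CLASS_PRIORITY = [
    "rRNA", "miRNA_candidate", "tRNA", "snRNA", "snoRNA", "repeat",
    "exon_sense", "exon_antisense", "intron_sense", "intron_antisense",
    "unannotated",
]

#: classes whose tags are taken forward into miRNA discovery
DISCOVERY_CLASSES = {"miRNA_candidate", "intron_sense", "intron_antisense",
                     "exon_antisense", "unannotated"}


class FastqParseError(ValueError):
    pass


@dataclass
class LibraryStats:
    """Per-library read accounting through cleaning."""

    raw_reads: int = 0
    clean_reads: int = 0
    unique_tags: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    length_histogram: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"raw_reads": self.raw_reads, "clean_reads": self.clean_reads,
                "unique_tags": self.unique_tags, "dropped": dict(self.dropped),
                "length_histogram": {str(k): v
                                     for k, v in sorted(self.length_histogram.items())}}


@dataclass
class SmallRNATag:
    """A collapsed unique read with per-sample counts and genome annotation."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    annotation_class: str = "unannotated"
    genome_hits: list[tuple[str, int, int, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def parse_fastq(path: str | Path):
    """Yield (id, seq, qual) from a FASTQ file, flagging malformed records."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield rec.id, str(rec.seq).upper(), ""
    except ValueError as exc:
        raise FastqParseError(f"malformed FASTQ in {path}: {exc}") from exc


def _find_adapter(seq: str, adapter: str, min_match: int = 8,
                  max_mismatch: int = 1) -> int:
    """Leftmost start of a >=min_match adapter-prefix match (<=1 mismatch).

    Returns -1 when no acceptable occurrence exists (including when fewer
    than ``min_match`` read bases remain).
    """
    probe = adapter[:min_match]
    limit = len(seq) - min_match
    if limit < 0:
        return -1
    exact = seq.find(probe)
    last = exact if exact != -1 else limit
    for p in range(0, last + 1):
        mism = 0
        for a, b in zip(seq[p:p + min_match], probe):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return p
    return -1


def trim_and_filter(reads, adapter: str, min_len: int = 18, max_len: int = 30
                    ) -> tuple[list[str], LibraryStats]:
    """Trim 3' adapters and drop impurities and out-of-window inserts.

    ``reads`` is an iterable of (id, sequence, quality).  Reads containing
    N, lacking an adapter hit, or trimming outside [min_len, max_len] are
    dropped and tallied by reason.  Returns the clean insert sequences and
    the library statistics.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    stats = LibraryStats()
    clean: list[str] = []
    for _rid, seq, _q in reads:
        stats.raw_reads += 1
        if "N" in seq:
            stats.dropped["impurity_N"] = stats.dropped.get("impurity_N", 0) + 1
            continue
        p = _find_adapter(seq, adapter)
        if p < 0:
            stats.dropped["no_adapter"] = stats.dropped.get("no_adapter", 0) + 1
            continue
        insert = seq[:p]
        if len(insert) < min_len:
            stats.dropped["too_short"] = stats.dropped.get("too_short", 0) + 1
            continue
        if len(insert) > max_len:
            stats.dropped["too_long"] = stats.dropped.get("too_long", 0) + 1
            continue
        clean.append(insert)
        stats.clean_reads += 1
        stats.length_histogram[len(insert)] = \
            stats.length_histogram.get(len(insert), 0) + 1
    stats.unique_tags = len(set(clean))
    return clean, stats


def collapse_tags(clean_by_sample: dict[str, list[str]]) -> list[SmallRNATag]:
    """Collapse clean reads to unique tags with per-sample counts.

    Count conservation holds exactly: the per-sample sum of tag counts
    equals that sample's clean read count.
    """
    table: dict[str, SmallRNATag] = {}
    for sample, seqs in clean_by_sample.items():
        for seq in seqs:
            tag = table.get(seq)
            if tag is None:
                tag = table[seq] = SmallRNATag(sequence=seq)
            tag.counts[sample] = tag.counts.get(sample, 0) + 1
    return sorted(table.values(), key=lambda t: t.sequence)


class _GenomeIndex:
    """Exact-match lookup of short tags in a genome, both strands."""

    def __init__(self, genome: dict[str, str], k: int = 18):
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(0, len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((chrom, i))

    def hits(self, tag: str) -> list[tuple[str, int, int, str]]:
        out = []
        for strand, probe in (("+", tag), ("-", revcomp(tag))):
            for chrom, i in self.index.get(probe[: self.k], ()):
                if self.genome[chrom][i:i + len(probe)] == probe:
                    out.append((chrom, i, i + len(probe), strand))
        return sorted(set(out))


def _class_of_hit(hit, features_by_chrom) -> list[str]:
    chrom, s, e, strand = hit
    classes = []
    for fs, fe, ftype, fstrand in features_by_chrom.get(chrom, ()):
        if s < fe and fs < e:
            if ftype in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat"):
                classes.append(ftype)
            elif ftype in ("exon", "intron"):
                sense = "sense" if strand == fstrand else "antisense"
                classes.append(f"{ftype}_{sense}")
    return classes


def annotate_tags(tags: list[SmallRNATag], genome: dict[str, str],
                  features: pd.DataFrame,
                  references: dict[str, list[str]] | None = None
                  ) -> list[SmallRNATag]:
    """Assign genome hits and one annotation class per tag.

    Features is the 0-based table (chrom/type/start0/end0/strand); classes
    are decided by the fixed :data:`CLASS_PRIORITY` across all genome hits
    of a tag, so GFF record order never matters.  ``references`` maps a
    class name (e.g. ``miRNA_candidate``) to known mature sequences; a tag
    equal to, or an end-trimmed subsequence of, a reference mature is a
    candidate of that class.
    """
    unknown = set(features["chrom"]) - set(genome)
    if unknown:
        raise ValueError(f"annotation references unknown chromosomes: {unknown}")
    idx = _GenomeIndex(genome)
    by_chrom: dict[str, list] = {}
    for rec in features.itertuples():
        by_chrom.setdefault(rec.chrom, []).append(
            (rec.start0, rec.end0, rec.type, rec.strand))
    ref_matures = (references or {}).get("miRNA_candidate", [])
    rank = {c: i for i, c in enumerate(CLASS_PRIORITY)}
    for tag in tags:
        tag.genome_hits = idx.hits(tag.sequence)
        candidates = ["unannotated"]
        if any(tag.sequence in m or m in tag.sequence for m in ref_matures):
            candidates.append("miRNA_candidate")
        for hit in tag.genome_hits:
            candidates.extend(_class_of_hit(hit, by_chrom))
        tag.annotation_class = min(candidates, key=rank.__getitem__)
    return tags


def discovery_tags(tags: list[SmallRNATag]) -> list[SmallRNATag]:
    """Tags flagged for miRNA discovery (must have >=1 genome hit)."""
    return [t for t in tags
            if t.annotation_class in DISCOVERY_CLASSES and t.genome_hits]


def frame_to_tags(df: pd.DataFrame) -> list[SmallRNATag]:
    """Inverse of :func:`tags_to_frame`."""
    samples = [c for c in df.columns if c not in ("sequence", "class", "hits")]
    tags = []
    for rec in df.to_dict("records"):
        hits = []
        if isinstance(rec["hits"], str) and rec["hits"]:
            for part in rec["hits"].split(";"):
                chrom, span, strand = part.rsplit(":", 2)
                s, e = span.split("-")
                hits.append((chrom, int(s), int(e), strand))
        tags.append(SmallRNATag(
            sequence=rec["sequence"],
            counts={s: int(rec[s]) for s in samples if rec[s]},
            annotation_class=rec["class"],
            genome_hits=hits))
    return tags


def tags_to_frame(tags: list[SmallRNATag], samples: list[str]) -> pd.DataFrame:
    """TSV-ready tag table: sequence, per-sample counts, class, hits."""
    rows = []
    for t in tags:
        row = {"sequence": t.sequence, "class": t.annotation_class,
               "hits": ";".join(f"{c}:{s}-{e}:{st}" for c, s, e, st in t.genome_hits)}
        for s in samples:
            row[s] = t.counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=["sequence", *samples, "class", "hits"])
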