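"""Synthetic reference bundle and read simulators.

Emulates the statistical structure of a four-condition (high/low
temperature x long/short photoperiod: HL/HS/LL/LS), three-replicate plant
small-RNA study so that every downstream stage of the pipeline can be
exercised without any external download:

* a genome hosting planted stem-loop precursors (mature + loop +
  reverse-complement star arm, exact 2-nt 3' overhangs on both duplex
  ends) and decoy loci whose composition-shuffled sequences do not fold
  into an acceptable hairpin;
* an annotation with rRNA/tRNA/snRNA/snoRNA/repeat/exon/intron features
  feeding the read-annotation classes;
* adapter-ligated small-RNA libraries with isomiR end variants, structural
  background, exon/intron fragments and unannotatable reads;
* degradome (PARE) tags whose 5' ends mark slicing opposite miRNA
  positions 10/11 of planted target sites;
* negative-binomial gene counts with miRNA-anticorrelated fold changes.

All sampling is driven by ``numpy.random.Generator`` seeded from
``SimulationConfig.seed``; equal configs give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .folding import fold_hairpin, pair_chain, pair_table
from .util import revcomp

CONDITIONS = ("HL", "HS", "LL", "LS")
_COMP = str.maketrans("ACGTU", "TGCAA")
BASES = "ACGT"


class ConfigurationError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


class PlacementError(RuntimeError):
    """Raised when planted loci cannot be placed without overlap."""


def default_design(n_samples: int) -> dict[str, str]:
    """Sample -> condition map: replicates grouped per condition."""
    conds = [CONDITIONS[(i * len(CONDITIONS)) // n_samples] for i in range(n_samples)]
    return {f"s{i + 1:02d}": c for i, c in enumerate(conds)}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe the emulated design: 12 libraries (4 conditions x 3
    replicates), ~21-nt matures on 8-15 nt loops, a handful of
    temperature-responsive miRNAs with 4-fold effects and anticorrelated
    targets, PARE signal depth 50 over a 1e-3 tags/nt background.
    """

    seed: int = 0
    n_hairpins: int = 20
    n_decoy_loci: int = 20
    mature_len: int = 21
    loop_len_range: tuple[int, int] = (8, 15)
    stem_mismatch_rate: float = 0.0
    n_samples: int = 12
    design: dict[str, str] | None = None
    mirna_abundances: dict[tuple[str, str], float] | None = None
    mirna_fold_changes: dict[str, dict[str, float]] | None = None
    abundance_range: tuple[float, float] = (30.0, 400.0)
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_len: int = 50
    isomir_fraction: float = 0.1
    star_fraction: float = 0.1
    background_read_count: int = 1500
    offsize_fraction: float = 0.02
    impurity_fraction: float = 0.01
    n_transcripts: int = 40
    transcript_len_range: tuple[int, int] = (600, 1000)
    targets_per_mirna: int = 2
    degradome_signal_depth: int = 50
    degradome_background_rate: float = 1e-3
    degradome_tag_len: int = 20
    nb_dispersion: float = 0.05
    de_fold_changes: dict[str, dict[str, float]] | None = None
    anticorrelate_targets: bool = True

    def __post_init__(self) -> None:
        if not 18 <= self.mature_len <= 30:
            raise ConfigurationError("mature_len must be in [18, 30]")
        for name in ("stem_mismatch_rate", "isomir_fraction", "star_fraction",
                     "offsize_fraction", "impurity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if self.design is None:
            self.design = default_design(self.n_samples)
        if len(self.design) != self.n_samples:
            raise ConfigurationError("design size does not match n_samples")
        if self.mirna_fold_changes is None:
            self.mirna_fold_changes = {}
            if self.n_hairpins >= 1:
                self.mirna_fold_changes["syn-mir001"] = {"HL": 4.0, "HS": 4.0}
            if self.n_hairpins >= 2:
                self.mirna_fold_changes["syn-mir002"] = {"HL": 0.25, "HS": 0.25}

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator per simulation stream."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )


def mirna_name(i: int) -> str:
    return f"syn-mir{i + 1:03d}"


@dataclass
class ReferenceBundle:
    """In-memory reference genome, annotation, transcripts and truth tables."""

    genome: dict[str, str]
    features: pd.DataFrame       # chrom, type, start0, end0, strand, feature_id
    transcripts: dict[str, str]
    precursors: pd.DataFrame     # per planted/decoy locus incl. truth columns
    target_sites: pd.DataFrame   # planted miRNA target sites on transcripts
    gene_truth: pd.DataFrame     # per-gene base mean and condition folds
    mirna_truth: pd.DataFrame    # per-miRNA base abundance and condition folds

    def write(self, outdir: str | Path) -> None:
        """Write genome/transcript FASTA, GFF3 annotation and truth TSVs."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(out / "genome.fa", self.genome.items())
        _write_fasta(out / "transcripts.fa", self.transcripts.items())
        write_gff3(self.features, out / "annotation.gff3")
        self.precursors.to_csv(out / "truth_precursors.tsv", sep="\t", index=False)
        self.target_sites.to_csv(out / "truth_targets.tsv", sep="\t", index=False)
        self.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.mirna_truth.to_csv(out / "truth_mirnas.tsv", sep="\t", index=False)


def _write_fasta(path: Path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"]


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table as GFF3 (1-based inclusive coordinates)."""
    rows = []
    for rec in features.itertuples():
        rows.append({
            "seqid": rec.chrom, "source": "mirapex_sim", "type": rec.type,
            "start": rec.start0 + 1, "end": rec.end0, "score": ".",
            "strand": rec.strand, "phase": ".",
            "attributes": f"ID={rec.feature_id}",
        })
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        pd.DataFrame(rows, columns=GFF_COLUMNS).to_csv(
            fh, sep="\t", header=False, index=False)


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file back into the internal 0-based feature table."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF_COLUMNS)
    out = pd.DataFrame({
        "chrom": df["seqid"],
        "type": df["type"],
        "start0": df["start"] - 1,
        "end0": df["end"],
        "strand": df["strand"],
        "feature_id": df["attributes"].str.replace("ID=", "", regex=False),
    })
    return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


_WOBBLE = {"G": "T", "T": "G"}


def _nonpairing_base(rng: np.random.Generator, partner: str) -> str:
    """A base that can neither Watson-Crick nor wobble pair with partner."""
    banned = {partner.translate(_COMP), _WOBBLE.get(partner, "")}
    choices = [b for b in BASES if b not in banned]
    return choices[int(rng.integers(0, len(choices)))]


def _design_realized(precursor: str, mature_len: int) -> bool:
    """Does the MFE structure reproduce the designed duplex geometry?

    Checks stability (<= -25 kcal/mol), the exact 2-nt 3' overhangs on
    both duplex ends (mature 5' start pairs the 3rd-last precursor base
    and the star 5' start pairs mature position L-2) and the absence of
    large loops in the mature-spanning duplex.  Degenerate sequences
    (e.g. homopolymer runs with slipped pairing registers) fail here and
    are redrawn.
    """
    struct, mfe = fold_hairpin(precursor)
    if mfe > -25.0:
        return False
    n, L = len(precursor), mature_len
    table = pair_table(struct)
    if table.get(0) != n - 3 or table.get(n - L) != L - 3:
        return False
    for (a, b), (a2, b2) in zip(pair_chain(struct), pair_chain(struct)[1:]):
        if a >= L:
            break
        n1, n2 = a2 - a - 1, b - b2 - 1
        if (min(n1, n2) == 0 and max(n1, n2) > 3) or \
                (min(n1, n2) > 0 and max(n1, n2) > 5):
            return False
    return True


def _plant_precursor(rng: np.random.Generator, cfg: SimulationConfig):
    """Mature/star/loop for one stem-loop with exact 2-nt 3' overhangs.

    Layout (5'->3'): mature_5p (L nt) + loop + star, where the first L-2 nt
    of the star are the reverse complement of mature_5p[:L-2]; the star's
    last 2 nt and the mature's last 2 nt are the unpaired Dicer overhangs.
    Matures are redrawn until the mismatch-free precursor's MFE structure
    realises that design below -25 kcal/mol (so clean plants clear the
    -18 kcal/mol gate with margin) and neither arm's 3' end spuriously
    resembles the adapter prefix (which would mis-trim its reads).
    """
    from .preprocess import _find_adapter

    L = cfg.mature_len
    for _ in range(500):
        mature = _random_seq(rng, L)
        loop_len = int(rng.integers(cfg.loop_len_range[0], cfg.loop_len_range[1] + 1))
        loop = _random_seq(rng, loop_len)
        clean_core = revcomp(mature[: L - 2])
        # the 2-nt star tail is the 3' overhang: it must not pair (WC or
        # G:T wobble) with the mature 5' end, or the stem would extend
        tail = (_nonpairing_base(rng, mature[1])
                + _nonpairing_base(rng, mature[0]))
        clean_star = clean_core + tail
        if not _design_realized(mature + loop + clean_star, L):
            continue
        if _find_adapter(mature + cfg.adapter, cfg.adapter) != L or \
                _find_adapter(clean_star + cfg.adapter, cfg.adapter) != L:
            continue
        star_core = list(clean_core)
        n_mm = rng.binomial(L - 2, cfg.stem_mismatch_rate)
        mm_pos = rng.choice(L - 2, size=n_mm, replace=False)
        for p in mm_pos:
            alt = [b for b in BASES if b != star_core[p]]
            star_core[p] = alt[int(rng.integers(0, 3))]
        star = "".join(star_core) + tail
        return mature, star, loop_len, mature + loop + star
    raise PlacementError("could not draw a stable precursor")  # pragma: no cover


def _draw_decoy(rng: np.random.Generator, length: int) -> str:
    """Shuffled-composition locus guaranteed to miss the hairpin MFE gate."""
    for _ in range(500):
        seq = _random_seq(rng, length)
        _, mfe = fold_hairpin(seq)
        if mfe > -15.0:
            return seq
    raise PlacementError("could not draw an unstable decoy")  # pragma: no cover


def _chr2_features() -> list[dict]:
    feats = [
        ("rRNA", 100, 2100, "+"), ("tRNA", 2500, 2580, "+"),
        ("snRNA", 3000, 3150, "+"), ("snoRNA", 3500, 3650, "+"),
        ("repeat", 4000, 5000, "+"),
        ("exon", 5200, 5800, "+"), ("intron", 5800, 6400, "+"),
        ("exon", 6400, 7200, "+"),
        ("exon", 7400, 7700, "-"), ("intron", 7700, 7900, "-"),
        ("exon", 7900, 8100, "-"),
    ]
    return [
        {"chrom": "chr2", "type": t, "start0": s, "end0": e, "strand": st,
         "feature_id": f"{t}_{i + 1}"}
        for i, (t, s, e, st) in enumerate(feats)
    ]


def simulate_reference(cfg: SimulationConfig) -> ReferenceBundle:
    """Build genome, annotation, transcripts and the complete truth tables."""
    rng = cfg.rng(0)
    slot = 520
    chr1_len = 1000 + (cfg.n_hairpins + cfg.n_decoy_loci) * slot
    chr1 = list(_random_seq(rng, chr1_len))

    loci = []
    intervals: list[tuple[int, int, str]] = []
    for idx in range(cfg.n_hairpins + cfg.n_decoy_loci):
        is_decoy = idx >= cfg.n_hairpins
        start = 500 + idx * slot + int(rng.integers(0, 60))
        strand = "-" if idx % 3 == 2 else "+"
        if is_decoy:
            L = cfg.mature_len
            loop_len = int(rng.integers(*cfg.loop_len_range))
            seq = _draw_decoy(rng, 2 * L + loop_len)
            mature = seq[:L]   # decoy "pseudo-mature" used for background reads
            star = ""
        else:
            mature, star, loop_len, seq = _plant_precursor(rng, cfg)
        end = start + len(seq)
        for s0, e0, name in intervals:
            if start < e0 and s0 < end:
                raise PlacementError(f"loci overlap: {name} and locus {idx}")
        name = f"decoy{idx - cfg.n_hairpins + 1:03d}" if is_decoy else mirna_name(idx)
        intervals.append((start, end, name))
        chr1[start:end] = list(seq if strand == "+" else revcomp(seq))
        loci.append({
            "locus_id": name, "kind": "decoy" if is_decoy else "mirna",
            "chrom": "chr1", "start0": start, "end0": end, "strand": strand,
            "precursor_seq": seq, "mature_5p": mature, "mature_3p": star,
            "loop_len": loop_len,
        })
    # Stabilise decoy neighbourhoods: any discovery window around a decoy
    # is a subsequence of one of two oriented super-windows; flanks (and,
    # as a last resort, the decoy core) are redrawn until both fold above
    # -15 kcal/mol, so no decoy window can clear the -18 kcal/mol gate.
    for loc in loci:
        if loc["kind"] != "decoy":
            continue
        ls, le = loc["start0"], loc["end0"]
        for attempt in range(100):
            wa = "".join(chr1[max(0, ls - 186):le + 26])
            wb = "".join(chr1[max(0, ls - 26):le + 186])
            if loc["strand"] == "-":
                wa, wb = revcomp(wa), revcomp(wb)
            if fold_hairpin(wa)[1] > -15.0 and fold_hairpin(wb)[1] > -15.0:
                break
            chr1[max(0, ls - 186):ls] = list(_random_seq(rng, ls - max(0, ls - 186)))
            chr1[le:le + 186] = list(_random_seq(rng, 186))
            if attempt % 10 == 9:
                core = _draw_decoy(rng, le - ls)
                loc["precursor_seq"] = core
                loc["mature_5p"] = core[:cfg.mature_len]
                chr1[ls:le] = list(core if loc["strand"] == "+" else revcomp(core))
        else:  # pragma: no cover - rejection sampling exhausts
            raise PlacementError(f"could not stabilise decoy {loc['locus_id']}")
    genome = {"chr1": "".join(chr1), "chr2": _random_seq(rng, 8200)}
    features = pd.DataFrame(
        _chr2_features(),
        columns=["chrom", "type", "start0", "end0", "strand", "feature_id"])
    precursors = pd.DataFrame(
        loci, columns=["locus_id", "kind", "chrom", "start0", "end0", "strand",
                       "precursor_seq", "mature_5p", "mature_3p", "loop_len"])

    # transcripts with planted perfect-complement target sites
    t_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_transcripts)]
    lengths = rng.integers(cfg.transcript_len_range[0],
                           cfg.transcript_len_range[1] + 1,
                           size=cfg.n_transcripts)
    transcripts = {tid: list(_random_seq(rng, int(n)))
                   for tid, n in zip(t_ids, lengths)}
    sites = []
    planted = precursors[precursors.kind == "mirna"]
    occupied: dict[str, list[tuple[int, int]]] = {tid: [] for tid in t_ids}
    if cfg.n_transcripts > 0:
        for i, rec in enumerate(planted.itertuples()):
            site_seq = revcomp(rec.mature_5p)
            for j in range(cfg.targets_per_mirna):
                tid = t_ids[(i * cfg.targets_per_mirna + j) % cfg.n_transcripts]
                tlen = len(transcripts[tid])
                pos = None
                for _ in range(30):
                    cand = int(rng.integers(100, tlen - 150))
                    if all(abs(cand - s) > 40 for s, _ in occupied[tid]):
                        pos = cand
                        break
                if pos is None:
                    continue
                occupied[tid].append((pos, pos + len(site_seq)))
                transcripts[tid][pos:pos + len(site_seq)] = list(site_seq)
                sites.append({
                    "mirna_id": rec.locus_id, "transcript_id": tid,
                    "site_start0": pos, "site_end0": pos + len(site_seq),
                    "cleavage_pos0": pos + len(site_seq) - 10,
                })
    transcripts = {tid: "".join(s) for tid, s in transcripts.items()}
    target_sites = pd.DataFrame(
        sites, columns=["mirna_id", "transcript_id", "site_start0",
                        "site_end0", "cleavage_pos0"])

    # per-miRNA base abundance and condition folds
    lo, hi = cfg.abundance_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_hairpins))
    m_rows = []
    for i, rec in enumerate(planted.itertuples()):
        folds = {c: 1.0 for c in CONDITIONS}
        folds.update(cfg.mirna_fold_changes.get(rec.locus_id, {}))
        m_rows.append({"mirna_id": rec.locus_id, "base_abundance": base[i],
                       **{f"fold_{c}": folds[c] for c in CONDITIONS},
                       "is_de": any(f != 1.0 for f in folds.values())})
    mirna_truth = pd.DataFrame(
        m_rows, columns=["mirna_id", "base_abundance",
                         *[f"fold_{c}" for c in CONDITIONS], "is_de"])

    # per-gene base mean and condition folds (anticorrelated with miRNAs)
    gene_fold: dict[str, dict[str, float]] = {}
    if cfg.de_fold_changes is not None:
        unknown = set(cfg.de_fold_changes) - set(t_ids)
        if unknown:
            raise ConfigurationError(f"de_fold_changes for unknown genes: {unknown}")
        gene_fold = {g: dict(f) for g, f in cfg.de_fold_changes.items()}
    elif cfg.anticorrelate_targets and len(target_sites):
        for rec in mirna_truth[mirna_truth.is_de].itertuples():
            for tid in target_sites.loc[
                    target_sites.mirna_id == rec.mirna_id, "transcript_id"]:
                gene_fold.setdefault(tid, {})
                for c in CONDITIONS:
                    f = getattr(rec, f"fold_{c}")
                    if f != 1.0:
                        gene_fold[tid][c] = 1.0 / f
    for folds in gene_fold.values():
        if any(f <= 0 for f in folds.values()):
            raise ConfigurationError("fold multipliers must be positive")
    g_base = np.exp(rng.uniform(np.log(50.0), np.log(400.0), size=cfg.n_transcripts))
    g_rows = []
    for tid, bm in zip(t_ids, g_base):
        folds = {c: 1.0 for c in CONDITIONS}
        folds.update(gene_fold.get(tid, {}))
        g_rows.append({"gene_id": tid, "length": len(transcripts[tid]),
                       "base_mean": bm,
                       **{f"fold_{c}": folds[c] for c in CONDITIONS},
                       "is_de": any(f != 1.0 for f in folds.values())})
    gene_truth = pd.DataFrame(
        g_rows, columns=["gene_id", "length", "base_mean",
                         *[f"fold_{c}" for c in CONDITIONS], "is_de"])

    return ReferenceBundle(genome=genome, features=features,
                           transcripts=transcripts, precursors=precursors,
                           target_sites=target_sites, gene_truth=gene_truth,
                           mirna_truth=mirna_truth)


def _oriented_context(bundle: ReferenceBundle, rec, flank: int = 30) -> tuple[str, int]:
    """Precursor with flanks in transcription orientation + mature_5p offset."""
    chrom = bundle.genome[rec.chrom]
    s = max(0, rec.start0 - flank)
    e = min(len(chrom), rec.end0 + flank)
    seg = chrom[s:e]
    if rec.strand == "+":
        return seg, rec.start0 - s
    return revcomp(seg), e - rec.end0


def _finish_read(insert: str, adapter: str, read_len: int) -> str:
    full = insert + adapter
    if len(full) < read_len:
        full += "A" * (read_len - len(full))
    return full[:read_len]


def expected_abundance(cfg: SimulationConfig, bundle: ReferenceBundle,
                       mirna_id: str, sample: str) -> float:
    """Expected read count of one miRNA in one library."""
    if cfg.mirna_abundances is not None:
        try:
            return cfg.mirna_abundances[(mirna_id, sample)]
        except KeyError:
            raise ConfigurationError(
                f"no abundance for {mirna_id} in sample {sample}") from None
    row = bundle.mirna_truth.set_index("mirna_id").loc[mirna_id]
    cond = cfg.design[sample]
    return float(row["base_abundance"] * row[f"fold_{cond}"])


def simulate_srna_reads(bundle: ReferenceBundle, cfg: SimulationConfig
                        ) -> dict[str, list[tuple[str, str, str]]]:
    """Per-sample small-RNA libraries as (read_id, sequence, quality) lists.

    Reads are insert + 3' adapter padded to ``read_len``; miRNA reads come
    from the planted loci (with isomiR end shifts taken from the genomic
    context), background reads from annotated structural RNA, exon/intron
    fragments, decoy loci and unmappable sequence; a small fraction of
    inserts fall outside the 18-30 nt window or carry impurities so that
    the preprocessing filters are exercised.
    """
    rng = cfg.rng(1)
    planted = bundle.precursors[bundle.precursors.kind == "mirna"]
    decoys = bundle.precursors[bundle.precursors.kind == "decoy"]
    feat = bundle.features
    struct_feats = feat[feat.type.isin(["rRNA", "tRNA", "snRNA", "snoRNA"])]
    ei_feats = feat[feat.type.isin(["exon", "intron"])]
    libraries: dict[str, list[tuple[str, str, str]]] = {}
    qual = "I" * cfg.read_len

    for sample in cfg.design:
        inserts: list[str] = []
        # --- miRNA-derived reads (mature, isomiRs, star) ---
        for rec in planted.itertuples():
            ctx, off5 = _oriented_context(bundle, rec)
            L = cfg.mature_len
            mean = expected_abundance(cfg, bundle, rec.locus_id, sample)
            n5 = rng.poisson(mean)
            n3 = rng.poisson(mean * cfg.star_fraction)
            off3 = off5 + L + rec.loop_len
            for off, n in ((off5, n5), (off3, n3)):
                arm_len = L if off == off5 else len(rec.mature_3p)
                if arm_len == 0:
                    continue
                for _ in range(int(n)):
                    if rng.random() < cfg.isomir_fraction:
                        s5 = int(rng.integers(-1, 2))
                        s3 = int(rng.choice([-2, -1, 1, 2]))
                    else:
                        s5 = s3 = 0
                    a = max(0, off + s5)
                    b = min(len(ctx), off + arm_len + s3)
                    inserts.append(ctx[a:b])
        # --- background ---
        n_bg = cfg.background_read_count
        n_off = int(round(n_bg * cfg.offsize_fraction))
        n_imp = int(round(n_bg * cfg.impurity_fraction))
        n_core = n_bg - n_off - n_imp
        n_struct = int(round(n_core * 0.4))
        n_ei = int(round(n_core * 0.3))
        n_unk = n_core - n_struct - n_ei
        for _ in range(n_struct):
            f = struct_feats.iloc[int(rng.integers(len(struct_feats)))]
            flen = int(rng.integers(18, 29))
            start = int(rng.integers(f.start0, max(f.start0 + 1, f.end0 - flen)))
            inserts.append(bundle.genome[f.chrom][start:start + flen])
        for _ in range(n_ei):
            f = ei_feats.iloc[int(rng.integers(len(ei_feats)))]
            flen = int(rng.choice([21, 24]))
            start = f.start0 + 7 * int(rng.integers(0, max(1, (f.end0 - f.start0 - flen) // 7)))
            frag = bundle.genome[f.chrom][start:start + flen]
            if rng.random() < 0.3:  # antisense read of the region
                frag = revcomp(frag)
            inserts.append(frag)
        for k in range(n_unk):
            if k % 2 == 0 and len(decoys):
                d = decoys.iloc[int(rng.integers(len(decoys)))]
                ctx, off = _oriented_context(bundle, d)
                centre = off + (len(d.precursor_seq) - cfg.mature_len) // 2
                jitter = int(rng.integers(-2, 3))
                a = centre + jitter
                inserts.append(ctx[a:a + cfg.mature_len])
            else:
                inserts.append(_random_seq(rng, 21))
        for _ in range(n_off):  # violates the 18-30 nt window after trimming
            flen = int(rng.choice([15, 16, 17, 31, 32, 34]))
            inserts.append(_random_seq(rng, flen))

        reads = [(f"{sample}_r{i:06d}",
                  _finish_read(ins, cfg.adapter, cfg.read_len), qual)
                 for i, ins in enumerate(inserts)]
        for k in range(n_imp):  # impurities: N bases / adapter-less reads
            rid = f"{sample}_imp{k:04d}"
            if k % 2 == 0:
                seq = _finish_read("ACGTN" + _random_seq(rng, 16), cfg.adapter,
                                   cfg.read_len)
            else:
                seq = _random_seq(rng, cfg.read_len)
            reads.append((rid, seq, qual))
        libraries[sample] = reads
    return libraries


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_degradome(bundle: ReferenceBundle, cfg: SimulationConfig
                       ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Degradome tag FASTA records plus the emitted-event truth table.

    For every planted target site, ``degradome_signal_depth`` tags start at
    the transcript nucleotide opposite miRNA position 10 (the 3' cleavage
    fragment's 5' end); uniform background tags are added at
    ``degradome_background_rate`` per transcript nucleotide.  Sites too
    close to the transcript 3' end to yield a full-length tag are skipped
    with a warning and flagged in the returned table.
    """
    rng = cfg.rng(2)
    tags: list[tuple[str, str]] = []
    events = bundle.target_sites.copy()
    events["emitted"] = False
    k = cfg.degradome_tag_len
    serial = 0
    for idx, rec in enumerate(bundle.target_sites.itertuples()):
        tseq = bundle.transcripts[rec.transcript_id]
        pos = rec.cleavage_pos0
        if pos + k > len(tseq):
            warnings.warn(
                f"degradome site {rec.mirna_id}->{rec.transcript_id} too close"
                " to the transcript 3' end; event skipped")
            continue
        events.loc[events.index[idx], "emitted"] = cfg.degradome_signal_depth > 0
        for _ in range(cfg.degradome_signal_depth):
            tags.append((f"sig{serial:06d}", tseq[pos:pos + k]))
            serial += 1
    for tid, tseq in bundle.transcripts.items():
        n_bg = rng.poisson(cfg.degradome_background_rate * len(tseq))
        for _ in range(int(n_bg)):
            p = int(rng.integers(0, max(1, len(tseq) - k)))
            tags.append((f"bg{serial:06d}", tseq[p:p + k]))
            serial += 1
    return tags, events


def nb_counts(rng: np.random.Generator, mean: np.ndarray,
              dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion*mean^2) draws; Poisson at dispersion 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_gene_counts(bundle: ReferenceBundle, cfg: SimulationConfig
                         ) -> pd.DataFrame:
    """Negative-binomial gene count matrix (genes x samples)."""
    rng = cfg.rng(3)
    gt = bundle.gene_truth
    samples = list(cfg.design)
    mat = np.zeros((len(gt), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        cond = cfg.design[sample]
        mu = gt["base_mean"].to_numpy() * gt[f"fold_{cond}"].to_numpy()
        mat[:, j] = nb_counts(rng, mu, cfg.nb_dispersion)
    return pd.DataFrame(mat, index=gt["gene_id"].to_numpy(), columns=samples)


def simulate_count_matrix(n_features: int, design: dict[str, str],
                          mean_range: tuple[float, float], dispersion: float,
                          seed: int,
                          fold_changes: dict[int, dict[str, float]] | None = None
                          ) -> pd.DataFrame:
    """Generic NB count matrix for calibration studies.

    Feature means are log-uniform over ``mean_range``; ``fold_changes``
    maps feature index -> condition -> multiplier.  Used for null DE
    calibration (all folds 1) and planted fold-change recovery runs.
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]),
                              size=n_features))
    samples = list(design)
    mat = np.zeros((n_features, len(samples)), dtype=np.int64)
    folds = np.ones((n_features, len(samples)))
    if fold_changes:
        for i, per_cond in fold_changes.items():
            for j, s in enumerate(samples):
                folds[i, j] = per_cond.get(design[s], 1.0)
    for j in range(len(samples)):
        mat[:, j] = nb_counts(rng, base * folds[:, j], dispersion)
    return pd.DataFrame(mat, index=[f"f{i:05d}" for i in range(n_features)],
                        columns=samples)
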