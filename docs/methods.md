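# Methods

mirapex implements the computational pipeline of a plant small-RNA study
design: shoot-apex tissue sampled under four temperature–photoperiod
treatments (high/low temperature × long/short photoperiod, labelled
HL/HS/LL/LS) with three biological replicates, plus pooled degradome
(PARE) sequencing and matched RNA-seq of the same samples. The pipeline
discovers known and novel miRNAs from the small-RNA libraries, quantifies
them isomiR-tolerantly, predicts their targets with a plant-style
complementarity score, validates cleavage sites against the degradome,
and crosses miRNA and target differential expression.

## Read preprocessing

Raw reads are 3'-adapter ligated inserts. The adapter is located as the
leftmost position where at least an 8-nt prefix of the adapter matches
with at most one mismatch. Reads containing N, reads without an adapter
hit, and inserts trimming outside the 18–30 nt window are dropped and
tallied by reason ("impurities" are the N-containing and adapter-less
reads). Clean inserts are collapsed to non-redundant unique tags with
per-sample counts; collapsing conserves counts exactly.

Tags are aligned exactly to the genome (both strands, all hits kept) and
classified against the annotation with a fixed priority:
rRNA > miRNA candidate (match to a reference mature) > tRNA > snRNA >
snoRNA > repeat > exon sense > exon antisense > intron sense > intron
antisense > unannotated. The priority makes classification independent of
annotation record order. Tags classified as miRNA candidates,
intron-derived (either strand), exon-antisense or unannotated are carried
into discovery.

## Hairpin folding

Precursor calling needs only stem-loop (single hairpin) structures, so
the folding engine restricts the search to one chain of nested pairs —
stacked helices interrupted by bulges and internal loops, closed by a
terminal hairpin loop — and minimises free energy under a
nearest-neighbour model: a 6×6 stacking table over the canonical pair
types (Watson–Crick plus G:U) with Turner-style magnitudes, and additive
loop penalties. Loop penalties are deliberately stiff (hairpin
60 + 5·(L−3) deci-kcal capped at 110; bulge 45 + 6·(n−1); internal
30 + 6·(n₁+n₂) + 12·|n₁−n₂|): single-hairpin topology has no multiloop
bookkeeping, and softer penalties would let long random windows
accumulate enough short helices to slip under the −18 kcal/mol gate,
destroying the gate's discriminating power. Under these tables a random
260-nt window folds to about −11 kcal/mol on average (about 5 % reach
−18), while a planted 19-bp clean stem folds near −30.

Energies are integers in deci-kcal/mol end to end, so the dynamic
program (O(n²·k²) with interior loops capped at k = 10 nt per side,
numba-compiled) and the exhaustive enumeration oracle used in the tests
agree bit-for-bit. Because co-optimal structures exist, "same structure"
is asserted as: identical MFE, plus the traceback structure re-scoring to
that MFE under the oracle's standalone energy function. Sequences longer
than 400 nt are refused; DNA input is read as RNA. The energy model is a
frozen dataclass and can be swapped for an external folding engine
anywhere a `(structure, mfe)` pair is consumed.

## Precursor evaluation

Tags seeding discovery (summed count ≥ 6 across libraries) open two
windows per genome hit in transcription orientation — [tag−20, tag+180]
and [tag−180, tag+20] — clipped at chromosome ends and deduplicated at
90 % overlap. Each window is folded and judged by six criteria; every
failed criterion appends one machine-readable reason code:

1. `NOT_HAIRPIN` — the window (or duplex region) folds to no stabilising
   single hairpin.
2. `MATURE_NOT_IN_ARM` — the most abundant tag must lie entirely within
   one arm. Arms are delimited by the hairpin-loop midpoint, with 4 nt of
   slack beyond the paired extent so the unpaired 2-nt 3' overhangs still
   belong to their arm.
3. `OVERHANG` — when both arms carry tags, the implied miRNA/miRNA*
   duplex must show exact 2-nt 3' overhangs on both ends (no tolerance):
   the pairing partner of each arm's 5' end must sit exactly 3 nt inside
   the other arm's 3' end.
4. `LARGE_LOOP` — within the mature-spanning duplex, no bulge larger than
   3 nt and no internal loop larger than 5 nt per side.
5. `MFE_GATE` — precursor MFE ≤ −18.0 kcal/mol (inclusive).
6. `MIN_COUNT` — the summed dominant-arm tag count must exceed 5. The
   count is summed over all libraries; dominant-tag ties break by count
   then lexicographic sequence.

When both arms are sequenced, criteria 3–5 are evaluated on the precursor
proper — the region from the dominant 5p tag start to the dominant 3p tag
end, re-folded without flanks — because flank base-pairing in the wide
window can otherwise perturb the duplex geometry. With one sequenced arm
the window's hairpin extent stands in for the precursor and the overhang
criterion is vacuously satisfied (single-arm miRNAs are common).
Accepted calls whose loci overlap are collapsed to the lowest-MFE call.

Accepted matures are matched against a reference of known plant mature
miRNAs: known iff some reference aligns ungapped with ≤ 2 substitutions
over the overlap and total end offset (5' shift plus 3' length
difference) ≤ 2 nt; best match by fewest mismatches, then smallest
offset, then name. Known members of a multi-locus family receive
alphabetical suffixes in (chromosome, start) order; single-member
families carry no suffix; unmatched precursors are serialised
`{prefix}-novel-mir{n}` in genome order. The organism prefix (default
`csa`) is configurable.

## miRNA quantification and differential expression

A tag counts toward a mature sequence when an ungapped register exists
in which all positions outside the terminal 3 nt of each end match
exactly, and each end's overhang plus terminal mismatches total at most
3 ("no mismatches in the middle"). Each tag counts toward at most one
mature (fewest end edits, then catalog order); duplicate mature
sequences across precursors are counted once. Abundance is normalised to
tags per million clean reads: TPM = count / clean reads × 10⁶, per
sample; when features partition a library the TPM column sums to 10⁶
exactly.

Differential expression between two conditions uses the Audic–Claverie
exact test on pooled raw counts with pooled library sizes as offsets.
The conditional law of one pooled count given the other is negative
binomial (size x+1, probability n₁/(n₁+n₂)); the two-sided p doubles the
smaller of the two conditional lower tails P(Y≤y|x) and P(X≤x|y), making
the test exactly symmetric under swapping the groups. Fold change is
log2((mean TPM_A + c)/(mean TPM_B + c)) with pseudocount c = 0.01. A
feature is called at |log2FC| ≥ 1 and p < 10⁻³ (raw; a
Benjamini–Hochberg column is emitted for reference but does not gate
status). All six pairwise treatment comparisons are reported. The pooled
exact test models shot-noise (Poisson) sampling; under strong
extra-Poisson replicate dispersion it is anticonservative, which is why
its null-calibration study runs at the Poisson limit of the
negative-binomial generator.

## Target prediction

Duplexes are scored with the standard plant penalty convention: mismatch
1.0, G:U wobble 0.5, gapped position 2.0, all doubled over miRNA
positions 2–13 (5'-anchored numbering). Transcripts are scanned on the
sense strand: an exhaustive vectorised ungapped pass, and for the
permissive configuration a banded dynamic program allowing up to two
gaps (net register offset ≤ 2). Two stringency configurations play the
roles of the two commonly used plant prediction tools — strict (cutoff
2.5, ungapped) and permissive (cutoff 4.0, gapped) — and the consensus
set is their intersection keyed by (miRNA, transcript); site coordinates
need not agree. The published per-tool target counts are properties of
those exact third-party tools on the full transcriptome and are not
reproduction targets for these stand-in configurations.

## Degradome validation

Degradome tags are placed on transcripts by exact sense-strand match;
each tag's 5'-most coordinate increments the transcript's 5'-end
profile, multi-hit tags counting at every hit. A predicted site is
validated when its penalty score is ≤ 4 and the transcript position
opposite miRNA position 10 or 11 carries tag signal — the canonical
slicing site between positions 10 and 11; for an ungapped site ending at
`end0` (exclusive), the position opposite miRNA position p is
`end0 − p`. Events are categorised CleaveLand-style from the transcript's
profile: 0 unique maximum, 1 tied maximum, 4 a non-maximal singleton,
2 above the median of non-zero positions, 3 at or below it.

The empirical p-value shuffles the miRNA (composition-preserving
permutations, default 1000, seeded), rescans the transcript with the
ungapped scorer, and counts shuffles achieving a site at most as penal
as the event's with position-10/11 signal at least as abundant:
p = (1 + hits)/(1 + n). Events with p < 0.05 are reported with
t-plot-ready per-position tables.

## Gene expression integration

Gene abundance is FPKM = count / (length/10³ × mapped reads/10⁶). A gene
is differentially expressed between two treatments when the mean-FPKM
fold change exceeds 2 and the probability exceeds 0.8, where the
probability is defined as the frequency, over seeded bootstrap resamples
of replicates (with replacement, default 1000 draws), that
|log2 FC| > 1. This is a deliberately simple, pluggable reading of the
fold-change-with-probability convention of NOISeq-era pipelines.
Degradome-validated miRNA–target pairs are crossed with the two DE
tables: a pair is emitted per comparison in which the gene is DE, and
flagged negative when the miRNA moves the opposite way (non-significant
miRNAs are labelled "flat" and never negative). Target-set enrichment
uses the hypergeometric upper tail per annotation term against a
background of expressed genes (FPKM > 0 in ≥ 1 sample by default), with
Benjamini–Hochberg adjustment and significance at q < 0.05.

## The synthetic data generator

The generator emulates the study's statistical structure so every stage
is testable without external data.

**Reference.** Planted precursors are mature (21 nt default) + loop
(8–15 nt) + star, where the star's first 19 nt are the reverse complement
of the mature's first 19 nt and its last 2 nt are chosen unable to pair
(Watson–Crick or wobble) with the mature 5' end — producing exact 2-nt 3'
overhangs on both duplex ends. A candidate is redrawn until its
mismatch-free fold realises that design below −25 kcal/mol (so clean
plants clear the −18 gate with margin) and until neither arm's 3' end
resembles the adapter prefix (which would silently mis-trim its reads).
Decoy loci are random sequences redrawn until they fold above
−15 kcal/mol, and their flanks are additionally redrawn until every
possible discovery window around them folds above −15 kcal/mol — decoys
fail the hairpin criteria by construction, not by luck. Loci occupy
disjoint 520-nt slots on chr1 (a placement error is raised on overlap,
with ≥ 20 nt flanks guaranteed); chr2 carries rRNA/tRNA/snRNA/snoRNA/
repeat features and two genes with exons and introns on both strands.
Transcripts carry perfect-complement target sites for each planted
miRNA, ≥ 100 nt from the ends, with recorded cleavage positions
(site end − 10). Truth tables record all of it.

**Small-RNA reads.** Reads are insert + 3' adapter padded to 50 nt
(Phred+33 qualities). Per library, each miRNA contributes
Poisson-distributed mature reads (default per-miRNA base abundance
log-uniform in 30–400, times condition fold changes: by default one
miRNA 4× up and one 4× down under high temperature), star reads at 10 %
of the mature rate, and a 10 % isomiR fraction with end shifts of up to
±2–3 nt taken from the genomic context. Background reads (default 1500
per library) are drawn 40 % from structural RNA features, 30 % from
exon/intron fragments (30 % of those antisense), and 30 % unannotatable
(half decoy-locus pseudo-matures so decoys are actually evaluated
downstream, half random sequence); 2 % of inserts violate the 18–30 nt
window and 1 % carry impurities, to exercise the filters.

**Degradome.** Each planted site emits exactly `degradome_signal_depth`
20-nt tags starting at the position opposite miRNA position 10 (events
too close to the 3' end are skipped with a warning and flagged in the
truth table), over a uniform background of 10⁻³ tags per transcript
nucleotide.

**Gene counts.** Negative binomial with var = μ + φμ² (φ default 0.05,
typical of RNA-seq biological replicates; φ = 0 is the exact Poisson
limit), means scaled per condition; targets of differentially expressed
miRNAs receive reciprocal fold changes when anticorrelation is enabled.

All randomness flows from `SimulationConfig.seed` through per-stream
`SeedSequence` spawns; equal configs give byte-identical outputs.

**What the generator does not emulate** — sequencing error beyond the
planted impurity reads, quality-score structure, ligation and PCR bias,
multi-locus miRNA families with diverged paralogs, repeat-driven
multi-mapping, 3' tailing/editing of matures, and the full compositional
complexity of a real transcriptome. Passing the property suite therefore
demonstrates correctness of the pipeline's logic under its stated
assumptions, not performance on real libraries.

## Validation studies and problem sizes

The benchmark module fixes the canonical self-checks at these sizes:
discovery recovery with 30 mismatch-free planted precursors and 30
decoys (expected: all planted accepted at their true loci, no decoy
accepted); degradome validation with ~50 planted events at depth 50 over
a 10⁻³/nt background and 1000 shuffles (expected: ≥ 95 % detected at
p < 0.05, all detected planted events category 0; with signal depth 0,
false events ≤ 5 % of candidate alignments); null differential
expression with 2000 Poisson-limit features 3 vs 3 (expected: p < 10⁻³
in ≤ 0.5 %); and bootstrap recovery of 30 planted 4-fold genes among 200
(expected: probability > 0.8 for ≥ 90 %). The gene study fixes equal
mapped totals across samples: in its scaled-down 200-gene universe the
planted genes are a sizeable share of library mass, and deriving library
sizes from column sums would deflate the planted fold change — a
composition artifact that vanishes at real transcriptome scale. The
folding oracle study checks 200 random sequences of 8–25 nt against
exhaustive enumeration, exactly.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; GFF3 and report tables are
1-based inclusive. Folding refuses sequences over 400 nt; open chains
report an MFE of exactly 0.0. TPM requires positive library totals; FPKM
requires positive lengths and totals; the bootstrap requires ≥ 2
replicates per group; the shuffle p-value requires ≥ 100 shuffles.
Rejection of a precursor is a result carrying reason codes, never an
exception. Known limitations: the pooled exact test ignores replicate
overdispersion (see above); exact-match tag alignment ignores
sequencing errors; the two scanner configurations are stand-ins, not
re-implementations, for the third-party prediction tools; and the
single-hairpin energy model is calibrated for gate discrimination, not
for thermodynamic accuracy against full Turner-model folders.
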