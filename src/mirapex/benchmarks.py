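"""Standard validation studies over fully synthetic data.

Each function generates its inputs with the synthetic module, runs the
relevant pipeline stage end to end, and returns summary metrics.  These
are the package's canonical self-checks: precursor discovery recovery
and decoy specificity, degradome cleavage-site sensitivity and false
positive calibration, differential-expression null calibration and
planted fold-change recovery.
"""

from __future__ import annotations

import numpy as np

from . import degradome as deg
from . import discovery, expression, integration, preprocess, synthetic
from .targets import CONFIG_B, scan_transcripts


def run_discovery_study(seed: int, n_hairpins: int = 30, n_decoys: int = 30,
                        background: int = 1000) -> dict:
    """Plant mismatch-free precursors plus decoys; measure recovery.

    Returns counts of planted precursors accepted at their true loci and
    decoy loci accepted (specificity violations), from a full
    reads -> trim -> collapse -> annotate -> discover pass.
    """
    cfg = synthetic.SimulationConfig(
        seed=seed, n_hairpins=n_hairpins, n_decoy_loci=n_decoys,
        stem_mismatch_rate=0.0, background_read_count=background)
    bundle = synthetic.simulate_reference(cfg)
    reads = synthetic.simulate_srna_reads(bundle, cfg)
    clean = {s: preprocess.trim_and_filter(r, cfg.adapter)[0]
             for s, r in reads.items()}
    tags = preprocess.collapse_tags(clean)
    preprocess.annotate_tags(tags, bundle.genome, bundle.features)
    flagged = preprocess.discovery_tags(tags)
    records, _calls = discovery.discover(flagged, bundle.genome)
    accepted = [r.call for r in records]
    planted = bundle.precursors.query("kind == 'mirna'")
    recovered = sum(
        any(c.locus[0] == rec.chrom and c.locus[3] == rec.strand
            and abs(c.locus[1] - rec.start0) <= 3
            and abs(c.locus[2] - rec.end0) <= 3 for c in accepted)
        for rec in planted.itertuples())
    decoys = bundle.precursors.query("kind == 'decoy'")
    decoys_accepted = sum(
        any(c.locus[0] == rec.chrom and c.locus[1] < rec.end0
            and rec.start0 < c.locus[2] for c in accepted)
        for rec in decoys.itertuples())
    return {"n_planted": len(planted), "recovered": int(recovered),
            "n_decoys": len(decoys), "decoys_accepted": int(decoys_accepted)}


def _degradome_bundle(seed: int, depth: int, background_rate: float):
    cfg = synthetic.SimulationConfig(
        seed=seed, n_hairpins=25, n_decoy_loci=0, targets_per_mirna=2,
        n_transcripts=50, degradome_signal_depth=depth,
        degradome_background_rate=background_rate)
    bundle = synthetic.simulate_reference(cfg)
    return cfg, bundle


def run_degradome_study(seed: int, depth: int = 50,
                        background_rate: float = 1e-3,
                        n_shuffles: int = 1000, alpha: float = 0.05) -> dict:
    """Planted PARE events: sensitivity, categories, and false positives.

    The positive arm plants ~50 cleavage events at the given depth over a
    uniform background; the null arm re-simulates the same bundle with
    signal depth 0 and counts events that still pass the p filter, as a
    fraction of candidate alignments.
    """
    cfg, bundle = _degradome_bundle(seed, depth, background_rate)
    matures = {r.locus_id: r.mature_5p for r in
               bundle.precursors.itertuples()}
    alignments = []
    for mid, mat in matures.items():
        alignments.extend(scan_transcripts(mid, mat, bundle.transcripts,
                                           CONFIG_B))
    tags, emitted = synthetic.simulate_degradome(bundle, cfg)
    profiles = deg.map_degradome(tags, bundle.transcripts)
    events = deg.detect_cleavage(profiles, alignments)
    deg.attach_pvalues(events, profiles, matures, bundle.transcripts,
                       n_shuffles=n_shuffles, seed=seed)
    found = {(e.mirna_id, e.transcript_id, e.cleavage_pos0): e
             for e in events if e.pvalue < alpha}
    expected = {(r.mirna_id, r.transcript_id, r.cleavage_pos0)
                for r in emitted[emitted.emitted].itertuples()}
    hits = expected & set(found)
    cat0 = sum(found[k].category == 0 for k in hits)

    null_cfg, null_bundle = _degradome_bundle(seed, 0, background_rate)
    null_tags, _ = synthetic.simulate_degradome(null_bundle, null_cfg)
    null_profiles = deg.map_degradome(null_tags, null_bundle.transcripts)
    null_events = deg.detect_cleavage(null_profiles, alignments)
    deg.attach_pvalues(null_events, null_profiles, matures,
                       null_bundle.transcripts, n_shuffles=n_shuffles,
                       seed=seed + 1)
    false_events = sum(e.pvalue < alpha for e in null_events)
    return {"n_events": len(expected), "detected": len(hits),
            "category0": int(cat0), "n_candidates": len(alignments),
            "false_events": int(false_events)}


def run_null_de_study(seed: int, n_features: int = 2000) -> dict:
    """Null DE calibration at the exact test's Poisson sampling model."""
    design = {f"s{i}": ("HL" if i < 3 else "LS") for i in range(6)}
    counts = synthetic.simulate_count_matrix(
        n_features, design, (5.0, 500.0), dispersion=0.0, seed=seed)
    tpm = expression.normalize_tpm(
        counts, {s: int(counts[s].sum()) for s in counts})
    calls = expression.diff_expression(counts, tpm, design, ("HL", "LS"))
    n_sig = sum(c.pvalue < 1e-3 for c in calls)
    return {"n_features": n_features, "significant": int(n_sig)}


def run_gene_de_recovery(seed: int, n_genes: int = 200,
                         n_planted: int = 30, fold: float = 4.0,
                         dispersion: float = 0.05,
                         n_boot: int = 1000) -> dict:
    """Planted gene fold changes recovered by the bootstrap probability."""
    import pandas as pd

    design = {f"s{i}": ("HL" if i < 3 else "LS") for i in range(6)}
    fold_changes = {i: {"HL": fold} for i in range(n_planted)}
    counts = synthetic.simulate_count_matrix(
        n_genes, design, (50.0, 400.0), dispersion=dispersion, seed=seed,
        fold_changes=fold_changes)
    lengths = pd.Series(1000, index=counts.index)
    # fixed equal mapped totals: the planted genes are a large share of
    # this scaled-down universe, and letting them dominate the library
    # size would deflate their own fold change — in the emulated
    # experiment totals are set by the (unchanged) whole transcriptome
    totals = pd.Series(1e6, index=counts.columns)
    fpkm = integration.compute_fpkm(counts, lengths, totals)
    calls = integration.diff_expression_genes(fpkm, design, ("HL", "LS"),
                                              n_boot=n_boot, seed=seed)
    planted_ids = set(counts.index[:n_planted])
    recovered = sum(c.probability > 0.8 for c in calls
                    if c.gene_id in planted_ids)
    return {"n_planted": n_planted, "recovered": int(recovered)}
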