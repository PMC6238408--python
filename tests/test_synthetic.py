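"""Synthetic-data generator: determinism, planted structure, read classes."""

import numpy as np
import pandas as pd
import pytest

from mirapex import synthetic
from mirapex.folding import fold_hairpin, pair_table
from mirapex.util import revcomp


def _tiny_cfg(**kw):
    base = dict(seed=5, n_hairpins=3, n_decoy_loci=2, n_transcripts=6,
                background_read_count=200)
    base.update(kw)
    return synthetic.SimulationConfig(**base)


def test_empty_simulation_has_no_loci():
    cfg = _tiny_cfg(n_hairpins=0, n_decoy_loci=0, n_transcripts=0)
    bundle = synthetic.simulate_reference(cfg)
    assert len(bundle.precursors) == 0
    assert len(bundle.target_sites) == 0
    assert len(bundle.gene_truth) == 0


def test_reference_write_is_byte_deterministic(tmp_path):
    cfg = _tiny_cfg(seed=7)
    for sub in ("a", "b"):
        bundle = synthetic.simulate_reference(synthetic.SimulationConfig(
            **{**cfg.__dict__, "design": None}))
        bundle.write(tmp_path / sub)
    for name in ("genome.fa", "transcripts.fa", "annotation.gff3",
                 "truth_precursors.tsv", "truth_targets.tsv",
                 "truth_genes.tsv", "truth_mirnas.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes(), name


def test_srna_and_degradome_and_counts_deterministic():
    cfg1, cfg2 = _tiny_cfg(), _tiny_cfg()
    b1 = synthetic.simulate_reference(cfg1)
    b2 = synthetic.simulate_reference(cfg2)
    assert synthetic.simulate_srna_reads(b1, cfg1) == \
        synthetic.simulate_srna_reads(b2, cfg2)
    t1, _ = synthetic.simulate_degradome(b1, cfg1)
    t2, _ = synthetic.simulate_degradome(b2, cfg2)
    assert t1 == t2
    pd.testing.assert_frame_equal(synthetic.simulate_gene_counts(b1, cfg1),
                                  synthetic.simulate_gene_counts(b2, cfg2))


def test_planted_precursors_fold_below_mfe_gate():
    cfg = synthetic.SimulationConfig(seed=3, n_hairpins=10, n_decoy_loci=0,
                                     stem_mismatch_rate=0.0)
    bundle = synthetic.simulate_reference(cfg)
    for seq in bundle.precursors.precursor_seq:
        _, mfe = fold_hairpin(seq)
        assert mfe <= -18.0


def test_planted_duplex_has_two_nt_three_prime_overhangs():
    cfg = _tiny_cfg(stem_mismatch_rate=0.0)
    bundle = synthetic.simulate_reference(cfg)
    for rec in bundle.precursors.query("kind == 'mirna'").itertuples():
        struct, _ = fold_hairpin(rec.precursor_seq)
        table = pair_table(struct)
        n, L = len(rec.precursor_seq), len(rec.mature_5p)
        assert table[0] == n - 3          # star 3' end overhangs by 2 nt
        assert table[n - L] == L - 3      # mature 3' end overhangs by 2 nt


def test_planted_precursor_embedded_at_recorded_coordinates():
    cfg = _tiny_cfg()
    bundle = synthetic.simulate_reference(cfg)
    for rec in bundle.precursors.itertuples():
        segment = bundle.genome[rec.chrom][rec.start0:rec.end0]
        expected = rec.precursor_seq if rec.strand == "+" else \
            revcomp(rec.precursor_seq)
        assert segment == expected


def test_planted_target_sites_are_transcript_subsequences():
    cfg = _tiny_cfg()
    bundle = synthetic.simulate_reference(cfg)
    matures = bundle.precursors.set_index("locus_id")["mature_5p"]
    assert len(bundle.target_sites)
    for rec in bundle.target_sites.itertuples():
        site = bundle.transcripts[rec.transcript_id][rec.site_start0:rec.site_end0]
        assert site == revcomp(matures[rec.mirna_id])
        assert rec.cleavage_pos0 == rec.site_end0 - 10


def test_zero_abundance_gives_background_only_reads():
    cfg = _tiny_cfg(n_samples=2, star_fraction=0.0)
    bundle = synthetic.simulate_reference(cfg)
    cfg.mirna_abundances = {(m, s): 0.0
                            for m in bundle.mirna_truth.mirna_id
                            for s in cfg.design}
    reads = synthetic.simulate_srna_reads(bundle, cfg)
    matures = set(bundle.precursors.query("kind == 'mirna'").mature_5p)
    for recs in reads.values():
        for _rid, seq, _q in recs:
            assert seq[:21] not in matures


def test_missing_abundance_entry_is_configuration_error():
    cfg = _tiny_cfg(n_samples=2)
    bundle = synthetic.simulate_reference(cfg)
    cfg.mirna_abundances = {("syn-mir001", "s01"): 10.0}  # everything else absent
    with pytest.raises(synthetic.ConfigurationError):
        synthetic.simulate_srna_reads(bundle, cfg)


def test_exact_mature_read_counts_follow_poisson_means():
    """With isomiRs off, exact-mature reads per library track the mean."""
    mean = 100.0
    cfg = _tiny_cfg(n_samples=2, isomir_fraction=0.0, star_fraction=0.0,
                    mirna_fold_changes={})
    bundle = synthetic.simulate_reference(cfg)
    cfg.mirna_abundances = {(m, s): mean
                            for m in bundle.mirna_truth.mirna_id
                            for s in cfg.design}
    reads = synthetic.simulate_srna_reads(bundle, cfg)
    for rec in bundle.precursors.query("kind == 'mirna'").itertuples():
        probe = synthetic._finish_read(rec.mature_5p, cfg.adapter, cfg.read_len)
        for sample, recs in reads.items():
            n = sum(1 for _r, seq, _q in recs if seq == probe)
            assert abs(n - mean) <= 4 * np.sqrt(mean), (rec.locus_id, sample)


def test_degradome_tags_mark_position_opposite_mirna_ten():
    cfg = _tiny_cfg(degradome_background_rate=0.0, degradome_signal_depth=50)
    bundle = synthetic.simulate_reference(cfg)
    tags, events = synthetic.simulate_degradome(bundle, cfg)
    emitted = events[events.emitted]
    assert len(tags) == 50 * len(emitted)
    by_site = {}
    for _tid, seq in tags:
        by_site[seq] = by_site.get(seq, 0) + 1
    for rec in emitted.itertuples():
        tseq = bundle.transcripts[rec.transcript_id]
        expected = tseq[rec.cleavage_pos0:rec.cleavage_pos0 + 20]
        assert by_site.get(expected, 0) >= 50


def test_degradome_depth_zero_emits_background_only():
    cfg = _tiny_cfg(degradome_signal_depth=0, degradome_background_rate=1e-3)
    bundle = synthetic.simulate_reference(cfg)
    tags, events = synthetic.simulate_degradome(bundle, cfg)
    assert not events.emitted.any()
    assert all(tid.startswith("bg") for tid, _ in tags)


def test_gene_counts_poisson_limit_variance_tracks_mean():
    rng = np.random.default_rng(0)
    mu = np.full(4000, 100.0)
    counts = synthetic.nb_counts(rng, mu, dispersion=0.0)
    ratio = counts.var() / counts.mean()
    assert 0.9 < ratio < 1.1


def test_planted_gene_fold_change_recovered_in_expectation():
    """A 4-fold HL-vs-LS gene shows a mean ratio within [2, 8] at 3 reps."""
    design = {f"s{i}": c for i, c in enumerate(["HL"] * 3 + ["LS"] * 3)}
    inside = 0
    n_rep = 300
    for k in range(n_rep):
        m = synthetic.simulate_count_matrix(
            1, design, (100.0, 100.0), dispersion=0.05, seed=k,
            fold_changes={0: {"HL": 4.0}})
        row = m.iloc[0]
        ratio = row[:3].mean() / max(row[3:].mean(), 1e-9)
        inside += 2.0 <= ratio <= 8.0
    assert inside / n_rep > 0.95


def test_negative_fold_multiplier_rejected():
    cfg = _tiny_cfg()
    with pytest.raises(synthetic.ConfigurationError):
        bad = _tiny_cfg(de_fold_changes={"gene0001": {"HL": -2.0}})
        synthetic.simulate_reference(bad)


def test_anticorrelated_targets_get_reciprocal_folds():
    cfg = _tiny_cfg()
    bundle = synthetic.simulate_reference(cfg)
    up = bundle.mirna_truth.set_index("mirna_id").loc["syn-mir001"]
    assert up.fold_HL == 4.0
    target_gene = bundle.target_sites.query(
        "mirna_id == 'syn-mir001'").transcript_id.iloc[0]
    g = bundle.gene_truth.set_index("gene_id").loc[target_gene]
    assert g.fold_HL == pytest.approx(0.25)
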