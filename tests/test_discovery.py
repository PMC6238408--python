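"""Hairpin evaluation criteria, family classification and naming."""

import numpy as np
import pytest

from mirapex import discovery, synthetic
from mirapex.discovery import (LARGE_LOOP, MFE_GATE, MIN_COUNT, OVERHANG,
                               CandidateWindow, HairpinCall,
                               classify_known, evaluate_precursor,
                               extract_candidates, name_mirnas)
from mirapex.folding import fold_hairpin
from mirapex.preprocess import SmallRNATag
from mirapex.util import revcomp


def _window(seq, chrom="c1", start=0, strand="+"):
    return CandidateWindow(chrom, start, start + len(seq), strand, seq)


def _tag(seq, count, sample="s"):
    return SmallRNATag(sequence=seq, counts={sample: count})


@pytest.fixture(scope="module")
def clean_precursor():
    """A mismatch-free planted stem-loop with its arm sequences."""
    cfg = synthetic.SimulationConfig(seed=21, n_hairpins=1, n_decoy_loci=0,
                                     stem_mismatch_rate=0.0)
    bundle = synthetic.simulate_reference(cfg)
    rec = bundle.precursors.iloc[0]
    return rec


def test_clean_precursor_accepted_with_no_reasons(clean_precursor):
    rec = clean_precursor
    w = _window(rec.precursor_seq)
    tags = [(_tag(rec.mature_5p, 50), 0),
            (_tag(rec.mature_3p, 8), len(rec.precursor_seq) - 21)]
    call = evaluate_precursor(w, tags)
    assert call.reasons == []
    assert call.accepted
    assert call.dominant_arm == "5p"
    assert call.mature_5p == rec.mature_5p
    assert call.mature_3p == rec.mature_3p


def test_count_gate_requires_strictly_more_than_five(clean_precursor):
    rec = clean_precursor
    w = _window(rec.precursor_seq)
    call5 = evaluate_precursor(w, [(_tag(rec.mature_5p, 5), 0)])
    assert call5.reasons == [MIN_COUNT]
    call6 = evaluate_precursor(w, [(_tag(rec.mature_5p, 6), 0)])
    assert call6.reasons == []


def test_overhang_gate_rejects_one_nt_shift(clean_precursor):
    """A star tag shifted 1 nt breaks the 2-nt 3' overhang geometry."""
    rec = clean_precursor
    ext = rec.precursor_seq + "A"  # one spare base beyond the star 3' end
    w = _window(ext)
    shifted_star = ext[len(ext) - 21:]    # star shifted +1 toward 3'
    call = evaluate_precursor(w, [(_tag(rec.mature_5p, 50), 0),
                                  (_tag(shifted_star, 8), len(ext) - 21)])
    assert call.reasons == [OVERHANG]


def test_mfe_gate_rejects_weak_but_clean_hairpin():
    """An AU-only perfect stem folds cleanly yet misses -18 kcal/mol."""
    mature = "ATTAATTAATAATTAATTATA"
    loop = "CCCCCCCCCC"
    tail = "CC"  # cannot pair with the A/T mature start
    precursor = mature + loop + revcomp(mature[:19]) + tail
    _, mfe = fold_hairpin(precursor)
    assert -18.0 < mfe < 0.0
    call = evaluate_precursor(_window(precursor), [(_tag(mature, 50), 0)])
    assert call.reasons == [MFE_GATE]


def test_mfe_threshold_boundary_is_inclusive(clean_precursor):
    rec = clean_precursor
    w = _window(rec.precursor_seq)
    tags = [(_tag(rec.mature_5p, 50), 0)]
    _, mfe = fold_hairpin(rec.precursor_seq)
    at_gate = evaluate_precursor(w, tags, mfe_max=mfe)
    assert MFE_GATE not in at_gate.reasons
    below_gate = evaluate_precursor(w, tags, mfe_max=mfe - 0.1)
    assert MFE_GATE in below_gate.reasons


def test_mfe_monotonicity(clean_precursor):
    """Tightening the MFE threshold never rescues an MFE rejection."""
    rec = clean_precursor
    w = _window(rec.precursor_seq)
    tags = [(_tag(rec.mature_5p, 50), 0)]
    accepted_at = None
    for thr in np.arange(-40.0, -10.0, 1.0):  # loosening the gate
        call = evaluate_precursor(w, tags, mfe_max=float(thr))
        if MFE_GATE not in call.reasons:
            accepted_at = thr
        elif accepted_at is not None:
            pytest.fail("acceptance is not monotone in the MFE threshold")
    assert accepted_at is not None


def test_large_loop_gate_on_bulged_stem():
    """A 5-nt bulge inside the mature-spanning duplex is rejected."""
    mature = "GCGCTTGAGCACGTCAGGTCA"
    bulge = "AAAAA"
    star = revcomp(mature[:19])
    precursor = mature + "GCAACAGCAA" + star[:9] + bulge + star[9:] + "CC"
    call = evaluate_precursor(_window(precursor), [(_tag(mature, 50), 0)])
    assert LARGE_LOOP in call.reasons


def test_no_tags_rejected_for_count():
    seq = "GGGGGGGCCCAAAACCCGGGCCCCCCC"
    call = evaluate_precursor(_window(seq), [])
    assert MIN_COUNT in call.reasons
    assert not call.accepted


def test_extract_candidates_clipped_at_chromosome_start():
    genome = {"c1": "ACGT" * 200}
    tag = SmallRNATag(sequence="ACGTACGTACGTACGTACGT",
                      counts={"s": 10},
                      genome_hits=[("c1", 0, 20, "+")])
    windows = extract_candidates([tag], genome)
    assert windows
    for w in windows:
        assert 0 <= w.start0 < w.end0 <= 800


def test_extract_candidates_two_windows_per_hit():
    genome = {"c1": "A" * 2000}
    tag = SmallRNATag(sequence="T" * 20, counts={"s": 10},
                      genome_hits=[("c1", 1000, 1020, "+"),
                                   ("c1", 1500, 1520, "-")])
    windows = extract_candidates([tag], genome)
    assert len(windows) <= 4
    assert {w.strand for w in windows} == {"+", "-"}


def test_low_count_tags_do_not_seed_windows():
    genome = {"c1": "A" * 500}
    tag = SmallRNATag(sequence="T" * 20, counts={"s": 5},
                      genome_hits=[("c1", 100, 120, "+")])
    assert extract_candidates([tag], genome) == []


def test_classify_known_thresholds():
    ref = {"ath-miR156a": "TGACAGAAGAGAGTGAGCACA"}
    exact = ref["ath-miR156a"]
    assert classify_known(exact, ref) == ("miR156", "ath-miR156a")
    two_subs = "AGACAGAAGAGAGTGAGCACT"
    assert classify_known(two_subs, ref)[0] == "miR156"
    three_subs = "AGACAGAAGAGAGTGAGGACT"
    assert classify_known(three_subs, ref) == ("novel", None)


def test_classify_known_offset_limit():
    ref = {"ath-miR156a": "TGACAGAAGAGAGTGAGCACA"}
    shifted_two = ref["ath-miR156a"][2:] + "GG"     # 5' shift 2, same length
    assert classify_known(shifted_two, ref)[0] == "novel"  # 2 shift + 2 subs at end
    shorter_two = ref["ath-miR156a"][:-2]           # 2-nt 3' overhang only
    assert classify_known(shorter_two, ref)[0] == "miR156"


def test_naming_orders_family_members_by_genome_position():
    def call_at(chrom, start, mature):
        return HairpinCall((chrom, start, start + 60, "+"), "A" * 60,
                           "." * 60, -30.0, mature, None, "5p", 99)

    ref = {"ath-miR169a": "TAGCCAAGGATGACTTGCCTG"}
    mature = ref["ath-miR169a"]
    calls = [call_at("chr1", 900, mature), call_at("chr1", 100, mature)]
    records = name_mirnas(calls, ref, prefix="csa")
    names = {r.call.locus[1]: r.name for r in records}
    assert names[100] == "csa-miR169a"
    assert names[900] == "csa-miR169b"


def test_naming_single_member_family_has_no_suffix():
    ref = {"ath-miR169a": "TAGCCAAGGATGACTTGCCTG"}
    call = HairpinCall(("chr1", 5, 65, "+"), "A" * 60, "." * 60, -30.0,
                       ref["ath-miR169a"], None, "5p", 99)
    records = name_mirnas([call], ref)
    assert records[0].name == "csa-miR169"


def test_novel_serials_follow_genome_order_across_chromosomes():
    def novel_at(chrom, start, seq):
        return HairpinCall((chrom, start, start + 60, "+"), "A" * 60,
                           "." * 60, -30.0, seq, None, "5p", 99)

    calls = [novel_at("chr2", 10, "ACGTACGTACGTACGTACGTA"),
             novel_at("chr1", 500, "TTGCATGCATGCATGCATGCA"),
             novel_at("chr1", 50, "GGGCATGCATGCATGCATGCA")]
    records = name_mirnas(calls, reference=None)
    ordered = sorted(records, key=lambda r: r.name)
    assert [r.call.locus[:2] for r in ordered] == \
        [("chr1", 50), ("chr1", 500), ("chr2", 10)]


def test_duplicate_locus_raises_naming_error():
    call = HairpinCall(("chr1", 5, 65, "+"), "A" * 60, "." * 60, -30.0,
                       "ACGTACGTACGTACGTACGTA", None, "5p", 99)
    with pytest.raises(ValueError):
        name_mirnas([call, call])


def test_full_discovery_recovers_planted_and_rejects_decoys(small_run):
    bundle = small_run.bundle
    accepted = [r.call for r in small_run.records]
    planted = bundle.precursors.query("kind == 'mirna'")
    for rec in planted.itertuples():
        assert any(c.locus[0] == rec.chrom and c.locus[3] == rec.strand
                   and abs(c.locus[1] - rec.start0) <= 3
                   and abs(c.locus[2] - rec.end0) <= 3
                   for c in accepted), rec.locus_id
    decoys = bundle.precursors.query("kind == 'decoy'")
    for rec in decoys.itertuples():
        assert not any(c.locus[0] == rec.chrom and c.locus[1] < rec.end0
                       and rec.start0 < c.locus[2] for c in accepted), \
            rec.locus_id


def test_planted_window_contains_precursor(small_run):
    bundle = small_run.bundle
    windows = extract_candidates(small_run.flagged, bundle.genome)
    for rec in bundle.precursors.query("kind == 'mirna'").itertuples():
        assert any(w.chrom == rec.chrom and w.strand == rec.strand
                   and w.start0 <= rec.start0 and rec.end0 <= w.end0
                   for w in windows), rec.locus_id
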