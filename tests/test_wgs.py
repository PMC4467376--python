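"""WGS deletion extraction, read filters, dedup, the control-aware filter
cascade (checked against a brute-force interval-arithmetic oracle),
frameshift classification and locus allele fractions."""

import numpy as np
import pytest

from crisprindel.wgs import (FRAMESHIFT, IN_FRAME, NO_CODING_OVERLAP,
                             AlignmentFormatError, AlignmentSegment,
                             DeletionEvent, ExonInterval, WgsFilterConfig,
                             allele_fractions_at_locus, call_sample,
                             classify_frameshift, coverage_from_segments,
                             deduplicate_and_combine, extract_candidate_indels,
                             filter_deletions, filter_read_level,
                             read_segments)
from oracles import brute_filter


def seg(read_id="r1", pos=1000, cigar=(("M", 50), ("D", 10), ("M", 51)),
        chrom="chr1", **kw):
    return AlignmentSegment(read_id=read_id, chrom=chrom, pos=pos,
                            cigar=tuple(cigar), **kw)


def ev(start, end, support=3, sample="T", chrom="chr1", **kw):
    return DeletionEvent(sample=sample, chrom=chrom, start=start, end=end,
                        support=support, **kw)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def test_cigar_deletion_coordinates_and_stretches():
    dels, ins = extract_candidate_indels([seg()])
    (ob,) = dels
    assert (ob.start, ob.end) == (1050, 1060)
    assert ob.m_runs == (50, 51) and sum(ob.m_runs) == 101
    assert ins == []


def test_contiguous_match_yields_no_observation():
    dels, ins = extract_candidate_indels([seg(cigar=(("M", 101),))])
    assert dels == [] and ins == []


def test_split_read_gap_becomes_deletion():
    a = seg("r9/1", pos=1950, cigar=(("M", 50), ("S", 51)))
    b = seg("r9/1", pos=3200, cigar=(("S", 50), ("M", 51)),
            is_supplementary=True)
    dels, _ = extract_candidate_indels([a, b])
    (ob,) = dels
    assert (ob.start, ob.end) == (2000, 3200)
    assert ob.source == "split"


def test_split_segments_on_different_chrom_or_strand_are_not_joined():
    a = seg("r9/1", pos=1950, cigar=(("M", 50), ("S", 51)))
    b_chrom = seg("r9/1", pos=3200, cigar=(("S", 50), ("M", 51)), chrom="chr2")
    b_strand = seg("r9/1", pos=3200, cigar=(("S", 50), ("M", 51)), strand="-")
    for b in (b_chrom, b_strand):
        dels, _ = extract_candidate_indels([a, b])
        assert dels == []


def test_insertions_go_to_the_side_channel():
    dels, ins = extract_candidate_indels(
        [seg(cigar=(("M", 50), ("I", 4), ("M", 47)))])
    assert dels == []
    (ob,) = ins
    assert ob.kind == "ins" and ob.start == ob.end == 1050 and ob.ins_length == 4


def test_unknown_cigar_op_is_an_error_naming_the_read():
    with pytest.raises(AlignmentFormatError, match="rBad"):
        AlignmentSegment(read_id="rBad", chrom="c", pos=0, cigar=(("Z", 5),))


# ---------------------------------------------------------------------------
# read-level filter
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("cigar,keep", [
    ((("M", 50), ("D", 5), ("M", 51)), True),    # stretches 50/51, total 101
    ((("M", 20), ("D", 5), ("M", 81)), False),   # 20 < 25
    ((("M", 47), ("D", 5), ("M", 47)), False),   # total 94 < 95
    ((("M", 25), ("D", 5), ("M", 70)), True),    # both bounds inclusive
])
def test_read_level_stretch_and_total_bounds(cigar, keep):
    dels, _ = extract_candidate_indels([seg(cigar=cigar)])
    assert filter_read_level(dels[0], WgsFilterConfig()) is keep


# ---------------------------------------------------------------------------
# dedup + combine
# ---------------------------------------------------------------------------


def test_duplicate_templates_counted_once():
    obs = []
    for i, tkey in enumerate([("c", 900, 300), ("c", 900, 300), ("c", 910, 290),
                              ("c", 920, 280), ("c", 930, 270)]):
        dels, _ = extract_candidate_indels([seg(f"r{i}/1", template_key=tkey)])
        obs.extend(dels)
    (event,) = deduplicate_and_combine(obs, sample="T")
    assert (event.start, event.end, event.support) == (1050, 1060, 4)


def test_one_bp_breakpoint_difference_separates_events():
    d1, _ = extract_candidate_indels([seg("a/1", pos=1000)])
    d2, _ = extract_candidate_indels([seg("b/1", pos=1001)])
    events = deduplicate_and_combine(d1 + d2)
    assert len(events) == 2


def test_empty_observations_yield_no_events():
    assert deduplicate_and_combine([]) == []


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------


def _cov(depth, chrom="chr1", length=10_000):
    return {chrom: np.full(length, depth, dtype=np.int64)}


def test_size_bounds_are_inclusive():
    events = [ev(100, 103), ev(100, 104), ev(100, 100_100), ev(100, 100_101)]
    res = filter_deletions(events, [], [], [], _cov(0, length=200_000))
    sizes = {e.size for e in res.retained}
    assert sizes == {4, 100_000} and res.tally["size"] == 2


def test_breakpoint_near_control_event_is_dropped():
    control = [ev(500, 700, sample="C")]
    dropped = filter_deletions([ev(504, 900)], control, [], [], _cov(0))
    kept = filter_deletions([ev(506, 900)], control, [], [], _cov(0))
    assert dropped.tally["control_breakpoint"] == 1 and not dropped.retained
    assert kept.retained and kept.tally["control_breakpoint"] == 0


def test_polymorphic_reciprocal_overlap_is_strictly_above_080():
    poly = [("chr1", 1000, 2000)]
    identical = filter_deletions([ev(1000, 2000)], [], poly, [], _cov(0))
    assert identical.tally["polymorphic"] == 1
    partial = filter_deletions([ev(1000, 1800)], [], poly, [], _cov(0))
    assert partial.retained  # reciprocal overlap 0.8 is not > 0.8


def test_repeat_overlap_within_pad_drops_event():
    repeats = [("chr1", 1004, 1100)]
    res = filter_deletions([ev(990, 1000)], [], [], repeats, _cov(0))
    assert res.tally["repeat"] == 1
    res2 = filter_deletions([ev(990, 998)], [], [], repeats, _cov(0))
    assert res2.retained


def test_control_coverage_cutoff_is_strictly_above_250():
    at250 = filter_deletions([ev(100, 200)], [], [], [], _cov(250))
    at251 = filter_deletions([ev(100, 200)], [], [], [], _cov(251))
    assert at250.retained and not at251.retained
    assert at251.tally["control_coverage"] == 1


def test_missing_track_is_an_error():
    with pytest.raises(ValueError):
        filter_deletions([ev(100, 200)], [], None, [], _cov(0))


def test_tally_accounts_for_every_event():
    rng = np.random.default_rng(5)
    events = [ev(int(s), int(s) + int(d), chrom="chr1")
              for s, d in zip(rng.integers(10, 9000, 300),
                              rng.integers(1, 900, 300))]
    controls = [ev(int(s), int(s) + 50, sample="C")
                for s in rng.integers(10, 9000, 30)]
    poly = [("chr1", int(s), int(s) + int(d))
            for s, d in zip(rng.integers(10, 9000, 20),
                            rng.integers(5, 400, 20))]
    reps = [("chr1", int(s), int(s) + 30) for s in rng.integers(10, 9000, 20)]
    cov = {"chr1": rng.integers(0, 400, 10_000)}
    res = filter_deletions(events, controls, poly, reps, cov)
    assert sum(res.tally.values()) == len(events)  # drops + retained


@pytest.mark.parametrize("seed", range(5))
def test_cascade_matches_bruteforce_interval_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 500
    events = [ev(int(s), int(s) + int(d))
              for s, d in zip(rng.integers(10, 40_000, n),
                              rng.integers(1, 3000, n))]
    controls = [ev(int(s), int(s) + int(d), sample="C")
                for s, d in zip(rng.integers(10, 40_000, 40),
                                rng.integers(4, 500, 40))]
    poly = [("chr1", int(s), int(s) + int(d))
            for s, d in zip(rng.integers(10, 40_000, 30),
                            rng.integers(5, 2000, 30))]
    reps = [("chr1", int(s), int(s) + int(d))
            for s, d in zip(rng.integers(10, 40_000, 30),
                            rng.integers(10, 200, 30))]
    cov = {"chr1": rng.integers(0, 300, 50_000)}
    res = filter_deletions(events, controls, poly, reps, cov)
    exp_retained, exp_tally = brute_filter(events, controls, poly, reps, cov)
    assert [(e.start, e.end) for e in res.retained] == \
        [(e.start, e.end) for e in exp_retained]
    assert res.tally == exp_tally


# ---------------------------------------------------------------------------
# frameshift classification
# ---------------------------------------------------------------------------

EXON = ExonInterval("chr1", 1000, 1300)


@pytest.mark.parametrize("start,end,expected", [
    (1100, 1107, FRAMESHIFT),        # 7 exonic bp = 3N+1
    (1100, 1106, IN_FRAME),          # 6 exonic bp = 3N
    (1100, 1108, FRAMESHIFT),        # 8 exonic bp = 3N+2
    (200, 300, NO_CODING_OVERLAP),   # entirely outside the exon
    (990, 1297, IN_FRAME),           # partial overlap: 297 exonic bp = 3N
])
def test_exonic_loss_modulo_three(start, end, expected):
    d = min(end, EXON.end) - max(start, EXON.start)
    if expected == IN_FRAME:
        assert d % 3 == 0
    assert classify_frameshift(ev(start, end), EXON) == expected


def test_frameshift_classification_is_shift_invariant():
    event = ev(1100, 1157)
    for shift in (0, 17, 3001, -500):
        shifted_ev = ev(1100 + shift, 1157 + shift)
        shifted_exon = ExonInterval("chr1", 1000 + shift, 1300 + shift)
        assert classify_frameshift(shifted_ev, shifted_exon) == \
            classify_frameshift(event, EXON)


# ---------------------------------------------------------------------------
# allele fractions at the locus
# ---------------------------------------------------------------------------


def test_reads_partition_into_deletion_and_wt_classes():
    cut = 1055
    event = ev(1050, 1060)  # 10 bp, frameshift vs EXON
    segments = [seg(f"d{i}/1") for i in range(80)]
    segments += [seg(f"w{i}/1", cigar=(("M", 101),)) for i in range(20)]
    af = allele_fractions_at_locus(segments, [event], EXON, cut_pos=cut)
    assert af.frameshift == pytest.approx(0.8)
    assert af.wt == pytest.approx(0.2)
    assert af.in_frame == 0.0
    assert af.n_unassigned == 0


def test_all_contiguous_reads_give_wt_one():
    segments = [seg(f"w{i}/1", cigar=(("M", 101),)) for i in range(10)]
    af = allele_fractions_at_locus(segments, [], EXON, cut_pos=1050)
    assert af.wt == pytest.approx(1.0)


def test_no_covering_reads_is_not_applicable():
    segments = [seg("far/1", pos=5000, cigar=(("M", 101),))]
    assert allele_fractions_at_locus(segments, [], EXON, cut_pos=1050) is None


def test_biallelic_knockout_population_has_no_wt_reads(locus_and_cut, rng):
    from crisprindel.simulate import (SimConfig, biallelic_ko_population,
                                      simulate_wgs_alignments)

    locus, cut = locus_and_cut
    pop = biallelic_ko_population(locus, cut, rng=rng)
    records, _ = simulate_wgs_alignments(pop, SimConfig(seed=3, wgs_depth=40),
                                         rng, sample="ko")
    segments = [r.segment for r in records]
    exon = ExonInterval(pop.chrom, cut - 300, cut + 300)
    events = call_sample(segments, "ko")
    af = allele_fractions_at_locus(segments, events, exon, cut_pos=cut)
    assert af is not None
    assert af.wt <= 0.01


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------


def test_sam_round_trip_preserves_events(tmp_path, locus_and_cut, rng):
    from crisprindel.simulate import (Clone, CloneEdit, ClonePopulation,
                                      SimConfig, simulate_wgs_alignments,
                                      write_sam)

    locus, cut = locus_and_cut
    pop = ClonePopulation(locus, cut, [Clone("c", CloneEdit(cut - 4, cut + 6), 1.0)])
    records, _ = simulate_wgs_alignments(pop, SimConfig(seed=4, wgs_depth=30), rng)
    path = tmp_path / "t.sam"
    write_sam(records, path, chrom=pop.chrom, chrom_len=len(locus))
    loaded = read_segments(str(path))
    direct = call_sample([r.segment for r in records], "s")
    via_sam = call_sample(loaded, "s")
    assert [(e.start, e.end, e.support) for e in direct] == \
        [(e.start, e.end, e.support) for e in via_sam]


def test_unsorted_sam_is_rejected(tmp_path):
    path = tmp_path / "bad.sam"
    path.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:c\tLN:5000\n"
        "r1\t0\tc\t2000\t60\t101M\t*\t0\t0\t*\t*\n"
        "r2\t0\tc\t1000\t60\t101M\t*\t0\t0\t*\t*\n")
    with pytest.raises(AlignmentFormatError):
        read_segments(str(path))


def test_coverage_counts_m_bases_only():
    segments = [seg("a/1", pos=0, cigar=(("M", 10), ("D", 5), ("M", 10)))]
    cov = coverage_from_segments(segments, {"chr1": 30})
    assert cov["chr1"][:10].tolist() == [1] * 10
    assert cov["chr1"][10:15].tolist() == [0] * 5
    assert cov["chr1"][15:25].tolist() == [1] * 10
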