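"""Deletion calling from whole-genome sequencing alignments.

Candidate deletions are extracted per read end from two evidence types:
CIGAR deletions (a D run between two mapped M runs) and split reads (two
alignment segments of one read end on the same chromosome and strand, in
consistent order, whose reference gap is the deletion). Read-level filters
require every mapped stretch to be at least 25 bp and at least 95 bp mapped
in total. Reads indicating the same deletion are combined after removing
putative PCR duplicates (identical outer template coordinates), and the
resulting events pass a five-stage cascade against the pooled controls:

  size in [4 bp, 100 kb] -> breakpoints clear of control-event breakpoints
  (padded 5 bp) -> not matching a known polymorphic indel (>80% reciprocal
  overlap) -> breakpoints (padded 5 bp) clear of simple repeats ->
  breakpoints not in regions of combined control coverage above 250.

The module also classifies the coding consequence of a deletion (frameshift
when the exonic loss is not a multiple of 3) and estimates per-allele read
fractions at the target locus by assigning each read covering the cut site
to a called deletion allele or to the wild-type allele.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

CIGAR_OPS = set("MIDSH")
_CONSUMES_REF = {"M": True, "I": False, "D": True, "S": False, "H": False}
_CONSUMES_QUERY = {"M": True, "I": True, "D": False, "S": True, "H": False}


class AlignmentFormatError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentSegment:
    """One alignment of (part of) a read end.

    ``read_id`` must be unique per read end (mates are independent
    observations, so a pair yields ids like ``name/1`` and ``name/2``).
    ``template_key`` carries the outer template coordinates used for PCR
    duplicate removal; segments without one are never deduplicated.
    """

    read_id: str
    chrom: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    strand: str = "+"
    is_supplementary: bool = False
    mate_pos: int | None = None
    template_key: tuple | None = None

    def __post_init__(self) -> None:
        if not self.cigar:
            raise AlignmentFormatError(f"read {self.read_id}: empty CIGAR")
        bad = {op for op, _ in self.cigar} - CIGAR_OPS
        if bad:
            raise AlignmentFormatError(
                f"read {self.read_id}: unknown CIGAR op(s) {sorted(bad)}")
        if self.pos < 0:
            raise AlignmentFormatError(f"read {self.read_id}: negative pos")

    @property
    def m_runs(self) -> tuple[int, ...]:
        return tuple(n for op, n in self.cigar if op == "M")

    @property
    def ref_length(self) -> int:
        return sum(n for op, n in self.cigar if _CONSUMES_REF[op])

    @property
    def ref_end(self) -> int:
        return self.pos + self.ref_length

    @property
    def query_start(self) -> int:
        """Offset of the first aligned base within the full read."""
        off = 0
        for op, n in self.cigar:
            if op in "SH":
                off += n
            else:
                break
        return off


@dataclass(frozen=True)
class IndelObservation:
    """A deletion or insertion observed in a single read end."""

    read_id: str
    chrom: str
    start: int
    end: int                     # half-open; for insertions end == start
    kind: str                    # "del" | "ins"
    source: str                  # "cigar" | "split"
    m_runs: tuple[int, ...]      # all mapped stretches of the read end
    ins_length: int = 0
    template_key: tuple | None = None

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DeletionEvent:
    """A deletion supported by one or more non-duplicate reads."""

    sample: str
    chrom: str
    start: int
    end: int
    support: int
    source: str = "cigar"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("DeletionEvent requires end > start")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WgsFilterConfig:
    min_stretch: int = 25          # every mapped stretch at least this long
    min_mapped_total: int = 95     # total mapped bases per read end
    min_size: int = 4
    max_size: int = 100_000
    control_pad: int = 5           # breakpoint padding vs controls/repeats
    polymorphic_identity: float = 0.80   # reciprocal overlap above this drops
    max_control_coverage: int = 250      # combined control depth above this drops

    def __post_init__(self) -> None:
        if self.min_size > self.max_size:
            raise ValueError("min_size must not exceed max_size")
        if min(self.min_stretch, self.min_mapped_total, self.min_size,
               self.control_pad, self.max_control_coverage) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class ExonInterval:
    chrom: str
    start: int
    end: int
    frame_bearing: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ExonInterval requires end > start")


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------


def _cigar_observations(seg: AlignmentSegment) -> list[IndelObservation]:
    """D/I runs strictly between two M runs of one segment."""
    obs: list[IndelObservation] = []
    m_runs = seg.m_runs
    if len(m_runs) < 2:
        return obs
    ref = seg.pos
    seen_m = False
    pending: list[tuple[str, int, int, int]] = []  # kind, start, end, ins_len
    for op, n in seg.cigar:
        if op == "M":
            if seen_m and pending:
                for kind, start, end, ins_len in pending:
                    obs.append(IndelObservation(
                        read_id=seg.read_id, chrom=seg.chrom, start=start,
                        end=end, kind=kind, source="cigar", m_runs=m_runs,
                        ins_length=ins_len, template_key=seg.template_key))
            pending = []
            seen_m = True
        elif op == "D" and seen_m:
            pending.append(("del", ref, ref + n, 0))
        elif op == "I" and seen_m:
            pending.append(("ins", ref, ref, n))
        if _CONSUMES_REF[op]:
            ref += n
    return obs


def _split_observations(segments: Sequence[AlignmentSegment]) -> list[IndelObservation]:
    """Pair split segments of one read end into deletion observations.

    Requires same chromosome and strand and consistent order: reference
    order must follow query order (reversed on the minus strand).
    """
    obs: list[IndelObservation] = []
    if len(segments) < 2:
        return obs
    segs = sorted(segments, key=lambda s: (s.pos, s.query_start))
    for left, right in zip(segs, segs[1:]):
        if left.chrom != right.chrom or left.strand != right.strand:
            continue
        gap = right.pos - left.ref_end
        if gap <= 0:
            continue
        if left.strand == "+":
            ordered = left.query_start < right.query_start
        else:
            ordered = left.query_start > right.query_start
        if not ordered:
            continue
        m_runs = left.m_runs + right.m_runs
        obs.append(IndelObservation(
            read_id=left.read_id, chrom=left.chrom, start=left.ref_end,
            end=right.pos, kind="del", source="split", m_runs=m_runs,
            template_key=left.template_key or right.template_key))
    return obs


def extract_candidate_indels(
    segments: Iterable[AlignmentSegment],
) -> tuple[list[IndelObservation], list[IndelObservation]]:
    """Extract raw (deletion, insertion) observations from alignment segments.

    Both mate ends are treated independently; only read ends with at least
    two mapped stretches separated by indels, or split alignments on the
    same chromosome, contribute. Returns ``(deletions, insertions)``.
    """
    by_read: dict[str, list[AlignmentSegment]] = defaultdict(list)
    deletions: list[IndelObservation] = []
    insertions: list[IndelObservation] = []
    for seg in segments:
        by_read[seg.read_id].append(seg)
        for ob in _cigar_observations(seg):
            (deletions if ob.kind == "del" else insertions).append(ob)
    for read_segments in by_read.values():
        deletions.extend(_split_observations(read_segments))
    return deletions, insertions


def filter_read_level(
    observation: IndelObservation,
    config: WgsFilterConfig = WgsFilterConfig(),
) -> bool:
    """Keep an observation iff every mapped stretch of its read end is at
    least ``min_stretch`` bp and at least ``min_mapped_total`` bp are mapped
    in total."""
    runs = observation.m_runs
    return (min(runs) >= config.min_stretch
            and sum(runs) >= config.min_mapped_total)


def deduplicate_and_combine(
    observations: Iterable[IndelObservation],
    sample: str = "sample",
) -> list[DeletionEvent]:
    """Combine reads indicating the same deletion, removing PCR duplicates.

    Two observations are duplicates when their templates share identical
    outer alignment coordinates on both ends (``template_key``); support is
    the number of distinct templates. Observations without a template key
    are counted individually.
    """
    groups: dict[tuple[str, int, int], list[IndelObservation]] = defaultdict(list)
    for ob in observations:
        if ob.kind != "del":
            continue
        groups[(ob.chrom, ob.start, ob.end)].append(ob)
    events = []
    for (chrom, start, end), obs in sorted(groups.items()):
        keys = set()
        support = 0
        source = "cigar"
        for ob in obs:
            if ob.template_key is None:
                support += 1
            elif ob.template_key not in keys:
                keys.add(ob.template_key)
                support += 1
            if ob.source == "split":
                source = "split"
        events.append(DeletionEvent(sample=sample, chrom=chrom, start=start,
                                    end=end, support=support, source=source))
    return events


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

Interval = tuple[str, int, int]

FILTER_ORDER = ("size", "control_breakpoint", "polymorphic", "repeat",
                "control_coverage")


def _tree(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end in intervals:
        if end > start:
            trees[chrom].addi(start, end)
    return trees


def _coverage_at(coverage: Mapping[str, np.ndarray], chrom: str, pos: int) -> int:
    arr = coverage.get(chrom)
    if arr is None or len(arr) == 0:
        return 0
    return int(arr[min(max(pos, 0), len(arr) - 1)])


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


@dataclass
class FilterResult:
    retained: list[DeletionEvent]
    tally: dict[str, int]


def filter_deletions(
    events: Sequence[DeletionEvent],
    control_events: Sequence[DeletionEvent],
    polymorphic_track: Iterable[Interval],
    repeat_track: Iterable[Interval],
    control_coverage: Mapping[str, np.ndarray],
    config: WgsFilterConfig = WgsFilterConfig(),
) -> FilterResult:
    """Apply the five-stage deletion filter cascade.

    ``control_events`` are the pooled deletion events of all control
    samples; ``control_coverage`` is the combined per-position mapped depth
    of the controls. Each dropped event is attributed to the first failing
    filter in the fixed order size -> control breakpoints -> polymorphic ->
    repeats -> control coverage. Tracks are required arguments but may be
    empty.
    """
    if polymorphic_track is None or repeat_track is None:
        raise ValueError("polymorphic and repeat tracks are required (may be empty)")
    pad = config.control_pad
    control_bp = _tree(
        (ev.chrom, bp - pad, bp + pad + 1)
        for ev in control_events for bp in (ev.start, ev.end))
    poly = _tree(polymorphic_track)
    repeats = _tree(repeat_track)

    tally = {name: 0 for name in FILTER_ORDER}
    retained: list[DeletionEvent] = []
    for ev in events:
        if not (config.min_size <= ev.size <= config.max_size):
            tally["size"] += 1
            continue
        if any(control_bp[ev.chrom][bp] for bp in (ev.start, ev.end)):
            tally["control_breakpoint"] += 1
            continue
        hits = poly[ev.chrom].overlap(ev.start, ev.end)
        if any(reciprocal_overlap((ev.start, ev.end), (iv.begin, iv.end))
               > config.polymorphic_identity for iv in hits):
            tally["polymorphic"] += 1
            continue
        if any(repeats[ev.chrom].overlap(bp - pad, bp + pad + 1)
               for bp in (ev.start, ev.end)):
            tally["repeat"] += 1
            continue
        if any(_coverage_at(control_coverage, ev.chrom, bp)
               > config.max_control_coverage for bp in (ev.start, ev.end)):
            tally["control_coverage"] += 1
            continue
        retained.append(ev)
    tally["retained"] = len(retained)
    return FilterResult(retained=retained, tally=tally)


def coverage_from_segments(
    segments: Iterable[AlignmentSegment],
    chrom_lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Per-position mapped (M-base) depth from alignment segments."""
    cov = {chrom: np.zeros(length, dtype=np.int64)
           for chrom, length in chrom_lengths.items()}
    for seg in segments:
        arr = cov.get(seg.chrom)
        if arr is None:
            continue
        ref = seg.pos
        for op, n in seg.cigar:
            if op == "M":
                arr[max(ref, 0):min(ref + n, len(arr))] += 1
            if _CONSUMES_REF[op]:
                ref += n
    return cov


# ---------------------------------------------------------------------------
# coding consequence + allele fractions
# ---------------------------------------------------------------------------

NO_CODING_OVERLAP = "no_coding_overlap"
IN_FRAME = "in_frame"
FRAMESHIFT = "frameshift"


def classify_frameshift(event: DeletionEvent, exon: ExonInterval) -> str:
    """Coding consequence of a deletion: the exonic loss is a frameshift
    when it is not a multiple of 3 (3N+1 or 3N+2 bp), in-frame at 3N bp."""
    if event.chrom != exon.chrom:
        return NO_CODING_OVERLAP
    d = min(event.end, exon.end) - max(event.start, exon.start)
    if d <= 0:
        return NO_CODING_OVERLAP
    return IN_FRAME if d % 3 == 0 else FRAMESHIFT


@dataclass(frozen=True)
class AlleleFractions:
    wt: float
    frameshift: float
    in_frame: float
    n_assigned: int
    n_unassigned: int


def allele_fractions_at_locus(
    segments: Iterable[AlignmentSegment],
    locus_events: Sequence[DeletionEvent],
    exon: ExonInterval,
    cut_pos: int,
    flank: int = 10,
) -> AlleleFractions | None:
    """Assign reads covering the cut site to deletion alleles or wild type.

    Each read end whose alignment overlaps ``cut_pos +/- flank`` is assigned
    to exactly one class: a locus deletion event (its own deletion
    observation exactly matches the event; classified frameshift/in-frame
    against the exon), wild type (a contiguous mapped stretch across the cut
    position), or unassigned. Fractions are class counts over all reads
    considered, so they sum to <= 1. Returns None when no read covers the
    window.
    """
    window = (cut_pos - flank, cut_pos + flank)
    event_class = {(ev.chrom, ev.start, ev.end): classify_frameshift(ev, exon)
                   for ev in locus_events}
    by_read: dict[str, list[AlignmentSegment]] = defaultdict(list)
    for seg in segments:
        by_read[seg.read_id].append(seg)

    counts = {FRAMESHIFT: 0, IN_FRAME: 0, "wt": 0, "unassigned": 0}
    total = 0
    for read_id, segs in by_read.items():
        if not any(s.pos <= window[1] and s.ref_end >= window[0] for s in segs):
            continue
        total += 1
        dels, _ = extract_candidate_indels(segs)
        cls = None
        for ob in dels:
            cls = event_class.get((ob.chrom, ob.start, ob.end))
            if cls is not None:
                break
        if cls in (FRAMESHIFT, IN_FRAME):
            counts[cls] += 1
            continue
        wt = False
        for seg in segs:
            ref = seg.pos
            for op, n in seg.cigar:
                if op == "M" and ref <= cut_pos < ref + n:
                    wt = True
                if _CONSUMES_REF[op]:
                    ref += n
        if wt and cls is None and not dels:
            counts["wt"] += 1
        else:
            counts["unassigned"] += 1
    if total == 0:
        return None
    return AlleleFractions(
        wt=counts["wt"] / total,
        frameshift=counts[FRAMESHIFT] / total,
        in_frame=counts[IN_FRAME] / total,
        n_assigned=total - counts["unassigned"],
        n_unassigned=counts["unassigned"],
    )


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------


def read_segments(path: str, require_sorted: bool = True) -> list[AlignmentSegment]:
    """Load alignment segments from a SAM/BAM file via pysam.

    Secondary and unmapped records are skipped; mates get distinct read ids
    (``/1`` and ``/2``). The template key for duplicate removal is
    (chromosome, leftmost template start, |TLEN|) when mate information is
    present.
    """
    import pysam

    segments: list[AlignmentSegment] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        if require_sorted and fh.header.get("HD", {}).get("SO") == "unsorted":
            raise AlignmentFormatError(f"{path}: declared unsorted")
        last = (None, -1)
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if require_sorted:
                key = (rec.reference_name, rec.reference_start)
                if key[0] == last[0] and key[1] < last[1]:
                    raise AlignmentFormatError(
                        f"{path}: not coordinate-sorted at {rec.query_name}")
                last = key
            suffix = "/2" if rec.is_read2 else "/1"
            tkey = None
            if rec.is_paired and rec.next_reference_id >= 0:
                tkey = (rec.reference_name,
                        min(rec.reference_start, rec.next_reference_start),
                        abs(rec.template_length))
            cigar = tuple(("MIDNSHP=XB"[op], n) for op, n in rec.cigartuples or ())
            cigar = tuple((("M" if c in "=X" else c), n) for c, n in cigar)
            segments.append(AlignmentSegment(
                read_id=rec.query_name + suffix,
                chrom=rec.reference_name,
                pos=rec.reference_start,
                cigar=cigar,
                strand="-" if rec.is_reverse else "+",
                is_supplementary=rec.is_supplementary,
                mate_pos=(rec.next_reference_start if rec.is_paired else None),
                template_key=tkey,
            ))
    return segments


def call_sample(
    segments: Iterable[AlignmentSegment],
    sample: str = "sample",
    config: WgsFilterConfig = WgsFilterConfig(),
) -> list[DeletionEvent]:
    """Extraction, read-level filtering and dedup/combine for one sample
    (the control-aware cascade is applied separately via filter_deletions)."""
    dels, _ = extract_candidate_indels(segments)
    kept = [ob for ob in dels if filter_read_level(ob, config)]
    return deduplicate_and_combine(kept, sample=sample)
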