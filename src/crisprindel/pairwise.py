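"""Low-level sequence primitives: reverse complement, paired-read overlap
merging, global alignment and indel normalisation.

The merge step replaces an external read merger: among all overlap offsets it
picks the one maximising the number of matching bases, subject to a minimum
overlap length and a maximum mismatch fraction, and resolves disagreeing
positions by base quality. Match counting over all offsets is done with a
cross-correlation of one-hot base encodings, so the search is exact, not
seeded.

Indel extraction runs a global end-to-end alignment (affine gap penalties)
and emits each maximal gap run as one event; a deletion run immediately
adjacent to an insertion run is merged into a single replacement event.
Pure insertions and deletions are left-aligned so that the same physical
event has one canonical representation regardless of which amplicon it was
observed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# paired-read merging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MergeResult:
    seq: str
    overlap: int
    mismatches: int


def _overlap_match_counts(fwd: str, rev_rc: str) -> np.ndarray:
    """match_counts[o-1] = number of equal bases between fwd[-o:] and rev_rc[:o].

    Computed for every overlap o = 1..min(len) at once via one-hot
    cross-correlation (exact integer counts).
    """
    f = np.frombuffer(fwd.encode(), dtype=np.uint8)
    r = np.frombuffer(rev_rc.encode(), dtype=np.uint8)
    l1, l2 = len(f), len(r)
    total = np.zeros(l1 + l2 - 1)
    for base in b"ACGT":
        total += np.correlate((f == base).astype(np.float64),
                              (r == base).astype(np.float64), "full")
    # lag d = k - (l2 - 1); overlap o aligns f[l1-o:] with r[:o], i.e. d = l1-o
    max_o = min(l1, l2)
    idx = l1 - np.arange(1, max_o + 1) + l2 - 1
    return np.rint(total[idx]).astype(np.int64)


def merge_pair(
    fwd_seq: str,
    fwd_qual: str,
    rev_seq: str,
    rev_qual: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergeResult | None:
    """Merge a read pair into the sequenced fragment, or return None.

    ``rev_seq`` is the raw reverse read; it is reverse-complemented (and its
    quality string reversed) before the overlap search. The admissible
    overlap maximising the match count wins; ties go to the longer overlap.
    At disagreeing overlap positions the base with the higher quality is
    kept (the forward base on a quality tie).
    """
    r = revcomp(rev_seq)
    rq = rev_qual[::-1]
    matches = _overlap_match_counts(fwd_seq, r)
    best: tuple[int, int] | None = None  # (match_count, overlap)
    for o in range(min_overlap, len(matches) + 1):
        m = int(matches[o - 1])
        if (o - m) / o <= max_mismatch_frac:
            if best is None or (m, o) >= best:
                best = (m, o)
    if best is None:
        return None
    m, o = best
    head = fwd_seq[: len(fwd_seq) - o]
    tail = r[o:]
    if m == o:
        mid = fwd_seq[len(fwd_seq) - o:]
    else:
        f_mid = fwd_seq[len(fwd_seq) - o:]
        fq_mid = fwd_qual[len(fwd_seq) - o:]
        r_mid = r[:o]
        rq_mid = rq[:o]
        mid = "".join(
            fb if fb == rb or fqb >= rqb else rb
            for fb, rb, fqb, rqb in zip(f_mid, r_mid, fq_mid, rq_mid)
        )
    return MergeResult(seq=head + mid + tail, overlap=o, mismatches=o - m)


# ---------------------------------------------------------------------------
# global alignment and indel extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap global alignment scores.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``. The
    defaults favour one consolidated gap over several scattered ones,
    matching the single-deletion repair outcomes this pipeline targets.
    """

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


@lru_cache(maxsize=8)
def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def left_align_indel(ref: str, start: int, span: int, alt: str) -> tuple[int, int, str]:
    """Shift a pure insertion or deletion to its leftmost representation.

    Replacement events (span > 0 and alt non-empty) are returned unchanged;
    their placement is pinned by the alignment.
    """
    if span > 0 and alt:
        return start, span, alt
    if span > 0:  # pure deletion
        while start > 0 and ref[start - 1] == ref[start + span - 1]:
            start -= 1
        return start, span, ""
    # pure insertion: rotate the inserted sequence leftwards
    while start > 0 and alt and ref[start - 1] == alt[-1]:
        alt = ref[start - 1] + alt[:-1]
        start -= 1
    return start, 0, alt


@dataclass(frozen=True)
class RawIndel:
    """An indel in local reference coordinates (0-based, half-open)."""

    start: int
    span: int
    alt: str

    @property
    def length(self) -> int:
        """Signed length: affected reference length minus alternative length
        (positive = net deletion, negative = net insertion)."""
        return self.span - len(self.alt)


def align_score(ref: str, query: str, scoring: AlignScoring = AlignScoring()) -> float:
    return _aligner(scoring).score(ref, query)


def extract_indels(ref: str, query: str,
                   scoring: AlignScoring = AlignScoring()) -> list[RawIndel]:
    """Globally align ``query`` to ``ref`` and return normalised indels.

    Every maximal gap run becomes one event; adjacent deletion/insertion
    runs (no aligned base between them) merge into a single replacement.
    Events are left-aligned against ``ref``. Identical sequences yield [].
    """
    if ref == query:
        return []
    aln = _aligner(scoring).align(ref, query)[0]
    ref_blocks, query_blocks = aln.aligned
    events: list[RawIndel] = []
    prev_r = 0
    prev_q = 0
    bounds = list(zip(ref_blocks, query_blocks)) + [((len(ref), len(ref)),
                                                     (len(query), len(query)))]
    for (rs, re), (qs, qe) in bounds:
        span = rs - prev_r
        alt = query[prev_q:qs]
        if span > 0 or alt:
            start, span, alt = left_align_indel(ref, prev_r, span, alt)
            events.append(RawIndel(start=start, span=span, alt=alt))
        prev_r, prev_q = re, qe
    return events
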