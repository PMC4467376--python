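"""Genome-wide guide off-target scanning and recurrence screens.

A guide's 20-nt protospacer is matched against every genomic window on
both strands within a Hamming-distance budget (the screen used to verify
that a non-targeting control guide has no near matches, and that tumour
deletions map only to the intended target). Deletion calls are then
partitioned by proximity of their breakpoints to guide matches, and two
recurrence screens flag suspicious loci: loci mutated in every tumour
sample, and loci where one sample carries two or more distinct deletions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pairwise import revcomp
from .wgs import DeletionEvent

PROTOSPACER_LEN = 20


@dataclass(frozen=True)
class GuideRNA:
    name: str
    protospacer: str
    pam: str = "NGG"

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"guide {self.name!r}: protospacer must be {PROTOSPACER_LEN} nt")
        if set(self.protospacer) - set("ACGT"):
            raise ValueError(f"guide {self.name!r}: protospacer must be A/C/G/T")


@dataclass(frozen=True)
class GuideHit:
    """A genomic window matching the protospacer within the mismatch budget.

    ``pos`` is the 0-based start of the 20-mer on the plus strand and
    ``matched_seq`` the plus-strand window; for minus-strand hits the
    mismatch count is against the reverse complement of ``matched_seq``.
    """

    chrom: str
    pos: int
    strand: str
    mismatches: int
    matched_seq: str


def _mismatch_profile(genome: np.ndarray, pattern: str) -> np.ndarray:
    """mismatches[i] = Hamming distance of genome[i:i+20] vs pattern.

    Any non-ACGT genome base (e.g. N) differs from every pattern base, so
    windows containing N never reach a small budget.
    """
    k = len(pattern)
    n = len(genome) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    mism = np.zeros(n, dtype=np.int32)
    for j in range(k):
        mism += genome[j:j + n] != pat[j]
    return mism


def _pam_ok(genome_seq: str, pos: int, strand: str, pam: str) -> bool:
    k = PROTOSPACER_LEN
    if strand == "+":
        site = genome_seq[pos + k: pos + k + len(pam)]
    else:
        site = revcomp(genome_seq[pos - len(pam): pos]) if pos >= len(pam) else ""
    if len(site) != len(pam):
        return False
    return all(p == "N" or p == b for p, b in zip(pam, site))


def scan_genome(
    guide: GuideRNA,
    genome: Mapping[str, str],
    max_mm: int = 3,
    require_pam: bool = False,
) -> list[GuideHit]:
    """Find every window within ``max_mm`` mismatches of the protospacer.

    Both strands are scanned; hits are reported once each and sorted by
    (chrom, pos, strand). ``genome`` maps chromosome name to sequence
    (pyfaidx.Fasta works via its string access). The PAM constraint (NGG
    3' of the protospacer) is applied only when ``require_pam`` is set,
    matching scanners that search the bare 20-mer.
    """
    hits: list[GuideHit] = []
    for chrom in genome:
        seq = str(genome[chrom]).upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand, pattern in (("+", guide.protospacer),
                                ("-", revcomp(guide.protospacer))):
            mism = _mismatch_profile(arr, pattern)
            for pos in np.flatnonzero(mism <= max_mm):
                pos = int(pos)
                if require_pam and not _pam_ok(seq, pos, strand, guide.pam):
                    continue
                hits.append(GuideHit(
                    chrom=str(chrom), pos=pos, strand=strand,
                    mismatches=int(mism[pos]),
                    matched_seq=seq[pos:pos + PROTOSPACER_LEN]))
    hits.sort(key=lambda h: (h.chrom, h.pos, h.strand))
    return hits


# ---------------------------------------------------------------------------
# matching deletions to guide sites
# ---------------------------------------------------------------------------


@dataclass
class GuideMatchPartition:
    on_target: list[DeletionEvent]
    off_target_matched: list[DeletionEvent]
    unmatched: list[DeletionEvent]


def match_deletions_to_guide(
    events: Sequence[DeletionEvent],
    guide: GuideRNA,
    genome: Mapping[str, str],
    on_target: tuple[str, int, int],
    max_mm: int = 3,
    window: int = 30,
    require_pam: bool = False,
) -> GuideMatchPartition:
    """Partition deletions by whether a guide match lies near a breakpoint.

    An event is guide-matched iff some hit (within ``max_mm`` mismatches)
    starts within ``+/- window`` of either breakpoint. Matched events
    overlapping the declared on-target interval are ``on_target``; other
    matched events are ``off_target_matched``; the rest ``unmatched``.
    """
    hits = scan_genome(guide, genome, max_mm=max_mm, require_pam=require_pam)
    by_chrom: dict[str, np.ndarray] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h.pos)  # type: ignore[arg-type]
    by_chrom = {c: np.asarray(sorted(p)) for c, p in by_chrom.items()}

    def near_hit(chrom: str, bp: int) -> bool:
        pos = by_chrom.get(chrom)
        if pos is None:
            return False
        i = np.searchsorted(pos, bp - window)
        return i < len(pos) and pos[i] <= bp + window

    ot_chrom, ot_start, ot_end = on_target
    part = GuideMatchPartition([], [], [])
    for ev in events:
        matched = near_hit(ev.chrom, ev.start) or near_hit(ev.chrom, ev.end)
        if not matched:
            part.unmatched.append(ev)
        elif ev.chrom == ot_chrom and ev.start < ot_end and ev.end > ot_start:
            part.on_target.append(ev)
        else:
            part.off_target_matched.append(ev)
    return part


# ---------------------------------------------------------------------------
# recurrence screens
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusCluster:
    chrom: str
    start: int
    end: int
    members: tuple[tuple[str, DeletionEvent], ...]

    @property
    def n_samples(self) -> int:
        return len({s for s, _ in self.members})

    @property
    def n_distinct_deletions_per_sample(self) -> dict[str, int]:
        per: dict[str, set[tuple[int, int]]] = defaultdict(set)
        for sample, ev in self.members:
            per[sample].add((ev.start, ev.end))
        return {s: len(v) for s, v in per.items()}


def cluster_loci(
    events_by_sample: Mapping[str, Sequence[DeletionEvent]],
    pad: int = 5,
) -> list[LocusCluster]:
    """Merge events whose padded intervals overlap, transitively, into loci."""
    items: list[tuple[str, int, int, str, DeletionEvent]] = []
    for sample, events in events_by_sample.items():
        for ev in events:
            items.append((ev.chrom, ev.start - pad, ev.end + pad, sample, ev))
    items.sort(key=lambda t: (t[0], t[1], t[2]))
    clusters: list[LocusCluster] = []
    cur: list[tuple[str, DeletionEvent]] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for chrom, start, end, sample, ev in items:
        if cur and chrom == cur_chrom and start <= cur_end:
            cur_end = max(cur_end, end)
            cur.append((sample, ev))
        else:
            if cur:
                clusters.append(LocusCluster(cur_chrom, cur_start + pad,
                                             cur_end - pad, tuple(cur)))
            cur_chrom, cur_start, cur_end = chrom, start, end
            cur = [(sample, ev)]
    if cur:
        clusters.append(LocusCluster(cur_chrom, cur_start + pad,
                                     cur_end - pad, tuple(cur)))
    return clusters


def recurrent_loci(
    clusters: Iterable[LocusCluster],
    all_samples: Sequence[str],
) -> list[LocusCluster]:
    """Loci carrying at least one event from every tumour sample."""
    required = set(all_samples)
    if len(required) < 2:
        raise ValueError("recurrence screen requires at least two samples")
    return [c for c in clusters
            if required <= {s for s, _ in c.members}]


def multi_deletion_loci(clusters: Iterable[LocusCluster]) -> list[LocusCluster]:
    """Loci where some single sample contributes >= 2 distinct deletions."""
    return [c for c in clusters
            if any(n >= 2 for n in c.n_distinct_deletions_per_sample.values())]
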