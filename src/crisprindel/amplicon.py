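"""Indel calling from paired-end amplicon deep sequencing.

The target locus is amplified with several staggered primer pairs that all
cover the nuclease cut site, and each product is sequenced 251 bp paired-end
at very high depth. The caller follows a demultiplex -> merge -> collapse ->
annotate -> threshold procedure:

1. read pairs are assigned to amplicons by exact primer prefixes on both
   ends (no mismatches; both read orientations accepted);
2. mates are merged into the sequenced fragment by overlap consensus;
3. identical fragments are combined and rare fragments (count below a
   cutoff, default 100) removed; per (amplicon, fragment length) only the
   most frequent sequence is kept as the predominant sequence;
4. each non-reference fragment is globally aligned to the amplicon
   reference and its gap runs annotated as indels in locus coordinates,
   with the signed length convention
   ``length = affected reference length - alternative length``;
5. an indel is called if it is supported at >= 0.5% of merged reads in at
   least two different amplicons (both thresholds configurable).

A clonality summary reports how many distinct indels were called and how
the called read mass concentrates on the top clones.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pairwise import AlignScoring, RawIndel, extract_indels, merge_pair, revcomp

logger = logging.getLogger(__name__)

_DNA = set("ACGT")


class PanelError(ValueError):
    """Raised for an inconsistent amplicon panel."""


@dataclass(frozen=True)
class Amplicon:
    """One staggered PCR product over the target locus.

    ``ref_seq`` is the full expected product in forward orientation; it
    begins with the forward primer and ends with the reverse complement of
    the reverse primer. ``ref_offset`` places the product on the locus
    (0-based start of ``ref_seq``).
    """

    name: str
    fwd_primer: str
    rev_primer: str
    ref_seq: str
    ref_offset: int

    def __post_init__(self) -> None:
        for primer in (self.fwd_primer, self.rev_primer):
            if not primer or set(primer) - _DNA:
                raise PanelError(
                    f"amplicon {self.name!r}: primers must be non-empty A/C/G/T")
        if not self.ref_seq.startswith(self.fwd_primer):
            raise PanelError(
                f"amplicon {self.name!r}: ref_seq does not start with fwd_primer")
        if not self.ref_seq.endswith(revcomp(self.rev_primer)):
            raise PanelError(
                f"amplicon {self.name!r}: ref_seq does not end with "
                "reverse-complemented rev_primer")
        if self.ref_offset < 0:
            raise PanelError(f"amplicon {self.name!r}: ref_offset must be >= 0")

    @property
    def end_offset(self) -> int:
        return self.ref_offset + len(self.ref_seq)


@dataclass(frozen=True)
class MergedFragment:
    """A distinct merged fragment sequence with its read count."""

    seq: str
    count: int
    amplicon: str


@dataclass(frozen=True)
class IndelCall:
    """A called indel with its per-amplicon read support.

    Coordinates are 0-based on the locus; ``length = ref_span - len(alt_seq)``
    (positive = deletion, negative = insertion).
    """

    ref_start: int
    ref_span: int
    alt_seq: str
    amplicon_set: frozenset[str]
    read_fraction: Mapping[str, float]

    @property
    def length(self) -> int:
        return self.ref_span - len(self.alt_seq)

    @property
    def max_fraction(self) -> float:
        return max(self.read_fraction.values())

    @property
    def mean_fraction(self) -> float:
        """Mean fraction across the supporting amplicons."""
        vals = [self.read_fraction[a] for a in self.amplicon_set]
        return sum(vals) / len(vals)


@dataclass(frozen=True)
class CallerConfig:
    min_fragment_count: int = 100     # fragments occurring below this are removed
    min_fraction: float = 0.005       # per-amplicon read fraction to support a call
    min_amplicons: int = 2            # amplicons that must independently support
    min_indel_len_for_clonality: int = 1   # clonality counts |length| strictly above
    min_merge_overlap: int = 10
    max_merge_mismatch_frac: float = 0.1
    scoring: AlignScoring = field(default_factory=AlignScoring)
    # "per_amplicon": min_fraction must hold in each supporting amplicon;
    # "overall": pooled fraction across amplicons must reach min_fraction.
    fraction_mode: str = "per_amplicon"
    # denominator for read fractions: merged reads before ("pre") or after
    # ("post") the rare-fragment filter.
    denominator: str = "pre"

    def __post_init__(self) -> None:
        if not (0 < self.min_fraction < 1):
            raise ValueError("min_fraction must lie in (0, 1)")
        if min(self.min_fragment_count, self.min_amplicons,
               self.min_merge_overlap) < 0 or self.max_merge_mismatch_frac < 0:
            raise ValueError("thresholds must be non-negative")
        if self.fraction_mode not in ("per_amplicon", "overall"):
            raise ValueError("fraction_mode must be 'per_amplicon' or 'overall'")
        if self.denominator not in ("pre", "post"):
            raise ValueError("denominator must be 'pre' or 'post'")


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

ReadPair = tuple[tuple[str, str, str], tuple[str, str, str]]  # (name, seq, qual) x2


def _validate_panel(amplicons: Sequence[Amplicon]) -> None:
    pairs = Counter((a.fwd_primer, a.rev_primer) for a in amplicons)
    dup = [p for p, n in pairs.items() if n > 1]
    if dup:
        raise PanelError(f"two amplicons share an identical primer pair: {dup[0]}")


def demultiplex_reads(
    read_pairs: Iterable[ReadPair],
    amplicons: Sequence[Amplicon],
) -> tuple[dict[str, list[ReadPair]], int]:
    """Assign read pairs to amplicons by exact primer prefixes.

    A pair goes to amplicon A iff read1 starts with A.fwd_primer and read2
    with A.rev_primer, or the swapped orientation; in the swapped case the
    reads are flipped so the stored pair is always (forward-read,
    reverse-read). Unassignable pairs are only counted.
    """
    _validate_panel(amplicons)
    assigned: dict[str, list[ReadPair]] = {a.name: [] for a in amplicons}
    unassigned = 0
    for pair in read_pairs:
        (n1, s1, q1), (n2, s2, q2) = pair
        for amp in amplicons:
            if s1.startswith(amp.fwd_primer) and s2.startswith(amp.rev_primer):
                assigned[amp.name].append(pair)
                break
            if s1.startswith(amp.rev_primer) and s2.startswith(amp.fwd_primer):
                assigned[amp.name].append(((n2, s2, q2), (n1, s1, q1)))
                break
        else:
            unassigned += 1
    return assigned, unassigned


# ---------------------------------------------------------------------------
# merge + collapse
# ---------------------------------------------------------------------------


def merge_pairs(
    pairs: Iterable[ReadPair],
    config: CallerConfig = CallerConfig(),
) -> tuple[list[str], int]:
    """Merge demultiplexed pairs; returns (merged sequences, n_failures).

    Results are memoised on the raw read strings, which makes deep amplicon
    data (many identical pairs) cheap to merge.
    """
    cache: dict[tuple[str, str, str, str], str | None] = {}
    merged: list[str] = []
    failures = 0
    for (_, s1, q1), (_, s2, q2) in pairs:
        key = (s1, q1, s2, q2)
        if key not in cache:
            res = merge_pair(s1, q1, s2, q2,
                             min_overlap=config.min_merge_overlap,
                             max_mismatch_frac=config.max_merge_mismatch_frac)
            cache[key] = res.seq if res is not None else None
        seq = cache[key]
        if seq is None:
            failures += 1
        else:
            merged.append(seq)
    return merged, failures


def collapse_fragments(
    merged: Iterable[tuple[str, str]],
    config: CallerConfig = CallerConfig(),
) -> list[MergedFragment]:
    """Combine identical (amplicon, sequence) fragments and drop rare ones.

    Fragments occurring strictly fewer than ``min_fragment_count`` times are
    removed (a count equal to the cutoff is retained). Output is sorted by
    descending count, then amplicon, then sequence, for determinism.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for amp, seq in merged:
        counts[(amp, seq)] += 1
    frags = [
        MergedFragment(seq=seq, count=n, amplicon=amp)
        for (amp, seq), n in counts.items()
        if n >= config.min_fragment_count
    ]
    frags.sort(key=lambda f: (-f.count, f.amplicon, f.seq))
    return frags


def select_predominant_per_length(
    fragments: Sequence[MergedFragment],
) -> tuple[list[MergedFragment], int]:
    """Keep only the most frequent fragment per (amplicon, length).

    Ties on count are broken towards the lexicographically smallest
    sequence. Returns (retained fragments, total discarded read count).
    """
    groups: dict[tuple[str, int], MergedFragment] = {}
    discarded = 0
    for frag in fragments:
        key = (frag.amplicon, len(frag.seq))
        best = groups.get(key)
        if best is None:
            groups[key] = frag
        elif (frag.count, [best.seq]) > (best.count, [frag.seq]):
            discarded += best.count
            groups[key] = frag
        else:
            discarded += frag.count
    retained = sorted(groups.values(), key=lambda f: (-f.count, f.amplicon, f.seq))
    return retained, discarded


# ---------------------------------------------------------------------------
# annotation + calling
# ---------------------------------------------------------------------------


class AnnotationError(ValueError):
    pass


def annotate_indels(
    fragment: MergedFragment,
    amplicon: Amplicon,
    config: CallerConfig = CallerConfig(),
) -> list[RawIndel]:
    """Align a fragment to its amplicon reference and annotate its indels.

    Returned coordinates are on the locus (``amplicon.ref_offset`` added).
    A reference-identical fragment yields an empty list.
    """
    if len(fragment.seq) < len(amplicon.fwd_primer) + len(amplicon.rev_primer):
        raise AnnotationError(
            f"fragment in amplicon {amplicon.name!r} shorter than its two primers")
    local = extract_indels(amplicon.ref_seq, fragment.seq, config.scoring)
    return [
        RawIndel(start=amplicon.ref_offset + ev.start, span=ev.span, alt=ev.alt)
        for ev in local
    ]


def call_indels(
    per_amplicon_fragments: Mapping[str, Sequence[MergedFragment]],
    amplicons: Sequence[Amplicon],
    config: CallerConfig = CallerConfig(),
    merged_totals: Mapping[str, int] | None = None,
) -> list[IndelCall]:
    """Merge per-amplicon indel annotations and apply the calling thresholds.

    ``merged_totals`` gives the per-amplicon merged read count used as the
    fraction denominator (the count before the rare-fragment filter); if
    omitted, the sum of the supplied fragment counts is used, which equals
    the post-filter denominator.
    """
    amp_by_name = {a.name: a for a in amplicons}
    totals: dict[str, int] = {}
    for amp, frags in per_amplicon_fragments.items():
        post = sum(f.count for f in frags)
        if merged_totals is not None and config.denominator == "pre":
            totals[amp] = merged_totals.get(amp, post)
        else:
            totals[amp] = post
    live = {a for a, t in totals.items() if t > 0}
    for amp, t in totals.items():
        if t == 0:
            logger.warning("amplicon %s has zero merged reads; excluded", amp)

    # (ref_start, ref_span, alt) -> amplicon -> supporting read count
    support: dict[tuple[int, int, str], dict[str, int]] = defaultdict(
        lambda: defaultdict(int))
    for amp, frags in per_amplicon_fragments.items():
        if amp not in live:
            continue
        for frag in frags:
            for ev in annotate_indels(frag, amp_by_name[amp], config):
                support[(ev.start, ev.span, ev.alt)][amp] += frag.count

    calls: list[IndelCall] = []
    for (start, span, alt), amp_counts in support.items():
        fractions = {a: c / totals[a] for a, c in amp_counts.items()}
        if config.fraction_mode == "per_amplicon":
            passing = {a for a, f in fractions.items() if f >= config.min_fraction}
        else:
            pooled = sum(amp_counts.values()) / sum(totals[a] for a in amp_counts)
            passing = set(fractions) if pooled >= config.min_fraction else set()
        if len(passing) >= config.min_amplicons:
            calls.append(IndelCall(
                ref_start=start, ref_span=span, alt_seq=alt,
                amplicon_set=frozenset(passing),
                read_fraction=dict(sorted(fractions.items())),
            ))
    calls.sort(key=lambda c: (-c.max_fraction, c.ref_start, c.ref_span, c.alt_seq))
    return calls


# ---------------------------------------------------------------------------
# clonality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClonalitySummary:
    """Distinct-indel count and read-mass concentration for one sample.

    ``top_k_read_share[k]`` is the called read mass (mean-across-amplicon
    fractions) of the k most frequent indels divided by the total mass of
    all called indels; None when there are no calls.
    """

    n_distinct_indels: int
    top_k_read_share: Mapping[int, float] | None


def clonality_summary(
    calls: Sequence[IndelCall],
    config: CallerConfig = CallerConfig(),
    max_k: int = 5,
) -> ClonalitySummary:
    counted = [c for c in calls
               if abs(c.length) > config.min_indel_len_for_clonality]
    if not calls:
        return ClonalitySummary(n_distinct_indels=0, top_k_read_share=None)
    masses = sorted((c.mean_fraction for c in calls), reverse=True)
    total = sum(masses)
    shares = {}
    running = 0.0
    for k in range(1, max_k + 1):
        running += masses[k - 1] if k <= len(masses) else 0.0
        shares[k] = running / total
    return ClonalitySummary(n_distinct_indels=len(counted), top_k_read_share=shares)


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------


@dataclass
class AmpliconResult:
    """End-to-end result for one sample."""

    n_pairs: int
    n_unassigned: int
    n_merge_failures: int
    merged_totals: dict[str, int]
    fragments: list[MergedFragment]
    calls: list[IndelCall]
    clonality: ClonalitySummary


def run_amplicon_pipeline(
    read_pairs: Iterable[ReadPair],
    amplicons: Sequence[Amplicon],
    config: CallerConfig = CallerConfig(),
) -> AmpliconResult:
    """Demultiplex, merge, collapse, annotate and call one sample."""
    pairs = list(read_pairs)
    assigned, unassigned = demultiplex_reads(pairs, amplicons)
    merged_by_amp: dict[str, list[str]] = {}
    failures = 0
    for amp, amp_pairs in assigned.items():
        merged, failed = merge_pairs(amp_pairs, config)
        merged_by_amp[amp] = merged
        failures += failed
    totals = {amp: len(seqs) for amp, seqs in merged_by_amp.items()}
    flat = [(amp, seq) for amp, seqs in merged_by_amp.items() for seq in seqs]
    fragments = collapse_fragments(flat, config)
    fragments, _ = select_predominant_per_length(fragments)
    per_amp: dict[str, list[MergedFragment]] = defaultdict(list)
    for frag in fragments:
        per_amp[frag.amplicon].append(frag)
    calls = call_indels(per_amp, amplicons, config, merged_totals=totals)
    return AmpliconResult(
        n_pairs=len(pairs),
        n_unassigned=unassigned,
        n_merge_failures=failures,
        merged_totals=totals,
        fragments=fragments,
        calls=calls,
        clonality=clonality_summary(calls, config),
    )
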