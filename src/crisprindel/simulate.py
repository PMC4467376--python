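"""Ground-truthed simulation of polyclonal CRISPR-edited tumour sequencing.

The generator emulates the two sequencing layers of a somatic-editing
experiment on a surrogate target locus (random DNA with a real guide
protospacer planted at the cut site):

* a polyclonal population of edited alleles — a few predominant clones plus
  a long tail of rare ones, deletions from 1 bp up to multi-kb, insertions
  under 10 bp, all straddling the cut site — with explicit frequencies and
  a wild-type remainder;
* 251 bp paired-end amplicon reads over a panel of staggered PCR products
  (clone-proportional multinomial sampling, uniform substitution errors,
  alleles that lose a primer site yield no product);
* 101 bp paired-end WGS alignment records with correct CIGAR strings —
  deletions appear as ``xM nD yM`` when small enough for an aligner to
  represent in one record, and as split (primary + supplementary) segments
  when large — plus matched wild-type control samples and the annotation
  tracks the deletion filter cascade consumes.

Every simulated read traces back to exactly one clone in the truth table,
and a fixed seed reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .amplicon import Amplicon, ReadPair
from .known_sequences import GUIDES
from .pairwise import left_align_indel, revcomp
from .wgs import AlignmentSegment

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_CHROM = "chrLocus"

# Cas9 cuts between the 17th and 18th protospacer base (3 bp 5' of the PAM),
# so a protospacer planted at p puts the blunt cut at p + 17.
CUT_OFFSET_IN_PROTOSPACER = 17


@dataclass(frozen=True)
class CloneEdit:
    """One edited allele: delete [del_start, del_end) and insert insert_seq."""

    del_start: int
    del_end: int
    insert_seq: str = ""

    @property
    def length(self) -> int:
        return (self.del_end - self.del_start) - len(self.insert_seq)

    def canonical(self, locus_seq: str) -> tuple[int, int, str]:
        """Left-aligned (ref_start, ref_span, alt) identity on the locus."""
        return left_align_indel(locus_seq, self.del_start,
                                self.del_end - self.del_start, self.insert_seq)

    def apply(self, locus_seq: str) -> str:
        return (locus_seq[: self.del_start] + self.insert_seq
                + locus_seq[self.del_end:])


@dataclass(frozen=True)
class Clone:
    name: str
    edit: CloneEdit
    frequency: float


@dataclass
class ClonePopulation:
    """The generative ground truth: a locus and its edited-allele mixture."""

    locus_seq: str
    cut_pos: int
    clones: list[Clone]
    chrom: str = DEFAULT_CHROM

    def __post_init__(self) -> None:
        total = sum(c.frequency for c in self.clones)
        if any(c.frequency < 0 for c in self.clones) or total > 1 + 1e-9:
            raise ValueError("clone frequencies must be >= 0 and sum to <= 1")

    @property
    def wt_fraction(self) -> float:
        return max(0.0, 1.0 - sum(c.frequency for c in self.clones))

    def allele_seq(self, clone: Clone) -> str:
        return clone.edit.apply(self.locus_seq)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_pairs_per_amplicon: int = 50_000
    read_len: int = 251
    wgs_read_len: int = 101
    wgs_depth: float = 23.3
    error_rate: float = 0.001
    n_background_clones: int = 20
    control: bool = False
    insert_mean: float = 320.0
    insert_sd: float = 30.0
    duplicate_rate: float = 0.0
    # deletions up to this size are representable in one CIGAR; larger ones
    # are emitted as split alignments, as a short-read aligner would.
    split_threshold: int = 100
    quality_char: str = "F"          # Q37


# ---------------------------------------------------------------------------
# locus + panel construction
# ---------------------------------------------------------------------------


def make_locus(
    length: int = 3000,
    cut_pos: int | None = None,
    seed: int = 0,
    protospacer: str = GUIDES["Ptch1.1"],
    rng: np.random.Generator | None = None,
) -> tuple[str, int]:
    """A random surrogate locus with ``protospacer`` + NGG planted at the cut.

    Returns (locus sequence, cut position). The protospacer occupies
    ``[cut-17, cut+3)`` with a TGG PAM immediately 3' of it.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if cut_pos is None:
        cut_pos = length // 2
    seq = rng.choice(BASES, size=length).tobytes().decode()
    p = cut_pos - CUT_OFFSET_IN_PROTOSPACER
    if p < 0 or p + len(protospacer) + 3 > length:
        raise ValueError("cut_pos leaves no room for the protospacer + PAM")
    seq = seq[:p] + protospacer + "TGG" + seq[p + len(protospacer) + 3:]
    return seq, cut_pos


def make_panel(
    locus_seq: str,
    cut_pos: int,
    n_amplicons: int = 5,
    amp_len: int = 400,
    primer_len: int = 20,
    stagger: int = 25,
    name_prefix: str = "amp",
) -> list[Amplicon]:
    """A panel of consecutively shifted amplicons all covering the cut site.

    Primers are taken from the locus itself (the surrogate locus is random,
    so locus-derived primers play the role the published primer pairs play
    on the real locus).
    """
    first = cut_pos - amp_len // 2 - stagger * (n_amplicons // 2)
    panel = []
    for i in range(n_amplicons):
        start = first + i * stagger
        end = start + amp_len
        if start < 0 or end > len(locus_seq):
            raise ValueError("amplicon extends beyond the locus")
        ref = locus_seq[start:end]
        panel.append(Amplicon(
            name=f"{name_prefix}{i + 1}",
            fwd_primer=ref[:primer_len],
            rev_primer=revcomp(ref[-primer_len:]),
            ref_seq=ref,
            ref_offset=start,
        ))
    return panel


# ---------------------------------------------------------------------------
# clone spectrum
# ---------------------------------------------------------------------------


def _draw_edit(
    rng: np.random.Generator,
    locus_len: int,
    cut_pos: int,
    size_range: tuple[int, int] | None = None,
) -> CloneEdit:
    """One random edit straddling the cut site.

    Background deletion sizes mix small (1-30 bp), medium (31-500 bp) and
    large (501-2500 bp) events; a quarter of background clones are short
    insertions (1-9 bp) at the cut instead, matching the observation that
    induced insertions stay below 10 bp while deletions reach multi-kb.
    """
    if size_range is None:
        u = rng.random()
        if u < 0.25:
            ins_len = int(rng.integers(1, 10))
            ins = rng.choice(BASES, size=ins_len).tobytes().decode()
            return CloneEdit(del_start=cut_pos, del_end=cut_pos, insert_seq=ins)
        u = rng.random()
        if u < 0.6:
            size = int(rng.integers(1, 31))
        elif u < 0.9:
            size = int(rng.integers(31, 501))
        else:
            size = int(rng.integers(501, 2501))
    else:
        size = int(rng.integers(size_range[0], size_range[1] + 1))
    start = cut_pos - int(rng.integers(0, size))
    start = max(1, min(start, locus_len - size - 1))
    return CloneEdit(del_start=start, del_end=start + size)


def simulate_clones(
    locus_seq: str,
    cut_pos: int,
    major_freqs: Sequence[float] = (0.45, 0.27, 0.18),
    n_background: int = 20,
    tail_mass: float = 0.10,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    major_size_range: tuple[int, int] = (5, 40),
) -> ClonePopulation:
    """A polyclonal population: few predominant clones plus a rare tail.

    ``major_freqs`` are the absolute frequencies of the predominant clones;
    ``tail_mass`` is shared equally by ``n_background`` rare clones; the
    remainder (>= 0) is wild type. All edits overlap the cut site and have
    distinct left-aligned identities.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    total = sum(major_freqs) + (tail_mass if n_background else 0.0)
    if total > 1 + 1e-9:
        raise ValueError(f"clone frequencies sum to {total:.3f} > 1")
    clones: list[Clone] = []
    seen: set[tuple[int, int, str]] = set()

    def add(name: str, freq: float, size_range: tuple[int, int] | None) -> None:
        for _ in range(100):
            edit = _draw_edit(rng, len(locus_seq), cut_pos, size_range)
            key = edit.canonical(locus_seq)
            if key not in seen:
                seen.add(key)
                clones.append(Clone(name=name, edit=edit, frequency=freq))
                return
        raise RuntimeError("could not draw a distinct clone edit")

    for i, freq in enumerate(major_freqs):
        add(f"clone{i + 1}", freq, major_size_range)
    for i in range(n_background):
        add(f"bg{i + 1}", tail_mass / n_background if n_background else 0.0, None)
    return ClonePopulation(locus_seq=locus_seq, cut_pos=cut_pos, clones=clones)


def biallelic_ko_population(
    locus_seq: str,
    cut_pos: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ClonePopulation:
    """Both alleles disrupted: two frameshift clones at 0.5 each, no WT."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    pop = simulate_clones(locus_seq, cut_pos, major_freqs=(0.5, 0.5),
                          n_background=0, tail_mass=0.0, rng=rng)
    return pop


def control_population(locus_seq: str, cut_pos: int,
                       polymorphic_edits: Sequence[CloneEdit] = (),
                       frequency: float = 0.5) -> ClonePopulation:
    """An unedited sample: pure WT plus optional heterozygous germline
    (polymorphic) deletions shared with the polymorphic track."""
    clones = [Clone(name=f"poly{i + 1}", edit=e, frequency=frequency)
              for i, e in enumerate(polymorphic_edits)]
    return ClonePopulation(locus_seq=locus_seq, cut_pos=cut_pos, clones=clones)


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------


def _amplicon_product(amplicon: Amplicon, edit: CloneEdit | None) -> str | None:
    """The PCR product of one allele, or None if a primer site is disrupted."""
    a0, a1 = amplicon.ref_offset, amplicon.end_offset
    ref = amplicon.ref_seq
    if edit is None:
        return ref
    fwd_site = (a0, a0 + len(amplicon.fwd_primer))
    rev_site = (a1 - len(amplicon.rev_primer), a1)
    ds, de = edit.del_start, edit.del_end
    touches = lambda lo, hi: ds < hi and de > lo if de > ds else lo <= ds < hi
    if touches(*fwd_site) or touches(*rev_site):
        return None
    if de <= a0 or ds >= a1:
        return ref
    # edit interior to the product
    return ref[: ds - a0] + edit.insert_seq + ref[de - a0:]


def _apply_errors(reads: list[bytearray], rng: np.random.Generator,
                  error_rate: float) -> None:
    if not reads or error_rate <= 0:
        return
    lengths = np.array([len(r) for r in reads])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    k = rng.binomial(total, error_rate)
    if k == 0:
        return
    flat = np.sort(rng.choice(total, size=min(k, total), replace=False))
    rows = np.searchsorted(offsets, flat, side="right") - 1
    subs = rng.integers(1, 4, size=len(flat))
    for pos, row, shift in zip(flat, rows, subs):
        col = int(pos - offsets[row])
        read = reads[row]
        old = BASES.tobytes().index(read[col]) if read[col] in BASES.tobytes() else 0
        read[col] = BASES[(old + int(shift)) % 4]


def _exact_survival(product_len: int, config: SimConfig,
                    amplicon: Amplicon) -> float:
    """Probability that a merged fragment reproduces its product exactly.

    Conditioned on demultiplexing (both primer prefixes error-free), a
    merged position is wrong iff the read whose base the consensus keeps
    carried an error there: the forward read everywhere it reaches, the
    reverse read beyond it. That leaves ``min(read_len, L) - |fwd primer|``
    forward-sourced and ``max(0, L - |rev primer| - read_len)``
    reverse-sourced error-prone positions.
    """
    fwd_len = len(amplicon.fwd_primer)
    rev_len = len(amplicon.rev_primer)
    exposed = (min(config.read_len, product_len) - fwd_len
               + max(0, product_len - rev_len - config.read_len))
    return (1.0 - config.error_rate) ** max(exposed, 0)


def simulate_amplicon_reads(
    pop: ClonePopulation,
    panel: Sequence[Amplicon],
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw clone-proportional paired amplicon reads plus the truth table.

    For each amplicon, alleles whose edit removes a primer site yield no
    product; reads are multinomially distributed over the remaining alleles
    (frequencies renormalised, which is what PCR on the surviving templates
    does). The truth table records each clone's left-aligned indel identity
    and, per amplicon, two expectations: ``expected_frac_<amp>``, the
    clone's share of sequenced read pairs (0 where the product is lost),
    and ``expected_called_frac_<amp>``, the share of merged reads whose
    sequence survives exactly — i.e. ``expected_frac`` times the
    probability that no substitution error persists through the overlap
    consensus — which is what the fragment-counting caller estimates.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    alleles: list[tuple[str, CloneEdit | None, float]] = [
        (c.name, c.edit, c.frequency) for c in pop.clones]
    alleles.append(("WT", None, pop.wt_fraction))

    truth_rows = []
    for name, edit, freq in alleles:
        if edit is not None:
            start, span, alt = edit.canonical(pop.locus_seq)
            row = {"clone": name, "frequency": freq, "ref_start": start,
                   "ref_span": span, "alt_seq": alt, "length": span - len(alt)}
        else:
            row = {"clone": name, "frequency": freq, "ref_start": -1,
                   "ref_span": 0, "alt_seq": "", "length": 0}
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    pairs: list[ReadPair] = []
    for amplicon in panel:
        if amplicon.ref_offset < 0 or amplicon.end_offset > len(pop.locus_seq):
            raise ValueError(f"amplicon {amplicon.name} absent from locus")
        products = [_amplicon_product(amplicon, edit) for _, edit, _ in alleles]
        mass = [f if p is not None else 0.0
                for (_, _, f), p in zip(alleles, products)]
        denom = sum(mass)
        fracs = [m / denom if denom > 0 else 0.0 for m in mass]
        truth[f"expected_frac_{amplicon.name}"] = fracs
        truth[f"expected_called_frac_{amplicon.name}"] = [
            frac * _exact_survival(len(product), config, amplicon)
            if product is not None else 0.0
            for frac, product in zip(fracs, products)]
        if denom == 0:
            continue
        counts = rng.multinomial(config.n_pairs_per_amplicon,
                                 np.asarray(mass) / denom)
        serial = 0
        for (name, _, _), product, n in zip(alleles, products, counts):
            if n == 0:
                continue
            f_tmpl = product[: config.read_len]
            r_tmpl = revcomp(product)[: config.read_len]
            f_reads = [bytearray(f_tmpl.encode()) for _ in range(n)]
            r_reads = [bytearray(r_tmpl.encode()) for _ in range(n)]
            _apply_errors(f_reads, rng, config.error_rate)
            _apply_errors(r_reads, rng, config.error_rate)
            for fr, rr in zip(f_reads, r_reads):
                rid = f"sim:{amplicon.name}:{serial}"
                serial += 1
                pairs.append(((rid, fr.decode(), config.quality_char * len(fr)),
                              (rid, rr.decode(), config.quality_char * len(rr))))
    return pairs, truth


# ---------------------------------------------------------------------------
# WGS alignment records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamRecord:
    """One SAM line worth of information (segment + sequence + pairing)."""

    segment: AlignmentSegment
    seq: str
    flag: int
    mate_pos: int
    tlen: int


def _map_read_to_segments(
    read_id: str,
    allele_start: int,
    read_len: int,
    strand: str,
    edit: CloneEdit | None,
    locus_len: int,
    split_threshold: int,
    template_key: tuple,
) -> list[AlignmentSegment]:
    """Reference alignment segments for a read drawn from an edited allele."""
    s, e = allele_start, allele_start + read_len
    if edit is None:
        return [AlignmentSegment(read_id=read_id, chrom=DEFAULT_CHROM, pos=s,
                                 cigar=(("M", read_len),), strand=strand,
                                 template_key=template_key)]
    ds, de, ins = edit.del_start, edit.del_end, edit.insert_seq
    ins_len = len(ins)
    del_size = de - ds
    shift = del_size - ins_len

    def common(pos: int, cigar: tuple, supplementary: bool = False) -> AlignmentSegment:
        return AlignmentSegment(read_id=read_id, chrom=DEFAULT_CHROM, pos=pos,
                                cigar=cigar, strand=strand,
                                is_supplementary=supplementary,
                                template_key=template_key)

    if e <= ds:
        return [common(s, (("M", read_len),))]
    if s >= ds + ins_len:
        return [common(s + shift, (("M", read_len),))]
    # the read touches the edited junction
    a = max(0, ds - s)                                   # left mapped flank
    i = min(e, ds + ins_len) - max(s, ds)                # inserted bases covered
    b = max(0, e - (ds + ins_len))                       # right mapped flank
    if a == 0:
        # starts inside the insertion: clip the inserted prefix
        cigar = ((("S", i),) if i else ()) + (("M", b),)
        return [common(de, cigar)]
    if b == 0:
        cigar = (("M", a),) + ((("S", i),) if i else ())
        return [common(s, cigar)]
    if del_size > split_threshold:
        # too large for one alignment: primary + supplementary split
        left = common(s, (("M", a),) + ((("I", i),) if i else ()) + (("S", b),))
        right = common(de, (("S", a + i), ("M", b)), supplementary=(b < a))
        if b >= a:
            left = dataclasses.replace(left, is_supplementary=True)
        return [left, right]
    cigar = (("M", a),)
    if i:
        cigar += (("I", i),)
    if del_size:
        cigar += (("D", del_size),)
    cigar += (("M", b),)
    return [common(s, cigar)]


def _read_seq(allele: str, start: int, length: int, strand: str) -> str:
    raw = allele[start: start + length]
    return revcomp(raw) if strand == "-" else raw


def simulate_wgs_alignments(
    pop: ClonePopulation,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
    sample: str = "tumour",
) -> tuple[list[SamRecord], list[tuple[str, int, int, str]]]:
    """Paired-end WGS alignment records plus the somatic-deletion truth.

    Templates are drawn clone-proportionally at ``wgs_depth`` mean coverage;
    each template yields a forward and a reverse 101 bp read mapped back to
    reference coordinates with correct CIGARs (split segments for deletions
    beyond ``split_threshold``). The truth lists every simulated somatic
    deletion as (chrom, start, end, clone); for a control sample
    (``config.control``) the truth is empty.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    locus_len = len(pop.locus_seq)
    read_len = config.wgs_read_len
    alleles: list[tuple[str, CloneEdit | None, float, str]] = [
        (c.name, c.edit, c.frequency, pop.allele_seq(c)) for c in pop.clones]
    alleles.append(("WT", None, pop.wt_fraction, pop.locus_seq))
    probs = np.array([a[2] for a in alleles])
    if probs.sum() <= 0:
        raise ValueError("population has zero total mass")
    probs = probs / probs.sum()

    n_templates = int(round(config.wgs_depth * locus_len / (2 * read_len)))
    records: list[SamRecord] = []
    if n_templates > 0:
        choices = rng.choice(len(alleles), size=n_templates, p=probs)
        for t, ai in enumerate(choices):
            name, edit, _, allele = alleles[ai]
            alen = len(allele)
            insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            insert = max(read_len + 10, min(insert, alen))
            tstart = int(rng.integers(0, alen - insert + 1))
            n_copies = 1 + (1 if rng.random() < config.duplicate_rate else 0)
            ends = ((tstart, "+"), (tstart + insert - read_len, "-"))
            for copy in range(n_copies):
                rid_base = f"{sample}:t{t}" + (f":dup{copy}" if copy else "")
                segs_per_end = []
                for mate, (astart, strand) in enumerate(ends, start=1):
                    segs = _map_read_to_segments(
                        f"{rid_base}/{mate}", astart, read_len, strand, edit,
                        locus_len, config.split_threshold,
                        template_key=None)
                    segs_per_end.append((astart, strand, segs))
                outer_lo = min(s.pos for _, _, segs in segs_per_end for s in segs)
                outer_hi = max(s.ref_end for _, _, segs in segs_per_end for s in segs)
                tkey = (pop.chrom, outer_lo, outer_hi - outer_lo)
                for (astart, strand, segs), mate_i in zip(segs_per_end, (1, 2)):
                    other = segs_per_end[1 - (mate_i - 1)][2][0]
                    for seg in segs:
                        seg = dataclasses.replace(seg, template_key=tkey,
                                                  mate_pos=other.pos)
                        flag = 0x1 | 0x2 | (0x40 if mate_i == 1 else 0x80)
                        if strand == "-":
                            flag |= 0x10
                        else:
                            flag |= 0x20
                        if seg.is_supplementary:
                            flag |= 0x800
                        tlen = (outer_hi - outer_lo) * (1 if mate_i == 1 else -1)
                        records.append(SamRecord(
                            segment=seg,
                            seq=_read_seq(allele, astart, read_len, strand),
                            flag=flag, mate_pos=other.pos, tlen=tlen))
    records.sort(key=lambda r: (r.segment.pos, r.segment.read_id))

    truth: list[tuple[str, int, int, str]] = []
    if not config.control:
        for c in pop.clones:
            if c.edit.del_end > c.edit.del_start:
                truth.append((pop.chrom, c.edit.del_start, c.edit.del_end, c.name))
    return records, truth


def write_sam(records: Sequence[SamRecord], path: str | Path,
              chrom: str = DEFAULT_CHROM, chrom_len: int = 3000,
              quality_char: str = "F") -> None:
    """Write simulated records as a coordinate-sorted SAM file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_len}\n")
        for rec in sorted(records, key=lambda r: (r.segment.pos, r.segment.read_id)):
            seg = rec.segment
            qname = seg.read_id.rsplit("/", 1)[0]
            cigar = "".join(f"{n}{op}" for op, n in seg.cigar)
            qual = quality_char * len(rec.seq)
            fh.write("\t".join([
                qname, str(rec.flag), seg.chrom, str(seg.pos + 1), "60",
                cigar, "=", str(rec.mate_pos + 1), str(rec.tlen),
                rec.seq, qual]) + "\n")


def write_fastq_pairs(pairs: Sequence[ReadPair], r1_path: str | Path,
                      r2_path: str | Path) -> None:
    with Path(r1_path).open("w") as f1, Path(r2_path).open("w") as f2:
        for (n1, s1, q1), (n2, s2, q2) in pairs:
            f1.write(f"@{n1}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{n2}/2\n{s2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------


def emit_tracks(
    pop: ClonePopulation,
    out_dir: str | Path,
    repeats: Iterable[tuple[int, int]] = (),
    polymorphic: Iterable[tuple[int, int]] = (),
) -> dict[str, Path]:
    """Write the surrogate genome FASTA plus repeat/polymorphic BED tracks.

    Both tracks may be empty; intervals are given on the locus and are the
    caller's responsibility to place (they are not moved away from the cut
    site unless the caller chooses so).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fa"
    with fasta.open("w") as fh:
        fh.write(f">{pop.chrom}\n")
        seq = pop.locus_seq
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")
    paths = {"genome": fasta}
    for name, ivs in (("repeats", repeats), ("polymorphic", polymorphic)):
        bed = out / f"{name}.bed"
        with bed.open("w") as fh:
            for start, end in ivs:
                fh.write(f"{pop.chrom}\t{start}\t{end}\t{name}\n")
        paths[name] = bed
    return paths
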