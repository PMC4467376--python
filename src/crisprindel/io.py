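"""File-format plumbing: FASTQ pairs, amplicon panels, BED tracks, and
TSV/VCF/JSON output of calls."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .amplicon import Amplicon, AmpliconResult, IndelCall, ReadPair
from .pairwise import revcomp
from .wgs import DeletionEvent


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open()


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    """Iterate paired FASTQ records from two (optionally gzipped) files."""
    with _open_text(r1) as f1, _open_text(r2) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError(
                    f"{r2}: fewer records than {r1} (pair {rec1[0]})") from None
            yield rec1, rec2
        if next(it2, None) is not None:
            raise ValueError(f"{r2}: more records than {r1}")


def read_interleaved_pairs(path: str | Path) -> Iterator[ReadPair]:
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        for rec1 in it:
            rec2 = next(it, None)
            if rec2 is None:
                raise ValueError(f"{path}: odd number of interleaved records")
            yield rec1, rec2


def read_panel(panel_tsv: str | Path, locus_fasta: str | Path) -> list[Amplicon]:
    """Load an amplicon panel from a TSV (name, fwd_primer, rev_primer,
    ref_offset) plus the locus FASTA.

    Each amplicon's reference sequence is cut out of the locus: it starts
    at ``ref_offset`` (which must begin with the forward primer) and ends
    at the first downstream occurrence of the reverse-complemented reverse
    primer.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(locus_fasta), as_raw=True)
    locus = str(fasta[list(fasta.keys())[0]][:]).upper()
    panel: list[Amplicon] = []
    with _open_text(panel_tsv) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            name, fwd, rev, off = line.split("\t")[:4]
            offset = int(off)
            site = revcomp(rev.upper())
            end = locus.find(site, offset + len(fwd))
            if end < 0:
                raise ValueError(f"amplicon {name}: reverse primer site not "
                                 "found on the locus")
            end += len(site)
            panel.append(Amplicon(name=name, fwd_primer=fwd.upper(),
                                  rev_primer=rev.upper(),
                                  ref_seq=locus[offset:end], ref_offset=offset))
    return panel


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    intervals = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return intervals


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_calls_tsv(calls: Sequence[IndelCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("amplicons\tref_start\tref_span\talt\tlength\tfractions\n")
        for c in calls:
            fracs = ",".join(f"{a}={c.read_fraction[a]:.6f}"
                             for a in sorted(c.read_fraction))
            fh.write(f"{','.join(sorted(c.amplicon_set))}\t{c.ref_start}\t"
                     f"{c.ref_span}\t{c.alt_seq or '-'}\t{c.length}\t{fracs}\n")


def write_calls_vcf(calls: Sequence[IndelCall], locus_seq: str, chrom: str,
                    path: str | Path) -> None:
    """Minimal VCF 4.2 with left-aligned, anchor-based indel records."""
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(locus_seq)}>\n")
        fh.write("##INFO=<ID=MAXFRAC,Number=1,Type=Float,"
                 'Description="Maximum per-amplicon read fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: c.ref_start):
            anchor_pos = c.ref_start - 1  # 0-based anchor base before the event
            if anchor_pos < 0:
                continue
            anchor = locus_seq[anchor_pos]
            ref = anchor + locus_seq[c.ref_start: c.ref_start + c.ref_span]
            alt = anchor + c.alt_seq
            fh.write(f"{chrom}\t{anchor_pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"MAXFRAC={c.max_fraction:.6f}\n")


def write_events_bed(events: Sequence[DeletionEvent], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for i, ev in enumerate(sorted(events, key=lambda e: (e.chrom, e.start))):
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t"
                     f"{ev.sample}_del{i + 1}\t{ev.support}\n")


def write_events_vcf(events: Sequence[DeletionEvent], chrom_lengths: dict[str, int],
                     path: str | Path) -> None:
    """Symbolic <DEL> VCF with END info tags."""
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,'
                 'Description="Supporting reads">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for ev in sorted(events, key=lambda e: (e.chrom, e.start)):
            fh.write(f"{ev.chrom}\t{ev.start + 1}\t.\tN\t<DEL>\t.\tPASS\t"
                     f"END={ev.end};SUPPORT={ev.support}\n")


def write_json(obj, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def clonality_to_dict(result: AmpliconResult) -> dict:
    summary = result.clonality
    return {
        "n_pairs": result.n_pairs,
        "n_unassigned": result.n_unassigned,
        "n_merge_failures": result.n_merge_failures,
        "n_calls": len(result.calls),
        "n_distinct_indels": summary.n_distinct_indels,
        "top_k_read_share": (
            {str(k): v for k, v in summary.top_k_read_share.items()}
            if summary.top_k_read_share is not None else None),
    }
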