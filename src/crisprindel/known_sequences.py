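"""Published primer and guide sequences used throughout the package.

These are the five consecutively shifted Ptch1 amplicon primer pairs used for
targeted deep sequencing of the guide target region in exon 2 of murine
*Ptch1*, and the 20-nt protospacers of the guides used for tumour induction
(plus the non-targeting control guide, which has no perfect match in mm10).
"""

from __future__ import annotations

# Amplicon index -> (forward primer, reverse primer), 5'->3' as synthesised.
PTCH1_AMPLICON_PRIMERS: dict[int, tuple[str, str]] = {
    1: ("CTCACTGATTTACAACCAAGGC", "CATCAAACACAGTAAAGGGAAGG"),
    2: ("GCACCCCAAGTCTCATTCAG", "GTCTCGAGATTAGCTGCCTTT"),
    3: ("CACACTGCTGTCCAGAGGG", "ACTGGCCAGCCATGCAAAC"),
    4: ("CCTGGTCCCTAGAGTACAG", "CGCCTGATCGCTTACCTTC"),
    5: ("GGTTCCAGTCCGAGGGAG", "CAAGGGCTTCTCGTTGGCTA"),
}

# Guide name -> 20-nt protospacer (genomic strand as targeted).
GUIDES: dict[str, str] = {
    "Ptch1.1": "CTGGCCGGAAAGCGCCGCTG",
    "Ptch1.2": "TCAGAGACTCTTATTTAAAC",
    "Ptch1.3": "GTTGTGGGTCTCCTCATATT",
    "Nf1": "AGTCAGCACCGAGCACAACA",
    "Pten": "AAAGACTTGAAGGTGTATAC",
    "Trp53": "ACAGCCATCACCTCACTGCA",
    "gNT": "GCGACCAATACGCGAACGTC",
}
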