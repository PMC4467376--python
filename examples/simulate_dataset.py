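"""Generate a complete ground-truthed synthetic dataset on disk.

Writes paired amplicon FASTQ, a coordinate-sorted WGS SAM for tumour and
control, the surrogate genome FASTA, annotation tracks and truth tables —
everything the callers consume — for a polyclonal edited sample.
"""

import numpy as np

from crisprindel.simulate import (SimConfig, control_population, emit_tracks,
                                  make_locus, make_panel,
                                  simulate_amplicon_reads, simulate_clones,
                                  simulate_wgs_alignments, write_fastq_pairs,
                                  write_sam)

out = "scratch/example_dataset"
locus, cut = make_locus(seed=5)
panel = make_panel(locus, cut)
rng = np.random.default_rng(5)
pop = simulate_clones(locus, cut, rng=rng)
config = SimConfig(seed=5, n_pairs_per_amplicon=2_000, wgs_depth=23.3)

pairs, truth = simulate_amplicon_reads(pop, panel, config, rng)
records, wgs_truth = simulate_wgs_alignments(pop, config, rng, sample="T")
ctl_records, _ = simulate_wgs_alignments(
    control_population(locus, cut),
    SimConfig(seed=6, wgs_depth=23.3, control=True),
    np.random.default_rng(6), sample="C")
paths = emit_tracks(pop, out)
write_fastq_pairs(pairs, f"{out}/amplicon_R1.fastq", f"{out}/amplicon_R2.fastq")
write_sam(records, f"{out}/tumour.sam", chrom=pop.chrom, chrom_len=len(locus))
write_sam(ctl_records, f"{out}/control.sam", chrom=pop.chrom,
          chrom_len=len(locus))
truth.to_csv(f"{out}/amplicon_truth.tsv", sep="\t", index=False)

print(f"population: {len(pop.clones)} clones, WT fraction {pop.wt_fraction:.2f}")
print(f"amplicon reads: {len(pairs)} pairs over {len(panel)} amplicons")
print(f"WGS records: tumour {len(records)}, control {len(ctl_records)} "
      f"(~23.3x)")
print(f"somatic truth deletions: {[(s, e) for _, s, e, _ in wgs_truth]}")
print(f"files under {out}: genome.fa, repeats.bed, polymorphic.bed, "
      "FASTQ pairs, SAM, truth tables")
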