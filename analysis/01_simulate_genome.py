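#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the default study genome — eight 580 kb chromosomes plus unplaced
scaffolds, five planted satellite families (40-2500 bp monomers, ~100-4900
copies, one to eight chromosomes, substitutions <= 5%), four planted
contaminant arrays with matching reference sets — simulates 10x short reads
and 15x >=10 kb long reads, and writes FASTA/FASTQ plus the truth manifest
under results/inputs/.
"""

import sys
from pathlib import Path

from satellome import simulate
from satellome.report import assembly_stats

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/inputs")
OUT.mkdir(parents=True, exist_ok=True)

refs, contaminants = simulate.make_reference_sets(seed=SEED + 17)
genome, truth = simulate.build_genome(
    simulate.default_family_specs(),
    simulate.default_chromosome_lengths(),
    contaminants,
    seed=SEED,
)
rp = simulate.ReadSimParams(seed=SEED + 2)
short_reads = simulate.simulate_short_reads(genome, rp)
long_reads = simulate.simulate_long_reads(genome, rp)

simulate.write_fasta(genome, OUT / "genome.fasta")
simulate.write_fastq(short_reads, OUT / "short_reads.fastq")
simulate.write_fasta(long_reads, OUT / "long_reads.fasta")
simulate.write_truth(truth, OUT / "truth.tsv", OUT / "truth.json")
for kind, entries in refs.items():
    simulate.write_fasta(entries, OUT / f"ref_{kind}.fasta")

gc, n, n50, l50 = assembly_stats(genome)
print(f"genome: {n} scaffolds, {sum(len(s) for s in genome.values())} bp, "
      f"GC {gc:.2f}%, N50 {n50} bp, L50 {l50}")
print(f"planted: {len(truth.true_monomers)} satellite families, "
      f"{len(truth.array_intervals)} arrays, "
      f"{len(truth.contaminant_intervals)} contaminant arrays")
print(f"reads: {len(short_reads)} short (150 bp), {len(long_reads)} long (>=10 kb)")
print(f"wrote inputs under {OUT}/")
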