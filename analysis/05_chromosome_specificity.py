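#!/usr/bin/env python
"""Chromosome specificity: per-chromosome counts, CA, Mahalanobis ranking.

Aligns every consensus against the assembly (unplaced-scaffold hits are
tallied separately and excluded from the ordination), runs correspondence
analysis on ln(1+x) counts, ranks families by Mahalanobis distance from
the origin, and calls peak-copy-number chromosomes, strict 1-/2-chromosome
specificity and the fully-anchored fraction.
"""

from pathlib import Path

import numpy as np

from satellome import chromspec as cs
from satellome.curate import SatFamily
from satellome.report import preprocess_assembly
from satellome.seqio import read_fasta, read_fasta_list

IN = Path("results/inputs")
OUT = Path("results")

assembly = preprocess_assembly(read_fasta(IN / "genome.fasta"))
families = [SatFamily(n.split()[0], s)
            for n, s in read_fasta_list(OUT / "satellitome_raw.fasta")]

profiles = [cs.count_hits_per_chromosome(f, assembly) for f in families]
(OUT / "chromosome_counts.tsv").write_text(cs.count_matrix_tsv(profiles))

ca = cs.correspondence_analysis(profiles)
maha = cs.mahalanobis_from_origin(ca)
rows = ["family\tdim1\tdim2\tmahalanobis\tpcn\tstrict\tunplaced\tanchored"]
for prof, coord in zip(profiles, ca.row_coordinates):
    pcn, strict = cs.call_pcn_and_specificity(prof)
    rows.append("\t".join([
        prof.family, f"{coord[0]:.6f}", f"{coord[1]:.6f}",
        f"{maha[prof.family]:.4f}", ",".join(sorted(pcn)), strict,
        str(prof.unplaced_count), str(int(prof.fully_anchored)),
    ]))
(OUT / "chromosome_specificity.tsv").write_text("\n".join(rows) + "\n")

print(f"CA inertia shares (2 dims): {np.round(ca.inertia_shares, 3)}")
for prof in sorted(profiles, key=lambda p: -maha[p.family]):
    pcn, strict = cs.call_pcn_and_specificity(prof)
    print(f"{prof.family}: Mahalanobis {maha[prof.family]:.2f}, "
          f"PCN {{{','.join(sorted(pcn))}}}, strict={strict}, "
          f"unplaced={prof.unplaced_count}")
print(f"fully anchored fraction: {cs.anchored_fraction(profiles):.2f}")
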