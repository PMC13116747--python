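#!/usr/bin/env python
"""Detect tandem arrays and curate the satellitome.

Reads the simulated assembly, runs three detection rounds with increasing
period ranges (masking between rounds), builds rotation/strand-standardized
consensus candidates with the k-mer-coverage >= 0.5 filter, deduplicates at
80% circular identity, removes coding/TE/organelle/rDNA contaminants, and
clusters the survivors (bitscore similarity graph + Markov clustering).
Writes array calls (BED), candidate and final consensus FASTA, and the
screen report under results/.
"""

import sys
from pathlib import Path

from satellome import curate, detect, screen
from satellome.pipeline import candidates_from_calls
from satellome.report import preprocess_assembly
from satellome.seqio import read_fasta, read_fasta_list
from satellome.simulate import write_fasta

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
IN = Path("results/inputs")
OUT = Path("results")

assembly = preprocess_assembly(read_fasta(IN / "genome.fasta"))
calls = detect.run_rounds(assembly, seed=SEED + 1)
(OUT / "array_calls.bed").write_text(detect.calls_to_bed(calls))
print(f"detection: {len(calls)} array calls over {len(assembly)} scaffolds")

candidates = candidates_from_calls(calls, assembly)
write_fasta([(f"{c.candidate_id}|round{c.source_round}|{c.source_detector}|"
              f"kcov={c.kmer_coverage:.3f}", c.sequence) for c in candidates],
            OUT / "candidates.fasta")
deduped = curate.dedup_identity(candidates)
print(f"candidates: {len(candidates)} raw -> {len(deduped)} after two-pass dedup")

refs = {kind: read_fasta_list(IN / f"ref_{kind}.fasta")
        for kind in ("protein", "te", "organelle", "rdna")}
retained, log = screen.run_screens(
    deduped, refs["protein"], refs["te"], refs["organelle"] + refs["rdna"]
)
(OUT / "screen_report.tsv").write_text(screen.screen_report_tsv(log))
print(f"screens: removed {len(deduped) - len(retained)} contaminant candidates "
      f"({', '.join(sorted(r.screen for r in log if r.removed))})")

families = curate.finalize_families(curate.merge_with_known(retained, []))
write_fasta([(f.name, f.sequence) for f in families], OUT / "satellitome_raw.fasta")
print(f"satellitome: {len(families)} families "
      f"(lengths {sorted(f.length for f in families)})")
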