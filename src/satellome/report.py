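"""Nomenclature, cross-species comparison, in-silico PCR and assembly
statistics.

Family names follow the satellitome convention
``<SpeciesPrefix>Sat<rank>-<monomer length>[-<suffix>]`` with ranks
assigned in order of decreasing final genomic abundance; e.g. the most
abundant 377 bp subtelomeric family of a species with prefix ``Ac``
becomes ``AcSat1-377-subtel``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .align import AlignmentParams, encode_dna, revcomp
from .curate import SatFamily, _circular_match


@dataclass(frozen=True)
class SatName:
    prefix: str
    rank: int
    length: int
    suffix: str = "none"

    def render(self) -> str:
        base = f"{self.prefix}Sat{self.rank}-{self.length}"
        return base if self.suffix in ("none", "", None) else f"{base}-{self.suffix}"


def assign_names(
    families: Sequence[SatFamily],
    abundances: dict[str, float],
    prefix: str,
    suffixes: Optional[dict[str, str]] = None,
) -> tuple[list[SatFamily], dict[str, str]]:
    """Rank families 1..N by decreasing final abundance (ties: longer
    monomer, then lexicographically smaller sequence) and render names.
    Returns the renamed families plus an old->new mapping that also covers
    known-library provenance entries."""
    suffixes = suffixes or {}
    order = sorted(
        families,
        key=lambda f: (-abundances.get(f.name, 0.0), -f.length, f.sequence),
    )
    mapping: dict[str, str] = {}
    renamed = []
    for rank, fam in enumerate(order, start=1):
        suffix = suffixes.get(fam.name, fam.suffix)
        new = SatName(prefix, rank, fam.length, suffix).render()
        mapping[fam.name] = new
        for _src, old in fam.provenance:
            mapping.setdefault(old, new)
        renamed.append(SatFamily(new, fam.sequence, suffix, list(fam.provenance)))
    return renamed, mapping


# ---------------------------------------------------------------------------
# Cross-species homology


def cross_species_homology(
    satellitome_a: Sequence[SatFamily],
    satellitome_b: Sequence[SatFamily],
    params: AlignmentParams = AlignmentParams(),
    min_identity_pct: float = 80.0,
    min_coverage_pct: float = 50.0,
) -> dict[str, dict[str, tuple[str, Optional[str], float]]]:
    """Classify every family in each satellitome as shared or specific.

    A pair is shared when the best rotation-invariant alignment reaches
    >= 80% identity over >= 50% of the shorter consensus; each shared
    family records its best partner and the identity.  The relation is
    symmetric by construction (the same pair matrix serves both species).
    """
    pair_id: dict[tuple[str, str], float] = {}
    for fa in satellitome_a:
        for fb in satellitome_b:
            ident, cov, _, _ = _circular_match(fa.sequence, fb.sequence, params)
            if ident >= min_identity_pct and cov >= min_coverage_pct:
                pair_id[(fa.name, fb.name)] = ident
    out = {"a": {}, "b": {}}
    for fa in satellitome_a:
        matches = [(ident, b) for (a, b), ident in pair_id.items() if a == fa.name]
        if matches:
            ident, partner = max(matches)
            out["a"][fa.name] = ("shared", partner, ident)
        else:
            out["a"][fa.name] = ("specific", None, 0.0)
    for fb in satellitome_b:
        matches = [(ident, a) for (a, b), ident in pair_id.items() if b == fb.name]
        if matches:
            ident, partner = max(matches)
            out["b"][fb.name] = ("shared", partner, ident)
        else:
            out["b"][fb.name] = ("specific", None, 0.0)
    return out


# ---------------------------------------------------------------------------
# In-silico PCR


@dataclass(frozen=True)
class PrimerPair:
    forward: str  # 5'->3'
    reverse: str  # 5'->3'
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise ValueError("primers must be >= 15 bp")


def _match_positions(template: str, primer: str, max_mismatches: int) -> list[int]:
    """0-based start positions where the primer matches the plus strand."""
    n, m = len(template), len(primer)
    if m > n:
        return []
    if max_mismatches == 0:
        out = []
        start = template.find(primer)
        while start != -1:
            out.append(start)
            start = template.find(primer, start + 1)
        return out
    t = encode_dna(template)
    p = encode_dna(primer)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mismatches = np.sum(windows != p[None, :], axis=1)
    return np.nonzero(mismatches <= max_mismatches)[0].tolist()


def in_silico_pcr(
    template: str, primers: PrimerPair, circular: bool = False
) -> list[int]:
    """Predicted amplicon lengths on a template.

    An amplicon is a plus-strand stretch reading ``forward ... revcomp(
    reverse)`` or, symmetrically, ``reverse ... revcomp(forward)``; the
    length runs from the 5' start of one primer's site to the 5' start of
    the other's, inclusive.  Circular templates are searched doubled and
    products longer than the template are discarded.
    """
    work = template + template if circular else template
    L = len(template)
    products: set[tuple[int, int]] = set()  # (anchor position mod L, length)
    for left, right in ((primers.forward, primers.reverse),
                        (primers.reverse, primers.forward)):
        f_sites = _match_positions(work, left, primers.max_mismatches)
        r_sites = _match_positions(work, revcomp(right), primers.max_mismatches)
        for f in f_sites:
            for r in r_sites:
                r5 = r + len(right) - 1  # 5' end of the reverse primer site
                if r5 <= f + len(left) - 1:
                    continue
                length = r5 - f + 1
                if circular:
                    if length > L:
                        continue
                    products.add((f % L, length))
                else:
                    products.add((f, length))
    return sorted(length for _pos, length in products)


# ---------------------------------------------------------------------------
# Assembly statistics and preprocessing


def assembly_stats(assembly: dict[str, str]) -> tuple[float, int, int, int]:
    """(gc_pct over non-N bases, scaffold count, N50 bp, L50 count)."""
    lengths = sorted((len(s) for s in assembly.values()), reverse=True)
    total = sum(lengths)
    gc = 0
    acgt = 0
    for seq in assembly.values():
        codes = encode_dna(seq)
        acgt += int(np.sum(codes < 4))
        gc += int(np.sum((codes == 1) | (codes == 2)))
    if acgt == 0:
        import warnings

        warnings.warn("no unambiguous bases; GC reported as 0")
        gc_pct = 0.0
    else:
        gc_pct = 100.0 * gc / acgt
    cum = 0
    n50 = 0
    l50 = 0
    for i, length in enumerate(lengths, start=1):
        cum += length
        if cum * 2 >= total:
            n50 = length
            l50 = i
            break
    return gc_pct, len(lengths), n50, l50


_CLEAN = np.full(256, ord("N"), dtype=np.uint8)
for _b in b"ACGT":
    _CLEAN[_b] = _b
    _CLEAN[_b + 32] = _b  # lowercase soft-masked -> unmasked uppercase


def preprocess_assembly(assembly: dict[str, str]) -> dict[str, str]:
    """Unmask soft-masked bases and convert every ambiguous character to N;
    lengths are preserved exactly."""
    out = {}
    for name, seq in assembly.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        out[name] = _CLEAN[arr].tobytes().decode("ascii")
    return out


# ---------------------------------------------------------------------------
# Master report


def master_table_tsv(
    families: Sequence[SatFamily],
    records: dict[str, object],
    metrics: dict[str, object],
    profiles: dict[str, object],
    mahalanobis: dict[str, float],
    pcn: dict[str, tuple[set, str]],
) -> str:
    header = [
        "name", "length", "gc_pct", "suffix", "provenance",
        "illumina_mapped_reads", "illumina_abundance_pct", "illumina_cn",
        "pacbio_cn", "pacbio_cn_2c", "acn", "final_abundance_pct", "discrepant",
        "mcnpr", "mtspr", "mcopr", "clustered",
        "mahalanobis", "pcn_chromosomes", "strict_level",
        "unplaced_count", "fully_anchored",
    ]
    lines = ["\t".join(header)]
    for fam in families:
        rec = records.get(fam.name)
        met = metrics.get(fam.name)
        prof = profiles.get(fam.name)
        pcn_set, strict = pcn.get(fam.name, (set(), "none"))
        row = [
            fam.name, str(fam.length), f"{fam.gc_pct:.2f}", fam.suffix,
            ";".join(f"{s}:{o}" for s, o in fam.provenance) or "-",
            str(rec.illumina_mapped_reads if rec else 0),
            f"{rec.illumina_abundance_pct:.6f}" if rec else "0",
            f"{rec.illumina_cn:.1f}" if rec else "0",
            str(rec.pacbio_cn if rec else 0),
            f"{rec.pacbio_cn_2c:.1f}" if rec else "0",
            f"{rec.acn:.1f}" if rec and rec.acn else "-",
            f"{rec.final_abundance_pct:.6f}" if rec and rec.final_abundance_pct else "-",
            str(int(rec.discrepant)) if rec else "0",
            str(met.mcnpr if met else 0),
            str(met.mtspr if met else 0),
            f"{met.mcopr:.2f}" if met else "0",
            str(int(met.clustered)) if met else "0",
            f"{mahalanobis.get(fam.name, float('nan')):.4f}",
            ",".join(sorted(pcn_set)) or "-",
            strict,
            str(prof.unplaced_count if prof else 0),
            str(int(prof.fully_anchored)) if prof else "-",
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def write_reports(outdir: str | Path, families: Sequence[SatFamily],
                  master_tsv: str, run_log: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .simulate import write_fasta

    write_fasta(
        [(f"{f.name} suffix={f.suffix} provenance=" +
          (";".join(f"{s}:{o}" for s, o in f.provenance) or "-"), f.sequence)
         for f in families],
        outdir / "satellitome.fasta",
    )
    (outdir / "satellitome.tsv").write_text(master_tsv)
    (outdir / "run_log.txt").write_text(run_log)
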