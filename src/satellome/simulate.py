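"""Synthetic genomes, read sets, and ground-truth manifests.

The generator emulates the inputs the pipeline expects from a real study:
multi-chromosome assemblies carrying planted tandem satellite arrays (with
per-copy substitutions and indels), unplaced scaffolds holding extra array
copies, planted contaminant arrays (organelle-, rDNA-, TE- and
protein-coding-like) with matching reference sets, uniform-coverage short
reads, and length-filtered long reads.  Everything is bit-reproducible
under a fixed seed, and every planted feature is recorded in a truth
manifest so downstream stages can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .align import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class FamilySpec:
    """Planted satellite family: what is true before the pipeline runs."""

    family_id: str
    monomer_length: int
    gc_fraction: float
    per_chromosome_copies: dict[str, int] = field(default_factory=dict)
    unplaced_copies: int = 0
    substitution_rate: float = 0.02
    indel_rate: float = 0.0
    n_arrays_per_chromosome: int = 1
    suffix: str = "none"

    def __post_init__(self) -> None:
        if self.monomer_length < 10:
            raise ValueError("monomer_length must be >= 10")
        if self.total_copies < 1:
            raise ValueError("at least one copy required")
        if not (0 <= self.substitution_rate <= 0.3 and 0 <= self.indel_rate <= 0.05):
            raise ValueError("mutation rates out of range")

    @property
    def total_copies(self) -> int:
        return sum(self.per_chromosome_copies.values()) + self.unplaced_copies


@dataclass
class ContaminantSpec:
    """A planted non-satellite tandem unit plus the screen that should
    remove it ('coding', 'te', 'organelle' or 'rdna')."""

    kind: str
    name: str
    unit: str
    copies: int
    chromosome: str


@dataclass
class GenomeTruth:
    chromosome_lengths: dict[str, int]
    array_intervals: list[tuple[str, int, int, str]]  # chrom, start, end (1-based incl.), family
    true_monomers: dict[str, str]
    contaminant_intervals: list[tuple[str, int, int, str]]

    def family_intervals(self, family_id: str) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, s, e, f in self.array_intervals if f == family_id]

    def true_copies(self, family_id: str, placed_only: bool = False) -> int:
        """Planted copy count inferred from interval spans."""
        mono = self.true_monomers[family_id]
        total = 0
        for c, s, e, f in self.array_intervals:
            if f != family_id:
                continue
            if placed_only and not c.startswith("chr"):
                continue
            total += round((e - s + 1) / len(mono))
        return total


@dataclass
class ReadSimParams:
    short_read_length: int = 150
    short_coverage: float = 10.0
    long_read_mean: int = 25_000
    long_read_min: int = 10_000
    long_error_rate: float = 0.002
    seed: int = 0
    short_error_rate: float = 0.01
    long_coverage: float = 15.0
    long_length_sigma: float = 0.35  # log-scale sd of the lognormal length model

    def __post_init__(self) -> None:
        if self.long_read_min < 10_000:
            raise ValueError("long_read_min must be >= 10,000 bp")
        if not (0 <= self.long_error_rate <= 0.05):
            raise ValueError("long_error_rate out of range")


# ---------------------------------------------------------------------------
# Sequence generation


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def make_monomer(length: int, gc_fraction: float, seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None) -> str:
    """I.i.d. monomer whose expected GC equals ``gc_fraction``."""
    if length < 10:
        raise ValueError("monomer length must be >= 10")
    if rng is None:
        rng = np.random.default_rng(seed)
    return _random_seq(length, gc_fraction, rng)


def mutate_copy(monomer: str, substitution_rate: float, indel_rate: float,
                rng: np.random.Generator) -> str:
    """One array copy: i.i.d. substitutions plus geometric-length indels."""
    out = []
    skip = 0
    for ch in monomer:
        if skip > 0:
            skip -= 1
            continue
        r = rng.random()
        if r < indel_rate:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion before this base
                out.append(_BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii"))
                out.append(ch)
            else:  # deletion of a geometric-length run starting here
                skip = length - 1
        elif r < indel_rate + substitution_rate:
            out.append("ACGT"[(("ACGT".index(ch) if ch in "ACGT" else 0) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(ch)
    return "".join(out)


def _make_array(monomer: str, copies: int, spec_sub: float, spec_indel: float,
                rng: np.random.Generator) -> str:
    seq = "".join(mutate_copy(monomer, spec_sub, spec_indel, rng) for _ in range(copies))
    if rng.random() < 0.5:
        seq = revcomp(seq)
    return seq


# ---------------------------------------------------------------------------
# Genome assembly


def _place_segments(length: int, segments: list[tuple[str, str]], rng: np.random.Generator,
                    min_gap: int = 2000, edge: int = 1000):
    """Random non-overlapping placement; returns [(start0, label, seq)]."""
    if not segments:
        return []
    order = list(rng.permutation(len(segments)))
    segs = [segments[i] for i in order]
    total = sum(len(s) for _, s in segs)
    slack = length - total - 2 * edge - min_gap * (len(segs) - 1)
    if slack < 0:
        raise ValueError(
            f"infeasible packing: {total} bp of arrays into a {length} bp scaffold"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=len(segs)))
    placed = []
    pos = edge
    prev_cut = 0
    for (label, seq), cut in zip(segs, cuts):
        pos += int(cut) - prev_cut
        prev_cut = int(cut)
        placed.append((pos, label, seq))
        pos += len(seq) + min_gap
    return placed


def build_genome(
    specs: list[FamilySpec],
    chromosome_lengths: dict[str, int],
    contaminants: Optional[list[ContaminantSpec]] = None,
    seed: int = 0,
    background_gc: float = 0.35,
) -> tuple[dict[str, str], GenomeTruth]:
    """Assemble a synthetic genome and its truth manifest.

    Each family is planted as ``n_arrays_per_chromosome`` contiguous arrays
    per chromosome (random strand per array); ``unplaced_copies`` go to a
    dedicated ``scaffold_<family>`` sequence.  Contaminant units are planted
    as tandem arrays so the detector picks them up as candidates.
    """
    rng = np.random.default_rng(seed)
    contaminants = contaminants or []
    monomers = {
        s.family_id: make_monomer(s.monomer_length, s.gc_fraction, rng=rng) for s in specs
    }

    # segments per scaffold
    per_scaffold: dict[str, list[tuple[str, str]]] = {c: [] for c in chromosome_lengths}
    scaffold_lengths = dict(chromosome_lengths)
    for s in specs:
        for chrom, copies in s.per_chromosome_copies.items():
            if copies <= 0:
                continue
            if chrom not in per_scaffold:
                raise ValueError(f"unknown chromosome {chrom}")
            n_arr = min(s.n_arrays_per_chromosome, copies)
            base, extra = divmod(copies, n_arr)
            for i in range(n_arr):
                c = base + (1 if i < extra else 0)
                per_scaffold[chrom].append(
                    (f"sat:{s.family_id}", _make_array(monomers[s.family_id], c,
                                                       s.substitution_rate, s.indel_rate, rng))
                )
        if s.unplaced_copies > 0:
            name = f"scaffold_{s.family_id}"
            arr = _make_array(monomers[s.family_id], s.unplaced_copies,
                              s.substitution_rate, s.indel_rate, rng)
            scaffold_lengths[name] = len(arr) + 24_000
            per_scaffold[name] = [(f"sat:{s.family_id}", arr)]
    for c in contaminants:
        if c.chromosome not in per_scaffold:
            raise ValueError(f"unknown chromosome {c.chromosome}")
        arr = "".join(mutate_copy(c.unit, 0.01, 0.0, rng) for _ in range(c.copies))
        per_scaffold[c.chromosome].append((f"cont:{c.kind}:{c.name}", arr))
    if "scaffold_decoy" not in scaffold_lengths:
        scaffold_lengths["scaffold_decoy"] = 20_000
        per_scaffold["scaffold_decoy"] = []

    genome: dict[str, str] = {}
    array_intervals: list[tuple[str, int, int, str]] = []
    contaminant_intervals: list[tuple[str, int, int, str]] = []
    for scaf, length in scaffold_lengths.items():
        placed = _place_segments(length, per_scaffold.get(scaf, []), rng)
        seq = np.frombuffer(_random_seq(length, background_gc, rng).encode(), dtype=np.uint8).copy()
        for pos, label, segment in placed:
            seq[pos : pos + len(segment)] = np.frombuffer(segment.encode(), dtype=np.uint8)
            start1, end1 = pos + 1, pos + len(segment)
            if label.startswith("sat:"):
                array_intervals.append((scaf, start1, end1, label[4:]))
            else:
                contaminant_intervals.append((scaf, start1, end1, label[5:]))
        genome[scaf] = seq.tobytes().decode("ascii")

    truth = GenomeTruth(
        chromosome_lengths={c: len(s) for c, s in genome.items()},
        array_intervals=sorted(array_intervals),
        true_monomers=monomers,
        contaminant_intervals=sorted(contaminant_intervals),
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Read simulation


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(codes)) < rate)[0]
    if len(hit) == 0:
        return seq
    lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
    for i in hit:
        alts = lut.get(int(codes[i]), b"ACGT")
        codes[i] = alts[int(rng.integers(0, len(alts)))]
    return codes.tobytes().decode("ascii")


def simulate_short_reads(genome: dict[str, str], params: ReadSimParams) -> list[tuple[str, str]]:
    """Uniform error-bearing short reads; count = coverage*G/len (rounded)."""
    rng = np.random.default_rng(params.seed)
    scaffolds = sorted(genome)
    lengths = np.array([len(genome[c]) for c in scaffolds], dtype=float)
    g = lengths.sum()
    rl = params.short_read_length
    n_reads = int(round(params.short_coverage * g / rl))
    if n_reads == 0:
        return []
    weights = np.maximum(lengths - rl + 1, 0)
    picks = rng.choice(len(scaffolds), size=n_reads, p=weights / weights.sum())
    reads = []
    for idx in range(n_reads):
        scaf = scaffolds[int(picks[idx])]
        start = int(rng.integers(0, len(genome[scaf]) - rl + 1))
        seq = genome[scaf][start : start + rl]
        strand = "+"
        if rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        seq = _apply_errors(seq, params.short_error_rate, rng)
        reads.append((f"sr{idx}|{scaf}:{start + 1}-{start + rl}({strand})", seq))
    return reads


def simulate_long_reads(genome: dict[str, str], params: ReadSimParams) -> list[tuple[str, str]]:
    """Long reads with lognormal lengths truncated at ``long_read_min``;
    sampled until total bases reach ``long_coverage`` * genome size."""
    rng = np.random.default_rng(params.seed + 1)
    scaffolds = sorted(c for c in genome if len(genome[c]) >= params.long_read_min)
    if not scaffolds:
        return []
    lengths = np.array([len(genome[c]) for c in scaffolds], dtype=float)
    g = sum(len(s) for s in genome.values())
    target = params.long_coverage * g
    mu = np.log(params.long_read_mean) - params.long_length_sigma**2 / 2
    reads = []
    total = 0
    idx = 0
    while total < target:
        scaf = scaffolds[int(rng.choice(len(scaffolds), p=lengths / lengths.sum()))]
        slen = len(genome[scaf])
        rl = int(rng.lognormal(mu, params.long_length_sigma))
        if rl < params.long_read_min:
            continue
        rl = min(rl, slen)
        start = int(rng.integers(0, slen - rl + 1))
        seq = genome[scaf][start : start + rl]
        strand = "+"
        if rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        seq = _apply_errors(seq, params.long_error_rate, rng)
        reads.append((f"lr{idx}|{scaf}:{start + 1}-{start + rl}({strand})", seq))
        total += rl
        idx += 1
    return reads


# ---------------------------------------------------------------------------
# Default study conditions: reference sets and contaminant plantings


def make_reference_sets(seed: int = 7) -> tuple[dict[str, list[tuple[str, str]]], list[ContaminantSpec]]:
    """Synthetic contaminant reference sets plus the matching planted units.

    Returns (refs, contaminant_specs) where refs has keys 'protein'
    (amino-acid FASTA records), 'te', 'organelle', 'rdna' (nucleotide).
    """
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    codon = {  # one unambiguous codon per residue keeps the back-translation exact
        "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
        "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
        "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
        "W": "TGG", "Y": "TAT",
    }
    protein = "".join(aa[i] for i in rng.integers(0, 20, size=100))
    orf = "ATG" + "".join(codon[c] for c in protein) + "TAA"
    coding_unit = orf + _random_seq(40, 0.4, rng)

    te_ref = _random_seq(3000, 0.42, rng)
    te_unit = te_ref[800:1200]

    organelle_ref = _random_seq(8000, 0.37, rng)
    organelle_unit = organelle_ref[2000:2300]

    rdna_ref = _random_seq(2500, 0.55, rng)
    rdna_unit = rdna_ref[500:1000]

    refs = {
        "protein": [("P_synth1", "M" + protein), ("P_decoy", "".join(aa[i] for i in rng.integers(0, 20, size=120)))],
        "te": [("TE_synth1", te_ref)],
        "organelle": [("chloroplast_synth", organelle_ref)],
        "rdna": [("rdna_synth", rdna_ref)],
    }
    contaminants = [
        ContaminantSpec("coding", "gene_cluster", coding_unit, 40, "chr1"),
        ContaminantSpec("te", "te_tandem", te_unit, 45, "chr7"),
        ContaminantSpec("organelle", "cp_insert", organelle_unit, 50, "chr2"),
        ContaminantSpec("rdna", "rdna_array", rdna_unit, 40, "chr5"),
    ]
    return refs, contaminants


def default_family_specs() -> list[FamilySpec]:
    """The study conditions of the synthetic pipeline: five families spanning
    monomer lengths 40-2500 bp, 80-4900 copies, one to eight chromosomes of a
    ~5 Mb genome, substitution rates <= 5%."""
    chrs = [f"chr{i}" for i in range(1, 9)]
    return [
        FamilySpec("sat377", 377, 0.38, {c: 150 for c in chrs}, unplaced_copies=30,
                   substitution_rate=0.03, indel_rate=0.002, n_arrays_per_chromosome=1,
                   suffix="subtel"),
        FamilySpec("sat40", 40, 0.45, {c: 600 for c in chrs}, unplaced_copies=100,
                   substitution_rate=0.02, indel_rate=0.0, n_arrays_per_chromosome=2),
        FamilySpec("sat2500", 2500, 0.35, {"chr6": 80}, substitution_rate=0.04,
                   indel_rate=0.002, n_arrays_per_chromosome=2),
        FamilySpec("sat183", 183, 0.40, {"chr3": 400}, substitution_rate=0.05,
                   indel_rate=0.002, n_arrays_per_chromosome=2),
        # dispersed family: short 3-copy arrays whose total per-chromosome
        # content (4 x 3 x 741 bp ~ 8.9 kb) stays below the 10 kb clustering
        # threshold even if one read spanned every array on a chromosome
        FamilySpec("sat741", 741, 0.42, {c: 12 for c in chrs}, substitution_rate=0.03,
                   indel_rate=0.002, n_arrays_per_chromosome=4),
    ]


def default_chromosome_lengths() -> dict[str, int]:
    return {f"chr{i}": 580_000 for i in range(1, 9)}


# ---------------------------------------------------------------------------
# I/O


def write_fasta(records: list[tuple[str, str]] | dict[str, str], path: str | Path,
                width: int = 80) -> None:
    if isinstance(records, dict):
        records = list(records.items())
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: GenomeTruth, tsv_path: str | Path, json_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("scaffold\tstart\tend\tkind\tlabel\n")
        for c, s, e, f in truth.array_intervals:
            fh.write(f"{c}\t{s}\t{e}\tsatellite\t{f}\n")
        for c, s, e, f in truth.contaminant_intervals:
            fh.write(f"{c}\t{s}\t{e}\tcontaminant\t{f}\n")
    with open(json_path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1)
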