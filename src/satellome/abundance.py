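"""Genomic abundance and copy-number estimation.

Short reads give a per-family abundance (share of all reads whose best
local alignment lands on the family's consensus) which converts to an
absolute copy number per diploid (2C) genome:

    CN_illumina = 2C_size(bp) * abundance(%) / (monomer_length(bp) * 100)

Long (>= 10 kb) reads give an independent copy number as the number of
threshold-passing consensus hits across all reads.  The two estimates are
cross-validated (CNCV): a family whose estimates disagree by more than an
order of magnitude is flagged and excluded from the regression; the
remaining families' agreement is summarized as the squared Pearson
correlation of the log10 copy numbers.  The adjusted copy number (ACN) is
the geometric mean of the two estimates, and the final genomic abundance
is the share of the genome occupied by ACN copies of the monomer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import (
    AlignmentHit,
    AlignmentParams,
    HitThresholds,
    _align_codes,
    encode_dna,
    kmer_codes,
    revcomp,
    scan_hits,
)

LONG_READ_THRESHOLDS = HitThresholds(max_evalue=1e-5, min_identity_pct=70.0,
                                     min_query_coverage_pct=70.0)


@dataclass(frozen=True)
class GenomeConstants:
    two_c_size: float  # bp per diploid (2C) nucleus
    species_prefix: str = "Sy"

    def __post_init__(self) -> None:
        if self.two_c_size <= 0:
            raise ValueError("two_c_size must be positive")


@dataclass
class AbundanceRecord:
    family: str
    illumina_mapped_reads: int = 0
    illumina_abundance_pct: float = 0.0
    illumina_cn: float = 0.0
    pacbio_cn: int = 0          # raw long-read hit count
    pacbio_cn_2c: float = 0.0   # hit count scaled to copies per 2C
    acn: Optional[float] = None
    final_abundance_pct: Optional[float] = None
    discrepant: bool = False


# ---------------------------------------------------------------------------
# Short-read mapping


class _FamilyIndex:
    """Seed index over the doubled consensus (both strands) of one family."""

    def __init__(self, name: str, sequence: str, k: int):
        self.name = name
        self.sequence = sequence
        self.doubled_codes = encode_dna(sequence + sequence)
        self.k = k
        fwd = kmer_codes(self.doubled_codes, k)
        rev = kmer_codes(encode_dna(revcomp(sequence + sequence)), k)
        self.fwd_kmers = set(int(c) for c in fwd if c >= 0)
        self.rev_kmers = set(int(c) for c in rev if c >= 0)


def map_short_reads(
    reads: Sequence[tuple[str, str]],
    satellitome: Sequence,
    params: AlignmentParams = AlignmentParams(),
    min_score: int = 30,
    min_seed_count: int = 2,
) -> tuple[dict[str, int], int, dict[str, list[tuple[int, int]]]]:
    """Assign each read to at most one family: the best-scoring local
    alignment with score >= ``min_score`` (best-hit-only, no multi-mapping
    fractions).  Candidate families are pre-filtered by shared seed k-mers.

    Returns (mapped read counts per family, total reads, per-family mapped
    consensus intervals for coverage profiling; intervals are 1-based
    inclusive on the monomer, junction-wrapping alignments split in two).
    """
    if not reads:
        raise ValueError("empty read set")
    k = params.seed_kmer
    index = [_FamilyIndex(f.name, f.sequence, k) for f in satellitome]
    counts = {f.name: 0 for f in satellitome}
    intervals: dict[str, list[tuple[int, int]]] = {f.name: [] for f in satellitome}
    for _rid, seq in reads:
        read_codes = encode_dna(seq)
        read_kmers = set(int(c) for c in kmer_codes(read_codes, k) if c >= 0)
        rc_codes = None
        best = None  # (score, ss, se, fam)
        for fam in index:
            nf = len(read_kmers & fam.fwd_kmers)
            nr = len(read_kmers & fam.rev_kmers)
            if max(nf, nr) < min_seed_count:
                continue
            # full alignment against the doubled consensus on the seed-voted
            # strand (a read from a minus-strand array copy is reverse
            # complemented; subject coordinates stay on the consensus)
            if nr > nf:
                if rc_codes is None:
                    rc_codes = encode_dna(revcomp(seq))
                q = rc_codes
            else:
                q = read_codes
            res = _align_codes(q, fam.doubled_codes, params)
            if res is None:
                continue
            score, _qs, _qe, ss, se, *_ = res
            if score < min_score:
                continue
            if best is None or score > best[0]:
                best = (score, ss, se, fam)
        if best is not None:
            score, ss, se, fam = best
            counts[fam.name] += 1
            L = len(fam.sequence)
            s = ss % L + 1
            e = s + (se - ss)
            if e <= L:
                intervals[fam.name].append((s, e))
            else:
                intervals[fam.name].append((s, L))
                intervals[fam.name].append((1, e - L))
    return counts, len(reads), intervals


def abundance_pct_from_counts(mapped: int, total: int) -> float:
    return 100.0 * mapped / total


# ---------------------------------------------------------------------------
# Copy-number formulas


def cn_from_abundance(abundance_pct: float, constants: GenomeConstants,
                      monomer_length: int) -> float:
    """Copies per 2C = 2C size x abundance(%) / (monomer length x 100)."""
    return constants.two_c_size * abundance_pct / (monomer_length * 100.0)


def abundance_from_cn(cn: float, monomer_length: int,
                      constants: GenomeConstants) -> float:
    """Percent of the genome occupied by ``cn`` monomer copies."""
    return cn * monomer_length / constants.two_c_size * 100.0


def adjusted_cn(illumina_cn: float, pacbio_cn: float) -> float:
    """Geometric mean exp((ln a + ln b)/2) of the two platform estimates."""
    if illumina_cn <= 0 or pacbio_cn <= 0:
        raise ValueError("both copy numbers must be positive")
    return math.exp((math.log(illumina_cn) + math.log(pacbio_cn)) / 2.0)


# ---------------------------------------------------------------------------
# Long-read hit scanning


def scan_long_reads(
    satellitome: Sequence,
    long_reads: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    thresholds: HitThresholds = LONG_READ_THRESHOLDS,
) -> tuple[dict[str, dict[str, list[AlignmentHit]]], dict[str, int]]:
    """Threshold-passing hits of every consensus on every long read.

    Returns (hits[family][read_id] -> hit list, read lengths)."""
    hits: dict[str, dict[str, list[AlignmentHit]]] = {f.name: {} for f in satellitome}
    read_lengths: dict[str, int] = {}
    for rid, seq in long_reads:
        read_lengths[rid] = len(seq)
        for fam in satellitome:
            found = scan_hits(fam.sequence, seq, params, thresholds,
                              query_id=fam.name, subject_id=rid)
            if found:
                hits[fam.name][rid] = found
    return hits, read_lengths


def pacbio_cn(
    family,
    long_reads: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    thresholds: HitThresholds = LONG_READ_THRESHOLDS,
) -> int:
    """Long-read copy number: total non-redundant hit count of the family
    consensus across all reads."""
    hits, _ = scan_long_reads([family], long_reads, params, thresholds)
    return sum(len(v) for v in hits[family.name].values())


def normalize_pacbio_cn(raw_hits: int, total_read_bases: int,
                        constants: GenomeConstants) -> float:
    """Scale a raw hit count to copies per 2C by the sampled long-read
    coverage (hits x 2C / read bases).  With a read set totalling ~1x 2C
    the scale factor is ~1 and the raw count is already per-2C."""
    if total_read_bases <= 0:
        raise ValueError("no long-read bases")
    return raw_hits * constants.two_c_size / total_read_bases


# ---------------------------------------------------------------------------
# Cross-validation


def cncv(
    records: Sequence[AbundanceRecord],
    log_ratio_threshold: float = 1.0,
) -> tuple[dict[str, bool], float]:
    """Copy-number cross-validation.

    Flags families whose platform estimates disagree by more than
    ``log_ratio_threshold`` orders of magnitude; returns the flags and the
    squared Pearson correlation of log10 copy numbers over non-flagged
    families (requires at least 3)."""
    flags: dict[str, bool] = {}
    xs, ys = [], []
    for rec in records:
        if rec.illumina_cn <= 0 or rec.pacbio_cn_2c <= 0:
            flags[rec.family] = True
            continue
        ratio = math.log10(rec.pacbio_cn_2c / rec.illumina_cn)
        flagged = abs(ratio) > log_ratio_threshold
        flags[rec.family] = flagged
        if not flagged:
            xs.append(math.log10(rec.illumina_cn))
            ys.append(math.log10(rec.pacbio_cn_2c))
    if len(xs) < 3:
        raise ValueError("fewer than 3 usable families for CNCV")
    r = np.corrcoef(xs, ys)[0, 1]
    return flags, float(r * r)


def quantify(
    satellitome: Sequence,
    short_reads: Sequence[tuple[str, str]],
    long_reads: Sequence[tuple[str, str]],
    constants: GenomeConstants,
    params: AlignmentParams = AlignmentParams(),
    thresholds: HitThresholds = LONG_READ_THRESHOLDS,
    min_score: int = 30,
) -> tuple[list[AbundanceRecord], float, dict[str, dict[str, list[AlignmentHit]]], dict[str, int]]:
    """Full quantification block: short-read abundance + CN, long-read CN,
    CNCV flags/R^2, ACN and final genomic abundance per family.

    Returns (records, r_squared, long-read hits, long-read lengths);
    the hit sets are reused by the clustering-metrics stage."""
    counts, total, _ = map_short_reads(short_reads, satellitome, params, min_score)
    lr_hits, read_lengths = scan_long_reads(satellitome, long_reads, params, thresholds)
    total_lr_bases = sum(read_lengths.values())
    records = []
    for fam in satellitome:
        ab = abundance_pct_from_counts(counts[fam.name], total)
        il_cn = cn_from_abundance(ab, constants, len(fam.sequence))
        raw = sum(len(v) for v in lr_hits[fam.name].values())
        pb_cn = normalize_pacbio_cn(raw, total_lr_bases, constants) if raw else 0.0
        records.append(
            AbundanceRecord(
                family=fam.name,
                illumina_mapped_reads=counts[fam.name],
                illumina_abundance_pct=ab,
                illumina_cn=il_cn,
                pacbio_cn=raw,
                pacbio_cn_2c=pb_cn,
            )
        )
    flags, r2 = cncv(records)
    for rec in records:
        rec.discrepant = flags[rec.family]
        if not rec.discrepant and rec.illumina_cn > 0 and rec.pacbio_cn_2c > 0:
            rec.acn = adjusted_cn(rec.illumina_cn, rec.pacbio_cn_2c)
            fam_len = next(len(f.sequence) for f in satellitome if f.name == rec.family)
            rec.final_abundance_pct = abundance_from_cn(rec.acn, fam_len, constants)
    return records, r2, lr_hits, read_lengths
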