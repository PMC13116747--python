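"""Per-read clustering statistics from long-read hit sets.

For every family and every long read we record the monomer hit count, the
total span (bases of the read covered by the union of hit intervals) and
the coverage fraction.  The family-level summaries are the maxima over
reads — MCNPR (max copy number per read), MTSPR (max total span per read,
bp) and MCOPR (max coverage per read, %) — each maximum taken
independently, so they may come from different reads.  A family is
classified as clustered when its MTSPR strictly exceeds the 10 kb
threshold: long contiguous arrays are what make a family detectable
cytogenetically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .align import AlignmentHit

CLUSTERING_THRESHOLD_BP = 10_000


@dataclass
class PerReadStats:
    read_id: str
    copy_number: int
    total_span: int
    coverage_fraction: float


@dataclass
class ClusterMetrics:
    family: str
    mcnpr: int
    mtspr: int
    mcopr: float  # percentage
    clustered: bool


def _interval_union_len(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    end = 0
    for s, e in sorted(intervals):
        if e <= end:
            continue
        total += e - max(s, end + 1) + 1
        end = e
    return total


def per_read_stats(
    hits: Sequence[AlignmentHit], read_length: int, read_id: str = ""
) -> PerReadStats:
    """Copy number, union span and coverage fraction of one read's hits."""
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    n = len(hits)
    span = _interval_union_len([(h.s_start, h.s_end) for h in hits])
    return PerReadStats(read_id, n, span, span / read_length)


def family_metrics(
    family: str,
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
    read_lengths: Mapping[str, int],
    threshold_bp: int = CLUSTERING_THRESHOLD_BP,
) -> tuple[ClusterMetrics, list[PerReadStats]]:
    """MCNPR / MTSPR / MCOPR over all reads with hits; each maximum is taken
    independently over reads."""
    stats = [
        per_read_stats(hits, read_lengths[rid], rid)
        for rid, hits in sorted(hits_by_read.items())
    ]
    mcnpr = max((s.copy_number for s in stats), default=0)
    mtspr = max((s.total_span for s in stats), default=0)
    mcopr = 100.0 * max((s.coverage_fraction for s in stats), default=0.0)
    metrics = ClusterMetrics(family, mcnpr, mtspr, mcopr,
                             classify_clustered(mtspr, threshold_bp))
    return metrics, stats


def classify_clustered(mtspr: int, threshold_bp: int = CLUSTERING_THRESHOLD_BP) -> bool:
    """Clustered iff MTSPR strictly exceeds the threshold (a family sitting
    exactly at 10 kb is not called clustered)."""
    return mtspr > threshold_bp


def per_read_stats_tsv(all_stats: Mapping[str, Sequence[PerReadStats]]) -> str:
    lines = ["family\tread\tcopy_number\ttotal_span\tcoverage_fraction"]
    for fam in sorted(all_stats):
        for s in all_stats[fam]:
            lines.append(f"{fam}\t{s.read_id}\t{s.copy_number}\t{s.total_span}\t{s.coverage_fraction:.6f}")
    return "\n".join(lines) + "\n"


def metrics_tsv(metrics: Sequence[ClusterMetrics]) -> str:
    lines = ["family\tmcnpr\tmtspr\tmcopr\tclustered"]
    for m in metrics:
        lines.append(f"{m.family}\t{m.mcnpr}\t{m.mtspr}\t{m.mcopr:.2f}\t{int(m.clustered)}")
    return "\n".join(lines) + "\n"
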