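"""Chromosome specificity of satellite families.

Consensus monomers are aligned against the assembly, hits are tallied per
chromosome (hits on unplaced scaffolds are counted separately and never
enter the ordination), and the families x chromosomes count table is
analysed by correspondence analysis on ln(1+x)-transformed counts.  The
Mahalanobis distance of each family's 2-D row coordinates from the origin
— the point a family matching the average chromosomal profile maps to —
ranks families by chromosomal specificity.  Peak-copy-number (PCN)
chromosomes and strict 1-/2-chromosome specificity are called from the raw
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import AlignmentParams, HitThresholds, scan_hits

GENOME_THRESHOLDS = HitThresholds(max_evalue=1e-5, min_identity_pct=70.0,
                                  min_query_coverage_pct=70.0)


@dataclass
class ChromosomeProfile:
    family: str
    counts: dict[str, int]
    unplaced_count: int = 0

    @property
    def fully_anchored(self) -> bool:
        return self.unplaced_count == 0


@dataclass
class CAResult:
    families: list[str]
    chromosomes: list[str]
    row_coordinates: np.ndarray      # families x 2
    column_coordinates: np.ndarray   # chromosomes x 2
    inertia_shares: np.ndarray
    mahalanobis: dict[str, float] = field(default_factory=dict)


def count_hits_per_chromosome(
    family,
    assembly: dict[str, str],
    params: AlignmentParams = AlignmentParams(),
    thresholds: HitThresholds = GENOME_THRESHOLDS,
    chromosome_prefix: str = "chr",
) -> ChromosomeProfile:
    """Tally threshold-passing consensus hits per chromosome-named scaffold;
    hits on any other scaffold count as unplaced."""
    counts: dict[str, int] = {c: 0 for c in sorted(assembly) if c.startswith(chromosome_prefix)}
    unplaced = 0
    for scaf in sorted(assembly):
        n = len(scan_hits(family.sequence, assembly[scaf], params, thresholds,
                          query_id=family.name, subject_id=scaf))
        if scaf.startswith(chromosome_prefix):
            counts[scaf] += n
        else:
            unplaced += n
    return ChromosomeProfile(family.name, counts, unplaced)


def correspondence_analysis(
    profiles: Sequence[ChromosomeProfile],
    n_dims: int = 2,
) -> CAResult:
    """Correspondence analysis of the families x chromosomes table after an
    ln(1+x) transform (the +1 admits zero counts; the log damps the
    multiplicative copy-number differences between chromosomes).

    Standard CA: correspondence matrix P = X/sum(X), standardized residuals
    S = Dr^-1/2 (P - r c^T) Dc^-1/2, SVD of S, row principal coordinates
    Dr^-1/2 U Sigma.  The first two dimensions are retained, with a fixed
    sign convention (first nonzero loading of each dimension positive) so
    runs are bit-reproducible.  All-zero rows are dropped with a warning.
    """
    chromosomes = sorted(profiles[0].counts) if profiles else []
    fams = []
    rows = []
    for p in profiles:
        if sorted(p.counts) != chromosomes:
            raise ValueError("profiles disagree on the chromosome set")
        vec = np.array([p.counts[c] for c in chromosomes], dtype=float)
        if vec.sum() == 0:
            import warnings

            warnings.warn(f"family {p.family} has no placed hits; dropped from CA")
            continue
        fams.append(p.family)
        rows.append(vec)
    x = np.log1p(np.asarray(rows))
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 families and 2 chromosomes with hits")
    p = x / x.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = np.diag(1 / np.sqrt(r)) @ (p - np.outer(r, c)) @ np.diag(1 / np.sqrt(c))
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    rank = int(np.sum(sig > 1e-12))
    if rank < n_dims:
        raise ValueError(f"count table has rank {rank} < {n_dims}; CA is degenerate")
    for d in range(n_dims):
        col = u[:, d]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            u[:, d] = -col
            vt[d, :] = -vt[d, :]
    row_coords = (u[:, :n_dims] * sig[:n_dims]) / np.sqrt(r)[:, None]
    col_coords = (vt[:n_dims, :].T * sig[:n_dims]) / np.sqrt(c)[:, None]
    inertia = sig**2
    shares = inertia[:n_dims] / inertia.sum() if inertia.sum() > 0 else np.zeros(n_dims)
    return CAResult(fams, chromosomes, row_coords, col_coords, shares)


def mahalanobis_from_origin(ca: CAResult) -> dict[str, float]:
    """Covariance-scaled distance of each family's CA coordinates from the
    origin; larger = less uniform distribution across chromosomes."""
    coords = ca.row_coordinates
    cov = np.cov(coords, rowvar=False)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular CA coordinate covariance; using pseudo-inverse")
        inv = np.linalg.pinv(cov)
    out = {}
    for fam, v in zip(ca.families, coords):
        out[fam] = float(np.sqrt(v @ inv @ v))
    ca.mahalanobis = out
    return out


def call_pcn_and_specificity(
    profile: ChromosomeProfile, pcn_fraction: float = 0.5
) -> tuple[set[str], str]:
    """PCN chromosomes: counts >= ``pcn_fraction`` of the per-chromosome
    maximum.  Strict specificity: positive counts on exactly 1 or 2
    chromosomes (unplaced copies do not affect strictness; anchoring is the
    separate ``fully_anchored`` flag)."""
    counts = profile.counts
    peak = max(counts.values(), default=0)
    if peak == 0:
        return set(), "none"
    pcn = {c for c, v in counts.items() if v >= pcn_fraction * peak}
    positive = sum(1 for v in counts.values() if v > 0)
    if positive == 1:
        strict = "1-chromosome"
    elif positive == 2:
        strict = "2-chromosome"
    else:
        strict = "none"
    return pcn, strict


def anchored_fraction(profiles: Sequence[ChromosomeProfile]) -> float:
    """Share of families with no copies on unplaced scaffolds."""
    if not profiles:
        raise ValueError("empty satellitome")
    return sum(1 for p in profiles if p.fully_anchored) / len(profiles)


def count_matrix_tsv(profiles: Sequence[ChromosomeProfile]) -> str:
    chroms = sorted(profiles[0].counts) if profiles else []
    lines = ["family\t" + "\t".join(chroms) + "\tunplaced"]
    for p in profiles:
        lines.append(
            p.family + "\t" + "\t".join(str(p.counts[c]) for c in chroms) + f"\t{p.unplaced_count}"
        )
    return "\n".join(lines) + "\n"
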