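"""Candidate curation: redundancy removal and family finalization.

Collapses near-identical consensus candidates within and across
assemblies/detectors (greedy centroid clustering on rotation-invariant
identity), merges the survivors with a library of previously published
satellite monomers, clusters the pool on a bitscore-weighted similarity
graph with Markov clustering, and provides read-coverage evidence for
flagging chimeric consensuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .align import (
    AlignmentParams,
    bitscore,
    circular_best_hit,
    gc_fraction,
)
from .detect import ConsensusCandidate


@dataclass
class SatFamily:
    """One curated consensus monomer with its provenance."""

    name: str
    sequence: str
    suffix: str = "none"
    provenance: list[tuple[str, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_pct(self) -> float:
        return 100.0 * gc_fraction(self.sequence)


@dataclass
class SimilarityGraph:
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # undirected, weight = bitscore
    max_evalue: float = 1e-5
    min_identity_pct: float = 80.0
    min_coverage_pct: float = 80.0


def _circular_match(a: str, b: str, params: AlignmentParams):
    """Best rotation-invariant hit of the shorter sequence against the
    longer; returns (identity_pct, coverage_of_shorter_pct, score, evalue)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    hit = circular_best_hit(short, long_, params)
    if hit is None:
        return 0.0, 0.0, 0, np.inf
    return hit.identity_pct, hit.query_coverage_pct, hit.score, hit.evalue


def _greedy_centroid(
    candidates: list[ConsensusCandidate],
    identity_threshold: float,
    min_coverage_pct: float,
    params: AlignmentParams,
) -> list[ConsensusCandidate]:
    order = sorted(candidates, key=lambda c: (-len(c.sequence), c.candidate_id))
    reps: list[ConsensusCandidate] = []
    for cand in order:
        merged = False
        for rep in reps:
            ident, cov, _, _ = _circular_match(cand.sequence, rep.sequence, params)
            if ident >= identity_threshold and cov >= min_coverage_pct:
                merged = True
                break
        if not merged:
            reps.append(cand)
    return reps


def dedup_identity(
    candidates: Sequence[ConsensusCandidate],
    identity_threshold: float = 80.0,
    min_coverage_pct: float = 80.0,
    params: AlignmentParams = AlignmentParams(),
) -> list[ConsensusCandidate]:
    """Two-pass greedy centroid deduplication: first within each assembly of
    origin, then across detectors/assemblies.  Longest-first; the centroid
    (longest member) represents each cluster.  Merging requires both the
    identity threshold and >= ``min_coverage_pct`` coverage of the shorter
    sequence, so short chance matches never collapse distinct families."""
    by_assembly: dict[str, list[ConsensusCandidate]] = {}
    for c in candidates:
        by_assembly.setdefault(c.assembly, []).append(c)
    pass1: list[ConsensusCandidate] = []
    for asm in sorted(by_assembly):
        pass1.extend(_greedy_centroid(by_assembly[asm], identity_threshold,
                                      min_coverage_pct, params))
    return _greedy_centroid(pass1, identity_threshold, min_coverage_pct, params)


# ---------------------------------------------------------------------------
# Similarity graph + Markov clustering


def build_similarity_graph(
    candidates: Sequence[ConsensusCandidate],
    params: AlignmentParams = AlignmentParams(),
    max_evalue: float = 1e-5,
    min_identity_pct: float = 80.0,
    min_coverage_pct: float = 80.0,
) -> SimilarityGraph:
    """Self-comparison graph: an edge is admitted only when E-value,
    identity, and coverage of the shorter sequence all pass; edge weight is
    the alignment bitscore."""
    nodes = [c.candidate_id for c in candidates]
    edges: list[tuple[str, str, float]] = []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            ident, cov, score, ev = _circular_match(
                candidates[i].sequence, candidates[j].sequence, params
            )
            if ev <= max_evalue and ident >= min_identity_pct and cov >= min_coverage_pct:
                edges.append((nodes[i], nodes[j], bitscore(score, params)))
    return SimilarityGraph(nodes, edges, max_evalue, min_identity_pct, min_coverage_pct)


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-9,
    prune: float = 1e-6,
) -> list[set[str]]:
    """Markov clustering of the similarity graph.

    Column-normalized weight matrix (unit self-loops added), iterated
    expansion (matrix squaring) and inflation (entrywise power followed by
    renormalization) until the maximum entry change drops below ``tol``;
    clusters are the attractor-connected components.
    """
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return []
    m = np.zeros((n, n))
    for a, b, w in graph.edges:
        if w <= 0:
            raise ValueError("edge weights must be positive")
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    # self-loops at each node's maximum incident weight (mcl default)
    np.fill_diagonal(m, np.maximum(m.max(axis=0), 1.0))
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = m @ m
        new = new**inflation
        new[new < prune] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = new / colsum
        delta = np.max(np.abs(new - m))
        m = new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations (last delta {delta:.2e})"
        )
    g = nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > prune)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [set(nodes[i] for i in comp) for comp in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# Known-library merge and family finalization


def merge_with_known(
    candidates: Sequence[ConsensusCandidate],
    known_library: Sequence[tuple[str, str]],
) -> list[ConsensusCandidate]:
    """Known published monomers join the candidate pool before the final
    clustering; they are tagged so their original names survive into
    family provenance."""
    pool = list(candidates)
    for name, seq in known_library:
        pool.append(
            ConsensusCandidate(
                candidate_id=f"known:{name}",
                sequence=seq,
                kmer_coverage=1.0,
                source_detector="known_library",
            )
        )
    return pool


def finalize_families(
    candidates: Sequence[ConsensusCandidate],
    abundances: Optional[dict[str, float]] = None,
    params: AlignmentParams = AlignmentParams(),
    suffixes: Optional[dict[str, str]] = None,
) -> list[SatFamily]:
    """Cluster the (candidate + known) pool with MCL and keep one
    representative per cluster: the member with the highest short-read
    abundance (ties to the longer sequence).  Known-library entries are
    never dropped -- a cluster containing one records its original name in
    provenance, and an unmatched known entry survives as its own family."""
    abundances = abundances or {}
    suffixes = suffixes or {}
    graph = build_similarity_graph(candidates, params)
    clusters = mcl_cluster(graph)
    by_id = {c.candidate_id: c for c in candidates}
    families: list[SatFamily] = []
    for cluster in sorted(clusters, key=lambda s: sorted(s)[0]):
        members = [by_id[i] for i in sorted(cluster)]
        rep = max(
            members,
            key=lambda c: (abundances.get(c.candidate_id, 0.0), len(c.sequence), c.candidate_id),
        )
        provenance = [
            ("known_library", m.candidate_id[len("known:"):])
            for m in members
            if m.candidate_id.startswith("known:")
        ]
        provenance += [
            (m.source_detector, m.candidate_id)
            for m in members
            if not m.candidate_id.startswith("known:")
        ]
        families.append(
            SatFamily(
                name=rep.candidate_id,
                sequence=rep.sequence,
                suffix=suffixes.get(rep.candidate_id, "none"),
                provenance=provenance,
            )
        )
    return families


# ---------------------------------------------------------------------------
# Coverage-profile curation evidence


def coverage_profile(
    family: SatFamily,
    read_alignments: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Per-position depth over the consensus from mapped read intervals
    (1-based inclusive subject coordinates on the consensus)."""
    depth = np.zeros(family.length, dtype=np.int64)
    for s, e in read_alignments:
        s = max(1, s)
        e = min(family.length, e)
        if e >= s:
            depth[s - 1 : e] += 1
    return depth


def coverage_profile_from_reads(
    family: SatFamily,
    short_reads: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    min_score: int = 30,
) -> np.ndarray:
    """Per-position depth over the consensus from sensitive local mapping of
    short reads (the abundance module's mapper, restricted to one family)."""
    from .abundance import map_short_reads

    _counts, _total, intervals = map_short_reads(short_reads, [family], params,
                                                 min_score)
    return coverage_profile(family, intervals[family.name])


def flag_chimeric(depth: np.ndarray, window_fraction: float = 0.2,
                  drop_ratio: float = 0.1) -> bool:
    """True when a contiguous stretch of >= ``window_fraction`` of the
    consensus has depth below ``drop_ratio`` x median depth -- the signature
    of a chimeric consensus half-supported by reads."""
    if len(depth) == 0:
        return False
    positive = depth[depth > 0]
    if len(positive) == 0:
        return False
    med = np.median(positive)
    low = depth < drop_ratio * med
    window = max(1, int(window_fraction * len(depth)))
    run = 0
    for flag in low:
        run = run + 1 if flag else 0
        if run >= window:
            return True
    return False
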