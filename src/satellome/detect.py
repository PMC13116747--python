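"""De-novo tandem-array detection and consensus building.

A deliberately simple detector: periodicity is read off the histogram of
distances between successive occurrences of repeated k-mers in a sliding
window, windows with a consistent period are merged into array calls,
monomer units are cut at the detected period, phase-standardized by
rotation, strand-standardized by k-mer profile, and summarized as a
majority-vote consensus scored by k-mer coverage.  Calls are made in
several rounds with increasing period ranges, hard-masking earlier calls,
which favours short periods first and lets long monomers surface later.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .align import (
    AlignmentParams,
    align_column_pairs,
    decode_dna,
    encode_dna,
    kmer_codes,
    revcomp,
)

DEFAULT_ROUND_RANGES = [(10, 200), (150, 1000), (800, 3000)]


@dataclass
class ArrayCall:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    period: int
    n_copies_est: int
    source_round: int = 1

    def __post_init__(self) -> None:
        if self.period < 10:
            raise ValueError("period must be >= 10")
        if self.end - self.start + 1 < 2 * self.period:
            raise ValueError("array must span at least two periods")


@dataclass
class ConsensusCandidate:
    candidate_id: str
    sequence: str
    kmer_coverage: float
    source_round: int = 1
    source_detector: str = "satellome"
    assembly: str = "asm"


# ---------------------------------------------------------------------------
# Periodicity


def _recurrence_distances(codes: np.ndarray, k: int) -> np.ndarray:
    """Distances between successive occurrences of each repeated k-mer."""
    kc = kmer_codes(codes, k)
    valid = kc >= 0
    if valid.sum() < 2:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(kc[valid], kind="stable")
    pos = np.nonzero(valid)[0][order]
    vals = kc[valid][order]
    same = vals[1:] == vals[:-1]
    return (pos[1:] - pos[:-1])[same]


def _modal_period(dists: np.ndarray, period_range: tuple[int, int]) -> Optional[tuple[int, int]]:
    pmin, pmax = period_range
    sel = dists[(dists >= pmin) & (dists <= pmax)]
    if len(sel) == 0:
        return None
    counts = np.bincount(sel)
    mode = int(np.argmax(counts))
    tol = max(2, int(0.02 * mode))
    support = int(np.sum((sel >= mode - tol) & (sel <= mode + tol)))
    return mode, support


def detect_periodicity(
    window: str,
    k: int = 13,
    period_range: tuple[int, int] = (10, 3000),
    min_support: int = 5,
    null_factor: float = 3.0,
    rng: Optional[np.random.Generator] = None,
) -> Optional[int]:
    """Modal spacing of repeated k-mers, if supported well above a
    shuffled-sequence null; None otherwise."""
    if len(window) < 2 * period_range[1]:
        period_range = (period_range[0], max(period_range[0], len(window) // 2))
    codes = encode_dna(window)
    res = _modal_period(_recurrence_distances(codes, k), period_range)
    if res is None:
        return None
    mode, support = res
    if support < min_support:
        return None
    if rng is None:
        rng = np.random.default_rng(0)
    shuffled = codes[rng.permutation(len(codes))]
    null = _modal_period(_recurrence_distances(shuffled, k), period_range)
    null_support = null[1] if null is not None else 0
    if support < null_factor * max(1, null_support):
        return None
    return mode


# ---------------------------------------------------------------------------
# Array segmentation


def _support_extent(codes: np.ndarray, k: int, period: int) -> list[tuple[int, int]]:
    """Window-offset extents of k-mers recurring at ~ the given period, as
    one (lo, hi) interval per positional cluster so two arrays separated by
    unique sequence inside one window yield two extents."""
    kc = kmer_codes(codes, k)
    valid = kc >= 0
    if valid.sum() < 2:
        return []
    order = np.argsort(kc[valid], kind="stable")
    pos = np.nonzero(valid)[0][order]
    vals = kc[valid][order]
    same = vals[1:] == vals[:-1]
    d = pos[1:] - pos[:-1]
    tol = max(2, int(0.02 * period))
    keep = same & (np.abs(d - period) <= tol)
    if keep.sum() == 0:
        return []
    support = np.unique(np.concatenate([pos[:-1][keep], pos[1:][keep]]))
    split = max(int(2.5 * period), 600)
    extents = []
    start = prev = int(support[0])
    for p in support[1:]:
        p = int(p)
        if p - prev > split:
            extents.append((start, prev + k))
            start = p
        prev = p
    extents.append((start, prev + k))
    return [(lo, hi) for lo, hi in extents if hi - lo >= 2 * period - 2 * tol]


def segment_arrays(
    genome: dict[str, str],
    period_range: tuple[int, int] = (10, 3000),
    k: int = 13,
    min_support: int = 5,
    null_factor: float = 3.0,
    source_round: int = 1,
    seed: int = 0,
) -> list[ArrayCall]:
    """Maximal consistent-period windows over all scaffolds, merged when
    adjacent with periods within 10%, with extents tightened to the
    period-supporting k-mer span."""
    rng = np.random.default_rng(seed)
    pmin, pmax = period_range
    window = max(6000, 4 * pmax)
    step = window // 2
    calls: list[ArrayCall] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        raw: list[tuple[int, int, int]] = []  # start0, end0(excl), period
        for w_start in range(0, max(1, len(seq) - k), step):
            sub = seq[w_start : w_start + window]
            if len(sub) < 4 * pmin:
                continue
            period = detect_periodicity(sub, k, (pmin, min(pmax, len(sub) // 2)),
                                        min_support, null_factor, rng)
            if period is None:
                continue
            for lo, hi in _support_extent(encode_dna(sub), k, period):
                raw.append((w_start + lo, w_start + hi, period))
        raw.sort()
        merged: list[list[int]] = []
        for s, e, p in raw:
            if merged and s <= merged[-1][1] + step // 4 and abs(p - merged[-1][2]) <= 0.1 * max(p, merged[-1][2]):
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = min(p, merged[-1][2])
            else:
                merged.append([s, e, p])
        for s, e, p in merged:
            s = max(0, s)
            e = min(len(seq), e)
            if e - s < 2 * p:
                continue
            calls.append(ArrayCall(chrom, s + 1, e, p, (e - s) // p, source_round))
    return calls


def run_rounds(
    genome: dict[str, str],
    rounds: list[tuple[int, int]] = DEFAULT_ROUND_RANGES,
    k: int = 13,
    seed: int = 0,
) -> list[ArrayCall]:
    """Multi-round detection with increasing period ranges; regions called in
    one round are hard-masked (N) before the next."""
    work = dict(genome)
    all_calls: list[ArrayCall] = []
    for rnd, prange in enumerate(rounds, start=1):
        calls = segment_arrays(work, prange, k=k, source_round=rnd, seed=seed + rnd)
        all_calls.extend(calls)
        if rnd < len(rounds):
            masked: dict[str, np.ndarray] = {}
            for call in calls:
                if call.chromosome not in masked:
                    masked[call.chromosome] = np.frombuffer(
                        work[call.chromosome].encode(), dtype=np.uint8
                    ).copy()
                masked[call.chromosome][call.start - 1 : call.end] = ord("N")
            for chrom, arr in masked.items():
                work[chrom] = arr.tobytes().decode("ascii")
    return all_calls


# ---------------------------------------------------------------------------
# Monomer extraction, re-orientation, consensus


def _best_rotation(unit: np.ndarray, ref: np.ndarray) -> int:
    """Rotation of ``unit`` minimizing Hamming distance to ``ref``."""
    p = len(ref)
    doubled = np.concatenate([unit, unit])
    windows = np.lib.stride_tricks.sliding_window_view(doubled, p)[: len(unit)]
    dists = np.sum(windows != ref[None, :], axis=1)
    return int(np.argmin(dists))


def extract_monomers(call: ArrayCall, genome: dict[str, str]) -> list[str]:
    """Cut the called span into period-length units, rotating each one to
    the phase of the first unit (absorbs indel drift across the array)."""
    seq = genome[call.chromosome][call.start - 1 : call.end]
    p = call.period
    units = [seq[i : i + p] for i in range(0, len(seq) - p + 1, p)]
    if not units:
        return []
    ref = encode_dna(units[0])
    out = []
    for u in units:
        cu = encode_dna(u)
        r = _best_rotation(cu, ref)
        out.append(u[r:] + u[:r])
    return out


def _kmer_multiset(seq: str, k: int) -> Counter:
    c: Counter = Counter()
    n = len(seq)
    for i in range(n - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            c[km] += 1
    return c


def reorient_monomers(monomers: list[str], k: int = 7) -> list[str]:
    """Standardize strand: each monomer keeps the orientation sharing more
    k-mers with the running aggregate profile (ties, including perfect
    palindromes, break toward the lexicographically smaller sequence)."""
    profile: Counter = Counter()
    out = []
    for mono in monomers:
        rc = revcomp(mono)
        fwd_k = _kmer_multiset(mono, k)
        rev_k = _kmer_multiset(rc, k)
        fwd_score = sum(min(v, profile[km]) for km, v in fwd_k.items())
        rev_score = sum(min(v, profile[km]) for km, v in rev_k.items())
        if fwd_score > rev_score:
            keep = mono
        elif rev_score > fwd_score:
            keep = rc
        else:
            keep = min(mono, rc)
        out.append(keep)
        profile.update(_kmer_multiset(keep, k))
    return out


def build_consensus(
    monomers: list[str],
    k: int = 7,
    candidate_id: str = "cand",
    source_round: int = 1,
    source_detector: str = "satellome",
    assembly: str = "asm",
    max_medoid_sample: int = 25,
) -> ConsensusCandidate:
    """Column-wise majority consensus over monomers phase-aligned to the
    medoid, scored by k-mer coverage: the fraction of all monomer k-mer
    occurrences whose k-mer also appears in the consensus."""
    if not monomers:
        raise ValueError("no monomers to build a consensus from")
    coded = [encode_dna(m) for m in monomers]
    p = int(np.median([len(c) for c in coded]))
    sample = [c for c in coded if len(c) == p][:max_medoid_sample] or [coded[0]]
    p = len(sample[0])
    best_i, best_d = 0, np.inf
    for i, ci in enumerate(sample):
        d = sum(np.sum(ci != np.concatenate([cj[r:], cj[:r]])[: len(ci)])
                for cj in sample
                for r in (_best_rotation(cj, ci),))
        if d < best_d:
            best_i, best_d = i, d
    medoid = sample[best_i]
    # column votes from local alignment of each unit against the doubled
    # medoid: rotation- and indel-tolerant, unlike a plain rotation vote
    doubled = np.concatenate([medoid, medoid])
    votes = np.zeros((p, 4), dtype=np.int64)
    params = AlignmentParams()
    for cu in coded:
        res = align_column_pairs(cu, doubled, params)
        if res is None:
            continue
        _score, qi, sj = res
        bases = cu[qi]
        ok = bases < 4
        np.add.at(votes, (sj[ok] % p, bases[ok]), 1)
    consensus_codes = np.where(votes.sum(axis=1) > 0, np.argmax(votes, axis=1),
                               medoid).astype(np.uint8)
    consensus = decode_dna(consensus_codes)
    total = 0
    covered = 0
    cons_kmers = set()
    for i in range(len(consensus) - k + 1):
        cons_kmers.add(consensus[i : i + k])
    for m in monomers:
        for i in range(len(m) - k + 1):
            km = m[i : i + k]
            if "N" in km:
                continue
            total += 1
            if km in cons_kmers:
                covered += 1
    kcov = covered / total if total else 0.0
    return ConsensusCandidate(candidate_id, consensus, kcov, source_round,
                              source_detector, assembly)


def calls_to_bed(calls: list[ArrayCall]) -> str:
    """BED (0-based half-open) serialization of array calls."""
    lines = [
        f"{c.chromosome}\t{c.start - 1}\t{c.end}\tperiod={c.period};round={c.source_round}\t{c.n_copies_est}\t+"
        for c in calls
    ]
    return "\n".join(lines) + ("\n" if lines else "")
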