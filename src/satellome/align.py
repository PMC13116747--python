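"""Local pairwise alignment and hit scanning.

Self-contained engine behind every similarity screen in the package: an
affine-gap Smith-Waterman/Gotoh aligner with full traceback (numba-jitted),
a seed-and-extend scanner for monomer-vs-chromosome/read searches, and
Karlin-Altschul E-values so hits can be admitted with the usual
E-value / identity / query-coverage thresholds.

Scoring defaults are +1 match / -2 mismatch with affine gaps costing
``gap_open + gap_extend * length`` (open 5, extend 2).  The default Karlin
constants (lambda = 1.28, K = 0.46) are the published ungapped values for
the +1/-2 nucleotide scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Sequence coding

_DNA_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _DNA_CODE[ord(_b)] = _i
    _DNA_CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_dna(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; anything else (incl. N) as 4."""
    return _DNA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_dna(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    codes = encode_dna(seq)
    acgt = int(np.sum(codes < 4))
    if acgt == 0:
        return 0.0
    return int(np.sum((codes == 1) | (codes == 2))) / acgt


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer codes along a coded sequence; -1 where a window
    contains an ambiguous base.  Length = len(codes) - k + 1."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    out = np.zeros(n - k + 1, dtype=np.int64)
    for i in range(k):
        out = (out << 2) | (c[i : n - k + 1 + i] & 3)
    bad = (codes >= 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    invalid = (cs[k:] - cs[:-k]) > 0
    out[invalid] = -1
    return out


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and statistics parameters for the local aligner."""

    match_score: int = 1
    mismatch_penalty: int = 2
    gap_open: int = 5
    gap_extend: int = 2
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46
    seed_kmer: int = 11

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.seed_kmer < 5:
            raise ValueError("seed_kmer must be >= 5")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin parameters must be positive")


@dataclass
class AlignmentHit:
    """One local similarity match; 1-based inclusive coordinates, subject
    coordinates always on the forward strand."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity_pct: float
    query_coverage_pct: float
    score: int
    evalue: float
    align_len: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("start must not exceed end")
        if not (0 <= self.identity_pct <= 100 and 0 <= self.query_coverage_pct <= 100):
            raise ValueError("percentages must lie in [0, 100]")


@dataclass(frozen=True)
class HitThresholds:
    max_evalue: float = 1e-5
    min_identity_pct: float = 70.0
    min_query_coverage_pct: float = 70.0
    max_hits: int = 10_000_000

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity_pct <= 100 and 0 <= self.min_query_coverage_pct <= 100):
            raise ValueError("percentages must lie in [0, 100]")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")

    def admits(self, hit: "AlignmentHit") -> bool:
        return (
            hit.evalue <= self.max_evalue
            and hit.identity_pct >= self.min_identity_pct
            and hit.query_coverage_pct >= self.min_query_coverage_pct
        )


def bitscore(score: int, params: AlignmentParams) -> float:
    """Normalized (bit) score, (lambda*S - ln K) / ln 2."""
    return (params.karlin_lambda * score - np.log(params.karlin_k)) / np.log(2.0)


def estimate_evalue(score: int, m: int, n: int, params: AlignmentParams) -> float:
    """Karlin-Altschul expected hit count K*m*n*exp(-lambda*score)."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return float(params.karlin_k * m * n * np.exp(-params.karlin_lambda * score))


# ---------------------------------------------------------------------------
# Gotoh local alignment with traceback (numba)

# pointer packing: bits 0-1 H-source (0 stop, 1 diag, 2 from E, 3 from F),
# bit 2 E extended, bit 3 F extended


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend, ambig):  # pragma: no cover
    m = a.shape[0]
    n = b.shape[0]
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    h_prev = np.zeros(n + 1, dtype=np.int64)
    h_cur = np.zeros(n + 1, dtype=np.int64)
    f_row = np.full(n + 1, -(1 << 60), dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    neg = -(1 << 60)
    for i in range(1, m + 1):
        e = neg
        h_cur[0] = 0
        ai = a[i - 1]
        for j in range(1, n + 1):
            # E: gap in b consumed along query? E = gap in subject direction
            e_open = h_cur[j - 1] - gap_open - gap_extend
            e_ext = e - gap_extend
            if e_ext > e_open:
                e = e_ext
                pe = 4
            else:
                e = e_open
                pe = 0
            f_open = h_prev[j] - gap_open - gap_extend
            f_ext = f_row[j] - gap_extend
            if f_ext > f_open:
                f = f_ext
                pf = 8
            else:
                f = f_open
                pf = 0
            f_row[j] = f
            bj_code = b[j - 1]
            if ai == bj_code and ai < ambig:
                diag = h_prev[j - 1] + match
            else:
                diag = h_prev[j - 1] - mismatch
            h = 0
            ph = 0
            if diag > h:
                h = diag
                ph = 1
            if e > h:
                h = e
                ph = 2
            if f > h:
                h = f
                ph = 3
            h_cur[j] = h
            ptr[i, j] = ph | pe | pf
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    return best, bi, bj, ptr


@njit(cache=True)
def _traceback(a, b, ptr, bi, bj, ambig):  # pragma: no cover
    i = bi
    j = bj
    matches = 0
    mismatches = 0
    gap_opens = 0
    columns = 0
    while i > 0 and j > 0:
        p = ptr[i, j]
        ph = p & 3
        if ph == 0:
            break
        if ph == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] < ambig:
                matches += 1
            else:
                mismatches += 1
            columns += 1
            i -= 1
            j -= 1
        elif ph == 2:
            # gap run along subject (query unchanged)
            gap_opens += 1
            while True:
                columns += 1
                ext = ptr[i, j] & 4
                j -= 1
                if ext == 0:
                    break
        else:
            gap_opens += 1
            while True:
                columns += 1
                ext = ptr[i, j] & 8
                i -= 1
                if ext == 0:
                    break
    return i, j, matches, mismatches, gap_opens, columns


@njit(cache=True)
def _traceback_pairs(a, b, ptr, bi, bj):  # pragma: no cover
    """Aligned (query index, subject index) pairs of the optimal path,
    diagonal steps only, in left-to-right order."""
    cap = a.shape[0] + b.shape[0]
    qi = np.empty(cap, dtype=np.int64)
    sj = np.empty(cap, dtype=np.int64)
    k = 0
    i = bi
    j = bj
    while i > 0 and j > 0:
        p = ptr[i, j]
        ph = p & 3
        if ph == 0:
            break
        if ph == 1:
            qi[k] = i - 1
            sj[k] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif ph == 2:
            while True:
                ext = ptr[i, j] & 4
                j -= 1
                if ext == 0:
                    break
        else:
            while True:
                ext = ptr[i, j] & 8
                i -= 1
                if ext == 0:
                    break
    return qi[:k][::-1].copy(), sj[:k][::-1].copy()


def align_column_pairs(a: np.ndarray, b: np.ndarray, params: AlignmentParams,
                       ambig: int = 4):
    """Best local alignment of coded sequences as (score, query_idx,
    subject_idx) arrays over the aligned (diagonal) columns; None when the
    best score is <= 0."""
    score, bi, bj, ptr = _gotoh_fill(
        a, b, params.match_score, params.mismatch_penalty,
        params.gap_open, params.gap_extend, ambig,
    )
    if score <= 0:
        return None
    qi, sj = _traceback_pairs(a, b, ptr, bi, bj)
    return int(score), qi, sj


def _align_codes(a: np.ndarray, b: np.ndarray, params: AlignmentParams, ambig: int = 4):
    """Best local alignment of coded sequences (codes >= ``ambig`` never
    match).  Returns None if best <= 0, else (score, qs, qe, ss, se,
    matches, mismatches, gap_opens, columns), 0-based inclusive."""
    score, bi, bj, ptr = _gotoh_fill(
        a,
        b,
        params.match_score,
        params.mismatch_penalty,
        params.gap_open,
        params.gap_extend,
        ambig,
    )
    if score <= 0:
        return None
    i0, j0, matches, mismatches, gap_opens, columns = _traceback(a, b, ptr, bi, bj, ambig)
    return int(score), i0, bi - 1, j0, bj - 1, int(matches), int(mismatches), int(gap_opens), int(columns)


def _validate_dna(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")


def local_align(
    a: str,
    b: str,
    params: AlignmentParams = AlignmentParams(),
    query_id: str = "query",
    subject_id: str = "subject",
    search_space_n: Optional[int] = None,
) -> Optional[AlignmentHit]:
    """Maximum-scoring local alignment of ``a`` against both strands of ``b``.

    Returns None when the best score is <= 0.  Subject coordinates are
    reported on the forward strand of ``b``; ``strand`` is '-' when the
    reverse complement of ``b`` scored best (forward wins ties).
    """
    _validate_dna(a, "query")
    _validate_dna(b, "subject")
    ca = encode_dna(a)
    cb = encode_dna(b)
    fwd = _align_codes(ca, cb, params)
    rev = _align_codes(ca, encode_dna(revcomp(b)), params)
    if fwd is None and rev is None:
        return None
    use_rev = rev is not None and (fwd is None or rev[0] > fwd[0])
    res = rev if use_rev else fwd
    score, qs, qe, ss, se, matches, mismatches, gap_opens, columns = res
    if use_rev:
        n = len(b)
        ss, se = n - 1 - se, n - 1 - ss
    nn = search_space_n if search_space_n is not None else len(b)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        q_start=qs + 1,
        q_end=qe + 1,
        s_start=ss + 1,
        s_end=se + 1,
        strand="-" if use_rev else "+",
        identity_pct=100.0 * matches / columns if columns else 0.0,
        query_coverage_pct=100.0 * (qe - qs + 1) / len(a),
        score=score,
        evalue=estimate_evalue(score, len(a), nn, params),
        align_len=columns,
        mismatches=mismatches,
        gap_opens=gap_opens,
    )


# ---------------------------------------------------------------------------
# Seed-and-extend scanning


def _candidate_loci(
    query_codes: np.ndarray,
    rc_query_codes: np.ndarray,
    subject_codes: np.ndarray,
    k: int,
    qlen: int,
) -> list[tuple[int, int, int, int]]:
    """Subject intervals (0-based half-open) sharing seed k-mers with the
    query, with per-locus counts of forward- and reverse-strand seed
    matches.  Isolated chance matches (fewer than a query-length-dependent
    floor per locus) are dropped."""
    qk = kmer_codes(query_codes, k)
    rq = kmer_codes(rc_query_codes, k)
    fwd_set = np.unique(qk[qk >= 0])
    rev_set = np.unique(rq[rq >= 0])
    seeds = np.union1d(fwd_set, rev_set)
    if len(seeds) == 0:
        return []
    sk = kmer_codes(subject_codes, k)
    pos = np.nonzero(np.isin(sk, seeds))[0]
    if len(pos) == 0:
        return []
    is_fwd = np.isin(sk[pos], fwd_set)
    is_rev = np.isin(sk[pos], rev_set)
    # chance matches for long queries are frequent enough to chain at a
    # query-length gap; cluster tighter and require real support
    gap = max(4 * k, min(qlen, 250))
    pad = max(qlen // 4, 2 * k)
    # a genuine copy at the 70%-identity admission floor still shares
    # ~0.7^k of its k-mers (~2% at k=11); chance clusters stay in the
    # low single digits
    min_matches = max(2, min(30, qlen // 100))
    loci: list[tuple[int, int, int, int]] = []
    start_i = 0
    for i in range(1, len(pos) + 1):
        if i == len(pos) or pos[i] - pos[i - 1] > gap:
            nf = int(is_fwd[start_i:i].sum())
            nr = int(is_rev[start_i:i].sum())
            if nf + nr >= min_matches:
                loci.append(
                    (max(0, int(pos[start_i]) - pad),
                     min(len(subject_codes), int(pos[i - 1]) + k + pad),
                     nf, nr)
                )
            start_i = i
    # merge adjacent admitted loci separated by less than a query length
    merged: list[list[int]] = []
    for lo, hi, nf, nr in loci:
        if merged and lo - merged[-1][1] <= qlen:
            merged[-1][1] = hi
            merged[-1][2] += nf
            merged[-1][3] += nr
        else:
            merged.append([lo, hi, nf, nr])
    return [tuple(x) for x in merged]


def _collapse_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Greedy non-redundancy: same-strand hits overlapping by >50% of the
    shorter are collapsed, keeping the higher score."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda x: (-x.score, x.s_start)):
        redundant = False
        for g in kept:
            if g.strand != h.strand:
                continue
            ov = min(g.s_end, h.s_end) - max(g.s_start, h.s_start) + 1
            if ov <= 0:
                continue
            shorter = min(g.s_end - g.s_start + 1, h.s_end - h.s_start + 1)
            if ov > 0.5 * shorter:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda x: (x.s_start, x.s_end))
    return kept


def scan_hits(
    query: str,
    subject: str,
    params: AlignmentParams = AlignmentParams(),
    thresholds: HitThresholds = HitThresholds(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[AlignmentHit]:
    """All threshold-passing local hits of ``query`` on both strands of
    ``subject`` (chromosome- or read-scale), non-redundant, sorted by
    subject position.

    Seed k-mer matches are clustered into candidate loci; within a locus a
    cursor tiles successive alignments so each monomer copy of a tandem
    array yields one hit.
    """
    _validate_dna(query, "query")
    _validate_dna(subject, "subject")
    qc = encode_dna(query)
    qc_rc = encode_dna(revcomp(query))
    sc = encode_dna(subject)
    qlen = len(query)
    n = len(subject)
    hits: list[AlignmentHit] = []
    window_len = qlen + qlen // 2 + 80
    segments = [
        (lo, hi, nf > 0 or nr == 0, nr > 0)
        for lo, hi, nf, nr in _candidate_loci(qc, qc_rc, sc, params.seed_kmer, qlen)
    ]
    while segments:
        lo, hi, try_fwd, try_rev = segments.pop()
        cur = lo
        while cur < hi:
            w_end = min(hi, cur + window_len)
            if w_end - cur < params.seed_kmer:
                break
            window = sc[cur:w_end]
            best = None
            best_rev = False
            if try_fwd:
                best = _align_codes(qc, window, params)
            if try_rev:
                res = _align_codes(qc_rc, window, params)
                if res is not None and (best is None or res[0] > best[0]):
                    best = res
                    best_rev = True
            hit = None
            if best is not None:
                score, qs, qe, ss, se, matches, mismatches, gap_opens, columns = best
                if best_rev:
                    qs, qe = qlen - 1 - qe, qlen - 1 - qs
                hit = AlignmentHit(
                    query_id=query_id, subject_id=subject_id,
                    q_start=qs + 1, q_end=qe + 1,
                    s_start=cur + ss + 1, s_end=cur + se + 1,
                    strand="-" if best_rev else "+",
                    identity_pct=100.0 * matches / columns if columns else 0.0,
                    query_coverage_pct=100.0 * (qe - qs + 1) / qlen,
                    score=score,
                    evalue=estimate_evalue(score, qlen, n, params),
                    align_len=columns, mismatches=mismatches, gap_opens=gap_opens,
                )
            if hit is not None and thresholds.admits(hit):
                hits.append(hit)
                # the best window alignment may not be the leftmost copy in a
                # mutated tandem array; rescan any skipped stretch wide enough
                # to hold another copy
                if hit.s_start - 1 - cur >= 0.5 * qlen:
                    segments.append((cur, hit.s_start - 1, try_fwd, try_rev))
                cur = hit.s_end  # 1-based inclusive end == next 0-based start
            else:
                if w_end >= hi:
                    break
                cur = w_end - qlen  # overlap so boundary-straddling copies survive
    hits = _collapse_hits(hits)
    return hits[: thresholds.max_hits]


def pairwise_identity_circular(
    a: str, b: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Identity (%) of the best local alignment of monomer ``a`` against the
    doubled monomer ``b`` (both strands), making the comparison invariant to
    the arbitrary rotation of tandem-repeat consensuses."""
    _validate_dna(a, "a")
    _validate_dna(b, "b")
    hit = local_align(a, b + b, params)
    return hit.identity_pct if hit is not None else 0.0


def circular_best_hit(
    a: str, b: str, params: AlignmentParams = AlignmentParams()
) -> Optional[AlignmentHit]:
    """Best rotation-invariant local alignment of ``a`` vs doubled ``b``."""
    return local_align(a, b + b, params)


# ---------------------------------------------------------------------------
# Protein-space alignment (contaminant screens)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODE = np.full(256, 25, dtype=np.uint8)
for _i, _c in enumerate(_AA):
    _AA_CODE[ord(_c)] = _i


def encode_protein(seq: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def local_align_protein(
    a: str, b: str, params: AlignmentParams = AlignmentParams()
) -> Optional[tuple[int, int, int, int, int, float]]:
    """Local alignment of two protein sequences with identity scoring.
    Returns (score, qs, qe, ss, se, identity_pct), 1-based inclusive,
    or None when the best score is <= 0."""
    if not a or not b:
        raise ValueError("empty protein sequence")
    res = _align_codes(encode_protein(a), encode_protein(b), params, ambig=25)
    if res is None:
        return None
    score, qs, qe, ss, se, matches, mismatches, gap_opens, columns = res
    ident = 100.0 * matches / columns if columns else 0.0
    return score, qs + 1, qe + 1, ss + 1, se + 1, ident


# ---------------------------------------------------------------------------
# Tabular export


def hits_to_tabular(hits: Iterable[AlignmentHit]) -> str:
    """12-column tab-separated text in the classic tabular-alignment layout:
    query, subject, identity, length, mismatches, gapopens, qstart, qend,
    sstart, send, evalue, score."""
    lines = []
    for h in hits:
        ss, se = (h.s_start, h.s_end) if h.strand == "+" else (h.s_end, h.s_start)
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.identity_pct:.2f}",
                    str(h.align_len),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.q_start),
                    str(h.q_end),
                    str(ss),
                    str(se),
                    f"{h.evalue:.2e}",
                    str(h.score),
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
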