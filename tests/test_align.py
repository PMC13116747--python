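"""Alignment engine: DP-oracle equivalence, E-values, scanning, rotation."""

import math

import numpy as np
import pytest

from conftest import mutate, random_dna
from satellome.align import (
    AlignmentParams,
    HitThresholds,
    estimate_evalue,
    hits_to_tabular,
    local_align,
    pairwise_identity_circular,
    revcomp,
    scan_hits,
)


def oracle_local_score(a, b, match=1, mismatch=2, go=5, ge=2):
    """Independent full-DP affine local alignment score (pure Python)."""
    m, n = len(a), len(b)
    neg = float("-inf")
    h = [[0.0] * (n + 1) for _ in range(m + 1)]
    e = [[neg] * (n + 1) for _ in range(m + 1)]
    f = [[neg] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e[i][j] = max(h[i][j - 1] - go - ge, e[i][j - 1] - ge)
            f[i][j] = max(h[i - 1][j] - go - ge, f[i - 1][j] - ge)
            s = match if a[i - 1] == b[j - 1] else -mismatch
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return int(best)


class TestLocalAlign:
    def test_identical_sequences(self, params):
        seq = "ACGTACGTACGTACGTACGT"
        hit = local_align(seq, seq, params)
        assert hit.identity_pct == 100.0
        assert hit.query_coverage_pct == 100.0
        assert hit.score == len(seq)

    def test_reverse_complement_detected(self, params, rng):
        a = random_dna(40, rng)
        hit = local_align(a, revcomp(a), params)
        assert hit.strand == "-"
        assert hit.identity_pct == 100.0
        assert (hit.q_start, hit.q_end) == (1, 40)
        assert (hit.s_start, hit.s_end) == (1, 40)

    def test_empty_sequence_rejected(self, params):
        with pytest.raises(ValueError):
            local_align("", "ACGT", params)

    def test_score_matches_full_dp_oracle(self, params, rng):
        """Engine score equals an exhaustive affine DP on >=100 random pairs
        of short sequences, including both-strand search."""
        for _ in range(120):
            a = random_dna(int(rng.integers(5, 51)), rng)
            b = random_dna(int(rng.integers(5, 51)), rng)
            expected = max(oracle_local_score(a, b), oracle_local_score(a, revcomp(b)))
            hit = local_align(a, b, params)
            got = hit.score if hit is not None else 0
            assert got == expected, (a, b)

    def test_returned_coordinates_within_bounds(self, params, rng):
        for _ in range(30):
            a = random_dna(30, rng)
            b = random_dna(60, rng)
            hit = local_align(a, b, params)
            if hit is None:
                continue
            assert 1 <= hit.q_start <= hit.q_end <= len(a)
            assert 1 <= hit.s_start <= hit.s_end <= len(b)


class TestEvalue:
    def test_monotone_decreasing_in_score(self, params):
        e1 = estimate_evalue(20, 100, 10_000, params)
        e2 = estimate_evalue(30, 100, 10_000, params)
        assert e2 < e1

    def test_hand_evaluated_closed_form(self):
        """K*m*n*exp(-lambda*S) at (50, 100, 1e6, 0.267, 0.041)."""
        p = AlignmentParams(karlin_lambda=0.267, karlin_k=0.041)
        expected = 0.041 * 100 * 1e6 * math.exp(-0.267 * 50)
        assert estimate_evalue(50, 100, 10**6, p) == pytest.approx(expected, rel=1e-6)

    def test_zero_score_limit(self, params):
        assert estimate_evalue(0, 50, 1000, params) == pytest.approx(
            params.karlin_k * 50 * 1000
        )

    def test_negative_score_rejected(self, params):
        with pytest.raises(ValueError):
            estimate_evalue(-1, 10, 10, params)


class TestScanHits:
    def test_three_planted_copies_found(self, params, rng):
        mon = random_dna(200, rng)
        bg = random_dna(50_000, rng)
        subject = bg[:10_000] + mon + bg[10_000:25_000] + mon + bg[25_000:40_000] + mon + bg[40_000:]
        hits = scan_hits(mon, subject, params, HitThresholds())
        starts = [h.s_start for h in hits]
        assert starts == [10_001, 25_201, 40_401]
        assert all(h.identity_pct == 100.0 for h in hits)

    def test_no_shared_seed_empty(self, params):
        query = "A" * 30
        subject = "C" * 1000
        assert scan_hits(query, subject, params, HitThresholds()) == []

    def test_planted_rc_copy_minus_strand(self, params, rng):
        mon = random_dna(200, rng)
        bg = random_dna(20_000, rng)
        subject = bg[:8000] + revcomp(mon) + bg[8000:]
        hits = scan_hits(mon, subject, params, HitThresholds())
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].s_start == 8001

    def test_mirror_coordinates_on_rc_subject(self, params, rng):
        mon = random_dna(150, rng)
        bg = random_dna(12_000, rng)
        subject = bg[:3000] + mon + bg[3000:8000] + revcomp(mon) + bg[8000:]
        fwd = scan_hits(mon, subject, params, HitThresholds())
        rev = scan_hits(mon, revcomp(subject), params, HitThresholds())
        n = len(subject)
        mirrored = sorted((n - h.s_end + 1, n - h.s_start + 1) for h in rev)
        assert sorted((h.s_start, h.s_end) for h in fwd) == mirrored
        assert sorted(h.strand for h in fwd) == sorted(
            "+" if s == "-" else "-" for s in (h.strand for h in rev)
        )

    def test_every_hit_satisfies_thresholds(self, params, rng):
        thr = HitThresholds(max_evalue=1e-5, min_identity_pct=80,
                            min_query_coverage_pct=80)
        mon = random_dna(120, rng)
        array = "".join(mutate(mon, 0.05, rng) for _ in range(15))
        subject = random_dna(5000, rng) + array + random_dna(5000, rng)
        hits = scan_hits(mon, subject, params, thr)
        assert hits, "planted array must be found"
        for h in hits:
            assert h.evalue <= thr.max_evalue
            assert h.identity_pct >= thr.min_identity_pct
            assert h.query_coverage_pct >= thr.min_query_coverage_pct

    def test_tandem_array_hit_count(self, params, rng):
        mon = random_dna(100, rng)
        array = "".join(mutate(mon, 0.03, rng) for _ in range(40))
        subject = random_dna(4000, rng) + array + random_dna(4000, rng)
        hits = scan_hits(mon, subject, params, HitThresholds())
        assert 38 <= len(hits) <= 42

    def test_max_hits_cap(self, params, rng):
        mon = random_dna(60, rng)
        subject = random_dna(1000, rng) + mon * 20 + random_dna(1000, rng)
        hits = scan_hits(mon, subject, params, HitThresholds(max_hits=5))
        assert len(hits) == 5


class TestCircularIdentity:
    def test_rotation_invariance(self, params, rng):
        a = random_dna(200, rng)
        assert pairwise_identity_circular(a, a[37:] + a[:37], params) == 100.0

    def test_mutated_monomer_identity_range(self, params, rng):
        for _ in range(5):
            a = random_dna(200, rng)
            b = mutate(a, 0.10, rng)
            ident = pairwise_identity_circular(a, b, params)
            assert 85.0 <= ident <= 95.0

    def test_symmetry_within_one_point(self, params, rng):
        a = random_dna(150, rng)
        b = mutate(a[60:] + a[:60], 0.05, rng)
        ab = pairwise_identity_circular(a, b, params)
        ba = pairwise_identity_circular(b, a, params)
        assert abs(ab - ba) <= 1.0

    def test_unrelated_monomers_low_coverage(self, params, rng):
        from satellome.align import circular_best_hit

        a, b = random_dna(200, rng), random_dna(200, rng)
        hit = circular_best_hit(a, b, params)
        if hit is not None:
            assert hit.query_coverage_pct < 50.0


def test_tabular_export_is_twelve_columns(params, rng):
    mon = random_dna(100, rng)
    subject = random_dna(2000, rng) + mon + random_dna(2000, rng)
    hits = scan_hits(mon, subject, params, HitThresholds())
    text = hits_to_tabular(hits)
    rows = [line.split("\t") for line in text.strip().split("\n")]
    assert all(len(r) == 12 for r in rows)
    assert rows[0][6] == "1"  # qstart
    assert float(rows[0][2]) == 100.0
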