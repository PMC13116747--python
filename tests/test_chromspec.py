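"""Chromosome specificity: counting, correspondence analysis, Mahalanobis."""

import numpy as np
import pytest

from conftest import mutate, random_dna
from satellome.chromspec import (
    CAResult,
    ChromosomeProfile,
    anchored_fraction,
    call_pcn_and_specificity,
    correspondence_analysis,
    count_hits_per_chromosome,
    mahalanobis_from_origin,
)
from satellome.curate import SatFamily
from satellome.simulate import FamilySpec, build_genome


def profile(family, counts, unplaced=0):
    return ChromosomeProfile(family, counts, unplaced)


def independent_ca(x, n_dims=2):
    """Independent CA of an already log-transformed matrix: standardized
    residuals + SVD, written from the textbook formulas."""
    import scipy.linalg

    p = x / x.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sig, vt = scipy.linalg.svd(s, full_matrices=False)
    return (u[:, :n_dims] * sig[:n_dims]) / np.sqrt(r)[:, None]


class TestCountHits:
    def test_family_on_one_chromosome_plus_unplaced(self, rng):
        spec = FamilySpec("fam", 150, 0.4, {"chr3": 60}, unplaced_copies=20,
                          substitution_rate=0.0)
        genome, truth = build_genome(
            [spec], {"chr1": 40_000, "chr2": 40_000, "chr3": 60_000}, seed=2
        )
        fam = SatFamily("fam", truth.true_monomers["fam"])
        prof = count_hits_per_chromosome(fam, genome)
        assert prof.counts["chr3"] > 0
        assert prof.counts["chr1"] == prof.counts["chr2"] == 0
        assert prof.unplaced_count > 0
        assert not prof.fully_anchored

    def test_absent_family_all_zero(self, rng):
        genome = {"chr1": random_dna(30_000, rng), "chr2": random_dna(30_000, rng)}
        fam = SatFamily("x", random_dna(200, rng))
        prof = count_hits_per_chromosome(fam, genome)
        assert not any(prof.counts.values()) and prof.unplaced_count == 0

    def test_copy_ratios_recovered_without_mutation(self, rng):
        spec = FamilySpec("fam", 120, 0.4, {"chr1": 40, "chr2": 80},
                          substitution_rate=0.0)
        genome, truth = build_genome([spec], {"chr1": 40_000, "chr2": 40_000}, seed=5)
        fam = SatFamily("fam", truth.true_monomers["fam"])
        prof = count_hits_per_chromosome(fam, genome)
        assert abs(prof.counts["chr1"] - 40) <= 4
        assert abs(prof.counts["chr2"] - 80) <= 8


class TestCorrespondenceAnalysis:
    def test_average_profile_maps_to_origin(self):
        """A family whose ln(1+x) profile is proportional to the column
        totals sits at the CA origin."""
        others = np.array([[5.0, 1.0, 0.5, 2.0],
                           [0.5, 6.0, 2.0, 1.0],
                           [1.0, 0.5, 7.0, 3.0]])
        centroid = 0.4 * others.sum(axis=0)  # stays ∝ totals once added
        transformed = np.vstack([others, centroid])
        raw = np.expm1(transformed)
        profs = [profile(f"f{i}", dict(zip("abcd", row))) for i, row in enumerate(raw)]
        ca = correspondence_analysis(profs)
        assert np.allclose(ca.row_coordinates[3], 0.0, atol=1e-9)
        assert not np.allclose(ca.row_coordinates[0], 0.0, atol=1e-6)

    def test_toy_matrix_matches_independent_svd(self):
        raw = np.expm1(np.array([[5.0, 1.0, 0.2], [1.0, 6.0, 1.0], [0.3, 1.0, 7.0]]))
        profs = [profile(f"f{i}", dict(zip("abc", row))) for i, row in enumerate(raw)]
        ca = correspondence_analysis(profs)
        expected = independent_ca(np.log1p(raw))
        for d in range(2):
            col = ca.row_coordinates[:, d]
            ref = expected[:, d]
            assert np.allclose(col, ref, atol=1e-9) or np.allclose(col, -ref, atol=1e-9)

    def test_duplicated_row_identical_coordinates(self):
        raw = [[50, 2, 3], [50, 2, 3], [1, 40, 2], [3, 1, 60]]
        profs = [profile(f"f{i}", dict(zip("abc", row))) for i, row in enumerate(raw)]
        ca = correspondence_analysis(profs)
        assert np.allclose(ca.row_coordinates[0], ca.row_coordinates[1], atol=1e-12)

    def test_all_zero_row_dropped_with_warning(self):
        profs = [
            profile("a", {"c1": 10, "c2": 1, "c3": 2}),
            profile("zero", {"c1": 0, "c2": 0, "c3": 0}),
            profile("b", {"c1": 1, "c2": 10, "c3": 3}),
            profile("c", {"c1": 5, "c2": 5, "c3": 20}),
        ]
        with pytest.warns(UserWarning, match="zero"):
            ca = correspondence_analysis(profs)
        assert "zero" not in ca.families

    def test_reproducible_to_1e9(self):
        raw = np.random.default_rng(0).integers(0, 200, size=(6, 5)).astype(float)
        profs = [profile(f"f{i}", dict(zip("abcde", row))) for i, row in enumerate(raw)]
        c1 = correspondence_analysis(profs)
        c2 = correspondence_analysis(profs)
        assert np.allclose(c1.row_coordinates, c2.row_coordinates, atol=1e-9)

    def test_unplaced_counts_never_enter_ca(self):
        profs = [
            profile("a", {"c1": 10, "c2": 1, "c3": 4}, unplaced=10_000),
            profile("b", {"c1": 1, "c2": 10, "c3": 2}, unplaced=0),
            profile("c", {"c1": 5, "c2": 5, "c3": 30}, unplaced=3),
        ]
        ca = correspondence_analysis(profs)
        assert ca.chromosomes == ["c1", "c2", "c3"]  # no unplaced column


class TestMahalanobis:
    def make_ca(self, coords, fams=None):
        coords = np.asarray(coords, dtype=float)
        fams = fams or [f"f{i}" for i in range(len(coords))]
        return CAResult(fams, ["c1", "c2"], coords, np.zeros((2, 2)), np.zeros(2))

    def test_origin_family_distance_zero(self):
        ca = self.make_ca([[0, 0], [1, 0.5], [-1, 2], [0.5, -1], [2, 0.3]])
        d = mahalanobis_from_origin(ca)
        assert d["f0"] == 0.0

    def test_invariant_under_axis_sign_flips(self):
        coords = np.array([[1, 0.5], [-1, 2], [0.5, -1], [2, 0.3]])
        d1 = mahalanobis_from_origin(self.make_ca(coords.copy()))
        flipped = coords * np.array([-1, 1])
        d2 = mahalanobis_from_origin(self.make_ca(flipped))
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], rel=1e-12)

    def test_matches_bruteforce_covariance_inverse(self):
        coords = np.array([[1.0, 2.0], [0.5, -1.0], [-2.0, 0.3], [0.1, 0.9], [3.0, -0.7]])
        ca = self.make_ca(coords.copy())
        d = mahalanobis_from_origin(ca)
        cov = np.cov(coords, rowvar=False)
        inv = np.linalg.inv(cov)
        for i, fam in enumerate(ca.families):
            v = coords[i]
            assert d[fam] == pytest.approx(float(np.sqrt(v @ inv @ v)), rel=1e-12)

    def test_singular_covariance_uses_pinv_with_warning(self):
        coords = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0], [4.0, 0.0]])
        with pytest.warns(UserWarning, match="singular"):
            d = mahalanobis_from_origin(self.make_ca(coords))
        assert all(np.isfinite(v) for v in d.values())


class TestPCNAndSpecificity:
    def test_single_chromosome(self):
        p = profile("f", {"chr1": 0, "chr2": 0, "chr3": 100, "chr4": 0})
        pcn, strict = call_pcn_and_specificity(p)
        assert pcn == {"chr3"} and strict == "1-chromosome"

    def test_two_chromosome_peaks(self):
        p = profile("f", {"chr1": 80, "chr2": 100, "chr3": 0})
        pcn, strict = call_pcn_and_specificity(p)
        assert pcn == {"chr1", "chr2"} and strict == "2-chromosome"

    def test_uniform_counts(self):
        p = profile("f", {f"chr{i}": 50 for i in range(1, 9)})
        pcn, strict = call_pcn_and_specificity(p)
        assert len(pcn) == 8 and strict == "none"

    def test_minor_counts_below_half_peak_excluded_from_pcn(self):
        p = profile("f", {"chr1": 100, "chr2": 49, "chr3": 51})
        pcn, strict = call_pcn_and_specificity(p)
        assert pcn == {"chr1", "chr3"} and strict == "none"


class TestAnchoredFraction:
    def test_all_anchored(self):
        profs = [profile(f"f{i}", {"c": 5}) for i in range(4)]
        assert anchored_fraction(profs) == 1.0

    def test_three_of_five(self):
        profs = [profile(f"f{i}", {"c": 5}, unplaced=(10 if i < 2 else 0))
                 for i in range(5)]
        assert anchored_fraction(profs) == pytest.approx(0.6)

    def test_empty_satellitome_rejected(self):
        with pytest.raises(ValueError):
            anchored_fraction([])
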