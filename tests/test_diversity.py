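"""Diversity statistics against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from trflpkit.diversity import (
    AbundanceSummary,
    abundances_from_partition,
    bray_curtis,
    bray_curtis_matrix,
    chao1,
    classical_scaling,
    cluster_otus,
    coverage_curve,
    default_grid,
    diversity_report,
    jc_distance,
    jc_distance_matrix,
    libshuff_test,
    nmds,
    shannon,
    shared_otus,
    stress1,
)
from trflpkit.errors import DomainError, UsageError
from trflpkit.synthetic import generate_library
from trflpkit.types import SequenceRecord


class TestShannon:
    def test_uniform_is_log_n(self):
        assert shannon([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_species_zero(self):
        assert shannon([1.0]) == 0.0

    def test_direct_evaluation(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_zero_entries_contribute_nothing(self):
        assert shannon([0.5, 0.5, 0.0]) == pytest.approx(shannon([0.5, 0.5]))

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            shannon([0.5, 0.6])
        with pytest.raises(DomainError):
            shannon([1.2, -0.2])


class TestChao1:
    def test_direct_formula(self):
        # S_obs 10, n1 4, n2 2 -> 10 + 16/4
        counts = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]
        assert chao1(counts) == pytest.approx(14.0)

    def test_no_singletons_returns_s_obs(self):
        assert chao1([2, 3, 4]) == 3.0

    def test_bias_corrected_when_no_doubletons(self):
        # n1=3, n2=0: S + 3*2/2
        assert chao1([1, 1, 1, 5]) == pytest.approx(4 + 3.0)

    def test_never_below_observed_richness(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            counts = rng.integers(1, 6, size=rng.integers(2, 30))
            s = AbundanceSummary.from_counts(counts)
            assert chao1(s) >= s.s_obs


class TestJukesCantor:
    def test_identical_sequences(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p_010(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        assert jc_distance(a, b) == pytest.approx(0.1073, abs=1e-4)

    def test_saturation_flagged_via_ceiling(self):
        a = "A" * 4
        b = "CCCA"
        assert jc_distance(a, b, ceiling=2.0) == 2.0

    def test_ambiguous_positions_excluded(self):
        assert jc_distance("ANGT", "ACGT") == 0.0
        with pytest.raises(DomainError):
            jc_distance("NNNN", "ACGT")

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(UsageError):
            jc_distance("ACGT", "ACG")

    def test_matrix_matches_pairwise_scalar(self, random_records):
        records = random_records(12, length=200, seed=6)
        D = jc_distance_matrix(records)
        for i in range(12):
            for j in range(12):
                assert D[i, j] == pytest.approx(
                    jc_distance(records[i], records[j]), abs=1e-12
                )


def brute_force_complete_linkage(dist, cutoff):
    """Naive agglomeration oracle: repeatedly merge the closest pair of
    clusters under the furthest-neighbor criterion while it fits the cutoff."""
    clusters = [{i} for i in range(dist.shape[0])]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        if d > cutoff:
            break
        clusters[a] |= clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


class TestClusterOtus:
    def test_all_zero_distances_one_otu(self):
        dist = np.zeros((5, 5))
        part = cluster_otus(dist, [f"c{i}" for i in range(5)], 0.0)
        assert part.n_otus == 1

    def test_two_tight_groups(self):
        dist = np.full((4, 4), 0.10)
        dist[0, 1] = dist[1, 0] = dist[2, 3] = dist[3, 2] = 0.005
        np.fill_diagonal(dist, 0)
        part = cluster_otus(dist, list("abcd"), 0.03)
        assert part.n_otus == 2
        assert part.assignment["a"] == part.assignment["b"]

    def test_asymmetric_matrix_rejected(self):
        dist = np.array([[0.0, 0.1], [0.2, 0.0]])
        with pytest.raises(UsageError):
            cluster_otus(dist, ["a", "b"], 0.03)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            n = 20
            raw = rng.uniform(0.0, 0.08, size=(n, n))
            dist = np.triu(raw, 1)
            dist = dist + dist.T
            ids = [f"c{i:02d}" for i in range(n)]
            for cutoff in (0.01, 0.03, 0.05):
                part = cluster_otus(dist, ids, cutoff)
                got = {
                    frozenset(int(m[1:]) for m in members)
                    for members in part.members().values()
                }
                assert got == brute_force_complete_linkage(dist, cutoff)

    def test_cutoff_zero_groups_identical_only(self):
        dist = np.array(
            [[0.0, 0.0, 0.2], [0.0, 0.0, 0.2], [0.2, 0.2, 0.0]]
        )
        part = cluster_otus(dist, ["a", "b", "c"], 0.0)
        assert part.assignment["a"] == part.assignment["b"]
        assert part.assignment["a"] != part.assignment["c"]
        big = cluster_otus(dist, ["a", "b", "c"], 0.2)
        assert big.n_otus == 1


class TestSharedOtus:
    def _part(self, assignment, library_of):
        from trflpkit.diversity import OTUPartition

        return OTUPartition(0.03, assignment, library_of)

    def test_disjoint_compositions_zero(self):
        part = self._part(
            {"a": "O1", "b": "O2"}, {"a": "X", "b": "Y"}
        )
        assert shared_otus(part) == 0

    def test_one_cross_library_otu(self):
        part = self._part(
            {"a": "O1", "b": "O1", "c": "O2"}, {"a": "X", "b": "Y", "c": "X"}
        )
        assert shared_otus(part) == 1

    def test_single_library_warns_zero(self):
        part = self._part({"a": "O1"}, {"a": "X"})
        assert shared_otus(part) == 0

    def test_abundances_from_partition(self):
        part = self._part(
            {"a": "O1", "b": "O1", "c": "O2"}, {"a": "X", "b": "Y", "c": "X"}
        )
        assert sorted(abundances_from_partition(part).abundances) == [1, 2]
        assert sorted(abundances_from_partition(part, "X").abundances) == [1, 1]


class TestCoverageCurve:
    def test_all_identical_full_coverage_at_zero(self):
        dist = np.zeros((4, 4))
        curve = coverage_curve(dist)
        assert curve.c_x[0] == 1.0

    def test_heterologous_at_zero_counts_exact_matches(self):
        dist_x = np.full((3, 3), 0.2)
        np.fill_diagonal(dist_x, 0)
        cross = np.array([[0.0, 0.3], [0.3, 0.3], [0.3, 0.0]])
        curve = coverage_curve(dist_x, cross)
        assert curve.c_xy[0] == pytest.approx(2 / 3)

    def test_nondecreasing(self):
        rng = np.random.default_rng(3)
        dist = squareform(pdist(rng.random((12, 3)) * 0.3))
        curve = coverage_curve(dist)
        assert np.all(np.diff(curve.c_x) >= 0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(14)
        raw = rng.uniform(0, 0.4, size=(10, 10))
        dist = np.triu(raw, 1)
        dist = dist + dist.T
        cross = rng.uniform(0, 0.4, size=(10, 7))
        grid = default_grid()
        curve = coverage_curve(dist, cross, grid)
        for gi, d in enumerate(grid):
            cx = np.mean([
                any(dist[i, j] <= d for j in range(10) if j != i) for i in range(10)
            ])
            cxy = np.mean([any(cross[i, j] <= d for j in range(7)) for i in range(10)])
            assert curve.c_x[gi] == pytest.approx(cx)
            assert curve.c_xy[gi] == pytest.approx(cxy)


class TestLibshuff:
    def test_result_contract(self, community):
        lib_x, _ = generate_library(community, 20, seed=41, library_id="X")
        lib_y, _ = generate_library(community, 20, seed=42, library_id="Y")
        comp = libshuff_test(lib_x, lib_y, n_permutations=99, seed=5)
        for res in (comp.xy, comp.yx):
            assert res.delta_c >= 0
            assert 1 / 100 <= res.p_value <= 1.0

    def test_too_small_libraries_rejected(self, community):
        lib_x, _ = generate_library(community, 2, seed=43)
        lib_y, _ = generate_library(community, 20, seed=44)
        with pytest.raises(UsageError):
            libshuff_test(lib_x, lib_y)
        with pytest.raises(UsageError):
            libshuff_test(lib_y, lib_y, n_permutations=10)

    def test_disjoint_communities_rejected_strongly(self, community):
        from trflpkit.synthetic import generate_community

        other = generate_community(seed=909)
        lib_x, _ = generate_library(community, 30, seed=45, library_id="X")
        lib_y, _ = generate_library(other, 30, seed=46, library_id="Y")
        comp = libshuff_test(lib_x, lib_y, n_permutations=999, seed=6)
        assert comp.min_p() <= 0.025
        assert comp.significant()


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_matches_formula_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            x, y = rng.uniform(0, 5, 8), rng.uniform(0, 5, 8)
            expected = np.abs(x - y).sum() / (x + y).sum()
            assert bray_curtis(x, y) == pytest.approx(expected, abs=1e-12)

    def test_both_zero_rejected(self):
        with pytest.raises(DomainError):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(18)
        D = bray_curtis_matrix(rng.uniform(0, 1, (5, 10)))
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


class TestNMDS:
    def test_exactly_embeddable_triangle(self):
        pts = np.array([[0, 0], [3.1, 0], [1.0, 2.3]])
        D = squareform(pdist(pts))
        assert nmds(D, seed=0).stress < 1e-6

    def test_duplicated_sample_coincident(self):
        rng = np.random.default_rng(1)
        X = rng.random((9, 4))
        X = np.vstack([X, X[0]])
        D = squareform(pdist(X))
        res = nmds(D, seed=2)
        gap = np.linalg.norm(res.coords[0] - res.coords[-1])
        assert gap <= 0.05 * pdist(res.coords).max()

    def test_iteration_improves_on_classical_start(self):
        rng = np.random.default_rng(4)
        for seed in range(3):
            D = squareform(pdist(rng.random((10, 5))))
            res = nmds(D, seed=seed)
            assert res.stress <= stress1(D, classical_scaling(D)) + 1e-12

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        D = squareform(pdist(rng.random((8, 3))))
        r1, r2 = nmds(D, seed=7), nmds(D, seed=7)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coords, r2.coords)

    def test_too_few_samples_rejected(self):
        with pytest.raises(UsageError):
            nmds(np.zeros((2, 2)))


class TestDiversityReportShape:
    def test_report_covers_libraries_and_cutoffs(self, community):
        """The per-library report has the observed richness / Chao1 /
        Shannon layout at the three standard cutoffs."""
        lib_x, _ = generate_library(community, 25, seed=51, library_id="1.2")
        lib_y, _ = generate_library(community, 25, seed=52, library_id="2.1")
        report = diversity_report({"1.2": lib_x, "2.1": lib_y})
        assert list(report.columns) == ["library", "cutoff", "s_obs", "chao1", "shannon"]
        assert len(report) == 6
        assert set(report.cutoff) == {0.01, 0.03, 0.05}
        assert (report.chao1 >= report.s_obs).all()
        assert (report.shannon >= 0).all()

    def test_shannon_recovery_from_library_sampling(self, community):
        """Bias-corrected Shannon from 100-clone libraries stays within 3
        empirical standard errors of the community value across seeds."""
        true_h = shannon(community.abundances)
        estimates = []
        for seed in range(20):
            _, truth = generate_library(community, 100, seed=700 + seed)
            counts = truth.parent_a.value_counts().to_numpy(dtype=float)
            h = shannon(counts / counts.sum()) + (len(counts) - 1) / 200.0
            estimates.append(h)
        estimates = np.array(estimates)
        sd = estimates.std(ddof=1)
        assert np.all(np.abs(estimates - true_h) <= 3 * sd)
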