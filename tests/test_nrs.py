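import itertools

import numpy as np
import pytest

from fldnrs import (
    ExpressionDataset,
    build_neighborhoods,
    compute_regions,
    dependency,
    pairwise_distance,
    sig_inner,
    sig_outer,
)
from ._oracles import brute_dependency, brute_regions
from .conftest import random_dataset


class TestPairwiseDistance:
    def test_three_four_five_triangle(self):
        ds = ExpressionDataset(np.array([[0.0, 0.0], [3.0, 4.0]]),
                               np.array([0, 1]))
        d = pairwise_distance(ds, ["1", "2"])
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 1] == d[1, 0]

    def test_measure_axioms_on_random_data(self):
        rng = np.random.default_rng(1)
        ds = ExpressionDataset(rng.random((10, 3)), rng.integers(0, 2, 10))
        for metric, p in [("euclidean", 2), ("manhattan", 1), ("pnorm", 3)]:
            d = pairwise_distance(ds, list(ds.attribute_ids), metric, p)
            np.testing.assert_allclose(np.diag(d), 0, atol=1e-12)
            np.testing.assert_allclose(d, d.T)
            for i, j, k in itertools.permutations(range(10), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_empty_subset_and_bad_p_rejected(self):
        ds = ExpressionDataset(np.ones((2, 2)), np.array([0, 1]))
        with pytest.raises(ValueError, match="nonempty"):
            pairwise_distance(ds, [])
        with pytest.raises(ValueError, match="triangle"):
            pairwise_distance(ds, ["1"], "pnorm", p=0.5)


class TestBuildNeighborhoods:
    def test_hand_enumeration(self, line_dataset):
        nm = build_neighborhoods(line_dataset, ["1"], beta=1.2)
        assert nm.neighborhood(0) == {0, 1}
        assert nm.neighborhood(1) == {0, 1}
        assert nm.neighborhood(2) == {2}

    def test_beta_zero_gives_singletons(self, line_dataset):
        nm = build_neighborhoods(line_dataset, ["1"], beta=0.0)
        for i in range(3):
            assert nm.neighborhood(i) == {i}

    def test_huge_beta_gives_universe(self, line_dataset):
        nm = build_neighborhoods(line_dataset, ["1"], beta=100.0)
        for i in range(3):
            assert nm.neighborhood(i) == {0, 1, 2}

    def test_self_membership_symmetry_and_beta_monotonicity(self):
        rng = np.random.default_rng(4)
        ds = random_dataset(rng)
        B = list(ds.attribute_ids)
        small = build_neighborhoods(ds, B, 0.2).adjacency
        large = build_neighborhoods(ds, B, 0.5).adjacency
        assert np.diag(small).all()
        assert (small == small.T).all()
        assert (small <= large).all()  # beta-monotone

    def test_negative_beta_rejected(self, line_dataset):
        with pytest.raises(ValueError, match="beta"):
            build_neighborhoods(line_dataset, ["1"], -0.1)


class TestComputeRegions:
    def test_hand_example_mixed_labels(self, line_dataset):
        nm = build_neighborhoods(line_dataset, ["1"], 1.2)
        rs = compute_regions(nm, line_dataset.labels)
        assert rs.positive == {2}
        assert rs.boundary == {0, 1}
        assert rs.negative == frozenset()
        assert rs.precision == pytest.approx(1 / 3)
        assert rs.roughness == pytest.approx(2 / 3)
        assert rs.K == pytest.approx(2 / 9)

    def test_hand_example_consistent_labels(self, line_dataset):
        nm = build_neighborhoods(line_dataset, ["1"], 1.2)
        rs = compute_regions(nm, np.array([1, 1, 2]))
        assert rs.positive == {0, 1, 2}
        assert rs.boundary == frozenset()
        assert rs.precision == pytest.approx(1.0)
        assert rs.K == pytest.approx(0.0)

    def test_beta_zero_positive_region_is_universe(self):
        rng = np.random.default_rng(8)
        ds = random_dataset(rng)
        rs = compute_regions(
            build_neighborhoods(ds, list(ds.attribute_ids), 0.0), ds.labels)
        assert rs.positive == frozenset(range(ds.n_samples))
        assert rs.K == pytest.approx(0.0)

    def test_label_count_mismatch(self, line_dataset):
        nm = build_neighborhoods(line_dataset, ["1"], 1.2)
        with pytest.raises(ValueError, match="labels"):
            compute_regions(nm, np.array([1, 2]))


class TestOracleEquivalence:
    """Vectorized region computation vs an independent nested-loop oracle."""

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(100)
        betas = np.linspace(0.05, 0.6, 12)
        for trial in range(100):
            ds = random_dataset(rng)
            beta = float(betas[trial % len(betas)])
            nm = build_neighborhoods(ds, list(ds.attribute_ids), beta)
            rs = compute_regions(nm, ds.labels)
            ref = brute_regions(ds.matrix.tolist(), ds.labels.tolist(), beta)
            assert rs.positive == ref["pos"]
            assert rs.boundary == ref["boundary"]
            assert rs.negative == ref["negative"]
            for c in ref["lower"]:
                assert rs.lower[c] == ref["lower"][c]
                assert rs.upper[c] == ref["upper"][c]
            assert abs(rs.precision - ref["rho"]) < 1e-12
            assert abs(rs.roughness - ref["roughness"]) < 1e-12
            assert abs(rs.K - ref["K"]) < 1e-12
            assert abs(rs.K_classic - ref["K_classic"]) < 1e-12

    def test_theorems_on_random_instances(self):
        """Upper union = U, K = rho(1-rho), K in [0, 0.25]."""
        rng = np.random.default_rng(200)
        for trial in range(50):
            ds = random_dataset(rng)
            beta = 0.05 + 0.55 * rng.random()
            rs = compute_regions(
                build_neighborhoods(ds, list(ds.attribute_ids), beta),
                ds.labels)
            universe = frozenset(range(ds.n_samples))
            assert frozenset().union(*rs.upper.values()) == universe
            for c in rs.lower:
                members = frozenset(np.flatnonzero(ds.labels == c).tolist())
                assert rs.lower[c] <= members <= rs.upper[c]
            assert rs.K == pytest.approx(rs.precision * (1 - rs.precision))
            assert 0.0 <= rs.K <= 0.25

    def test_positive_region_monotonicity(self):
        rng = np.random.default_rng(300)
        for _ in range(25):
            ds = random_dataset(rng, t_max=4)
            A = list(ds.attribute_ids)
            if len(A) < 2:
                continue
            B = A[: len(A) // 2]
            pos = {}
            for name, subset, beta in [("small_b", A, 0.1), ("large_b", A, 0.4),
                                       ("sub", B, 0.25), ("full", A, 0.25)]:
                rs = compute_regions(build_neighborhoods(ds, subset, beta),
                                     ds.labels)
                pos[name] = rs.positive
            assert pos["large_b"] <= pos["small_b"]  # anti-monotone in beta
            assert pos["sub"] <= pos["full"]         # monotone in B

    def test_sample_permutation_leaves_measures_unchanged(self):
        rng = np.random.default_rng(77)
        ds = random_dataset(rng)
        perm = rng.permutation(ds.n_samples)
        shuffled = ExpressionDataset(ds.matrix[perm], ds.labels[perm])
        a = compute_regions(
            build_neighborhoods(ds, list(ds.attribute_ids), 0.3), ds.labels)
        b = compute_regions(
            build_neighborhoods(shuffled, list(shuffled.attribute_ids), 0.3),
            shuffled.labels)
        assert a.precision == b.precision and a.K == b.K
        # sets permute consistently
        inv = {int(p): i for i, p in enumerate(perm)}
        assert {inv[i] for i in b.positive} == set(a.positive)


class TestDependencyAndSignificance:
    def test_hand_dependency(self, line_dataset):
        assert dependency(line_dataset, ["1"], 1.2) == pytest.approx(2 / 9)

    def test_separated_classes_give_zero(self):
        ds = ExpressionDataset(np.array([[0.0], [0.1], [0.9], [1.0]]),
                               np.array([0, 0, 1, 1]))
        assert dependency(ds, ["1"], 0.15) == pytest.approx(0.0)
        assert dependency(ds, ["1"], 0.15, variant="classic") == pytest.approx(1.0)

    def test_empty_subset_convention(self, line_dataset):
        assert dependency(line_dataset, [], 1.2) == 0.0
        # outer significance from the empty set is K({a}, D)
        s = sig_outer(line_dataset, "1", [], 1.2)
        assert s == pytest.approx(dependency(line_dataset, ["1"], 1.2))

    def test_range_bound_against_bruteforce(self):
        rng = np.random.default_rng(55)
        for _ in range(30):
            ds = random_dataset(rng, t_max=3)
            beta = 0.05 + 0.5 * rng.random()
            K = dependency(ds, list(ds.attribute_ids), beta)
            ref = brute_dependency(ds.matrix.tolist(), ds.labels.tolist(),
                                   list(range(ds.n_attributes)), beta)
            assert K == pytest.approx(ref, abs=1e-12)
            assert 0.0 <= K <= 0.25

    def test_sig_inner_matches_bruteforce(self):
        rng = np.random.default_rng(60)
        for _ in range(20):
            ds = random_dataset(rng, n_max=15, t_max=4)
            A = list(ds.attribute_ids)
            if len(A) < 2:
                continue
            beta = 0.1 + 0.3 * rng.random()
            a = A[int(rng.integers(len(A)))]
            got = sig_inner(ds, a, A, beta)
            cols = list(range(ds.n_attributes))
            rest = [c for c in cols if ds.attribute_ids[c] != a]
            want = (brute_dependency(ds.matrix.tolist(), ds.labels.tolist(),
                                     cols, beta)
                    - brute_dependency(ds.matrix.tolist(), ds.labels.tolist(),
                                       rest, beta))
            assert got == pytest.approx(want, abs=1e-12)

    def test_sig_outer_matches_bruteforce(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            ds = random_dataset(rng, n_max=15, t_max=4)
            A = list(ds.attribute_ids)
            if len(A) < 2:
                continue
            beta = 0.1 + 0.3 * rng.random()
            a = A[-1]
            B = A[:-1]
            got = sig_outer(ds, a, B, beta)
            m, lab = ds.matrix.tolist(), ds.labels.tolist()
            want = (brute_dependency(m, lab, list(range(len(A))), beta)
                    - brute_dependency(m, lab, list(range(len(A) - 1)), beta))
            assert got == pytest.approx(want, abs=1e-12)

    def test_duplicate_attribute_zero_inner_significance(self):
        # duplicated column constructed so neighborhoods are verifiably equal
        col = np.array([0.0, 0.3, 0.6, 1.0])
        ds = ExpressionDataset(np.column_stack([col, col]),
                               np.array([0, 0, 1, 1]))
        beta = 0.2
        nm_both = build_neighborhoods(ds, ["1", "2"], beta)
        nm_one = build_neighborhoods(ds, ["1"], beta / np.sqrt(2))
        assert (nm_both.adjacency == nm_one.adjacency).all()
        # with beta below half the gap, sets coincide and significance is 0
        assert sig_inner(ds, "2", ["1", "2"], 0.2) == pytest.approx(0.0)

    def test_constant_attribute_zero_outer_significance(self):
        ds = ExpressionDataset(
            np.array([[0.0, 0.5], [0.4, 0.5], [1.0, 0.5]]),
            np.array([0, 1, 1]))
        assert sig_outer(ds, "2", ["1"], 0.3) == pytest.approx(0.0)

    def test_membership_preconditions(self, line_dataset):
        with pytest.raises(ValueError, match="not in B"):
            sig_inner(line_dataset, "1", [], 1.2)
        with pytest.raises(ValueError, match="already in B"):
            sig_outer(line_dataset, "1", ["1"], 1.2)

    def test_determinism(self, line_dataset):
        vals = {dependency(line_dataset, ["1"], 1.2) for _ in range(5)}
        assert len(vals) == 1
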