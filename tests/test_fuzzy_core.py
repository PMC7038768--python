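"""Unit and property tests for the fuzzy c-means machinery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from canopyscan.fuzzy_core import (
    CenterSet,
    DegenerateClusterError,
    FuzzyPartition,
    SampleSet,
    fcm_converge,
    objective,
    quantile_centers,
    update_centers,
    update_memberships,
)
from conftest import random_partition, three_layer_values


# --- independent scalar oracles (plain loops, no vectorization) -----------

def centers_bruteforce(x, u, q):
    c, n = u.shape
    out = np.zeros(c)
    for i in range(c):
        num = den = 0.0
        for j in range(n):
            num += u[i, j] ** q * x[j]
            den += u[i, j] ** q
        out[i] = num / den
    return out


def memberships_bruteforce(x, v, q):
    c, n = len(v), len(x)
    u = np.zeros((c, n))
    for j in range(n):
        d2 = [(x[j] - v[p]) ** 2 for p in range(c)]
        if min(d2) == 0.0:
            hits = [p for p in range(c) if d2[p] == 0.0]
            for p in hits:
                u[p, j] = 1.0 / len(hits)
            continue
        for i in range(c):
            u[i, j] = 1.0 / sum(
                (d2[i] / d2[p]) ** (1.0 / (q - 1.0)) for p in range(c)
            )
    return u


def objective_bruteforce(x, v, u, q):
    total = 0.0
    for i in range(len(v)):
        for j in range(len(x)):
            total += u[i, j] ** q * (x[j] - v[i]) ** 2
    return total


# --- containers -----------------------------------------------------------

class TestContainers:
    def test_sample_set_rejects_bad_input(self):
        with pytest.raises(ValueError):
            SampleSet.from_distances([60.0])  # n < 2
        with pytest.raises(ValueError):
            SampleSet.from_distances([60.0, np.nan])
        with pytest.raises(ValueError):
            SampleSet.from_distances([60.0, 1200.0], max_range=1100.0)
        with pytest.raises(ValueError):
            SampleSet.from_distances([-1.0, 60.0], max_range=1100.0)

    def test_partition_constraints(self):
        FuzzyPartition([[0.3, 1.0], [0.7, 0.0]])
        with pytest.raises(ValueError):
            FuzzyPartition([[0.3, 0.3], [0.3, 0.7]])  # column sum != 1
        with pytest.raises(ValueError):
            FuzzyPartition([[1.2, -0.2], [-0.2, 1.2]])  # out of [0, 1]
        with pytest.raises(ValueError):
            FuzzyPartition([[1.0, 1.0], [0.0, 0.0]])  # empty cluster row

    def test_center_set_sorting(self):
        cs = CenterSet([[80.0], [63.0], [66.0]])
        assert cs.sorted().centers[:, 0].tolist() == [63.0, 66.0, 80.0]


# --- center update --------------------------------------------------------

class TestUpdateCenters:
    def test_crisp_partition_gives_arithmetic_means(self):
        x = SampleSet.from_distances([60.0, 62.0, 64.0, 80.0, 82.0])
        u = FuzzyPartition(
            [[1, 1, 1, 0, 0], [0, 0, 0, 1, 1]]
        )
        v = update_centers(x, u).centers[:, 0]
        assert v[0] == pytest.approx(62.0, abs=0)
        assert v[1] == pytest.approx(81.0, abs=0)

    def test_single_member_center_equals_sample(self):
        x = SampleSet.from_distances([55.5, 80.0])
        u = FuzzyPartition([[1, 0], [0, 1]])
        assert update_centers(x, u).centers[0, 0] == 55.5

    def test_matches_bruteforce_on_fixed_fuzzy_partition(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        u = np.array([[0.9, 0.7, 0.2, 0.1], [0.1, 0.3, 0.8, 0.9]])
        got = update_centers(
            SampleSet.from_distances(x), FuzzyPartition(u), q=2.0
        ).centers[:, 0]
        np.testing.assert_allclose(got, centers_bruteforce(x, u, 2.0), atol=1e-12)

    def test_underflowed_cluster_raises_named_error(self):
        # Row sums are positive (valid partition) but u**q underflows to 0.
        tiny = 1e-200
        u = np.array(
            [[tiny] * 3, [0.5] * 3, [0.5 - tiny] * 3]
        )
        x = SampleSet.from_distances([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateClusterError, match="cluster 0"):
            update_centers(x, FuzzyPartition(u), q=2.0)


# --- membership update ----------------------------------------------------

class TestUpdateMemberships:
    def test_equidistant_sample_splits_evenly(self):
        x = SampleSet.from_distances([70.0, 60.0])
        v = CenterSet([[60.0], [80.0]])
        u = update_memberships(x, v).memberships
        np.testing.assert_allclose(u[:, 0], [0.5, 0.5], atol=1e-15)

    def test_sample_at_one_center_is_crisp(self):
        x = SampleSet.from_distances([60.0, 70.0])
        v = CenterSet([[60.0], [66.0], [80.0]])
        u = update_memberships(x, v).memberships
        np.testing.assert_array_equal(u[:, 0], [1.0, 0.0, 0.0])

    def test_sample_at_two_coincident_centers_shares_mass(self):
        x = SampleSet.from_distances([60.0, 70.0])
        v = CenterSet([[60.0], [60.0], [80.0]])
        u = update_memberships(x, v).memberships
        np.testing.assert_array_equal(u[:, 0], [0.5, 0.5, 0.0])

    def test_hand_evaluated_value(self):
        # sample 61, centers {60, 80}, q=2: d^2 = (1, 361)
        # u_1 = 1/(1 + 1/361) = 361/362, u_2 = 1/362
        x = SampleSet.from_distances([61.0, 61.0])
        v = CenterSet([[60.0], [80.0]])
        u = update_memberships(x, v, q=2.0).memberships
        assert u[0, 0] == pytest.approx(361.0 / 362.0, abs=1e-15)
        assert u[1, 0] == pytest.approx(1.0 / 362.0, abs=1e-15)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(40, 85, size=9)
        v = np.array([45.0, 63.0, 80.0])
        got = update_memberships(
            SampleSet.from_distances(x), CenterSet(v.reshape(-1, 1)), q=2.0
        ).memberships
        np.testing.assert_allclose(
            got, memberships_bruteforce(x, v, 2.0), atol=1e-12
        )

    @given(seed=st.integers(0, 10_000), c=st.integers(2, 5), n=st.integers(2, 40))
    def test_columns_sum_to_one(self, seed, c, n):
        rng = np.random.default_rng(seed)
        x = SampleSet.from_distances(rng.uniform(30, 90, size=n))
        v = CenterSet(rng.uniform(30, 90, size=(c, 1)))
        u = update_memberships(x, v).memberships
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-9)


# --- objective ------------------------------------------------------------

class TestObjective:
    def test_zero_when_samples_sit_on_centers(self):
        x = SampleSet.from_distances([60.0, 80.0])
        v = CenterSet([[60.0], [80.0]])
        u = FuzzyPartition([[1, 0], [0, 1]])
        assert objective(x, v, u) == 0.0

    def test_simple_two_point_value(self):
        x = SampleSet.from_distances([0.0, 2.0])
        v = CenterSet([[1.0], [1.0]])
        u = FuzzyPartition([[1.0, 0.0], [0.0, 1.0]])
        # both centers at 1: (0-1)^2 + (2-1)^2 = 2
        assert objective(x, v, u) == pytest.approx(2.0, abs=0)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(30, 90, size=20)
        v = np.array([50.0, 70.0])
        u = random_partition(rng, 2, 20)
        got = objective(
            SampleSet.from_distances(x),
            CenterSet(v.reshape(-1, 1)),
            FuzzyPartition(u),
            q=2.0,
        )
        assert got == pytest.approx(objective_bruteforce(x, v, u, 2.0), rel=1e-12)


# --- convergence loop -----------------------------------------------------

class TestFcmConverge:
    def test_crisp_separated_data_is_a_fixed_point(self):
        x = SampleSet.from_distances([60.0, 60.0, 80.0, 80.0])
        u0 = FuzzyPartition([[1, 1, 0, 0], [0, 0, 1, 1]])
        state = fcm_converge(x, u0, epsilon=1e-4)
        assert state.converged and state.iteration <= 2
        np.testing.assert_allclose(
            np.sort(state.centers.centers[:, 0]), [60.0, 80.0], atol=1e-12
        )

    def test_three_bump_parameter_recovery(self):
        rng = np.random.default_rng(42)
        x = np.concatenate(
            [rng.normal(m, 0.5, 100) for m in (60.0, 66.0, 80.0)]
        )
        samples = SampleSet.from_distances(x)
        centers0 = quantile_centers(samples, 3)
        u0 = update_memberships(samples, centers0)
        state = fcm_converge(samples, u0, epsilon=1e-4)
        assert state.converged
        got = np.sort(state.centers.centers[:, 0])
        np.testing.assert_allclose(got, [60.0, 66.0, 80.0], atol=0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_trace_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        x = SampleSet.from_distances(rng.uniform(30, 90, size=200))
        u0 = FuzzyPartition(random_partition(rng, 3, 200))
        state = fcm_converge(x, u0, epsilon=1e-6)
        trace = np.array(state.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)
        assert state.objective <= trace[0] + 1e-9

    def test_iteration_cap_flags_nonconvergence(self, caplog):
        rng = np.random.default_rng(5)
        x = SampleSet.from_distances(rng.uniform(30, 90, size=100))
        u0 = FuzzyPartition(random_partition(rng, 3, 100))
        state = fcm_converge(x, u0, epsilon=1e-12, max_iter=2)
        assert not state.converged and state.iteration == 2

    def test_one_full_iteration_matches_scalar_oracle(self):
        # centers-then-memberships, n <= 10, c <= 3, d = 1, within 1e-12
        rng = np.random.default_rng(9)
        x = rng.uniform(40, 85, size=8)
        u0 = random_partition(rng, 3, 8)
        v_expected = centers_bruteforce(x, u0, 2.0)
        u_expected = memberships_bruteforce(x, v_expected, 2.0)
        samples = SampleSet.from_distances(x)
        v = update_centers(samples, FuzzyPartition(u0), q=2.0)
        u = update_memberships(samples, v, q=2.0)
        np.testing.assert_allclose(v.centers[:, 0], v_expected, atol=1e-12)
        np.testing.assert_allclose(u.memberships, u_expected, atol=1e-12)


# --- symmetry -------------------------------------------------------------

def test_permuting_samples_permutes_memberships_and_not_centers():
    rng = np.random.default_rng(21)
    x = rng.uniform(30, 90, size=50)
    u = random_partition(rng, 3, 50)
    perm = rng.permutation(50)
    v1 = update_centers(SampleSet.from_distances(x), FuzzyPartition(u))
    v2 = update_centers(
        SampleSet.from_distances(x[perm]), FuzzyPartition(u[:, perm])
    )
    np.testing.assert_allclose(v1.centers, v2.centers, atol=1e-12)
    m1 = update_memberships(SampleSet.from_distances(x), v1).memberships
    m2 = update_memberships(SampleSet.from_distances(x[perm]), v1).memberships
    np.testing.assert_array_equal(m1[:, perm], m2)
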