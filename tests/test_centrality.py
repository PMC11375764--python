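import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from numpy.linalg import matrix_power

from allonet import (
    betweenness_profile,
    betweenness_scores,
    centrality_profile,
    communicability,
    monomer_average,
    reach_profile,
    toy_network,
    truncated_exp_series,
    walk_count_oracle,
)
from allonet.centrality import CentralityProfile, betweenness_bruteforce
from allonet.network import build_contact_network
from allonet.synthetic import DimerSpec, generate_dimer

from conftest import make_network, random_adjacency


class TestBetweennessKnownGraphs:
    def test_path_middle_node(self):
        beta = betweenness_scores(toy_network("path", 3).adjacency)
        assert beta == [0.0, 1.0, 0.0]

    def test_complete_graph_all_zero(self):
        beta = betweenness_scores(toy_network("complete", 4).adjacency)
        assert beta == [0.0] * 4

    def test_star_center(self):
        beta = betweenness_scores(toy_network("star", 4).adjacency)
        assert beta[0] == 3.0  # three leaf pairs, one shortest path each
        assert beta[1:] == [0.0] * 3

    def test_bridge_node_dominates_two_cliques(self):
        net = toy_network("two_cliques_bridge", 5)
        beta = betweenness_scores(net.adjacency)
        bridge = 5
        assert np.argmax(beta) == bridge

    def test_disconnected_pairs_contribute_zero(self):
        # two isolated edges: nobody lies between anything
        A = np.zeros((4, 4), dtype=np.int8)
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        assert betweenness_scores(A) == [0.0] * 4


class TestBetweennessOracle:
    def test_exact_match_with_bruteforce_enumeration(self, rng):
        """Brandes with Fraction arithmetic reproduces exhaustive
        shortest-path enumeration exactly on 50 random connected graphs."""
        for _ in range(50):
            n = int(rng.integers(4, 13))
            A = random_adjacency(rng, n, p=0.4, connected=True)
            exact = betweenness_scores(A, exact=True)
            brute = betweenness_bruteforce(A)
            assert all(isinstance(b, Fraction) for b in exact)
            assert exact == brute

    def test_float_path_matches_exact_and_networkx(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            A = random_adjacency(rng, n, p=0.4)
            ours = betweenness_scores(A)
            exact = [float(b) for b in betweenness_scores(A, exact=True)]
            ref = nx.betweenness_centrality(nx.from_numpy_array(A), normalized=False)
            np.testing.assert_allclose(ours, exact, rtol=0, atol=1e-12)
            np.testing.assert_allclose(ours, [ref[i] for i in range(n)], atol=1e-9)


class TestWalkCountOracle:
    def test_k1_is_adjacency(self, rng):
        A = random_adjacency(rng, 6, p=0.4)
        assert np.array_equal(walk_count_oracle(A, 1), A)

    def test_single_edge_k2_go_and_return(self):
        A = np.array([[0, 1], [1, 0]], dtype=np.int8)
        assert np.array_equal(walk_count_oracle(A, 2), np.eye(2, dtype=int))

    def test_triangle_k3_closed_walks(self):
        A = toy_network("cycle", 3).adjacency
        counts = walk_count_oracle(A, 3)
        assert counts[0, 0] == 2  # the two directed traversals of the triangle

    def test_matrix_power_equals_enumeration(self, rng):
        """(A^k)_ij counts walks of exactly k steps: integer-exact on
        random graphs for k = 1..4."""
        for _ in range(10):
            n = int(rng.integers(3, 9))
            A = random_adjacency(rng, n, p=0.45)
            for k in range(1, 5):
                power = matrix_power(A.astype(np.int64), k)
                assert np.array_equal(power, walk_count_oracle(A, k))


class TestCommunicability:
    def test_edgeless_network_is_identity(self):
        A = np.zeros((6, 6), dtype=np.int8)
        cm = communicability(make_network(A, monomer_sizes=(3, 3)))
        np.testing.assert_allclose(cm.G, np.eye(6), atol=1e-14)
        rho = reach_profile(cm)
        np.testing.assert_allclose(rho["avg"], np.ones(3), atol=1e-14)

    def test_single_edge_closed_form(self):
        A = np.array([[0, 1], [1, 0]], dtype=np.int8)
        cm = communicability(make_network(A))
        expected = np.array(
            [[math.cosh(1), math.sinh(1)], [math.sinh(1), math.cosh(1)]]
        )
        np.testing.assert_allclose(cm.G, expected, atol=1e-12)
        np.testing.assert_allclose(cm.G.sum(axis=0), [math.e, math.e], atol=1e-12)

    def test_triangle_column_sums_e_squared(self):
        cm = communicability(toy_network("cycle", 3))
        np.testing.assert_allclose(cm.G.sum(axis=0), [math.e**2] * 3, atol=1e-10)

    def test_expm_matches_truncated_series(self, rng):
        for n in (5, 20, 50):
            A = random_adjacency(rng, n, p=0.2)
            cm = communicability(make_network(A))
            series = truncated_exp_series(A, k_max=60)
            np.testing.assert_allclose(cm.G, series, rtol=0, atol=1e-8)

    def test_blocks_conformal_and_diagnostic(self, rng):
        A = random_adjacency(rng, 10, p=0.3)
        cm = communicability(make_network(A, monomer_sizes=(5, 5)))
        for key in ("11", "22", "12", "21"):
            assert cm.blocks[key].shape == (5, 5)
        np.testing.assert_allclose(
            cm.averaged, (cm.blocks["11"] + cm.blocks["22"]) / 2
        )
        np.testing.assert_allclose(cm.blocks["12"], cm.blocks["21"].T, atol=1e-12)

    def test_adding_edge_never_decreases_reach(self, rng):
        for _ in range(5):
            A = random_adjacency(rng, 12, p=0.25)
            absent = np.argwhere(np.triu(A == 0, k=1))
            i, j = absent[rng.integers(len(absent))]
            B = A.copy()
            B[i, j] = B[j, i] = 1
            G_a = communicability(make_network(A, (6, 6))).G
            G_b = communicability(make_network(B, (6, 6))).G
            assert np.all(G_b >= G_a - 1e-10)


class TestReachProfile:
    def test_column_sum_identity(self, rng):
        A = random_adjacency(rng, 12, p=0.3)
        cm = communicability(make_network(A, (6, 6)))
        rho = reach_profile(cm)
        assert rho["m1"].sum() == pytest.approx(cm.blocks["11"].sum())
        assert rho["m2"].sum() == pytest.approx(cm.blocks["22"].sum())

    def test_identical_blocks_average_to_either(self):
        # a dimer of two identical disconnected monomers
        A1 = toy_network("cycle", 4).adjacency
        A = np.zeros((8, 8), dtype=np.int8)
        A[:4, :4] = A1
        A[4:, 4:] = A1
        cm = communicability(make_network(A, (4, 4)))
        rho = reach_profile(cm)
        np.testing.assert_allclose(rho["avg"], rho["m1"], atol=1e-12)
        np.testing.assert_allclose(rho["avg"], rho["m2"], atol=1e-12)


class TestMonomerAverage:
    def test_arithmetic_mean(self):
        out = monomer_average([4.0], [2.0])
        assert out[0] == 3.0

    def test_idempotent_on_identical_profiles(self, rng):
        v = rng.random(10)
        np.testing.assert_array_equal(monomer_average(v, v), v)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="monomer length mismatch"):
            monomer_average([1.0, 2.0], [1.0])

    def test_symmetric_dimer_monomers_agree(self):
        """An exact rigid copy with zero interface contacts yields equal
        per-monomer betweenness and reach."""
        model = generate_dimer(
            DimerSpec(n_res=40, seed=11, interface_contacts=0, monomer2="rigid_copy")
        )
        net = build_contact_network(model)
        profile = centrality_profile(net, "sym")
        np.testing.assert_array_equal(profile.beta_m1, profile.beta_m2)
        np.testing.assert_allclose(profile.rho_m1, profile.rho_m2, rtol=0, atol=1e-9)


class TestProfileAndInvariances:
    def test_permutation_equivariance(self, rng):
        A = random_adjacency(rng, 9, p=0.4)
        perm = rng.permutation(9)
        P = A[np.ix_(perm, perm)]
        beta_A = np.asarray(betweenness_scores(A))
        beta_P = np.asarray(betweenness_scores(P))
        np.testing.assert_allclose(beta_P, beta_A[perm], atol=1e-12)
        G_A = communicability(make_network(A)).G
        G_P = communicability(make_network(P)).G
        np.testing.assert_allclose(G_P, G_A[np.ix_(perm, perm)], atol=1e-10)

    def test_mean_vs_sum_averaging_preserves_order(self, rng):
        model = generate_dimer(DimerSpec(n_res=30, seed=13, interface_contacts=8))
        net = build_contact_network(model)
        mean_p = centrality_profile(net, "x", average="mean")
        sum_p = centrality_profile(net, "x", average="sum")
        np.testing.assert_allclose(sum_p.rho_avg, 2 * mean_p.rho_avg, rtol=1e-12)
        np.testing.assert_allclose(sum_p.beta_avg, 2 * mean_p.beta_avg, rtol=1e-12)
        for a, b in ((mean_p.rho_avg, sum_p.rho_avg), (mean_p.beta_avg, sum_p.beta_avg)):
            assert np.array_equal(
                np.argsort(-a, kind="stable"), np.argsort(-b, kind="stable")
            )

    def test_identity_term_shift_preserves_order(self, rng):
        """Excluding the k=0 identity term shifts every reach by exactly 1
        and cannot reorder residues."""
        A = random_adjacency(rng, 14, p=0.3)
        net = make_network(A, (7, 7))
        cm = communicability(net)
        rho_with = reach_profile(cm)["avg"]
        G_no_identity = cm.G - np.eye(14)
        p1, p2 = net.partition
        rho_without = (
            (G_no_identity[p1, p1] + G_no_identity[p2, p2]) / 2
        ).sum(axis=0)
        np.testing.assert_allclose(rho_with - 1.0, rho_without, atol=1e-10)
        assert np.array_equal(
            np.argsort(-rho_with, kind="stable"),
            np.argsort(-rho_without, kind="stable"),
        )

    def test_betweenness_scope_monomer_vs_dimer(self):
        model = generate_dimer(DimerSpec(n_res=25, seed=3, interface_contacts=0))
        net = build_contact_network(model)
        # with no interface the full-dimer and per-monomer graphs coincide
        np.testing.assert_allclose(
            betweenness_profile(net, scope="dimer"),
            betweenness_profile(net, scope="monomer"),
            atol=1e-9,
        )

    def test_profile_tsv_round_trip(self, tmp_path, rng):
        model = generate_dimer(DimerSpec(n_res=20, seed=8, interface_contacts=4))
        net = build_contact_network(model)
        profile = centrality_profile(net, "wt")
        path = tmp_path / "profile.tsv"
        profile.to_tsv(path)
        back = CentralityProfile.from_tsv(path, variant_label="wt")
        np.testing.assert_allclose(back.beta_avg, profile.beta_avg, rtol=1e-10)
        np.testing.assert_allclose(back.rho_avg, profile.rho_avg, rtol=1e-10)
        assert back.residue_names == profile.residue_names
        frame = profile.to_frame()
        assert len(frame) == 2 * profile.n_positions
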