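"""Simulator calibration: substitution process, amplification truth,
planted transfers and area histories; determinism under fixed seeds."""

import numpy as np
import pytest

from horizonte.errors import SimulationError
from horizonte.divergence import k2p_distance
from horizonte.landscape import RateSpec
from horizonte.reconciliation import min_transfers
from horizonte.simulate import (AmplificationParams, evolve_k2p,
                                random_binary_tree, random_sequence,
                                simulate_amplification, simulate_areas,
                                simulate_transfers)


class TestEvolveK2P:
    def test_zero_time_identity(self, rng):
        s = random_sequence(500, rng)
        assert evolve_k2p(s, 0.0, RateSpec(2.5e-9), seed=1) == s

    def test_deterministic_under_seed(self, rng):
        s = random_sequence(500, rng)
        a = evolve_k2p(s, 10.0, RateSpec(2.5e-9), seed=42)
        b = evolve_k2p(s, 10.0, RateSpec(2.5e-9), seed=42)
        assert a == b

    def test_gaps_and_ns_inert(self):
        s = evolve_k2p(
            __import__("horizonte").SequenceRecord("x", "AC-GNT" * 50),
            50.0, RateSpec(1e-8), seed=3)
        assert all(c in "-N" for c, o in zip(s.residues, "AC-GNT" * 50)
                   if o in "-N")

    def test_transition_bias_approaches_kappa(self, rng):
        kappa = 4.0
        s = random_sequence(150000, rng)
        out = evolve_k2p(s, 4.0, RateSpec(2.5e-9), kappa=kappa, rng=rng)
        res = k2p_distance(s, out)
        ratio = res.P / res.Q
        # binomial 3-SE band around kappa at these counts
        n_ts = res.P * res.sites_used
        se = kappa * np.sqrt(1 / n_ts + 1 / (res.Q * res.sites_used))
        assert abs(ratio - kappa) < 3 * se

    def test_estimator_consistency_small_t(self, rng):
        s = random_sequence(120000, rng)
        mu_t = 0.02
        out = evolve_k2p(s, 8.0, RateSpec(2.5e-9), rng=rng)
        d = k2p_distance(s, out).d
        se = np.sqrt(mu_t / 120000)
        assert abs(d - mu_t) < 3 * se

    def test_cpg_multiplier_accelerates(self):
        rng = np.random.default_rng(8)
        s = random_sequence(50000, rng)
        slow = evolve_k2p(s, 8.0, RateSpec(2.5e-9), cpg_multiplier=1.0,
                          seed=5)
        fast = evolve_k2p(s, 8.0, RateSpec(2.5e-9), cpg_multiplier=10.0,
                          seed=5)
        assert k2p_distance(s, fast).d > k2p_distance(s, slow).d


class TestAmplification:
    def test_copy_count_and_alignment_shape(self):
        p = AmplificationParams(master_length=300, n_copies=17, seed=1)
        master, aln, truth = simulate_amplification(p)
        assert aln.n_rows == 17
        assert aln.n_columns == 300
        assert len(truth.insertion_times) == 17

    def test_zero_rate_copies_identical_to_master(self):
        p = AmplificationParams(master_length=200, n_copies=5,
                                rate=RateSpec(1e-30), truncation_p=1.0,
                                seed=2)
        master, aln, truth = simulate_amplification(p)
        for row in aln.rows:
            assert row == master.residues
        assert truth.master_final.residues == master.residues

    def test_insertion_times_within_window(self):
        p = AmplificationParams(n_copies=50, window_start=20,
                                window_end=15, seed=3)
        _, _, truth = simulate_amplification(p)
        assert all(15 <= t <= 20 for t in truth.insertion_times)

    def test_truth_reproducible_under_seed(self):
        p = AmplificationParams(n_copies=20, seed=11)
        r1 = simulate_amplification(p)
        r2 = simulate_amplification(p)
        assert r1[0] == r2[0]
        assert r1[1].rows == r2[1].rows
        assert r1[2].insertion_times == r2[2].insertion_times

    def test_mean_divergence_matches_analytic_expectation(self):
        # E[d to present master] = 2 mu t, averaged over uniform times
        p = AmplificationParams(master_length=2000, n_copies=500,
                                truncation_p=1.0, seed=17)
        _, aln, truth = simulate_amplification(p)
        ds = np.array([k2p_distance(aln.record(c), truth.master_final).d
                       for c in aln.copy_ids])
        mu = p.rate.per_myr()
        expect = 2 * mu * np.mean(truth.insertion_times)
        se = ds.std(ddof=1) / np.sqrt(len(ds))
        # 3 SE of the copy-sampling noise plus the shared master-branch
        # Poisson noise (SD ~ sqrt(mu t L)/L on the common path)
        shared = np.sqrt(mu * 17.5 / p.master_length)
        assert abs(ds.mean() - expect) < 3 * (se + shared)

    def test_truncation_recorded_in_truth(self):
        p = AmplificationParams(master_length=500, n_copies=30,
                                truncation_p=0.01, seed=5)
        _, aln, truth = simulate_amplification(p)
        for row, tr in zip(aln.rows, truth.truncations):
            assert row[:tr] == "-" * tr
            assert "-" not in row[tr:]


class TestTransfers:
    def test_zero_events_congruent(self):
        host = random_binary_tree([f"H{i}" for i in range(6)],
                                  np.random.default_rng(1))
        te, m, truth = simulate_transfers(host, 0, seed=4)
        assert truth.events == ()
        assert min_transfers(te, host, m).transfer_count == 0

    def test_planted_count_upper_bounds_minimum(self):
        for seed in range(10):
            host = random_binary_tree([f"H{i}" for i in range(8)],
                                      np.random.default_rng(seed))
            te, m, truth = simulate_transfers(host, 3, seed=seed)
            assert len(truth.events) == 3
            assert min_transfers(te, host, m).transfer_count <= 3

    def test_map_is_total_and_valid(self):
        host = random_binary_tree([f"H{i}" for i in range(8)],
                                  np.random.default_rng(2))
        te, m, _ = simulate_transfers(host, 4, seed=9)
        hosts = set(host.leaf_names)
        assert set(m) == set(te.leaf_names)
        assert set(m.values()) <= hosts

    def test_infeasible_k_raises(self):
        host = random_binary_tree(["H1", "H2"], np.random.default_rng(0))
        with pytest.raises(SimulationError):
            simulate_transfers(host, 5, seed=1)


class TestAreas:
    def test_zero_dispersals_zero_cost(self):
        from horizonte.biogeography import diva_reconstruct
        tree = random_binary_tree([f"L{i}" for i in range(8)],
                                  np.random.default_rng(5))
        aa, truth = simulate_areas(tree, ("A", "B", "C"), d=0, seed=6)
        assert truth.dispersals == ()
        assert diva_reconstruct(tree, aa).cost == 0

    def test_truth_contains_all_nodes(self):
        tree = random_binary_tree([f"L{i}" for i in range(6)],
                                  np.random.default_rng(7))
        aa, truth = simulate_areas(tree, ("A", "B", "C"), d=1, seed=8)
        n_nodes = sum(1 for _ in tree.postorder())
        assert len(truth.node_areas) == n_nodes
        for leaf in tree.leaf_names:
            assert aa.leaf_areas[leaf] == truth.node_areas[leaf]

    def test_deterministic_under_seed(self):
        tree = random_binary_tree([f"L{i}" for i in range(6)],
                                  np.random.default_rng(9))
        a1 = simulate_areas(tree, ("A", "B", "C"), d=2, seed=10)
        a2 = simulate_areas(tree, ("A", "B", "C"), d=2, seed=10)
        assert a1[0].leaf_areas == a2[0].leaf_areas
        assert a1[1].dispersals == a2[1].dispersals
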