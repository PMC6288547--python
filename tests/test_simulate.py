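import numpy as np
import pytest
from scipy import stats

from phyloarch import MkModel, vcv
from phyloarch.architecture import (branching_index_table, exploration_index,
                                    integrative_index, photosynthetic_index,
                                    segregate_classes)
from phyloarch.simulate import (SimulationConfig, default_classes,
                                forward_tip_count,
                                generate_architecture_individuals,
                                simulate_bd_tree, simulate_bm_traits,
                                simulate_mk_states, simulate_musse)


class TestBdTree:
    def test_conditioned_tip_count_and_ultrametric(self):
        t = simulate_bd_tree(SimulationConfig(seed=0))
        assert t.n_tips == 27
        assert t.is_ultrametric()

    def test_crown_rescale_exact(self):
        t = simulate_bd_tree(SimulationConfig(seed=1))
        assert t.crown_age() == pytest.approx(2.4)

    def test_seed_determinism(self):
        a = simulate_bd_tree(SimulationConfig(seed=7))
        b = simulate_bd_tree(SimulationConfig(seed=7))
        np.testing.assert_array_equal(a.lengths, b.lengths)
        assert a.labels == b.labels

    def test_expected_tip_count(self):
        # E[N(t)] = 2 exp((lambda - mu) t) for a crown start
        lam, mu, t = 1.0, 0.2, 1.5
        counts = [forward_tip_count(lam, mu, t, seed=s) for s in range(800)]
        expected = 2 * np.exp((lam - mu) * t)
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)


class TestMkStates:
    def test_zero_rates_inherit_root(self, tree27):
        ts, nodes = simulate_mk_states(tree27, np.zeros((3, 3)), 2, seed=0)
        assert set(ts.values()) == {2}
        assert set(nodes.tolist()) == {2}

    def test_transition_frequencies_match_expm(self):
        # one long branch: empirical transitions ~ rows of exp(Qt)
        from phyloarch import read_newick
        from scipy.linalg import expm
        tree = read_newick("(A:3.0,B:0.0001);")
        Q = MkModel(3, "SYM", [0.3, 0.15, 0.4]).Q
        P = expm(Q * 3.0)
        counts = np.zeros(3)
        for s in range(1000):
            ts, _ = simulate_mk_states(tree, Q, 1, seed=s)
            counts[ts["A"] - 1] += 1
        chi2 = np.sum((counts - 1000 * P[0]) ** 2 / (1000 * P[0]))
        assert stats.chi2.sf(chi2, df=2) > 1e-4

    def test_relabeling_symmetry_distributional(self, tree27):
        # consistently relabeling (states, Q, root) permutes the tip-state
        # distribution
        Q = MkModel(3, "ARD", [0.5, 0.1, 0.3, 0.2, 0.15, 0.4]).Q
        perm = np.array([2, 0, 1])
        Qp = Q[np.ix_(perm, perm)]
        ca = np.zeros(3)
        cb = np.zeros(3)
        for s in range(300):
            a, _ = simulate_mk_states(tree27, Q, 1, seed=s)
            b, _ = simulate_mk_states(tree27, Qp, int(np.argsort(perm)[0]) + 1,
                                      seed=1000 + s)
            for v in a.values():
                ca[v - 1] += 1
            for v in b.values():
                cb[perm[v - 1]] += 1       # map new index back to old state
        np.testing.assert_allclose(ca / ca.sum(), cb / cb.sum(), atol=0.05)


class TestMusseSim:
    def test_equal_rates_reduces_to_bd(self):
        cfg = SimulationConfig(seed=0)
        counts = []
        for s in range(200):
            n = forward_tip_count(cfg.birth, cfg.death, 1.2, seed=s)
            counts.append(n)
        expected = 2 * np.exp((cfg.birth - cfg.death) * 1.2)
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)

    def test_states_recorded_and_sized(self):
        tree, ts = simulate_musse(SimulationConfig(seed=0).mussemodel(), 27,
                                  root_state=3, seed=2, crown_age=2.4)
        assert tree.n_tips == 27
        assert set(ts) == set(tree.tip_labels)
        assert set(ts.values()) <= {1, 2, 3}

    def test_lambda_asymmetry_enriches_state(self):
        m_hi_b = __import__("phyloarch").MuSSEModel(
            [0.5, 0.5, 1.5], [0.0, 0.0, 0.0],
            np.array([[0, .1, .1], [.1, 0, .1], [.1, .1, 0]]))
        frac_b = []
        for s in range(30):
            _, ts = simulate_musse(m_hi_b, 40, root_state=2, seed=s)
            v = np.array(list(ts.values()))
            frac_b.append(np.mean(v == 3))
        assert np.mean(frac_b) > 1 / 3

    def test_zero_mu_zero_q_monomorphic(self):
        m = __import__("phyloarch").MuSSEModel([1.0] * 3, [0.0] * 3,
                                               np.zeros((3, 3)))
        _, ts = simulate_musse(m, 10, root_state=2, seed=0)
        assert set(ts.values()) == {2}


class TestBmTraits:
    def test_zero_within_sd_replicates_identical(self, tree27):
        obs, reps, true = simulate_bm_traits(tree27, 1.0, 1.0, 0.0, 3, seed=0)
        np.testing.assert_allclose(obs.variance, 0.0)
        g = reps.groupby("species")["value"].nunique()
        assert (g == 1).all()

    def test_lambda_zero_is_iid(self):
        tree = simulate_bd_tree(SimulationConfig(seed=5, n_species=40))
        vals = []
        for s in range(100):
            _, _, true = simulate_bm_traits(tree, 1.0, 0.0, 0.0, 1, seed=s)
            vals.append(true)
        V = np.cov(np.array(vals).T)
        off = V[~np.eye(40, dtype=bool)]
        # no cross-species covariance beyond noise
        assert abs(off.mean()) < 0.15
        depth = tree.crown_age()
        assert np.diag(V).mean() == pytest.approx(depth, rel=0.2)

    def test_cross_species_covariance_matches_sigma2_c(self):
        tree = simulate_bd_tree(SimulationConfig(seed=9, n_species=8))
        sp = sorted(tree.tip_labels)
        C = vcv(tree, order=sp).matrix
        vals = [simulate_bm_traits(tree, 0.7, 1.0, 0.0, 1, seed=s)[2]
                for s in range(2000)]
        V = np.cov(np.array(vals).T)
        np.testing.assert_allclose(V, 0.7 * C, atol=0.12 * 0.7 * C.max())


class TestArchitectureGenerator:
    def test_determinism(self):
        classes = default_classes()
        a = generate_architecture_individuals(classes, seed=3)
        b = generate_architecture_individuals(classes, seed=3)
        assert branching_index_table(a).equals(branching_index_table(b))

    def test_type_invariants_hold(self):
        classes = default_classes()
        for ind in generate_architecture_individuals(classes, seed=1):
            assert ind.trunk_length >= 0
            assert all(a >= 0 for a in ind.trunk_leaf_areas)
            assert (ind.n_branches == 0) == (len(ind.branches) == 0)
            p = photosynthetic_index(ind)
            e = exploration_index(ind)
            assert 0 <= p <= 1 and 0 <= e <= 1

    def test_degenerate_concentration_pins_class_mean(self):
        cfg = SimulationConfig(concentration=1e6, ind_concentration=1e6,
                               individuals=3)
        classes = {f"m{i}": 1 for i in range(3)}
        inds = generate_architecture_individuals(classes, cfg, seed=0)
        ps = [photosynthetic_index(i) for i in inds]
        np.testing.assert_allclose(ps, 0.03, atol=0.01)

    def test_round_trip_class_recovery_reduced(self):
        classes = default_classes()
        ok = 0
        for seed in range(10):
            inds = generate_architecture_individuals(classes, seed=seed)
            table = branching_index_table(inds)
            means = table.groupby("species")[["photo", "explo"]].mean()
            ii = integrative_index(means)
            scores = ii.project(table)
            seg = segregate_classes(
                {sp: scores[table.species == sp].to_numpy()
                 for sp in means.index})
            ok += seg.classes == classes
        assert ok >= 8

    def test_spearman_rho_in_calibrated_band(self):
        classes = default_classes()
        rhos = []
        for seed in range(10):
            inds = generate_architecture_individuals(classes, seed=seed)
            means = branching_index_table(inds).groupby("species")[
                ["photo", "explo"]].mean()
            rhos.append(integrative_index(means).rho_spearman)
        assert 0.75 <= np.mean(rhos) <= 0.95

    def test_unbranched_species_never_branched_class(self):
        # force one monocaulous species to be exactly unbranched
        cfg = SimulationConfig(class_photo=(0.0, 0.36, 0.82),
                               class_explo=(0.0, 0.45, 0.76),
                               concentration=1e6, ind_concentration=1e6)
        classes = default_classes(cfg)
        inds = generate_architecture_individuals(classes, cfg, seed=0)
        zero_sp = {i.species for i in inds if i.n_branches == 0}
        assert zero_sp
        table = branching_index_table(inds)
        means = table.groupby("species")[["photo", "explo"]].mean()
        ii = integrative_index(means)
        scores = ii.project(table)
        seg = segregate_classes({sp: scores[table.species == sp].to_numpy()
                                 for sp in means.index})
        assert all(seg.classes[s] != 3 for s in zero_sp)

    def test_mean_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_photo=(0.0, 0.5, 1.2))
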