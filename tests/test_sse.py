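import numpy as np
import pytest

from phyloarch import (MuSSEModel, build_model_family, fit_family, fit_musse,
                       musse_loglik, read_newick, select_model, sse_ode)
from phyloarch.simulate import SimulationConfig, simulate_bd_tree, simulate_musse
from oracles import bd_closed_form_loglik, bd_extinction_prob


def equal_rates(lam=1.0, mu=0.0, q=0.0, k=3):
    qm = np.full((k, k), q)
    np.fill_diagonal(qm, 0.0)
    return MuSSEModel(np.full(k, lam), np.full(k, mu), qm)


class TestOde:
    def test_all_rates_zero(self):
        m = equal_rates(0.0, 0.0, 0.0)
        dD, dE = sse_ode(0.0, np.array([0.5, 0.2, 0.1]),
                         np.array([0.0, 0.1, 0.3]), m)
        np.testing.assert_allclose(dD, 0.0)
        np.testing.assert_allclose(dE, 0.0)

    def test_yule_closed_form_decay(self):
        # single effective state, q = 0, mu = 0: D(t) = D(0) e^{-lam t}, E = 0
        from phyloarch.sse import _integrate_branch
        lam = 0.8
        y0 = np.zeros(6)
        y0[3:] = 1.0
        y, ok = _integrate_branch(y0, 0.0, 1.5, np.full(3, lam), np.zeros(3),
                                  np.zeros((3, 3)), 1e-10, 1e-12)
        assert ok
        np.testing.assert_allclose(y[:3], 0.0, atol=1e-12)
        np.testing.assert_allclose(y[3:], np.exp(-lam * 1.5), rtol=1e-8)

    @pytest.mark.parametrize("t", [0.5, 1.0, 2.0])
    def test_extinction_probability_closed_form(self, t):
        from phyloarch.sse import _integrate_branch
        lam, mu = 1.2, 0.7
        y0 = np.zeros(6)
        y0[3:] = 1.0
        y, ok = _integrate_branch(y0, 0.0, t, np.full(3, lam), np.full(3, mu),
                                  np.zeros((3, 3)), 1e-12, 1e-14)
        assert ok
        assert y[0] == pytest.approx(bd_extinction_prob(lam, mu, t), abs=1e-8)


class TestLoglik:
    def test_two_tip_yule_by_hand(self):
        tree = read_newick("(A:1.0,B:1.0);")
        lam = 0.9
        ll = musse_loglik(tree, {"A": 1, "B": 1}, equal_rates(lam))
        assert ll == pytest.approx(np.log(lam) - 2 * lam, abs=1e-7)

    def test_single_state_matches_bd_closed_form(self):
        for seed in range(5):
            tree = simulate_bd_tree(SimulationConfig(
                seed=seed, n_species=12, birth=1.0, death=0.3, crown_age=None))
            ts = {lab: 2 for lab in tree.tip_labels}
            lam, mu = 0.9, 0.4
            ll = musse_loglik(tree, ts, equal_rates(lam, mu), rtol=1e-10,
                              atol=1e-12)
            assert ll == pytest.approx(bd_closed_form_loglik(tree, lam, mu),
                                       abs=1e-6)

    def test_rate_time_rescaling_with_jacobian(self):
        # multiplying rates by c and dividing lengths by c changes lnL only
        # by the speciation-density Jacobian (n-1) log c
        tree = simulate_bd_tree(SimulationConfig(seed=2, n_species=10))
        from phyloarch.tree import PhyloTree
        c = 2.5
        scaled = PhyloTree(tree.parent.copy(), tree.lengths / c,
                           tree.children, tree.labels)
        ts = {lab: 1 + i % 3 for i, lab in enumerate(tree.tip_labels)}
        m = equal_rates(1.0, 0.2, 0.15)
        mc = MuSSEModel(m.lam * c, m.mu * c, m.q * c)
        ll = musse_loglik(tree, ts, m, rtol=1e-10, atol=1e-12)
        llc = musse_loglik(scaled, ts, mc, rtol=1e-10, atol=1e-12)
        assert llc == pytest.approx(ll + (tree.n_tips - 1) * np.log(c),
                                    abs=1e-6)

    def test_renormalization_schedule_irrelevant(self):
        tree = simulate_bd_tree(SimulationConfig(seed=4, n_species=8))
        ts = {lab: 1 + i % 3 for i, lab in enumerate(tree.tip_labels)}
        m = equal_rates(1.1, 0.3, 0.2)
        a = musse_loglik(tree, ts, m, renorm="node", rtol=1e-12, atol=1e-14)
        b = musse_loglik(tree, ts, m, renorm="never", rtol=1e-12, atol=1e-14)
        assert a == pytest.approx(b, abs=1e-8)

    def test_state_relabeling_symmetry(self):
        tree = simulate_bd_tree(SimulationConfig(seed=6, n_species=10))
        ts = {lab: 1 + i % 3 for i, lab in enumerate(tree.tip_labels)}
        lam = np.array([0.8, 1.2, 1.6])
        mu = np.array([0.1, 0.2, 0.05])
        q = np.array([[0, 0.1, 0.2], [0.3, 0, 0.15], [0.25, 0.05, 0]], float)
        perm = [2, 0, 1]
        inv = np.argsort(perm)
        m1 = MuSSEModel(lam, mu, q)
        m2 = MuSSEModel(lam[perm], mu[perm], q[np.ix_(perm, perm)])
        ts2 = {s: int(inv[v - 1]) + 1 for s, v in ts.items()}
        assert musse_loglik(tree, ts, m1) == pytest.approx(
            musse_loglik(tree, ts2, m2), abs=1e-8)

    def test_polytomy_rejected(self):
        tree = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="polytomy"):
            musse_loglik(tree, {"A": 1, "B": 1, "C": 1}, equal_rates())

    def test_scipy_cross_check(self, tree27):
        from phyloarch.simulate import simulate_mk_states
        from phyloarch import MkModel
        ts, _ = simulate_mk_states(tree27, MkModel(3, "ER", [0.3]).Q, 3, seed=1)
        m = equal_rates(1.2, 0.1, 0.1)
        a = musse_loglik(tree27, ts, m)
        b = musse_loglik(tree27, ts, m, method="scipy")
        assert a == pytest.approx(b, abs=1e-5)

    def test_python_fallback_integrator_agrees(self, tree27):
        from phyloarch.simulate import simulate_mk_states
        from phyloarch import MkModel
        ts, _ = simulate_mk_states(tree27, MkModel(3, "ER", [0.3]).Q, 3, seed=2)
        m = equal_rates(1.1, 0.2, 0.1)
        a = musse_loglik(tree27, ts, m)
        b = musse_loglik(tree27, ts, m, method="python")
        assert a == pytest.approx(b, abs=1e-9)

    def test_e_bounded_and_monotone(self):
        from phyloarch.sse import _integrate_branch
        lam, mu = 1.0, 0.6
        vals = []
        for t in np.linspace(0.1, 3.0, 8):
            y0 = np.zeros(6)
            y0[3:] = 1.0
            y, _ = _integrate_branch(y0, 0.0, float(t), np.full(3, lam),
                                     np.full(3, mu), np.zeros((3, 3)),
                                     1e-10, 1e-12)
            vals.append(y[0])
        vals = np.array(vals)
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all((vals >= 0) & (vals <= 1))


class TestFamily:
    def test_family_size_and_counts(self):
        fam = build_model_family()
        assert len(fam) == 15
        counts = {p.name: p.n_params for p in fam}
        assert counts["1"] == 12
        assert counts["2"] == 3
        assert counts["3"] == 5
        assert counts["4"] == 7
        assert counts["5"] == 10
        assert counts["6"] == 8
        assert counts["7"] == 10
        assert all(counts[m] == 4 for m in ("8a", "8b", "8c"))
        assert all(counts[m] == 3 for m in ("9a", "9b", "9c"))
        assert counts["10"] == 2
        assert counts["11"] == 4

    def test_every_model_nests_in_model_one(self):
        fam = build_model_family()
        m1 = fam[0]
        assert all(p.nests_in(m1) for p in fam)

    def test_expand_project_round_trip(self):
        fam = {p.name: p for p in build_model_family()}
        theta = np.array([0.5, 1.5, 0.2, 0.3])
        m = fam["8a"].to_model(theta)
        np.testing.assert_allclose(m.lam, [0.5, 0.5, 1.5])
        np.testing.assert_allclose(m.mu, 0.2)
        back = fam["8a"].start_from(m)
        np.testing.assert_allclose(back, theta)

    def test_monomorphic_zero_q(self):
        tree = simulate_bd_tree(SimulationConfig(seed=3, n_species=8))
        ts = {lab: 2 for lab in tree.tip_labels}
        m = equal_rates(1.0, 0.0, 0.0)
        assert np.isfinite(musse_loglik(tree, ts, m))


class TestFitting:
    def test_model_one_dominates(self):
        tree, ts = simulate_musse(SimulationConfig(seed=0).mussemodel(), 16,
                                  root_state=2, seed=11, crown_age=2.4)
        fits = fit_family(tree, ts, seed=0, n_starts=1)
        m1 = next(f for f in fits if f.model == "1")
        for f in fits:
            assert m1.loglik >= f.loglik - 1e-6

    def test_equal_rates_selection_reduced(self):
        wins = 0
        for rep in range(5):
            tree, ts = simulate_musse(SimulationConfig(seed=0).mussemodel(),
                                      27, root_state=3, seed=400 + rep,
                                      crown_age=2.4)
            fits = fit_family(tree, ts, seed=rep)
            wins += select_model(fits).model in ("2", "10")
        assert wins >= 2

    def test_single_model_failure_recorded(self, tree27, monkeypatch):
        from phyloarch import sse as sse_mod

        orig = sse_mod.fit_musse

        def breaking(tree, ts, pattern, **kw):
            if pattern.name == "7":
                raise RuntimeError("synthetic failure")
            return orig(tree, ts, pattern, **kw)

        monkeypatch.setattr(sse_mod, "fit_musse", breaking)
        ts = {lab: 1 + i % 3 for i, lab in enumerate(tree27.tip_labels)}
        fam = [p for p in build_model_family() if p.name in ("2", "7", "10")]
        fits = sse_mod.fit_family(tree27, ts, fam, seed=0, n_starts=1)
        by = {f.model: f for f in fits}
        assert not by["7"].converged and by["7"].aicc == np.inf
        assert by["2"].converged
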