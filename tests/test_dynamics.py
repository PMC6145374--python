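import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lignindyn.dynamics import (
    EnzymeActivityProfile,
    LabeledState,
    assemble_rhs,
    find_steady_state,
    gma_flux,
    integrate,
    split_flux,
)
from lignindyn.topology import CYTOSOL, ER


@pytest.fixture(scope="module")
def truth_rhs(ground_truth):
    gt = ground_truth
    return assemble_rhs(gt.topology, gt.params, None, gt.feed)


class TestGmaFlux:
    def test_direct_evaluation(self, ground_truth):
        # a=2, substrate pooled (30, 70), g=0.5, enzyme=100, h=1 -> 2000
        gt = ground_truth
        t = gt.topology
        p = gt.params
        state = LabeledState.zeros(t)
        rxn = t.reaction("V1")
        idx = t.pool_index(rxn.substrate, rxn.compartment)
        state.labeled[idx] = 30.0
        state.unlabeled[idx] = 70.0
        import copy

        p2 = copy.deepcopy(p)
        p2.a["V1"] = 2.0
        p2.g["V1"] = 0.5
        assert gma_flux("V1", state, p2) == pytest.approx(2.0 * np.sqrt(100.0) * 100.0)

    def test_zero_orders_give_rate_constant(self, ground_truth):
        # g = 0 and no enzyme factor (sink flux): V == a
        import copy

        gt = ground_truth
        p2 = copy.deepcopy(gt.params)
        p2.g["H"] = 0.0
        state = LabeledState.zeros(gt.topology)
        assert gma_flux("H", state, p2) == pytest.approx(p2.a["H"])

    def test_label_blindness(self, ground_truth):
        gt = ground_truth
        t = gt.topology
        rxn = t.reaction("V5")
        idx = t.pool_index(rxn.substrate, rxn.compartment)
        s1 = LabeledState.zeros(t)
        s1.labeled[idx], s1.unlabeled[idx] = 30.0, 70.0
        s2 = LabeledState.zeros(t)
        s2.labeled[idx], s2.unlabeled[idx] = 70.0, 30.0
        assert gma_flux("V5", s1, gt.params) == gma_flux("V5", s2, gt.params)

    def test_er_reaction_reads_er_pool(self, ground_truth):
        gt = ground_truth
        t = gt.topology
        state = LabeledState.zeros(t)
        # fill only cytosolic pools; ER reaction with g>0 must see zero substrate
        state.unlabeled[: len(t.metabolites)] = 100.0
        v25 = gma_flux("V25", state, gt.params)
        if gt.params.g["V25"] > 0:
            assert v25 == 0.0


class TestSplitFlux:
    def test_worked_example(self):
        assert split_flux(20.0, 30.0, 100.0) == (6.0, 14.0)

    def test_edge_cases(self):
        assert split_flux(5.0, 0.0, 10.0) == (0.0, 5.0)
        v_l, v_ul = split_flux(5.0, 10.0, 10.0)
        assert v_l == pytest.approx(5.0) and v_ul == pytest.approx(0.0)
        assert split_flux(0.0, 0.0, 0.0) == (0.0, 0.0)

    def test_zero_substrate_with_flux_errors(self):
        with pytest.raises(ValueError):
            split_flux(1.0, 0.0, 0.0)

    @given(
        v=st.floats(0.0, 1e6),
        lab=st.floats(0.0, 1.0),
        tot=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_splits_sum_exactly(self, v, lab, tot):
        labeled = lab * tot
        v_l, v_ul = split_flux(v, labeled, tot)
        assert v_l + v_ul == pytest.approx(v, rel=1e-15, abs=1e-300)
        assert v_l >= 0.0 and v_ul >= 0.0


class TestRhs:
    def test_equation_count_is_68(self, truth_rhs):
        assert truth_rhs.n_equations == 68

    def test_wild_type_steady_state_is_root(self, ground_truth, truth_rhs):
        gt = ground_truth
        x0 = LabeledState.from_pooled(gt.topology, gt.params.wild_type_pooled(), 0.3)
        dy = truth_rhs(0.0, x0.vector())
        n = gt.topology.n_pools
        # pooled derivative (labeled + unlabeled) vanishes at the steady state
        assert np.max(np.abs(dy[:n] + dy[n : 2 * n])) < 1e-9

    def test_labeled_plus_unlabeled_equals_pooled_equation(self, ground_truth, truth_rhs):
        gt = ground_truth
        rng = np.random.default_rng(0)
        pooled = rng.uniform(10.0, 150.0, gt.topology.n_pools)
        frac = rng.uniform(0.0, 1.0, gt.topology.n_pools)
        state = LabeledState.zeros(gt.topology)
        state.labeled = pooled * frac
        state.unlabeled = pooled * (1 - frac)
        dy = truth_rhs(0.0, state.vector())
        n = gt.topology.n_pools
        assert np.allclose(dy[:n] + dy[n : 2 * n], truth_rhs.pooled_rhs(pooled), atol=1e-9)

    def test_total_mass_conservation(self, ground_truth, truth_rhs):
        """Volume-weighted pool mass + sink mass changes only by feed influx."""
        gt = ground_truth
        t = gt.topology
        rng = np.random.default_rng(1)
        pooled = rng.uniform(10.0, 150.0, t.n_pools)
        state = LabeledState.from_pooled(t, pooled, 0.5)
        dy = truth_rhs(0.0, state.vector())
        n = t.n_pools
        w = np.array(
            [gt.params.r if comp == CYTOSOL else 1 - gt.params.r for _m, comp in t.pools()]
        )
        pool_mass_rate = np.sum((dy[:n] + dy[n : 2 * n]) * w)
        sink_mass_rate = np.sum(dy[2 * n :])
        assert pool_mass_rate + sink_mass_rate == pytest.approx(
            gt.feed.total_influx, rel=1e-10
        )

    def test_label_redistribution_leaves_pooled_dynamics_unchanged(
        self, ground_truth, truth_rhs
    ):
        gt = ground_truth
        rng = np.random.default_rng(2)
        pooled = rng.uniform(10.0, 150.0, gt.topology.n_pools)
        n = gt.topology.n_pools
        outs = []
        for frac in (0.0, 0.3, 0.9):
            state = LabeledState.from_pooled(gt.topology, pooled, frac)
            dy = truth_rhs(0.0, state.vector())
            outs.append(dy[:n] + dy[n : 2 * n])
        assert np.allclose(outs[0], outs[1], atol=1e-9)
        assert np.allclose(outs[0], outs[2], atol=1e-9)

    def test_zero_diffusion_decouples_compartments(self, ground_truth):
        import copy

        gt = ground_truth
        t = gt.topology
        p = copy.deepcopy(gt.params)
        p.d = {k: 0.0 if np.isfinite(v) else v for k, v in p.d.items()}
        rhs = assemble_rhs(t, p, None, gt.feed)
        rng = np.random.default_rng(3)
        pooled = rng.uniform(10.0, 150.0, t.n_pools)
        base = rhs.pooled_rhs(pooled)
        # perturbing every ER pool must not change any cytosolic derivative
        perturbed = pooled.copy()
        perturbed[len(t.metabolites) :] *= 1.7
        after = rhs.pooled_rhs(perturbed)
        nx = len(t.metabolites)
        assert np.allclose(base[:nx], after[:nx], atol=1e-9)


class TestIntegrate:
    def test_zero_feed_zero_state(self, ground_truth):
        from lignindyn.observables import FeedSpec

        gt = ground_truth
        rhs = assemble_rhs(
            gt.topology, gt.params, None, FeedSpec(phe_rate=0.0, tyr_rate=0.0)
        )
        traj = integrate(rhs, LabeledState.zeros(gt.topology), 10.0)
        assert np.max(np.abs(traj.y)) < 1e-12

    def test_steady_state_initial_condition_stays_constant(self, ground_truth, truth_rhs):
        gt = ground_truth
        x0 = LabeledState.from_pooled(gt.topology, gt.params.wild_type_pooled(), 0.0)
        traj = integrate(truth_rhs, x0, 50.0)
        n = gt.topology.n_pools
        final_pooled = traj.y[:n, -1] + traj.y[n : 2 * n, -1]
        assert np.allclose(final_pooled, gt.params.wild_type_pooled(), rtol=1e-6)

    def test_label_split_of_initial_state_preserves_pooled_trajectory(
        self, ground_truth, truth_rhs
    ):
        gt = ground_truth
        n = gt.topology.n_pools
        t_eval = np.linspace(0, 20, 5)
        pooled_runs = []
        for frac in (0.2, 0.8):
            x0 = LabeledState.from_pooled(gt.topology, gt.params.wild_type_pooled(), frac)
            traj = integrate(truth_rhs, x0, 20.0, t_eval=t_eval)
            pooled_runs.append(traj.y[:n] + traj.y[n : 2 * n])
        assert np.allclose(pooled_runs[0], pooled_runs[1], rtol=1e-6, atol=1e-8)

    def test_label_conservation_along_trajectory(self, ground_truth):
        """d/dt (labeled mass in pools + sinks) equals the labeled influx."""
        gt = ground_truth
        t = gt.topology
        rhs = assemble_rhs(t, gt.params, None, gt.feed.with_labels(1.0, 0.0))
        x0 = LabeledState.from_pooled(t, gt.params.wild_type_pooled(), 0.0)
        horizon = 40.0
        traj = integrate(rhs, x0, horizon)
        final = traj.final_state()
        w = np.array(
            [gt.params.r if comp == CYTOSOL else 1 - gt.params.r for _m, comp in t.pools()]
        )
        labeled_mass = float(np.sum(final.labeled * w) + np.sum(final.sink_labeled))
        expected = gt.feed.phe_rate * horizon
        assert labeled_mass == pytest.approx(expected, rel=1e-6)

    def test_invalid_horizon_rejected(self, ground_truth, truth_rhs):
        x0 = LabeledState.zeros(ground_truth.topology)
        with pytest.raises(ValueError):
            integrate(truth_rhs, x0, -1.0)


class TestFindSteadyState:
    def test_wild_type_returned_unchanged(self, ground_truth, truth_rhs):
        gt = ground_truth
        wt = gt.params.wild_type_pooled()
        state, res = find_steady_state(truth_rhs, wt)
        assert res < 1e-9
        assert np.allclose(state, wt, rtol=1e-6)

    def test_knockdown_steady_state_matches_long_integration(self, ground_truth):
        gt = ground_truth
        t = gt.topology
        e = EnzymeActivityProfile({"CCR": 0.5})
        rhs = assemble_rhs(t, gt.params, e, gt.feed)
        wt = gt.params.wild_type_pooled()
        state, res = find_steady_state(rhs, wt)
        assert res < 1e-8
        assert not np.allclose(state, wt, rtol=1e-3)
        # oracle: long-horizon relaxation of the pooled system
        x0 = LabeledState.from_pooled(t, wt, 0.0)
        traj = integrate(rhs, x0, 2000.0, rtol=1e-9, atol=1e-11)
        relaxed = traj.final_state().pooled()
        assert np.allclose(state, relaxed, rtol=1e-4, atol=1e-6)

    def test_local_stability_of_ground_truth(self, ground_truth, truth_rhs):
        gt = ground_truth
        jac = truth_rhs.pooled_jacobian(gt.params.wild_type_pooled())
        assert np.max(np.real(np.linalg.eigvals(jac))) < 0

    def test_small_perturbation_relaxes_back(self, ground_truth, truth_rhs):
        gt = ground_truth
        wt = gt.params.wild_type_pooled()
        pert = wt.copy()
        pert[5] *= 1.01
        x0 = LabeledState.from_pooled(gt.topology, pert, 0.0)
        traj = integrate(truth_rhs, x0, 1000.0)
        assert np.allclose(traj.final_state().pooled(), wt, rtol=1e-4)
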