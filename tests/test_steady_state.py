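import numpy as np
import pytest
from scipy.optimize import fsolve

from lignindyn import steady_state as ss
from lignindyn.observables import FeedSpec, make_bands
from lignindyn.steady_state import (
    DegeneratePoolError,
    InfeasibleLabelingError,
    NoAdmissibleFluxError,
    compute_compartment_steady_states,
    detect_degenerate_pools,
    flux_ensemble_summary,
    propagate_label_fractions,
    sample_degenerate_steady_states,
    sample_steady_state_fluxes,
    solve_diffusion_link,
    static_readouts,
)
from lignindyn.topology import CYTOSOL, ER


def brute_force_link_solve(D, D_L, L_X, L_Y, r):
    """Independent oracle: generic numeric solve of the 3x3 system."""

    def eqs(v):
        d, x, y = v
        return [d * (x - y) - D, d * (L_X * x - L_Y * y) - D_L, r * x + (1 - r) * y - 100.0]

    sol, info, ier, _ = fsolve(eqs, [0.5, 120.0, 30.0], full_output=True)
    return sol, ier


class TestFluxSampling:
    def test_mass_balance_exact(self, flux_sample):
        assert flux_sample.mass_balance_residual() < 1e-10

    def test_all_fluxes_nonnegative_except_net_diffusion(self, topology, flux_sample):
        diff_ids = {d.id for d in topology.diffusion_links}
        for fid, v in flux_sample.values.items():
            if fid not in diff_ids:
                assert v >= 0.0

    def test_self_consistent_targets_accepted(self, topology, flux_sample):
        # noise-free targets generated from a known flux vector admit it
        bands = make_bands(static_readouts(topology, flux_sample))
        readouts = static_readouts(topology, flux_sample)
        for scen in bands.scenarios():
            assert bands.contains(scen, readouts[scen])

    def test_accepted_distributions_satisfy_targets(self, topology, flux_sample):
        bands = make_bands(static_readouts(topology, flux_sample))
        ens = sample_steady_state_fluxes(topology, bands, 2, seed=3, max_attempts=20000)
        assert len(ens) == 2
        assert 0 < ens.acceptance_rate <= 1
        for fd in ens:
            ro = static_readouts(topology, fd)
            for scen in bands.scenarios():
                assert bands.contains(scen, ro[scen])
            assert fd.mass_balance_residual() < 1e-9

    def test_impossible_target_raises(self, topology):
        # demand more G-sink flux than the total influx can supply
        bands = make_bands(
            {
                "control": ss.static_readouts(
                    topology, sample_steady_state_fluxes(topology, None, 1, seed=5)[0]
                )["control"]
            }
        )
        bands.bands["control"]["g_total"] = (500.0, 600.0)  # total influx is 100
        with pytest.raises(NoAdmissibleFluxError):
            sample_steady_state_fluxes(topology, bands, 1, seed=5, max_attempts=300)

    def test_seed_reproducibility(self, topology):
        a = sample_steady_state_fluxes(topology, None, 3, seed=42)
        b = sample_steady_state_fluxes(topology, None, 3, seed=42)
        for fa, fb in zip(a, b):
            assert fa.values == fb.values


class TestLabelPropagation:
    def test_fully_labeled_sources_saturate(self, topology, flux_sample):
        lf = propagate_label_fractions(
            topology, flux_sample, flux_sample.feed.with_labels(1.0, 1.0)
        )
        active = lf.throughput > 1e-9
        assert np.allclose(lf.L[active], 1.0, atol=1e-9)

    def test_unlabeled_sources_give_zero(self, topology, flux_sample):
        lf = propagate_label_fractions(
            topology, flux_sample, flux_sample.feed.with_labels(0.0, 0.0)
        )
        active = lf.throughput > 1e-9
        assert np.allclose(lf.L[active], 0.0, atol=1e-12)

    def test_every_pool_is_flux_weighted_average_of_inflows(
        self, topology, flux_sample, phe_label_field
    ):
        """Independent re-check: L_pool * total inflow == sum(inflow * L_src)."""
        t, f, lf = topology, flux_sample, phe_label_field
        feed = f.feed.with_labels(1.0, 0.0)
        for m in t.metabolites:
            for comp in (CYTOSOL, ER):
                if comp == ER and not m.has_er_pool:
                    continue
                inflow = 0.0
                labeled_in = 0.0
                for r in t.producers(m.id, comp):
                    v = f.values[r.id]
                    inflow += v
                    labeled_in += v * lf.label(r.substrate, r.compartment)
                if m.has_er_pool:
                    fxy, fyx = f.gross_diffusion[m.id]
                    if comp == CYTOSOL:
                        inflow += fyx
                        labeled_in += fyx * lf.label(m.id, ER)
                    else:
                        inflow += fxy
                        labeled_in += fxy * lf.label(m.id, CYTOSOL)
                if m.id == 1 and comp == CYTOSOL:
                    inflow += feed.phe_rate
                    labeled_in += feed.phe_rate * feed.phe_label
                if m.id == 3 and comp == CYTOSOL:
                    inflow += feed.tyr_rate
                    labeled_in += feed.tyr_rate * feed.tyr_label
                if inflow > 1e-9:
                    assert lf.label(m.id, comp) * inflow == pytest.approx(labeled_in, rel=1e-8)

    def test_labels_within_unit_interval(self, phe_label_field):
        valid = ~np.isnan(phe_label_field.L)
        assert np.all(phe_label_field.L[valid] >= 0.0)
        assert np.all(phe_label_field.L[valid] <= 1.0)


class TestDiffusionLinkSolve:
    def test_worked_example(self):
        sol = solve_diffusion_link(D=10.0, D_L=8.0, L_X=0.6, L_Y=0.2, r=0.9)
        assert sol.X_ss == pytest.approx(107.142857142857, rel=1e-9)
        assert sol.Y_ss == pytest.approx(35.7142857142857, rel=1e-9)
        assert sol.d == pytest.approx(0.14, rel=1e-9)

    def test_solution_satisfies_all_three_equations(self):
        sol = solve_diffusion_link(D=10.0, D_L=8.0, L_X=0.6, L_Y=0.2, r=0.9)
        assert sol.d * (sol.X_ss - sol.Y_ss) == pytest.approx(10.0, rel=1e-12)
        assert sol.d * (0.6 * sol.X_ss - 0.2 * sol.Y_ss) == pytest.approx(8.0, rel=1e-12)
        assert 0.9 * sol.X_ss + 0.1 * sol.Y_ss == pytest.approx(100.0, abs=1e-10)

    def test_degenerate_labels_raise(self):
        with pytest.raises(DegeneratePoolError):
            solve_diffusion_link(D=10.0, D_L=5.0, L_X=0.4, L_Y=0.4, r=0.9)

    def test_infeasible_labeling_raises(self):
        with pytest.raises(InfeasibleLabelingError):
            solve_diffusion_link(D=10.0, D_L=-8.0, L_X=0.6, L_Y=0.2, r=0.9)

    def test_agrees_with_brute_force_oracle(self, rng):
        checked = 0
        while checked < 200:
            r = rng.uniform(0.5, 0.95)
            x = rng.uniform(1.0, 199.0)
            y = (100.0 - r * x) / (1.0 - r)
            if y <= 0:
                continue
            d = rng.uniform(1e-3, 5.0)
            lx, ly = rng.uniform(0.0, 1.0, size=2)
            if abs(lx - ly) < 1e-3 or abs(x - y) < 1e-6:
                continue
            D = d * (x - y)
            D_L = d * (lx * x - ly * y)
            sol = solve_diffusion_link(D, D_L, lx, ly, r)
            assert sol.X_ss == pytest.approx(x, rel=1e-9)
            assert sol.Y_ss == pytest.approx(y, rel=1e-9)
            assert sol.d == pytest.approx(d, rel=1e-9)
            brute, ier = brute_force_link_solve(D, D_L, lx, ly, r)
            if ier == 1:
                assert sol.d == pytest.approx(brute[0], rel=1e-6)
                assert sol.X_ss == pytest.approx(brute[1], rel=1e-6)
                assert sol.Y_ss == pytest.approx(brute[2], rel=1e-6)
            checked += 1


class TestDegeneratePools:
    def test_builtin_topology_phe_feed(self, phe_label_field):
        assert detect_degenerate_pools(phe_label_field) == [2, 9, 16, 17]

    def test_same_ids_for_tyr_feed(self, topology, flux_sample):
        lf = propagate_label_fractions(
            topology, flux_sample, flux_sample.feed.with_labels(0.0, 1.0)
        )
        assert detect_degenerate_pools(lf) == [2, 9, 16, 17]

    def test_structural_across_flux_samples(self, topology):
        for seed in range(4):
            fd = sample_steady_state_fluxes(topology, None, 1, seed=100 + seed)[0]
            lf = propagate_label_fractions(topology, fd, fd.feed.with_labels(1.0, 0.0))
            assert detect_degenerate_pools(lf) == [2, 9, 16, 17]

    def test_distinct_labels_give_empty_list(self, topology, phe_label_field):
        import copy

        lf = copy.deepcopy(phe_label_field)
        lf.L = np.linspace(0.01, 0.99, lf.L.size)  # all distinct
        assert detect_degenerate_pools(lf) == []

    def test_full_tolerance_returns_all_flowing_pools(self, topology, phe_label_field):
        got = set(detect_degenerate_pools(phe_label_field, tol=1.0))
        expected = {
            m.id
            for m in topology.metabolites
            if m.has_er_pool
            and not m.is_source
            and abs(phe_label_field.net_diffusion[m.id]) > 1e-9
        }
        assert got == expected


class TestDegenerateSampling:
    def test_partner_from_normalization(self, topology, flux_sample):
        r = 0.9
        out = sample_degenerate_steady_states(flux_sample, [2, 9, 16, 17], r, seed=3)
        for met, (x, y, d) in out.items():
            assert r * x + (1 - r) * y == pytest.approx(100.0, abs=1e-10)
            # Eq-1 holds exactly against the distribution's net diffusion flux
            link = topology.diffusion_link_for(met)
            assert d * (x - y) == pytest.approx(flux_sample.values[link.id] / r, rel=1e-10)
            assert d > 0

    def test_receiving_pool_below_100(self, topology, flux_sample):
        out = sample_degenerate_steady_states(flux_sample, [2, 9, 16, 17], 0.9, seed=3)
        for met, (x, y, d) in out.items():
            link = topology.diffusion_link_for(met)
            net = flux_sample.values[link.id]
            receiver = y if net > 0 else x
            partner = x if net > 0 else y
            assert receiver < 100.0 < partner

    def test_deterministic_under_seed(self, flux_sample):
        a = sample_degenerate_steady_states(flux_sample, [2, 9], 0.9, seed=77)
        b = sample_degenerate_steady_states(flux_sample, [2, 9], 0.9, seed=77)
        assert a == b

    def test_paper_receiver_pattern(self, topology, flux_sample, phe_label_field):
        """Net diffusion pours into Y for cinnamic acid and into X for the
        three downstream degenerate pools."""
        cs = compute_compartment_steady_states(
            topology, flux_sample, phe_label_field, 0.9, seed=5
        )
        assert cs.sampled[2][1] < 100.0 < cs.sampled[2][0]  # Y2 receives
        for met in (9, 16, 17):
            assert cs.sampled[met][0] < 100.0 < cs.sampled[met][1]  # X receives


class TestCompartmentStates:
    def test_normalization_everywhere(self, topology, flux_sample, phe_label_field):
        cs = compute_compartment_steady_states(topology, flux_sample, phe_label_field, 0.9, seed=2)
        for m in topology.metabolites:
            i = m.id - 1
            if m.has_er_pool:
                assert 0.9 * cs.X[i] + 0.1 * cs.Y[i] == pytest.approx(100.0, abs=1e-9)
            else:
                assert cs.X[i] == 100.0

    def test_solved_links_reproduce_net_diffusion(self, topology, flux_sample, phe_label_field):
        r = 0.9
        cs = compute_compartment_steady_states(topology, flux_sample, phe_label_field, r, seed=2)
        for m in topology.metabolites:
            if not m.has_er_pool:
                continue
            link = topology.diffusion_link_for(m.id)
            i = m.id - 1
            assert cs.d[i] * (cs.X[i] - cs.Y[i]) == pytest.approx(
                flux_sample.values[link.id] / r, abs=1e-9
            )

    def test_matches_explicit_link_solver_on_nondegenerate(
        self, topology, flux_sample, phe_label_field
    ):
        r = 0.9
        cs = compute_compartment_steady_states(topology, flux_sample, phe_label_field, r, seed=2)
        degenerate = set(detect_degenerate_pools(phe_label_field))
        for m in topology.metabolites:
            if not m.has_er_pool or m.id in degenerate or m.is_source:
                continue
            if abs(phe_label_field.net_diffusion[m.id]) <= 1e-9:
                continue  # idle link: pinned at X = Y = 100, nothing to solve
            fxy, fyx = flux_sample.gross_diffusion[m.id]
            lx = phe_label_field.label(m.id, CYTOSOL)
            ly = phe_label_field.label(m.id, ER)
            sol = solve_diffusion_link(
                (fxy - fyx) / r, (fxy * lx - fyx * ly) / r, lx, ly, r
            )
            i = m.id - 1
            assert sol.X_ss == pytest.approx(cs.X[i], rel=1e-8)
            assert sol.Y_ss == pytest.approx(cs.Y[i], rel=1e-8)
            assert sol.d == pytest.approx(cs.d[i], rel=1e-8)


class TestEnsembleSummary:
    def test_identical_vectors_zero_iqr(self, topology, flux_sample):
        df = flux_ensemble_summary([flux_sample] * 4)
        assert np.allclose(df["q75"] - df["q25"], 0.0)

    def test_median_of_three(self, topology, flux_sample):
        import copy

        dists = []
        for scale in (1.0, 2.0, 3.0):
            fd = copy.deepcopy(flux_sample)
            fd.values = {k: v * scale for k, v in fd.values.items()}
            dists.append(fd)
        df = flux_ensemble_summary(dists)
        for fid in topology.flux_ids:
            assert df.loc[fid, "median"] == pytest.approx(2.0 * flux_sample.values[fid])

    def test_permutation_invariance(self, flux_sample, topology):
        ens = sample_steady_state_fluxes(topology, None, 4, seed=9)
        a = flux_ensemble_summary(list(ens))
        b = flux_ensemble_summary(list(ens)[::-1])
        assert np.allclose(a[["median", "q25", "q75", "min", "max"]], b[["median", "q25", "q75", "min", "max"]])

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            flux_ensemble_summary([])
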