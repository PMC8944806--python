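"""Equilibrium ensembles, FDCs, pathway statistics, apparatus stiffness."""

import numpy as np
import pytest
from scipy.special import logsumexp

from repeatspring import analysis
from repeatspring.elasticity import stretch_free_energy
from repeatspring.engine import (
    EnsembleModel,
    configuration_total_energy,
    simulate_apparatus_stiffness,
)
from repeatspring.ising import (
    Approximation,
    Configuration,
    HelixIsingParams,
    RESIDUES_PER_HELIX,
    RepeatParams,
    config_fold_energy,
    enumerate_configurations,
    helix_params_from_repeat,
)
from repeatspring.presets import get_preset
from repeatspring.superhelix import SuperhelixGeometry, extension_for_configuration

ROD = SuperhelixGeometry(radius=0.0, rise_per_repeat=0.9)


@pytest.fixture(scope="module")
def rv5(network):
    p = get_preset("ctprrv5")
    return EnsembleModel(p.helix_params(), p.geometry, network, 5)


class TestConfigurationTotalEnergy:
    def test_fully_unfolded_at_slack_is_zero(self, network):
        p = get_preset("ctprrv3")
        state = np.zeros(6, dtype=int)
        assert configuration_total_energy(state, 0.5, p.helix_params(), p.geometry, network) == 0.0

    def test_mechanical_term_dominates_at_large_separation(self, network):
        p = get_preset("ctprrv3")
        hp = p.helix_params()
        folded = np.ones(6, dtype=int)
        unfolded = np.zeros(6, dtype=int)
        d = 460.0
        e_f = configuration_total_energy(folded, d, hp, p.geometry, network)
        e_u = configuration_total_energy(unfolded, d, hp, p.geometry, network)
        # at small separations the fold energy favours the folded state;
        # far out, holding the folded state costs more mechanical energy
        assert e_f > e_u
        e_f0 = configuration_total_energy(folded, 350.0, hp, p.geometry, network)
        e_u0 = configuration_total_energy(unfolded, 350.0, hp, p.geometry, network)
        assert e_f0 < e_u0

    def test_composition_oracle_two_repeats(self, network):
        # independently compose fold energy + superhelix chord + per-element
        # stretching work at the balanced tension
        from repeatspring.elasticity import series_force_balance

        p = get_preset("ctpra5")
        hp = p.helix_params()
        state = Configuration.from_string("0111")
        d = 800.0
        xi = extension_for_configuration(state, p.geometry)
        contour = (4 - 3) * RESIDUES_PER_HELIX * network.nm_per_residue
        force = series_force_balance(d, network, xi, contour)
        mech = 2 * force**2 / (2 * network.trap_stiffness)
        mech += stretch_free_energy(force, network.handle)
        mech += stretch_free_energy(force, network.chain(contour))
        expected = config_fold_energy(state, hp) * network.thermal_energy + mech
        got = configuration_total_energy(state, d, hp, p.geometry, network)
        assert got == pytest.approx(expected, rel=1e-6)


class TestEquilibriumFdc:
    def test_zero_repeat_protein_equals_handle_response(self, network, mech_table):
        model = EnsembleModel(
            HelixIsingParams(0, 0, 0, 0), ROD, network, 0, table=mech_table
        )
        d = np.linspace(50.0, 400.0, 101)
        fdc = model.force_curve(d)
        f_ref, _ = mech_table.solve(d, 0.0, 0.0)
        assert np.allclose(fdc.force, f_ref, atol=1e-9)

    def test_deep_fold_energy_gives_folded_branch(self, network, mech_table):
        p = get_preset("ctprrv3")
        frozen = HelixIsingParams(-200.0, -200.0, -200.0, -200.0)
        model = EnsembleModel(frozen, p.geometry, network, 3, table=mech_table)
        d = np.linspace(300.0, 420.0, 200)
        fdc = model.force_curve(d)
        xi = extension_for_configuration(np.ones(6, dtype=np.uint8), p.geometry)
        f_ref, _ = mech_table.solve(d, 0.0, float(xi))
        assert np.allclose(fdc.force, f_ref, atol=1e-6)

    def test_zipper_matches_full_enumeration_two_repeats(self, network):
        p = get_preset("ctprrv3")
        hp = p.helix_params()
        mz = EnsembleModel(hp, p.geometry, network, 2, Approximation.zipper)
        mf = EnsembleModel(hp, p.geometry, network, 2, Approximation.full)
        d = mf.default_separations(step=0.5)
        df = np.abs(mz.force_curve(d).force - mf.force_curve(d).force)
        assert df.max() < 0.05

    def test_average_and_derivative_routes_agree(self, rv5):
        d = rv5.default_separations(step=0.25)
        fa = rv5.force_curve(d, method="average").force
        fd = rv5.force_curve(d, method="derivative").force
        assert np.abs(fa - fd)[2:-2].max() < 0.05

    def test_thermodynamic_identity_work_equals_free_energy(self, rv5):
        # integral of the equilibrium force over separation equals the
        # total-system free-energy difference from the partition function
        d = rv5.default_separations(step=0.05)
        force = rv5.force_curve(d).force
        work = np.trapezoid(force, d)
        logw, _ = rv5._log_group_weights(np.array([d[0], d[-1]]))
        free = -rv5.network.thermal_energy * logsumexp(logw, axis=0)
        assert work == pytest.approx(free[1] - free[0], rel=1e-3)

    def test_probability_normalisation(self, rv5):
        d = rv5.default_separations(step=2.0)
        logw, _ = rv5._log_group_weights(d)
        w = np.exp(logw - logsumexp(logw, axis=0))
        assert np.allclose(w.sum(axis=0), 1.0, atol=1e-9)

    def test_zipper_vs_skip_differ_only_marginally(self, network):
        # ten-repeat construct, exact skip enumeration over 23184 states
        p = get_preset("ctprrv10")
        hp = p.helix_params()
        mz = EnsembleModel(hp, p.geometry, network, 10, Approximation.zipper)
        ms = EnsembleModel(hp, p.geometry, network, 10, Approximation.skip)
        d = mz.default_separations(step=1.0)
        plateau = mz.plateau_window(d)
        df = np.abs(mz.force_curve(d).force - ms.force_curve(d).force)
        assert df[plateau].max() < 0.3


class TestEnsembleSnapshot:
    def test_small_separation_is_fully_folded(self, rv5):
        snap = rv5.snapshot(330.0)
        state, prob = snap.configurations[0]
        assert state == "1" * 10
        # the marginally stable terminal helix fluctuates a little even
        # at zero force, so "probability ~ 1" means a few percent short
        assert prob > 0.95

    def test_large_separation_is_fully_unfolded(self, rv5):
        d_hi = rv5.default_separation_span()[1]
        snap = rv5.snapshot(d_hi)
        assert snap.configurations[0][0] == "0" * 10
        assert snap.p_unfolded > 0.9

    def test_marginals_match_brute_force_three_repeats(self, network):
        # oracle: exhaustive 64-state Boltzmann marginalisation with the
        # exact (root-finder) energies, independent of the table fast path
        p = get_preset("ctprrv3")
        hp = p.helix_params()
        model = EnsembleModel(hp, p.geometry, network, 3, Approximation.full)
        d_mid = float(np.mean(model.default_separation_span()))
        states = enumerate_configurations(6, "full")
        energies = np.array(
            [
                configuration_total_energy(s, d_mid, hp, p.geometry, network)
                for s in states
            ]
        )
        w = np.exp(
            -(energies - energies.min()) / network.thermal_energy
        )
        w /= w.sum()
        oracle = states.T @ w
        got = model.helix_fold_profile(np.array([d_mid]))[:, 0]
        assert np.allclose(got, oracle, atol=1e-4)

    def test_ranking_and_probabilities_well_formed(self, rv5):
        d_mid = float(np.mean(rv5.default_separation_span()))
        snap = rv5.snapshot(d_mid, k=10)
        probs = [p for _, p in snap.configurations]
        assert probs == sorted(probs, reverse=True)
        assert all(0 <= p <= 1 for p in probs)
        assert np.all((snap.helix_fold_probability >= 0) & (snap.helix_fold_probability <= 1))


class TestSeedSize:
    def test_two_state_toy_gives_two_helices(self, network):
        # one repeat with enormous coupling: all-or-none behaviour
        toy = HelixIsingParams(g_A=5.0, g_B=5.0, g_AB=-30.0, g_BA=-30.0)
        model = EnsembleModel(toy, ROD, network, 1, Approximation.full)
        assert model.seed_size() == pytest.approx(2.0, abs=0.05)

    def test_matches_full_enumeration_at_crossing(self, network):
        hp = helix_params_from_repeat(RepeatParams(0.5, -9.0), helix_bias=0.0)
        model = EnsembleModel(hp, ROD, network, 4, Approximation.full)
        d_star = model.unfolded_crossing()
        assert model.p_unfolded([d_star])[0] == pytest.approx(0.5, abs=0.01)
        states = enumerate_configurations(8, "full")
        energies = np.array(
            [configuration_total_energy(s, d_star, hp, ROD, network) for s in states]
        )
        w = np.exp(-(energies - energies.min()) / network.thermal_energy)
        folded = states.sum(axis=1) > 0
        oracle = float(
            (w[folded] * states.sum(axis=1)[folded]).sum() / w[folded].sum()
        )
        assert model.seed_size() == pytest.approx(oracle, abs=0.05)

    def test_seed_size_independent_of_array_length(self, network):
        hp = helix_params_from_repeat(RepeatParams(1.1, -11.0), helix_bias=0.5)
        geom = get_preset("ctprrv10").geometry
        s10 = EnsembleModel(hp, geom, network, 10, Approximation.zipper).seed_size()
        s20 = EnsembleModel(hp, geom, network, 20, Approximation.zipper).seed_size()
        assert abs(s10 - s20) < 0.3


class TestHelixFoldProfile:
    def test_all_folded_at_small_separations(self, rv5):
        prof = rv5.helix_fold_profile(np.array([320.0, 330.0]))
        assert prof.min() > 0.97

    def test_symmetric_model_gives_symmetric_profile(self, network):
        hp = helix_params_from_repeat(RepeatParams(-1.9, -12.7), helix_bias=0.0)
        model = EnsembleModel(hp, ROD, network, 4, Approximation.full)
        d = model.default_separations(step=2.0)
        prof = model.helix_fold_profile(d)
        assert np.allclose(prof, prof[::-1], atol=1e-9)

    def test_unzipping_starts_at_c_terminus(self, network):
        # with the preset decomposition the C-terminal helix (row 0) loses
        # fold probability before the N-terminal one
        for name in ("ctpra_mean9", "ctprrv10"):
            p = get_preset(name)
            model = EnsembleModel(p.helix_params(), p.geometry, network, p.n_repeats)
            d = model.default_separations(step=0.5)
            prof = model.helix_fold_profile(d)
            d_c = d[np.argmax(prof[0] < 0.5)]
            d_n = d[np.argmax(prof[-1] < 0.5)]
            assert d_c < d_n


class TestApparatusStiffness:
    ANK = RepeatParams(-10.0, -6.0, 5)

    def test_soft_network_plateau_has_no_peaks(self, network):
        model = EnsembleModel(self.ANK, ROD, network, 5)
        d = model.default_separations(step=0.1)
        fdc = model.force_curve(d)
        mask = model.plateau_window(d)
        window = (d[mask][0], d[mask][-1])
        assert analysis.count_force_peaks(fdc, window, prominence=0.5) == 0

    def test_hundredfold_stiffening_gives_one_peak_per_repeat(self, network):
        stiff = network.stiffened(100)
        fdc = simulate_apparatus_stiffness(self.ANK, ROD, stiff, n_repeats=5)
        assert analysis.count_force_peaks(fdc, prominence=0.5) == 5

    def test_peak_prominence_grows_with_stiffness(self, network):
        from scipy.signal import find_peaks, peak_prominences

        proms = []
        for factor in (10, 100):
            stiff = network.stiffened(factor)
            model = EnsembleModel(self.ANK, ROD, stiff, 5)
            d = model.default_separations(step=0.02)
            f = model.force_curve(d).force
            peaks, _ = find_peaks(f, prominence=0.5)
            proms.append(np.min(peak_prominences(f, peaks)[0]))
        assert proms[1] > proms[0]
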