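"""Cycle averaging, alignment, plateau force, work and contour gain."""

import numpy as np
import pytest

from repeatspring import analysis
from repeatspring.engine import EnsembleModel, ForceDistanceCurve
from repeatspring.ising import RESIDUES_PER_REPEAT
from repeatspring.presets import get_preset
from repeatspring.synthetic import NoiseModel, generate_fdc_cycles


@pytest.fixture(scope="module")
def rv5_model(network):
    p = get_preset("ctprrv5")
    return EnsembleModel(p.helix_params(), p.geometry, network, 5)


@pytest.fixture(scope="module")
def rv5_curve(rv5_model):
    d = rv5_model.default_separations(step=0.25)
    return rv5_model.force_curve(d)


def _flat_curve(force=9.5, noise=0.0, seed=0, n=600):
    rng = np.random.default_rng(seed)
    d = np.linspace(100.0, 400.0, n)
    f = np.full(n, force) + rng.normal(0, noise, n)
    return ForceDistanceCurve(d, f)


class TestAverageCycles:
    def test_single_noiseless_cycle_is_identity_up_to_binning(self, rv5_curve):
        avg = analysis.average_cycles([rv5_curve], bin_width=1.0)
        interp = np.interp(avg.separation, rv5_curve.separation, rv5_curve.force)
        assert np.abs(avg.force - interp).max() < 0.02

    def test_opposite_noise_cancels_exactly(self):
        d = np.linspace(0, 10, 50)
        noise = np.sin(d * 3.1)
        up = ForceDistanceCurve(d, 5.0 + noise)
        down = ForceDistanceCurve(d, 5.0 - noise)
        avg = analysis.average_cycles([up, down], bin_width=0.2)
        assert np.allclose(avg.force, 5.0, atol=1e-12)

    def test_rms_error_shrinks_like_sqrt_cycles(self, network, rv5_model):
        p = get_preset("ctprrv5")
        truth_d = rv5_model.default_separations(step=0.5)
        truth_f = rv5_model.force_curve(truth_d).force
        rms = {}
        for n_cycles in (8, 32):
            cycles = generate_fdc_cycles(
                p.helix_params(), p.geometry, network,
                NoiseModel(seed=7, cycle_force_sigma=0.0, cycle_distance_sigma=0.0, thermal_from_stiffness=False),
                5, n_cycles=n_cycles, separations=truth_d, model=rv5_model,
            )
            avg = analysis.average_cycles(cycles, bin_width=1.0)
            model_at = np.interp(avg.separation, truth_d, truth_f)
            rms[n_cycles] = np.sqrt(np.mean((avg.force - model_at) ** 2))
        ratio = rms[8] / rms[32]
        assert 1.4 < ratio < 2.9  # ~2 expected from 1/sqrt(n)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            analysis.average_cycles([])


class TestAlignment:
    def test_identical_curves_get_zero_offsets(self, rv5_curve):
        offsets = analysis.align_fdcs([rv5_curve, rv5_curve, rv5_curve])
        for df, dd in offsets:
            assert abs(df) < 1e-6 and abs(dd) < 1e-6

    def test_constructed_shift_is_recovered(self, rv5_curve):
        shifted = ForceDistanceCurve(
            rv5_curve.separation + 3.0, rv5_curve.force + 0.5
        )
        (_, _), (df, dd) = analysis.align_fdcs([rv5_curve, shifted])
        assert df == pytest.approx(-0.5, abs=0.05)
        assert dd == pytest.approx(-3.0, abs=0.5)

    def test_alignment_is_idempotent(self, rv5_curve):
        shifted = ForceDistanceCurve(rv5_curve.separation + 2.0, rv5_curve.force - 0.3)
        offsets = analysis.align_fdcs([rv5_curve, shifted])
        aligned = analysis.apply_alignment([rv5_curve, shifted], offsets)
        second = analysis.align_fdcs(aligned)
        assert abs(second[1][0]) < 0.05
        assert abs(second[1][1]) < 0.5

    def test_disjoint_ranges_rejected(self):
        a = ForceDistanceCurve(np.linspace(0, 10, 30), np.ones(30))
        b = ForceDistanceCurve(np.linspace(500, 510, 30), np.ones(30))
        with pytest.raises(ValueError):
            analysis.align_fdcs([a, b])


class TestPlateauForce:
    def test_flat_noisy_plateau_recovered(self):
        curve = _flat_curve(force=9.5, noise=0.5, seed=1)
        fit = analysis.plateau_force(curve, window=(100.0, 400.0))
        assert fit.center == pytest.approx(9.5, abs=0.05)
        assert fit.sigma == pytest.approx(0.5, abs=0.1)

    def test_noiseless_constant_force(self):
        curve = _flat_curve(force=7.0, noise=0.0)
        fit = analysis.plateau_force(curve, window=(100.0, 400.0))
        assert fit.center == pytest.approx(7.0, abs=0.05)
        assert fit.sigma < 0.2

    def test_auto_window_on_model_curve(self, rv5_curve):
        fit = analysis.plateau_force(rv5_curve)
        lo, hi = fit.window
        assert lo < hi
        assert 5.0 < fit.center < 12.0  # the rv plateau region


class TestUnfoldingWork:
    def test_zero_protein_curve_gives_zero(self, network, mech_table):
        d = np.linspace(100.0, 500.0, 800)
        f, _ = mech_table.solve(d, 120 * network.nm_per_residue, 0.0)
        curve = ForceDistanceCurve(d, f)
        w = analysis.unfolding_work(curve, network, 120)
        assert abs(w) < 0.05

    def test_matches_partition_function_oracle(self, network, rv5_model, rv5_curve):
        # oracle: difference of total-system free energies relative to the
        # always-unfolded reference, from the partition function
        from scipy.special import logsumexp

        d = rv5_curve.separation
        w_f = analysis.unfolding_work(rv5_curve, network, 5 * RESIDUES_PER_REPEAT)
        kt = network.thermal_energy
        logw, _ = rv5_model._log_group_weights(np.array([d[0], d[-1]]))
        free = -kt * logsumexp(logw, axis=0)
        g = rv5_model._unfolded_group
        ref = -(logw[g] - rv5_model.log_group_weight[g]) * kt
        oracle = -((free[1] - free[0]) - (ref[1] - ref[0])) / kt
        assert w_f == pytest.approx(oracle, rel=0.05)
        assert w_f < 0  # folding work is negative for a stable array

    def test_magnitude_grows_with_repeat_number(self, network):
        works = []
        for name in ("ctprrv5", "ctprrv10"):
            p = get_preset(name)
            m = EnsembleModel(p.helix_params(), p.geometry, network, p.n_repeats)
            d = m.default_separations(step=0.5)
            works.append(
                analysis.unfolding_work(
                    m.force_curve(d), network, p.n_repeats * RESIDUES_PER_REPEAT
                )
            )
        assert abs(works[1]) > abs(works[0])

    def test_invariant_to_grid_density_and_rigid_offsets(self, network, rv5_model):
        d1 = rv5_model.default_separations(step=0.25)
        d2 = rv5_model.default_separations(step=1.0)
        w1 = analysis.unfolding_work(rv5_model.force_curve(d1), network, 5 * RESIDUES_PER_REPEAT)
        w2 = analysis.unfolding_work(rv5_model.force_curve(d2), network, 5 * RESIDUES_PER_REPEAT)
        assert w1 == pytest.approx(w2, rel=0.01)
        # a rigid offset removed by alignment leaves the work unchanged
        c = rv5_model.force_curve(d1)
        shifted = ForceDistanceCurve(c.separation + 2.5, c.force + 0.4)
        offsets = analysis.align_fdcs([c, shifted])
        restored = analysis.apply_alignment([c, shifted], offsets)[1]
        w3 = analysis.unfolding_work(restored, network, 5 * RESIDUES_PER_REPEAT)
        assert w3 == pytest.approx(w1, rel=0.01)


class TestContourLengthGain:
    def _windows(self, model, d):
        mask = model.plateau_window(d)
        lo, hi = d[mask][0], d[mask][-1]
        return (float(d[0]), lo - 5.0), (hi + 25.0, float(d[-1]))

    def test_five_repeat_gain(self, network, rv5_model, rv5_curve):
        pre, post = self._windows(rv5_model, rv5_curve.separation)
        gain, per_repeat = analysis.contour_length_gain(
            rv5_curve, network, pre, post, n_repeats=5
        )
        expected = 5 * RESIDUES_PER_REPEAT * network.nm_per_residue
        assert gain == pytest.approx(expected, rel=0.03)
        assert per_repeat == pytest.approx(expected / 5, rel=0.03)

    def test_gain_scales_linearly_with_repeats(self, network):
        gains = {}
        for name, n in (("ctprrv5", 5), ("ctprrv10", 10), ("ctprrv20", 20)):
            p = get_preset(name)
            m = EnsembleModel(p.helix_params(), p.geometry, network, n)
            d = m.default_separations(step=0.25)
            c = m.force_curve(d)
            pre, post = self._windows(m, d)
            gains[n] = analysis.contour_length_gain(c, network, pre, post)
        ns = np.array(sorted(gains))
        slope = np.polyfit(ns, [gains[n] for n in ns], 1)[0]
        assert slope == pytest.approx(
            RESIDUES_PER_REPEAT * network.nm_per_residue, rel=0.03
        )


class TestOscillations:
    def test_period_counts_for_long_arrays(self, network):
        for name, n, periods in (("ctprrv20", 20, 2), ("ctprrv26", 26, 3)):
            p = get_preset(name)
            m = EnsembleModel(p.helix_params(), p.geometry, network, n)
            d = m.default_separations()
            # count on the sequential-unfolding stretch, before the dip
            mask = m.plateau_window(d, p_unfolded_max=0.05)
            window = (d[mask][0], d[mask][-1])
            count = analysis.count_plateau_oscillations(
                m.force_curve(d), window, prominence=0.05
            )
            assert count == periods
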