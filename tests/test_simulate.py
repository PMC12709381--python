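"""Quasi-static instrument mechanics: jumps, stability, noise, determinism."""

import numpy as np
import pytest

from sfbkit import analysis, reference, simulate as sim
from sfbkit.dlvo import DlvoParams


def pure_vdw_truth(hamaker=2.2e-20):
    """Attractive-only interaction (psi_eff = 0)."""
    return sim.GroundTruth(
        dlvo=DlvoParams(psi_eff=0.0, kappa=1e8, p=0.5, hamaker=hamaker)
    )


class TestStructuralEnergy:
    def test_zero_amplitude_leaves_only_wall(self):
        spec = sim.StructuralForceSpec(
            layer_thickness=0.5e-9, amplitude=0.0, decay_length=0.4e-9,
            hard_wall=0.3e-9, wall_energy=1e-3,
        )
        d = np.linspace(0.35e-9, 5e-9, 50)
        wall_only = 1e-3 * (0.3e-9 / d) ** 12
        np.testing.assert_allclose(sim.structural_energy(d, spec), wall_only, rtol=1e-12)

    def test_oscillation_minima_spacing_equals_layer_thickness(self):
        spec = sim.StructuralForceSpec(
            layer_thickness=0.5e-9, amplitude=1e-3, decay_length=10e-9,
            hard_wall=0.3e-9, wall_energy=1e-12,
        )
        d = np.linspace(0.6e-9, 4e-9, 40000)
        w = sim.structural_energy(d, spec)
        minima = d[1:-1][(w[1:-1] < w[:-2]) & (w[1:-1] < w[2:])]
        np.testing.assert_allclose(np.diff(minima), 0.5e-9, rtol=1e-3)

    def test_finite_below_hard_wall(self):
        spec = sim.StructuralForceSpec(
            layer_thickness=0.5e-9, amplitude=1e-3, decay_length=0.4e-9,
            hard_wall=0.3e-9,
        )
        assert np.isfinite(sim.structural_energy(0.15e-9, spec))

    def test_stable_branch_spacing_under_default_spring(self, instrument):
        """Stability scan: unstable bands of the layered term recur every
        layer thickness, so mechanically stable branches are separated by
        one layer (~0.5 nm)."""
        spec = sim.StructuralForceSpec(
            layer_thickness=0.5e-9, amplitude=1e-3, decay_length=0.4e-9,
            hard_wall=0.3e-9,
        )
        d = np.linspace(0.35e-9, 3e-9, 60000)
        slope = sim.structural_energy_gradient(d, spec)
        threshold = instrument.spring_constant / (2 * np.pi * instrument.radius)
        unstable = slope > threshold
        onsets = d[1:][unstable[1:] & ~unstable[:-1]]
        assert len(onsets) >= 2
        np.testing.assert_allclose(np.diff(onsets), 0.5e-9, atol=0.05e-9)


class TestQuasistaticMechanics:
    def test_monotone_repulsion_reproduces_input_curve(self, instrument):
        truth = sim.GroundTruth(
            dlvo=DlvoParams(psi_eff=0.05, kappa=1.0 / 20e-9, p=0.5, hamaker=0.0)
        )
        curve = sim.simulate_quasistatic(truth, instrument, "approach", stop_load=4e-4)
        assert analysis.detect_jumps(curve) == []
        model = sim.energy_model(truth)
        np.testing.assert_allclose(
            curve.signal, model.energy(curve.separation), rtol=1e-9
        )

    def test_pure_vdw_jump_in_distance(self, instrument):
        curve = sim.simulate_quasistatic(pure_vdw_truth(), instrument, "approach")
        jumps = analysis.detect_jumps(curve)
        assert len(jumps) == 1
        d_theory = (2.2e-20 * instrument.radius / (3 * instrument.spring_constant)) ** (
            1.0 / 3.0
        )
        d_before, d_after = jumps[0]
        assert d_before == pytest.approx(d_theory, rel=0.15)
        assert d_after < 0.5e-9  # lands at contact

    def test_low_concentration_profile_jumps_near_four_nanometres(
        self, row_pro007, instrument
    ):
        curve = sim.simulate_quasistatic(
            reference.ground_truth(row_pro007), instrument, "approach"
        )
        jumps = analysis.detect_jumps(curve)
        assert len(jumps) == 1
        assert 1.5e-9 < jumps[0][0] < 6e-9  # "of order 4 nm"

    def test_every_sample_is_spring_stable(self, row_pro090, instrument):
        struct = sim.StructuralForceSpec(
            layer_thickness=0.5e-9, amplitude=1e-3, decay_length=0.4e-9,
            hard_wall=0.3e-9,
        )
        truth = reference.ground_truth(row_pro090, structural=struct)
        model = sim.energy_model(truth)
        approach, retract = sim.simulate_quasistatic(truth, instrument, "both")
        threshold = instrument.spring_constant / (2 * np.pi * instrument.radius)
        for curve in (approach, retract):
            grad = model.gradient(curve.separation)
            assert np.max(grad) <= threshold * (1.0 + 1e-6)

    def test_hysteresis_only_via_instability(self, row_pro007, instrument):
        """Approach and retraction coincide wherever both are stable."""
        truth = reference.ground_truth(row_pro007, adhesion_minimum=-1e-3)
        approach, retract = sim.simulate_quasistatic(truth, instrument, "both")
        jumps_out = analysis.detect_jumps(retract)
        release = max(after for _, after in jumps_out)
        overlap_lo, overlap_hi = release * 1.05, approach.separation.max() * 0.9
        mask = (approach.separation > overlap_lo) & (approach.separation < overlap_hi)
        w_retract = np.interp(
            approach.separation[mask], retract.separation, retract.signal
        )
        np.testing.assert_allclose(approach.signal[mask], w_retract, rtol=1e-3)

    def test_derjaguin_validity_guard(self, instrument):
        truth = pure_vdw_truth()
        with pytest.raises(ValueError, match="Derjaguin"):
            sim.simulate_quasistatic(truth, instrument, "approach", d_start=2e-5)

    def test_adhesion_calibration_sets_contact_minimum(self, row_pro007):
        truth = reference.ground_truth(row_pro007, adhesion_minimum=-1e-3)
        model = sim.energy_model(truth)
        d = np.geomspace(model.floor * 1.05, 1e-8, 8000)
        assert float(np.min(model.energy(d))) == pytest.approx(-1e-3, rel=1e-4)


class TestSynthesizeAndDatasets:
    def test_noise_free_synthesis_matches_model(self, row_pro007):
        truth = reference.ground_truth(row_pro007)
        grid = np.linspace(5e-9, 150e-9, 100)
        curve = sim.synthesize_curve(truth, grid)
        model = sim.energy_model(truth)
        # approach ordering: decreasing D
        assert np.all(np.diff(curve.separation) < 0)
        from sfbkit.dlvo import total_energy

        np.testing.assert_allclose(
            curve.signal, total_energy(curve.separation, truth.dlvo, truth.eps_e),
            rtol=1e-12,
        )
        del model

    def test_same_seed_identical_different_seed_distinct(self, row_pro007):
        truth = reference.ground_truth(row_pro007)
        grid = np.linspace(5e-9, 150e-9, 100)
        a = sim.synthesize_curve(truth, grid, noise_sigma=5e-6, seed=7)
        b = sim.synthesize_curve(truth, grid, noise_sigma=5e-6, seed=7)
        c = sim.synthesize_curve(truth, grid, noise_sigma=5e-6, seed=8)
        np.testing.assert_array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_noise_standard_deviation_calibrated(self, row_pro007):
        truth = reference.ground_truth(row_pro007)
        grid = np.linspace(5e-9, 150e-9, 300)
        sigma = 5e-6  # 0.005 mJ/m^2
        signals = np.array(
            [
                sim.synthesize_curve(truth, grid, noise_sigma=sigma, seed=s).signal
                for s in range(1, 51)
            ]
        )
        per_point_sd = np.std(signals, axis=0, ddof=1)
        assert np.mean(per_point_sd) == pytest.approx(sigma, rel=0.1)

    def test_dataset_generation_deterministic(self, tmp_path, row_pro007):
        config = sim.DatasetConfig(
            truths={"low": reference.ground_truth(row_pro007)},
            replicates=3,
            base_seed=1,
            noise_sigma=5e-6,
            mode="ideal",
            grid_nm=(5.0, 150.0, 60),
        )
        m1 = sim.generate_dataset(config, tmp_path / "run1")
        m2 = sim.generate_dataset(config, tmp_path / "run2")
        assert [f["path"] for f in m1["files"]] == [f["path"] for f in m2["files"]]
        for entry in m1["files"]:
            b1 = (tmp_path / "run1" / entry["path"]).read_bytes()
            b2 = (tmp_path / "run2" / entry["path"]).read_bytes()
            assert b1 == b2

    def test_replicates_share_truth_distinct_noise(self, tmp_path, row_pro007):
        config = sim.DatasetConfig(
            truths={"low": reference.ground_truth(row_pro007)},
            replicates=3,
            base_seed=1,
            noise_sigma=5e-6,
            mode="ideal",
            grid_nm=(5.0, 150.0, 60),
        )
        sim.generate_dataset(config, tmp_path / "out")
        from sfbkit import io as cio

        curves = [
            cio.read_curve(tmp_path / "out" / f"low_rep{i:03d}_approach.csv")
            for i in range(3)
        ]
        np.testing.assert_array_equal(curves[0].separation, curves[1].separation)
        assert not np.array_equal(curves[0].signal, curves[1].signal)
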