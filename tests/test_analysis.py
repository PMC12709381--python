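"""Fitting and feature-extraction pipeline: closed loops and recovery."""

import numpy as np
import pytest

from sfbkit import analysis, reference, simulate as sim
from sfbkit.constants import WATER_RELATIVE_PERMITTIVITY as EPS


def fit_window_above_jump(curve):
    jumps = analysis.detect_jumps(curve)
    lo = (jumps[0][0] if jumps else float(curve.separation.min())) + 0.3e-9
    return lo, float(curve.separation.max()) * 0.9


class TestFitDlvo:
    @pytest.mark.parametrize("row", reference.REFERENCE_FITS, ids=lambda r: r.label)
    def test_noiseless_closed_loop_recovers_truth(self, row, instrument):
        """simulate -> fit recovers every reference parameter set to < 0.1 %."""
        truth = reference.ground_truth(row)
        inst = instrument.model_copy(update={"sampling_step": 1e-10})
        curve = sim.simulate_quasistatic(truth, inst, "approach")
        config = analysis.FitConfig(
            window=fit_window_above_jump(curve),
            free=("psi_eff", "kappa", "p"),
            fixed={"hamaker": truth.dlvo.hamaker, "offset": 0.0},
        )
        fit = analysis.fit_dlvo(curve, EPS, config)
        assert fit.converged
        assert fit.params.psi_eff == pytest.approx(truth.dlvo.psi_eff, rel=1e-3)
        assert fit.params.kappa == pytest.approx(truth.dlvo.kappa, rel=1e-3)
        assert fit.params.p == pytest.approx(truth.dlvo.p, abs=1e-3)

    def test_free_p_never_fits_worse_than_fixed_p(self, row_mixture):
        """Nested-model inequality on a noisy curve."""
        truth = reference.ground_truth(row_mixture)
        grid = np.linspace(1.5e-9, 25e-9, 300)
        curve = sim.synthesize_curve(truth, grid, noise_sigma=5e-6, seed=11)
        window = (1.5e-9, 20e-9)
        free_cfg = analysis.FitConfig(
            window=window, free=("psi_eff", "kappa", "p"),
            fixed={"hamaker": truth.dlvo.hamaker, "offset": 0.0},
        )
        fixed_cfg = analysis.FitConfig(
            window=window, free=("psi_eff", "kappa"),
            fixed={"hamaker": truth.dlvo.hamaker, "offset": 0.0, "p": truth.dlvo.p},
        )
        free_fit = analysis.fit_dlvo(curve, EPS, free_cfg)
        fixed_fit = analysis.fit_dlvo(curve, EPS, fixed_cfg)
        assert free_fit.residual_rms <= fixed_fit.residual_rms * (1.0 + 1e-9)

    def test_window_with_too_few_points_rejected(self, row_pro007):
        truth = reference.ground_truth(row_pro007)
        curve = sim.synthesize_curve(truth, np.linspace(5e-9, 150e-9, 50))
        with pytest.raises(ValueError, match="points"):
            analysis.fit_dlvo(
                curve, EPS, analysis.FitConfig(window=(5e-9, 10e-9))
            )

    def test_residuals_grow_when_window_enters_structural_region(self, row_pro090):
        """Window monotonicity guards the fit-window advice."""
        struct = sim.StructuralForceSpec(
            layer_thickness=0.5e-9, amplitude=1e-3, decay_length=0.4e-9,
            hard_wall=0.3e-9,
        )
        truth = reference.ground_truth(row_pro090, structural=struct)
        grid = np.linspace(0.4e-9, 120e-9, 2000)
        curve = sim.synthesize_curve(truth, grid)  # noiseless, ideal grid
        fixed = {"hamaker": truth.dlvo.hamaker, "offset": 0.0}
        rms = []
        for lo in (6e-9, 2e-9, 0.5e-9):
            cfg = analysis.FitConfig(
                window=(lo, 110e-9), free=("psi_eff", "kappa", "p"), fixed=fixed
            )
            rms.append(analysis.fit_dlvo(curve, EPS, cfg).residual_rms)
        assert rms[0] < rms[1] < rms[2]

    def test_bootstrap_uncertainty_comparable_to_jacobian(self, row_mixture):
        truth = reference.ground_truth(row_mixture)
        grid = np.linspace(1.5e-9, 25e-9, 150)
        curve = sim.synthesize_curve(truth, grid, noise_sigma=5e-6, seed=4)
        base = analysis.FitConfig(
            window=(1.5e-9, 20e-9), free=("psi_eff", "kappa", "p"),
            fixed={"hamaker": truth.dlvo.hamaker, "offset": 0.0},
        )
        jac_fit = analysis.fit_dlvo(curve, EPS, base)
        boot_cfg = base.model_copy(update={"bootstrap_replicates": 30, "seed": 5})
        boot_fit = analysis.fit_dlvo(curve, EPS, boot_cfg)
        for name in ("psi_eff", "kappa", "p"):
            ratio = boot_fit.uncertainties[name] / jac_fit.uncertainties[name]
            assert 0.3 < ratio < 3.0

    def test_boundary_p_reported_exactly(self, instrument):
        row = reference.by_composition(0.0, 0.01)  # constant-charge-like fit
        truth = reference.ground_truth(row)
        inst = instrument.model_copy(update={"sampling_step": 1e-10})
        curve = sim.simulate_quasistatic(truth, inst, "approach")
        config = analysis.FitConfig(
            window=fit_window_above_jump(curve),
            fixed={"hamaker": truth.dlvo.hamaker, "offset": 0.0},
        )
        fit = analysis.fit_dlvo(curve, EPS, config)
        assert fit.params.p == 1.0


class TestDetectJumps:
    def test_continuous_curve_has_no_jumps(self):
        d = np.linspace(50e-9, 5e-9, 200)
        curve = sim.ForceCurve(
            separation=d, signal=np.exp(-d / 10e-9), direction="approach"
        )
        assert analysis.detect_jumps(curve) == []

    def test_minimum_samples_required(self):
        curve = sim.ForceCurve(
            separation=np.array([2e-9, 1e-9]), signal=np.zeros(2), direction="approach"
        )
        with pytest.raises(ValueError):
            analysis.detect_jumps(curve)

    def test_direction_awareness(self):
        d = np.concatenate([np.linspace(1e-9, 5e-9, 50), np.linspace(20e-9, 40e-9, 50)])
        curve = sim.ForceCurve(
            separation=d, signal=np.zeros_like(d), direction="retract"
        )
        jumps = analysis.detect_jumps(curve, jump_threshold=1e-9)
        assert len(jumps) == 1
        before, after = jumps[0]
        assert before == pytest.approx(5e-9)
        assert after == pytest.approx(20e-9)


class TestStepHeights:
    def test_no_structural_term_no_steps(self, instrument):
        truth = sim.GroundTruth(
            dlvo=reference.by_composition(0.07, 0.0).dlvo()
        )
        curve = sim.simulate_quasistatic(truth, instrument, "approach")
        assert analysis.step_heights(curve) == []

    def test_half_nanometre_proline_layer_recovered(self, row_pro090, instrument):
        struct = sim.StructuralForceSpec(
            layer_thickness=0.5e-9, amplitude=1e-3, decay_length=0.4e-9,
            hard_wall=0.3e-9,
        )
        truth = reference.ground_truth(row_pro090, structural=struct)
        curve = sim.simulate_quasistatic(truth, instrument, "approach")
        steps = analysis.step_heights(curve)
        assert steps
        assert np.median(steps) == pytest.approx(0.5e-9, abs=0.05e-9)

    def test_salt_case_three_angstrom_layer(self, row_mixture, instrument):
        struct = sim.StructuralForceSpec(
            layer_thickness=0.3e-9, amplitude=1e-3, decay_length=0.4e-9,
            hard_wall=0.3e-9,
        )
        truth = reference.ground_truth(row_mixture, structural=struct)
        curve = sim.simulate_quasistatic(truth, instrument, "approach")
        steps = analysis.step_heights(curve)
        assert steps
        assert np.median(steps) == pytest.approx(0.3e-9, abs=0.1e-9)

    @pytest.mark.parametrize("thickness_nm", [0.2, 0.3, 0.5, 0.7, 1.0])
    def test_thickness_sweep_within_ten_percent(self, thickness_nm, row_pro090):
        """Recovery across layer sizes, in a well-developed layering regime
        (envelope a few layers long, drive fine enough to resolve the
        thinnest steps against the jump threshold)."""
        inst = sim.InstrumentSpec(sampling_step=2.5e-11)
        struct = sim.StructuralForceSpec(
            layer_thickness=thickness_nm * 1e-9,
            amplitude=2e-3,
            decay_length=1.5 * thickness_nm * 1e-9,
            hard_wall=0.3e-9,
        )
        truth = reference.ground_truth(row_pro090, structural=struct)
        curve = sim.simulate_quasistatic(truth, inst, "approach")
        steps = analysis.step_heights(curve)
        assert steps
        assert abs(np.median(steps) - thickness_nm * 1e-9) < 0.1 * thickness_nm * 1e-9


class TestAdhesion:
    def test_purely_repulsive_retraction_reports_no_adhesion(self, instrument):
        from sfbkit.dlvo import DlvoParams

        truth = sim.GroundTruth(
            dlvo=DlvoParams(psi_eff=0.05, kappa=1.0 / 20e-9, p=0.5, hamaker=0.0)
        )
        _, retract = sim.simulate_quasistatic(
            truth, instrument, "both", stop_load=4e-4
        )
        assert analysis.adhesion_energy(retract) is None

    def test_requires_retraction_direction(self, row_pro007, instrument):
        truth = reference.ground_truth(row_pro007)
        approach = sim.simulate_quasistatic(truth, instrument, "approach")
        with pytest.raises(ValueError):
            analysis.adhesion_energy(approach)

    @pytest.mark.parametrize("target_mj", [-0.5, -1.0])
    def test_configured_pull_off_recovered_within_two_percent(
        self, target_mj, row_pro007, instrument
    ):
        truth = reference.ground_truth(row_pro007, adhesion_minimum=target_mj * 1e-3)
        _, retract = sim.simulate_quasistatic(truth, instrument, "both")
        adhesion = analysis.adhesion_energy(retract)
        assert adhesion == pytest.approx(target_mj * 1e-3, rel=0.02)


class TestFitReport:
    def _fit(self, row, seed=1):
        truth = reference.ground_truth(row)
        kappa_inv = truth.dlvo.kappa_inv
        grid = np.linspace(0.2 * kappa_inv, 4.0 * kappa_inv, 300)
        curve = sim.synthesize_curve(truth, grid, noise_sigma=5e-6, seed=seed)
        config = analysis.FitConfig(
            window=(float(grid[0]), float(grid[-1])),
            fixed={"hamaker": truth.dlvo.hamaker, "offset": 0.0},
        )
        return analysis.fit_dlvo(curve, EPS, config)

    def test_single_row_rounded_to_two_figures(self, row_pro007):
        from sfbkit import electrolyte as el

        table = analysis.fit_report(
            [self._fit(row_pro007)], [reference.solution(row_pro007)], ["low"]
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert row["psi_eff_mV"] == pytest.approx(63.0, abs=1.0)
        assert row["kappa_inv_nm"] == pytest.approx(40.0, abs=1.0)
        # zwitterion-only solution: no screening prediction
        assert row["kappa_pred_inv_nm"] is None
        del el

    def test_predicted_column_populated_with_salt(self, row_mixture):
        table = analysis.fit_report(
            [self._fit(row_mixture)], [reference.solution(row_mixture)], ["mix"]
        )
        # measured and predicted kept distinct; prediction at 2 s.f.
        assert table.iloc[0]["kappa_pred_inv_nm"] == pytest.approx(3.0)
        assert table.iloc[0]["kappa_inv_nm"] == pytest.approx(3.0, abs=0.3)

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            analysis.fit_report([], [])
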