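"""C-peptide kinetics, ISR deconvolution and secretion indexes."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivgttml.secretion_model import (
    CPeptideKinetics,
    SecretionProfile,
    acute_response,
    basal_secretion,
    body_surface_area,
    cpeptide_kinetics_from_anthropometrics,
    deconvolve_isr,
    phi_1c,
    secretion_aucs,
)

from conftest import constant_record


class TestPopulationKinetics:
    def test_age_moves_only_long_half_life(self):
        young = cpeptide_kinetics_from_anthropometrics(25.0, "F", 65.0, 164.0)
        old = cpeptide_kinetics_from_anthropometrics(55.0, "F", 65.0, 164.0)
        alpha_y, beta_y = young.decay_eigenvalues()
        alpha_o, beta_o = old.decay_eigenvalues()
        half_short = lambda a: np.log(2) / a
        # same decay structure apart from the long component
        assert young.F == old.F
        assert beta_o < beta_y  # older -> slower long decay
        # reconstructed short half-life is the population constant for both
        assert half_short(alpha_y) == pytest.approx(4.95, rel=1e-9)
        assert half_short(alpha_o) == pytest.approx(4.95, rel=1e-9)

    def test_volume_increases_with_bsa(self):
        small = cpeptide_kinetics_from_anthropometrics(33.0, "F", 50.0, 155.0)
        large = cpeptide_kinetics_from_anthropometrics(33.0, "F", 90.0, 175.0)
        assert body_surface_area(90.0, 175.0) > body_surface_area(50.0, 155.0)
        assert large.V_C > small.V_C

    def test_pure_function(self):
        a = cpeptide_kinetics_from_anthropometrics(33.0, "F", 65.8, 164.0)
        b = cpeptide_kinetics_from_anthropometrics(33.0, "F", 65.8, 164.0)
        assert a == b

    def test_missing_anthropometric_rejected(self):
        with pytest.raises(ValueError):
            cpeptide_kinetics_from_anthropometrics(33.0, "F", -1.0, 164.0)
        with pytest.raises(ValueError):
            cpeptide_kinetics_from_anthropometrics(33.0, "F", 65.8, 164.0, "weird")

    def test_half_life_round_trip(self):
        kin = CPeptideKinetics.from_half_lives(0.76, 4.95, 33.8, 3.9)
        alpha, beta = kin.decay_eigenvalues()
        assert np.log(2) / alpha == pytest.approx(4.95, rel=1e-12)
        assert np.log(2) / beta == pytest.approx(33.8, rel=1e-12)
        assert kin.impulse_response(np.array([0.0]))[0] == pytest.approx(1.0)


class TestBasalSecretion:
    def test_zero(self):
        kin = CPeptideKinetics.from_half_lives(0.76, 4.95, 33.8, 3.9)
        assert basal_secretion(kin, 0.0) == 0.0

    def test_hand_product(self):
        kin = dataclasses.replace(
            CPeptideKinetics.from_half_lives(0.76, 4.95, 33.8, 3.9), k01=0.06
        )
        assert basal_secretion(kin, 530.0) == pytest.approx(31.8)

    @given(cp=st.floats(0, 2000), scale=st.floats(0.1, 5))
    def test_linear_in_cp(self, cp, scale):
        kin = CPeptideKinetics.from_half_lives(0.76, 4.95, 33.8, 3.9)
        assert basal_secretion(kin, scale * cp) == pytest.approx(
            scale * basal_secretion(kin, cp), rel=1e-12, abs=1e-12
        )


class TestDeconvolution:
    def test_steady_state_identity(self, reference_truth):
        """Constant C-peptide deconvolves to ISR = k01 * Cp_b exactly."""
        rec = constant_record()
        kin = reference_truth.cpep_kinetics
        profile = deconvolve_isr(rec, kin)
        expected = kin.k01 * 545.0
        np.testing.assert_allclose(profile.isr, expected, atol=1e-9)

    def test_round_trip_rms_below_3pct_of_peak(
        self, reference_record, reference_truth, reference_dense
    ):
        """Forward-simulated secretion is recovered within 3% of pulse peak."""
        kin = reference_truth.cpep_kinetics
        profile = deconvolve_isr(reference_record, kin)
        true_isr = np.interp(
            profile.grid, reference_dense["t"], reference_dense["S_pre"] / kin.V_C
        )
        rms = np.sqrt(np.mean((profile.isr - true_isr) ** 2))
        assert rms < 0.03 * true_isr.max()

    def test_nonnegative_everywhere(self, reference_profile):
        assert np.all(reference_profile.isr >= -1e-12)

    def test_large_lambda_flattens(self, reference_record, reference_truth):
        kin = reference_truth.cpep_kinetics
        rough = deconvolve_isr(reference_record, kin, lam=0.25)
        flat = deconvolve_isr(reference_record, kin, lam=1e7)
        # penalty-dominated limit: curvature collapses (the null space of the
        # second-difference penalty is the straight line)
        d2 = lambda p: np.linalg.norm(np.diff(p.isr[:-1], n=2))
        assert d2(flat) < 0.01 * d2(rough)

    def test_smoothness_decreases_with_lambda(self, reference_record, reference_truth):
        kin = reference_truth.cpep_kinetics
        norms = [
            np.linalg.norm(np.diff(deconvolve_isr(reference_record, kin, lam).isr, n=2))
            for lam in (0.01, 1.0, 100.0)
        ]
        assert norms[0] > norms[1] > norms[2]

    def test_input_validation(self, reference_record, reference_truth):
        with pytest.raises(ValueError):
            deconvolve_isr(reference_record, reference_truth.cpep_kinetics, lam=-1.0)


class TestAcuteResponse:
    TIMES = np.array([0.0, 3, 4, 5, 6, 8])

    def test_at_baseline_is_zero(self):
        series = np.full(6, 165.6)
        assert acute_response(self.TIMES, series, 165.6) == 0.0

    def test_hand_arithmetic(self):
        series = np.array([165.6, 350, 400, 380, 360, 310.0])
        assert acute_response(self.TIMES, series, 165.6) == pytest.approx(194.4)

    @given(shift=st.floats(-100, 100))
    def test_shift_invariance(self, shift):
        series = np.array([165.6, 350, 400, 380, 360, 310.0])
        assert acute_response(self.TIMES, series + shift, 165.6 + shift) == pytest.approx(
            194.4, rel=1e-9, abs=1e-9
        )

    def test_symmetric_in_series(self, reference_record):
        """AIR and ACPR use one window definition; swapping series swaps results."""
        t = reference_record.times
        air = acute_response(t, reference_record.insulin, reference_record.insulin[0])
        acpr = acute_response(t, reference_record.cpeptide, reference_record.cpeptide[0])
        assert acute_response(
            t, reference_record.cpeptide, reference_record.cpeptide[0]
        ) == pytest.approx(acpr)
        assert air != pytest.approx(acpr)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            acute_response(self.TIMES, np.ones(6), 1.0, window=(8.5, 9.0))


class TestPhi1c:
    def _profile(self, grid, isr, bsr, v_c=3.9):
        return SecretionProfile(
            grid=grid, isr=isr, BSR=bsr, V_C=v_c, regularization_lambda=0.0
        )

    def test_basal_isr_gives_zero(self, reference_record):
        grid = np.arange(0.0, 181.0)
        profile = self._profile(grid, np.full(grid.size, 30.0), 30.0)
        assert phi_1c(profile, reference_record) == 0.0

    def test_hand_ratio(self):
        """Suprabasal ISR 13.6 against 11.1 mmol/L (=200 mg/dL) suprabasal glucose."""
        grid = np.arange(0.0, 181.0)
        profile = self._profile(grid, np.full(grid.size, 30.0 + 13.6), 30.0)
        rec = constant_record()
        rec.glucose = rec.glucose + 11.1
        rec.glucose[0] = 4.66  # fasting stays basal
        expected = 13.6 / (11.1 * 18.02)
        assert phi_1c(profile, rec) == pytest.approx(expected, rel=1e-9)

    def test_homogeneous_in_isr(self, reference_record, reference_profile):
        doubled = SecretionProfile(
            grid=reference_profile.grid,
            isr=reference_profile.BSR + 2 * (reference_profile.isr - reference_profile.BSR),
            BSR=reference_profile.BSR,
            V_C=reference_profile.V_C,
            regularization_lambda=0.0,
        )
        assert phi_1c(doubled, reference_record) == pytest.approx(
            2 * phi_1c(reference_profile, reference_record), rel=1e-9
        )


class TestSecretionAUCs:
    def test_constant_rate_rectangles(self):
        grid = np.arange(0.0, 181.0)
        profile = SecretionProfile(
            grid=grid, isr=np.full(grid.size, 2.0), BSR=2.0, V_C=4.0,
            regularization_lambda=0.0,
        )
        aucs = secretion_aucs(profile)
        assert aucs["AUC_SECR"] == pytest.approx(180 * 2.0 * 4.0)
        assert aucs["AUC_SECR_1P"] == pytest.approx(20 * 2.0 * 4.0)
        assert aucs["AUC_SECR_2P"] == pytest.approx(160 * 2.0 * 4.0)

    def test_phases_sum_to_total(self, reference_profile):
        aucs = secretion_aucs(reference_profile)
        assert aucs["AUC_SECR_1P"] + aucs["AUC_SECR_2P"] == pytest.approx(
            aucs["AUC_SECR"], rel=1e-6
        )

    def test_round_trip_total_secretion(self, reference_profile, reference_dense):
        true_total = np.trapezoid(reference_dense["S_pre"], reference_dense["t"])
        assert secretion_aucs(reference_profile)["AUC_SECR"] == pytest.approx(
            true_total, rel=0.02
        )
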