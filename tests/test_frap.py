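"""FRAP correction, recovery fitting, bleach-profile and diffusion estimate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtkquant import (
    FrapSeries,
    RecoveryCurveFitter,
    classify_oligomer,
    correct_series,
    diffusion_coefficient,
    estimate_effective_radius,
    fit_recovery,
)
from rtkquant.exceptions import (
    CorrectionError,
    InsufficientDataError,
    NoBleachError,
    ValidationError,
)


def make_series(f_roi, f_total, f_bg, pre=None, n_pre=3):
    f_roi = np.asarray(f_roi, dtype=float)
    n = len(f_roi)
    f_total = np.broadcast_to(np.asarray(f_total, dtype=float), n)
    f_bg = np.broadcast_to(np.asarray(f_bg, dtype=float), n)
    pre_roi, pre_total, pre_bg = pre if pre else (
        np.full(n_pre, f_total[0]), np.full(n_pre, f_total[0]), np.full(n_pre, f_bg[0])
    )
    return FrapSeries(
        times=np.arange(n, dtype=float) * 0.5,
        f_roi=f_roi, f_total=f_total, f_bg=f_bg,
        pre_roi=pre_roi, pre_total=pre_total, pre_bg=pre_bg,
    )


class TestCorrectSeries:
    def test_ratio_arithmetic(self):
        s = make_series([50.0], [90.0], [10.0])
        assert correct_series(s).f_corrected[0] == pytest.approx(0.5)

    def test_identity_when_background_zero_total_one(self):
        x = np.array([0.3, 0.5, 0.7])
        s = make_series(x, 1.0, 0.0, pre=(np.ones(3), np.ones(3), np.zeros(3)))
        np.testing.assert_allclose(correct_series(s).f_corrected, x)

    def test_prebleach_normalises_to_one(self):
        s = make_series([40.0, 50.0], [100.0], [10.0],
                        pre=(np.full(5, 70.0), np.full(5, 100.0), np.full(5, 10.0)))
        c = correct_series(s)
        assert c.prebleach_reference == pytest.approx(60.0 / 90.0)
        ref_series = make_series([70.0], [100.0], [10.0],
                                 pre=(np.full(5, 70.0), np.full(5, 100.0), np.full(5, 10.0)))
        assert correct_series(ref_series).f_normalized[0] == pytest.approx(1.0)

    def test_nonpositive_denominator_names_frame(self):
        s = make_series([5.0, 5.0], [10.0, 3.0], [4.0])
        with pytest.raises(CorrectionError, match="frame 1"):
            correct_series(s)

    @settings(deadline=None, max_examples=30)
    @given(
        st.floats(min_value=0.0, max_value=500.0),
        st.floats(min_value=0.001, max_value=0.05),
    )
    def test_invariant_to_background_and_common_fade(self, bg, fade):
        """Exact algebraic invariance of the corrected-normalised curve under
        an added constant background and a shared multiplicative fade of the
        above-background spot and whole-cell signals."""
        t = np.arange(20, dtype=float) * 0.5
        roi = 40.0 + 25.0 * (1 - np.exp(-0.2 * t))
        total = np.full_like(roi, 120.0)
        base = make_series(roi, total, np.zeros_like(roi),
                           pre=(np.full(4, 80.0), np.full(4, 120.0), np.zeros(4)))
        decay = np.exp(-fade * t)
        pre_decay = np.exp(-fade * np.arange(4))
        perturbed = FrapSeries(
            times=t, f_roi=roi * decay + bg, f_total=total * decay + bg,
            f_bg=np.full_like(roi, bg),
            pre_roi=80.0 * pre_decay + bg, pre_total=120.0 * pre_decay + bg,
            pre_bg=np.full(4, bg),
        )
        np.testing.assert_allclose(
            correct_series(perturbed).f_normalized,
            correct_series(base).f_normalized,
            rtol=1e-10,
        )


class TestRecoveryFit:
    def test_noiseless_model_data_roundtrip(self):
        t = np.arange(0, 60, 0.5)
        f = 0.2 + 0.8 * (1 - np.exp(-0.1386 * t))
        fit = RecoveryCurveFitter().fit(t, f)
        assert fit.amplitude_ == pytest.approx(0.8, abs=1e-6)
        assert fit.t_half_ == pytest.approx(0.69 / 0.1386, abs=1e-3)
        assert fit.offset_ == pytest.approx(0.2, abs=1e-6)

    def test_one_minute_halflife_gives_k_069(self):
        t = np.arange(0, 10, 1 / 6)  # minutes
        f = 0.3 + 0.6 * (1 - np.exp(-0.69 * t))
        fit = RecoveryCurveFitter(time_unit="min").fit(t, f)
        assert round(fit.rate_, 2) == 0.69

    def test_full_recovery_halftime_matches_convention_when_complete(self):
        t = np.arange(0, 60, 0.5)
        f = 0.4 + 0.6 * (1 - np.exp(-0.2 * t))  # offset + A == 1
        fit = RecoveryCurveFitter().fit(t, f)
        # conventions agree up to 0.69 vs ln 2 when recovery is complete
        assert fit.t_half_full_ == pytest.approx(fit.t_half_, rel=0.01)

    def test_flat_trace_flagged_no_recovery(self):
        t = np.arange(0, 30, 0.5)
        fit = RecoveryCurveFitter().fit(t, np.full_like(t, 0.5))
        assert fit.no_recovery_

    def test_too_few_frames_rejected(self):
        with pytest.raises(InsufficientDataError):
            RecoveryCurveFitter().fit(np.arange(5.0), np.arange(5.0))

    def test_fit_recovery_wrapper_returns_result(self):
        s = make_series(
            60.0 + 30.0 * (1 - np.exp(-0.1 * np.arange(30) * 0.5)), 120.0, 0.0,
            pre=(np.full(4, 110.0), np.full(4, 120.0), np.zeros(4)),
        )
        fit = fit_recovery(correct_series(s))
        assert fit.converged and fit.rate > 0


class TestBleachProfile:
    def _frame(self, depth, r_e, pixel_size=0.05, size=201, noise_sd=0.0, seed=0):
        c = size // 2
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(xx - c, yy - c) * pixel_size
        frame = 1.0 - depth * np.exp(-2 * r**2 / r_e**2)
        if noise_sd:
            frame = frame + np.random.default_rng(seed).normal(0, noise_sd, frame.shape)
        return frame, (c, c), pixel_size

    def test_noiseless_profile_recovered(self):
        frame, center, ps = self._frame(0.8, 1.5)
        r_e, depth = estimate_effective_radius(frame, center, ps)
        # agreement limited by 1-pixel radial binning
        assert r_e == pytest.approx(1.5, rel=5e-3)
        assert depth == pytest.approx(0.8, rel=5e-3)

    def test_uniform_frame_raises_no_bleach(self):
        frame = np.ones((201, 201))
        with pytest.raises(NoBleachError):
            estimate_effective_radius(frame, (100, 100), 0.05)

    def test_center_refinement_tolerates_offset_center(self):
        frame, center, ps = self._frame(0.7, 1.2)
        shifted = (center[0] + 6, center[1] - 5)
        r_e, _ = estimate_effective_radius(frame, shifted, ps)
        assert r_e == pytest.approx(1.2, rel=0.02)


class TestDiffusionCoefficient:
    def test_arithmetic(self):
        est = diffusion_coefficient(2.0, 50.0)
        assert est.d_confocal == pytest.approx(0.02)
        assert est.coefficient == 0.25

    def test_doubling_radius_quadruples_d(self):
        d1 = diffusion_coefficient(1.0, 10.0).d_confocal
        d2 = diffusion_coefficient(2.0, 10.0).d_confocal
        assert d2 == pytest.approx(4.0 * d1)

    @settings(deadline=None, max_examples=25)
    @given(
        st.floats(min_value=0.5, max_value=3.0),
        st.floats(min_value=1.0, max_value=100.0),
        st.floats(min_value=0.2, max_value=5.0),
    )
    def test_scaling_homogeneity(self, r_e, t_half, c):
        d0 = diffusion_coefficient(r_e, t_half).d_confocal
        d1 = diffusion_coefficient(c * r_e, c**2 * t_half).d_confocal
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            diffusion_coefficient(0.0, 10.0)
        with pytest.raises(ValidationError):
            diffusion_coefficient(1.0, -1.0)


class TestClassifyOligomer:
    MONO = np.linspace(0.028, 0.038, 20)
    DIM = np.linspace(0.018, 0.024, 20)

    def test_sample_equal_to_dimer_ref(self):
        out = classify_oligomer(self.DIM, self.MONO, self.DIM)
        assert out["label"] == "dimer-like"

    def test_sample_equal_to_monomer_ref(self):
        out = classify_oligomer(self.MONO, self.MONO, self.DIM)
        assert out["label"] == "monomer-like"

    def test_sample_unlike_both_references_indeterminate(self):
        sample = np.linspace(0.05, 0.07, 20)
        out = classify_oligomer(sample, self.MONO, self.DIM)
        assert out["label"] == "indeterminate"

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_oligomer([0.02] * 3, self.MONO, self.DIM)
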