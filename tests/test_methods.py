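"""Tests for the reference method and the simplified dose estimators."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renaldosim.curves import DOSE_RATE, TimeSample
from renaldosim.methods import (
    DEFAULT_DOSIMETRY,
    DoseEstimate,
    DoseFactorConfig,
    DosimetryConfig,
    ProtocolViolationError,
    apply_recovery,
    dispatch_method,
    fit_hybrid_curve,
    hybrid_rescale,
    imaging_burden_reduction,
    method_A,
    method_E_scale,
    method_F,
    method_G,
    method_P,
    planar_ad,
    planar_background_correct,
    scale_by_injected_activity,
)
from renaldosim.stats import e1_theoretical

from conftest import LAM_REF, make_pair, make_record, monoexp_planar_series


class TestElementaryOps:
    def test_recovery_identity_and_division(self):
        assert apply_recovery(0.03, 1.0) == 0.03
        assert apply_recovery(0.0340, 0.85) == pytest.approx(0.0400, rel=1e-12)

    @given(st.floats(0.001, 1.0), st.floats(0.2, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_recovery_never_decreases_the_dose_rate(self, rate, recovery):
        assert apply_recovery(rate, recovery) >= rate

    def test_recovery_rejects_non_positive_factor(self):
        with pytest.raises(ValueError):
            apply_recovery(0.03, 0.0)

    def test_background_correction_arithmetic(self):
        assert planar_background_correct(120.0, 0.1, 100, 0.8) == pytest.approx(112.0)
        assert planar_background_correct(120.0, 0.0, 100, 0.8) == 120.0

    def test_background_correction_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert planar_background_correct(1.0, 1.0, 100, 1.0) == 0.0

    def test_injected_activity_scaling(self):
        assert scale_by_injected_activity(6.0, 7400.0, 7400.0) == 6.0
        assert scale_by_injected_activity(6.0, 7400.0, 7030.0) == pytest.approx(5.7, abs=1e-8)
        assert scale_by_injected_activity(6.0, 7400.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            scale_by_injected_activity(6.0, 0.0, 7400.0)


class TestHybridRescale:
    def test_flat_series_maps_to_spect_value(self):
        series = [TimeSample(t, 50.0) for t in (1.0, 24.0, 48.0, 168.0)]
        spect = TimeSample(24.0, 0.04, DOSE_RATE)
        out = hybrid_rescale(series, spect)
        assert all(s.value == pytest.approx(0.04) for s in out)
        assert all(s.kind == DOSE_RATE for s in out)

    def test_ratio_arithmetic(self):
        series = [TimeSample(24.0, 100.0), TimeSample(48.0, 50.0),
                  TimeSample(96.0, 25.0), TimeSample(168.0, 10.0)]
        out = hybrid_rescale(series, TimeSample(24.0, 0.04, DOSE_RATE))
        assert out[1].value == pytest.approx(0.02, rel=1e-12)

    def test_zero_activity_maps_to_zero_rate(self):
        series = [TimeSample(1.0, 0.0), TimeSample(24.0, 100.0),
                  TimeSample(48.0, 50.0), TimeSample(168.0, 10.0)]
        out = hybrid_rescale(series, TimeSample(24.0, 0.04, DOSE_RATE))
        assert out[0].value == 0.0

    def test_spect_time_between_samples_uses_loglinear_interpolation(self):
        lam = LAM_REF
        series = monoexp_planar_series(100.0, lam)
        spect = TimeSample(30.0, 0.04 * math.exp(-lam * 6.0), DOSE_RATE)
        out = hybrid_rescale(series, spect)
        # exact log-linear recovery on an exact exponential
        assert out[1].value == pytest.approx(0.04, rel=1e-9)

    def test_zero_activity_at_spect_time_rejected(self):
        series = [TimeSample(24.0, 0.0), TimeSample(48.0, 1.0),
                  TimeSample(96.0, 1.0), TimeSample(168.0, 1.0)]
        with pytest.raises(ValueError):
            hybrid_rescale(series, TimeSample(24.0, 0.04, DOSE_RATE))


class TestMethodP:
    def test_noise_free_monoexp_recovers_closed_form_dose(self):
        left, right = make_pair(a24=100.0, lam=LAM_REF, r24=0.04)
        est = method_P(left, right)
        curve = fit_hybrid_curve(left)
        assert est.ad_left == pytest.approx(curve.integral(), rel=1e-10)
        # exact piecewise oracle: backward-monoexp first point -> chord line
        v0 = 0.04 * math.exp(-LAM_REF * (1.0 - 24.0))
        l0 = v0 + (0.0 - 1.0) * (0.04 - v0) / (24.0 - 1.0)
        expected = 0.5 * (l0 + 0.04) * 24.0 + 0.04 / LAM_REF
        assert est.ad_left == pytest.approx(expected, rel=1e-8)

    def test_left_right_symmetry(self):
        left, right = make_pair()
        est = method_P(left, right)
        assert est.ad_left == pytest.approx(est.ad_right, rel=1e-12)
        assert est.ad_mean == pytest.approx(est.ad_left, rel=1e-12)

    def test_homogeneous_of_degree_one_in_signal(self):
        left, right = make_pair()
        k = 3.7
        scale = lambda r: dataclasses.replace(
            r,
            planar_series=tuple(
                TimeSample(s.t, s.value * k, s.kind) for s in r.planar_series
            ),
            spect_sample=TimeSample(
                r.spect_sample.t, r.spect_sample.value * k, DOSE_RATE
            ),
        )
        base = method_P(left, right)
        scaled = method_P(scale(left), scale(right))
        assert scaled.ad_mean == pytest.approx(k * base.ad_mean, rel=1e-9)

    def test_missing_acquisitions_violate_protocol(self):
        left, right = make_pair()
        crippled = dataclasses.replace(left, planar_series=left.planar_series[:2])
        with pytest.raises(ProtocolViolationError):
            method_P(crippled, right)
        no_spect = dataclasses.replace(left, spect_sample=None)
        with pytest.raises(ProtocolViolationError):
            method_P(no_spect, right)

    def test_borrowed_half_time_uses_contralateral_decay(self):
        left = make_record(side="left", lam=LAM_REF)
        # corrupt right kidney's tail shape but flag it as borrowed
        right = make_record(side="right", lam=3.0 * LAM_REF, lambda_borrowed=True)
        est = method_P(left, right)
        assert est.lam_right == pytest.approx(est.lam_left, rel=1e-9)


class TestMethodA:
    def test_four_equal_cycles(self):
        est = [
            DoseEstimate("p", i, "P", 6.0, 6.0) for i in range(1, 5)
        ]
        assert method_A(est) == pytest.approx(24.0)

    def test_three_cycles_pad_with_third(self):
        est = [DoseEstimate("p", i + 1, "P", d, d) for i, d in enumerate([6.0, 5.0, 4.0])]
        assert method_A(est) == pytest.approx(19.0)

    def test_extra_cycles_truncated(self):
        est = [DoseEstimate("p", i, "P", 1.0, 1.0) for i in range(1, 8)]
        assert method_A(est) == pytest.approx(4.0)

    def test_fewer_than_three_rejected(self):
        est = [DoseEstimate("p", i, "P", 6.0, 6.0) for i in (1, 2)]
        with pytest.raises(ValueError):
            method_A(est)


class TestSingleTimePointFormulas:
    def test_method_E_identity_and_example(self):
        assert method_E_scale(5.0, 0.04, 0.04, 24.0, 24.0, LAM_REF) == pytest.approx(5.0)
        val = method_E_scale(5.0, 0.04, 0.048, 24.0, 26.0, LAM_REF)
        assert val == pytest.approx(5.0 * 1.2 * math.exp(LAM_REF * 2.0), rel=1e-12)
        assert val == pytest.approx(6.163, abs=1e-3)
        assert method_E_scale(5.0, 0.04, 0.0, 24.0, 24.0, LAM_REF) == 0.0
        with pytest.raises(ValueError):
            method_E_scale(5.0, 0.0, 0.04, 24.0, 24.0, LAM_REF)

    def test_method_F_is_monoexp_area_from_time_zero(self):
        lam_ref = math.log(2.0) / 51.6
        assert method_F(0.02, 0.0, lam_ref) == pytest.approx(0.02 / lam_ref)
        assert method_F(0.02, 24.0, lam_ref) == pytest.approx(2.055, abs=1e-3)
        assert method_F(0.04, 24.0, lam_ref) == pytest.approx(
            2.0 * method_F(0.02, 24.0, lam_ref)
        )
        with pytest.raises(ValueError):
            method_F(0.02, 24.0, 0.0)

    def test_method_G_at_reference_time_needs_no_half_time(self):
        assert method_G(0.01, 96.0, None, 96.0) == pytest.approx(
            2.0 * 96.0 / math.log(2.0) * 0.01, rel=1e-12
        )
        assert method_G(0.01, 96.0, None, 96.0) == pytest.approx(2.770, abs=1e-3)

    def test_method_G_extrapolates_with_individual_half_time(self):
        val = method_G(0.04, 24.0, LAM_REF, 96.0)
        r96 = 0.04 * math.exp(-LAM_REF * 72.0)
        assert r96 == pytest.approx(0.015207, abs=1e-6)
        assert val == pytest.approx(2.0 * 96.0 / math.log(2.0) * r96, rel=1e-12)
        assert val == pytest.approx(4.212, abs=1e-3)

    def test_method_G_requires_half_time_off_reference_time(self):
        with pytest.raises(ValueError):
            method_G(0.04, 24.0, None, 96.0)

    @pytest.mark.parametrize("t_half", [30.0, 51.6, 80.0, 120.0])
    def test_method_G_error_on_monoexp_equals_theory(self, t_half):
        # G vs the exact area of a mono-exponential washout reproduces E1
        lam = math.log(2.0) / t_half
        r_s, t_s, t_ref = 0.05, 24.0, 96.0
        d_true = r_s * math.exp(lam * t_s) / lam
        rel_err = method_G(r_s, t_s, lam, t_ref) / d_true - 1.0
        assert rel_err == pytest.approx(e1_theoretical(t_ref / t_half), abs=1e-9)


class TestPlanarAd:
    def test_dose_factor_mass_scaling(self):
        df = DoseFactorConfig(df_ref=0.003, mass_ref=150.0)
        assert df.factor(150.0) == pytest.approx(0.003)
        assert df.factor(75.0) == pytest.approx(0.006)

    def test_planar_dose_is_cumulated_activity_times_dose_factor(self):
        df = DoseFactorConfig(df_ref=0.003, mass_ref=150.0)
        rec = make_record(a24=100.0, mass=150.0)
        ad, lam = planar_ad(rec, df)
        curve = fit_hybrid_curve(rec)
        a_tilde = curve.integral() / curve.amplitude * 100.0  # activity scale
        assert lam == pytest.approx(LAM_REF, rel=1e-8)
        assert ad == pytest.approx(a_tilde * 0.003, rel=1e-8)

    def test_halving_mass_doubles_dose(self):
        df = DoseFactorConfig(df_ref=0.003, mass_ref=150.0)
        ad_150, _ = planar_ad(make_record(mass=150.0), df)
        ad_75, _ = planar_ad(make_record(mass=75.0), df)
        assert ad_75 == pytest.approx(2.0 * ad_150, rel=1e-10)

    def test_missing_mass_rejected(self):
        rec = dataclasses.replace(make_record(), kidney_mass=None)
        with pytest.raises(ProtocolViolationError):
            planar_ad(rec, DoseFactorConfig())


class TestDispatch:
    def _noise_free_dataset(self, n_cycles=3, **kw):
        records = []
        for cyc in range(1, n_cycles + 1):
            left, right = make_pair(cycle=cyc, **kw)
            records += [left, right]
        return records

    def test_methods_agree_on_noise_free_monoexp_data(self):
        # every-cycle SPECT methods agree with the reference up to the
        # documented line-segment treatment before 24 h
        records = self._noise_free_dataset(first_ratio=math.exp(LAM_REF * 23.0))
        p = dispatch_method("P", records)
        config = DEFAULT_DOSIMETRY
        f = dispatch_method("F", records, dataclasses.replace(config, half_time_ref=math.log(2) / LAM_REF))
        g = dispatch_method("G", records)
        for pe, fe, ge in zip(p, f, g):
            assert fe.ad_mean == pytest.approx(pe.ad_mean, rel=0.01)
            # single-time-point deviation ~ E1(96/51.6) = +2.5 %
            assert ge.ad_mean / pe.ad_mean - 1.0 == pytest.approx(
                e1_theoretical(96.0 * LAM_REF / math.log(2.0)), abs=0.005
            )

    def test_H_first_cycle_equals_G_first_cycle(self):
        records = self._noise_free_dataset()
        g = dispatch_method("G", records)
        h = dispatch_method("H", records)
        assert h[0].ad_mean == pytest.approx(g[0].ad_mean, rel=1e-12)

    def test_D_with_constant_injected_activity_repeats_cycle_one(self):
        records = self._noise_free_dataset()
        d = dispatch_method("D", records)
        assert all(e.ad_mean == pytest.approx(d[0].ad_mean, rel=1e-12) for e in d)

    def test_B_scales_cycle_one_planar_dose_by_activity_ratio(self):
        records = []
        for cyc, a_inj in enumerate([7400.0, 7030.0, 7400.0], start=1):
            left, right = make_pair(cycle=cyc, a_inj=a_inj)
            records += [left, right]
        b = dispatch_method("B", records)
        assert b[1].ad_mean == pytest.approx(b[0].ad_mean * 7030.0 / 7400.0, rel=1e-12)
        assert b[2].ad_mean == pytest.approx(b[0].ad_mean, rel=1e-12)

    def test_A_pads_and_tags_four_cycles(self):
        records = self._noise_free_dataset(n_cycles=3)
        a = dispatch_method("A", records)
        assert [e.cycle_index for e in a] == [1, 2, 3, 4]
        assert a[3].ad_mean == pytest.approx(a[2].ad_mean)
        assert method_A(dispatch_method("P", records)) == pytest.approx(
            sum(e.ad_mean for e in a), rel=1e-12
        )

    def test_spect_at_reference_time_needs_no_planar_data(self):
        left, right = make_pair(t_s=96.0)
        left = dataclasses.replace(left, planar_series=())
        right = dataclasses.replace(right, planar_series=())
        g = dispatch_method("G", [left, right])
        assert len(g) == 1 and g[0].ad_mean > 0

    def test_missing_spect_is_a_named_protocol_violation(self):
        left, right = make_pair()
        left = dataclasses.replace(left, spect_sample=None)
        with pytest.raises(ProtocolViolationError, match="method F"):
            dispatch_method("F", [left, right])

    def test_unknown_method_rejected_before_any_computation(self):
        with pytest.raises(ValueError, match="unknown method"):
            dispatch_method("Z", [])

    def test_I_uses_planar_value_at_96h(self):
        # centre with a 96-h planar point: dose = 2 t_ref/ln2 * A(96) * DF(m)
        left, right = make_pair(times=(1.0, 24.0, 96.0, 168.0))
        est = dispatch_method("I", [left, right])[0]
        a96 = 100.0 * math.exp(-LAM_REF * 72.0)
        df = DEFAULT_DOSIMETRY.dose_factor.factor(150.0)
        expected = 2.0 * 96.0 / math.log(2.0) * a96 * df
        assert est.ad_mean == pytest.approx(expected, rel=1e-9)

    def test_I_interpolates_when_96h_not_sampled(self):
        # 48-h schedule: log-linear interpolation between 48 and 168 h is
        # exact on an exact exponential
        a = dispatch_method("I", list(make_pair(times=(1.0, 24.0, 48.0, 168.0))))[0]
        b = dispatch_method("I", list(make_pair(times=(1.0, 24.0, 96.0, 168.0))))[0]
        assert a.ad_mean == pytest.approx(b.ad_mean, rel=1e-9)


def test_imaging_burden_reduction_arithmetic():
    red = imaging_burden_reduction()
    assert red["time_points_pct"] == pytest.approx(75.0)
    assert red["imaging_time_pct"] == pytest.approx(100.0 * (1 - 40.0 / 120.0))
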