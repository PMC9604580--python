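"""Wave speed, distensibility, separation, FCW/FEW features, beat model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from awia import (
    AorticSignal,
    BeatSpec,
    Wavelet,
    WiaConfig,
    analyse_beat,
    bramwell_hill,
    extract_features,
    increments,
    net_wave_intensity,
    separate_waves,
    simulate_beat,
    wave_speed_loop,
)
from awia.errors import DomainError, InsufficientDataError
from awia.signal import IncrementSeries
from awia.simulate import default_forward_shape
from awia.wia import wave_speed_from_distensibility


def make_inc(dU, dlnA, dt=0.03):
    dU = np.asarray(dU, float)
    t = np.arange(len(dU)) * dt + dt / 2
    return IncrementSeries(t_mid=t, dU=dU, dlnA=np.asarray(dlnA, float), dt=dt)


class TestWaveSpeedLoop:
    def test_exact_line_slope(self):
        lnA0 = np.log(6e-4)
        lnA = lnA0 + np.linspace(0, 0.05, 12)
        U = 5.0 * (lnA - lnA0)
        fit = wave_speed_loop(lnA, U, range(0, 12))
        assert fit.c == pytest.approx(5.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not fit.negative

    def test_forward_only_beat_recovers_true_c_within_1pct(self):
        spec = BeatSpec(
            c_true=4.0, forward_wavelets=default_forward_shape(0.78, 1.0)
        )
        sig, _ = simulate_beat(spec)
        res = analyse_beat(sig)
        assert res.c == pytest.approx(4.0, rel=0.01)

    def test_backward_wave_biases_then_window_restriction_restores(self):
        # backward wavelet overlapping the default loop window
        spec = BeatSpec(
            c_true=4.0,
            forward_wavelets=default_forward_shape(0.78, 1.0),
            backward_wavelets=(Wavelet(center=0.20, width=0.03, amplitude=0.25),),
        )
        sig, _ = simulate_beat(spec)
        res = analyse_beat(sig, WiaConfig(smooth_window=1))
        assert abs(res.c - 4.0) / 4.0 > 0.05  # contaminated estimate
        early = wave_speed_loop(res.smoothed.lnA, res.smoothed.U, range(0, 4))
        assert early.c == pytest.approx(4.0, rel=0.01)

    def test_too_few_points_and_flat_lnA(self):
        lnA = np.linspace(0, 0.1, 10)
        with pytest.raises(InsufficientDataError):
            wave_speed_loop(lnA, lnA, range(0, 3))
        with pytest.raises(DomainError):
            wave_speed_loop(np.zeros(10), lnA, range(0, 6))

    def test_negative_slope_flagged_but_returned(self):
        lnA = np.linspace(0, 0.05, 8)
        fit = wave_speed_loop(lnA, -3.0 * lnA, range(0, 8))
        assert fit.negative
        assert fit.c == pytest.approx(-3.0, rel=1e-12)


class TestBramwellHill:
    def test_unit_arithmetic(self):
        d_pa, d_mmhg = bramwell_hill(1.0, rho=1000.0)
        assert d_pa == pytest.approx(1.0e-3, rel=1e-12)

    def test_hand_evaluated_reference(self):
        # 1/(1060 * 3.9^2) = 6.20e-5 1/Pa = 8.27e-3 1/mmHg
        d_pa, d_mmhg = bramwell_hill(3.9, rho=1060.0)
        assert d_pa == pytest.approx(6.20e-5, rel=5e-3)
        assert d_mmhg == pytest.approx(8.27e-3, rel=5e-3)

    def test_inverse_square_scaling_and_round_trip(self):
        d1, _ = bramwell_hill(2.5)
        d2, _ = bramwell_hill(5.0)
        assert d2 == pytest.approx(d1 / 4, rel=1e-12)
        assert wave_speed_from_distensibility(d1) == pytest.approx(2.5, rel=1e-14)

    def test_domain_errors(self):
        for c, rho in [(0, 1060), (-1, 1060), (4, 0)]:
            with pytest.raises(DomainError):
                bramwell_hill(c, rho)


class TestNetIntensityAndSeparation:
    def test_zero_velocity_increments_give_zero_intensity(self):
        inc = make_inc(np.zeros(10), np.linspace(0, 0.01, 10))
        assert np.all(net_wave_intensity(inc) == 0)

    def test_forward_compression_sample(self):
        inc = make_inc([0.10], [0.01])
        dI = net_wave_intensity(inc)
        assert dI[0] == pytest.approx(1.0e-3, rel=1e-12)
        assert dI[0] > 0 and inc.dlnA[0] > 0  # forward compression

    def test_bilinearity_scales_quadratically(self):
        inc = make_inc([0.1, -0.05], [0.01, 0.02])
        inc3 = make_inc([0.3, -0.15], [0.03, 0.06])
        np.testing.assert_allclose(
            net_wave_intensity(inc3), 9 * net_wave_intensity(inc), rtol=1e-12
        )

    def test_forward_only_identity(self):
        c = 4.2
        dlnA = np.linspace(-0.01, 0.02, 15)
        inc = make_inc(c * dlnA, dlnA)
        fwd, bwd = separate_waves(inc, c)
        np.testing.assert_allclose(bwd, 0, atol=1e-18)
        np.testing.assert_allclose(fwd, net_wave_intensity(inc), rtol=1e-12)

    def test_backward_only_mirror_identity(self):
        c = 4.2
        dlnA = np.linspace(-0.01, 0.02, 15)
        inc = make_inc(-c * dlnA, dlnA)
        fwd, bwd = separate_waves(inc, c)
        np.testing.assert_allclose(fwd, 0, atol=1e-18)
        np.testing.assert_allclose(bwd, net_wave_intensity(inc), rtol=1e-12)

    def test_conservation_on_random_increments(self, rng):
        dU = rng.normal(0, 0.2, 1000)
        dlnA = rng.normal(0, 0.02, 1000)
        inc = make_inc(dU, dlnA)
        fwd, bwd = separate_waves(inc, 4.4)
        net = net_wave_intensity(inc)
        scale = np.max(np.abs(net))
        assert np.max(np.abs(fwd + bwd - net)) <= 1e-12 * scale
        assert np.all(fwd >= 0) and np.all(bwd <= 0)

    @given(
        hnp.arrays(np.float64, 20, elements=st.floats(-0.5, 0.5)),
        hnp.arrays(np.float64, 20, elements=st.floats(-0.05, 0.05)),
        st.floats(min_value=0.5, max_value=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, dU, dlnA, c):
        inc = make_inc(dU, dlnA)
        fwd, bwd = separate_waves(inc, c)
        net = net_wave_intensity(inc)
        # conservation at machine precision relative to the separated
        # component scale (the net can cancel to ~0)
        scale = max(np.max(np.abs(fwd)), np.max(np.abs(bwd)), 1e-30)
        np.testing.assert_allclose(fwd + bwd, net, atol=1e-12 * scale, rtol=0)

    def test_nonpositive_wave_speed_rejected(self):
        inc = make_inc([0.1], [0.01])
        with pytest.raises(DomainError):
            separate_waves(inc, 0.0)


class TestExtractFeatures:
    def brute_force_beat(self, c=4.0, T=0.78, amp=1.0, dt=0.03):
        """Independent oracle: evaluate the Gaussian velocity shape on the
        analysis grid with plain numpy and measure FCW/FEW by hand."""
        wavelets = default_forward_shape(T, amp)
        n_fine = int(round(T / 0.001))
        tf = np.linspace(0, T, n_fine + 1)
        uf = np.zeros_like(tf)
        for w in wavelets:
            uf += w.amplitude * np.exp(-0.5 * ((tf - w.center) / w.width) ** 2)
        uf -= uf[0] + (uf[-1] - uf[0]) * (tf - tf[0]) / T
        n_out = int(np.ceil(T / dt - 1e-9))
        t = np.linspace(0, T, n_out + 1)
        u = np.interp(t, tf, uf)
        lnA = np.log(6e-4) + u / c
        dU, dlnA = np.diff(u), np.diff(lnA)
        dI = dU * dlnA
        ipeak = int(np.argmax(u))
        pre, post = dI[:ipeak], dI[ipeak:]
        dt_eff = T / n_out
        fcw_peak = pre.max()
        fcw_energy = np.trapezoid(pre[pre > 0], dx=dt_eff)
        few_peak = post.max()
        return t, u, lnA, fcw_peak, fcw_energy, few_peak

    def test_single_forward_wavelet_recovered_within_2pct(self):
        t, u, lnA, fcw_peak, fcw_energy, few_peak = self.brute_force_beat()
        sig, _ = simulate_beat(
            BeatSpec(c_true=4.0, forward_wavelets=default_forward_shape(0.78, 1.0))
        )
        res = analyse_beat(sig, WiaConfig(smooth_window=1))
        assert res.features.fcw_peak == pytest.approx(fcw_peak, rel=0.02)
        assert res.features.fcw_energy == pytest.approx(fcw_energy, rel=0.02)
        assert res.features.few_peak == pytest.approx(few_peak, rel=0.02)

    def test_flat_signal_reports_absent_not_zero(self):
        t = np.linspace(0, 1, 30)
        sig = AorticSignal("flat", t, np.full_like(t, 6e-4), np.zeros_like(t))
        inc = increments(sig)
        feats = extract_features(net_wave_intensity(inc), inc, sig)
        assert feats.fcw is None and feats.few is None

    def test_energy_matches_independent_trapezoid(self):
        sig, _ = simulate_beat(
            BeatSpec(c_true=5.0, forward_wavelets=default_forward_shape(0.78, 0.8))
        )
        res = analyse_beat(sig)
        span = res.features.fcw.span
        seg = res.dI_net[span[0] : span[1]]
        # manual trapezoid: dt * (x0/2 + x1 + ... + x_{n-1}/2)
        oracle = res.dt * (seg[0] / 2 + seg[1:-1].sum() + seg[-1] / 2)
        assert res.features.fcw_energy == pytest.approx(oracle, abs=1e-10)


class TestAnalyseBeat:
    def test_forward_only_recovery_of_c_and_fcw(self, forward_beat):
        sig, truth = forward_beat(c_true=5.0)
        res = analyse_beat(sig)
        assert res.c == pytest.approx(5.0, rel=0.01)
        assert res.features.fcw_peak == pytest.approx(truth.fcw_peak, rel=0.05)
        assert res.features.fcw_energy == pytest.approx(truth.fcw_energy, rel=0.05)
        assert res.D_mmhg == pytest.approx(truth.D_true_mmhg, rel=0.02)

    def test_adjusted_flag_excludes_wave_speed_keeps_features(self, forward_beat):
        sig, _ = forward_beat(adjusted=True)
        res = analyse_beat(sig)
        assert "wave_speed_excluded_adjusted" in res.flags
        assert not res.wave_speed_eligible
        assert res.features.fcw is not None and res.features.few is not None
        assert np.isfinite(res.c)  # value still computed, just excluded

    def test_determinism_bitwise(self, forward_beat):
        sig, _ = forward_beat(noise_sd_U=0.01, noise_sd_A=0.5, seed=3)
        r1, r2 = analyse_beat(sig), analyse_beat(sig)
        assert r1.c == r2.c
        assert np.array_equal(r1.dI_net, r2.dI_net)
        assert r1.to_row() == r2.to_row()

    def test_flat_beat_reports_absent_features(self):
        sig, truth = simulate_beat(BeatSpec(c_true=4.0))
        res = analyse_beat(sig)
        assert "no_systolic_upstroke" in res.flags
        assert res.features.fcw is None and res.features.few is None
        assert truth.fcw_peak is None

    def test_energy_invariant_to_velocity_offset_and_area_scale(self, forward_beat):
        sig, _ = forward_beat()
        base = analyse_beat(sig)
        shifted = AorticSignal(
            sig.subject_id, sig.t, sig.A * 1.7, sig.U + 0.05,
            dt_native=sig.dt_native,
        )
        alt = analyse_beat(shifted)
        assert alt.features.fcw_energy == pytest.approx(
            base.features.fcw_energy, rel=1e-9
        )
        assert alt.features.few_energy == pytest.approx(
            base.features.few_energy, rel=1e-9
        )

    def test_fcw_peak_scales_quadratically_with_amplitude(self, forward_beat):
        k = 1.8
        p1 = analyse_beat(forward_beat(amplitude=0.5)[0]).features.fcw_peak
        pk = analyse_beat(forward_beat(amplitude=0.5 * k)[0]).features.fcw_peak
        assert pk == pytest.approx(k**2 * p1, rel=0.02)

    def test_loop_c_error_shrinks_with_dt(self, forward_beat):
        errs = []
        for dt in (0.030, 0.015, 0.0075):
            sig, _ = forward_beat(dt_out=dt)
            errs.append(abs(analyse_beat(sig, WiaConfig(dt=dt)).c - 4.0))
        assert errs[2] < errs[1] < errs[0]

    def test_conservation_holds_on_fitted_beat(self, forward_beat):
        sig, _ = forward_beat(noise_sd_U=0.02, noise_sd_A=1.0, seed=11)
        res = analyse_beat(sig)
        scale = np.max(np.abs(res.dI_net))
        assert np.max(np.abs(res.dI_fwd + res.dI_bwd - res.dI_net)) <= 1e-12 * scale
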