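import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smootheffort.metrics import (SegmentationError, check_validity,
                                  compute_metrics, flexext_split,
                                  normalize_phasic_areas,
                                  phasic_torque_areas, segment_movement)
from smootheffort.plant import GravityCondition, PlantParams


FS = 2000.0


def half_sine(T=0.6, fs=FS, pad=0):
    n = int(T * fs)
    v = np.sin(np.pi * np.arange(n) / n)
    if pad:
        v = np.concatenate([np.zeros(pad), v, np.zeros(pad)])
    return v


class TestSegmentation:
    def test_half_sine_crossings_match_closed_form(self):
        # v = sin(pi t / T) crosses 0.05 PV at t = asin(0.05) T / pi
        T = 0.6
        on, off = segment_movement(half_sine(T), FS)
        t_on = np.arcsin(0.05) / np.pi * T
        assert on == pytest.approx(t_on, abs=2 / FS)
        assert off == pytest.approx(T - t_on, abs=2 / FS)

    def test_padding_translates_but_preserves_duration(self):
        pad = 500
        on0, off0 = segment_movement(half_sine(), FS)
        on1, off1 = segment_movement(half_sine(pad=pad), FS)
        assert (off1 - on1) == pytest.approx(off0 - on0, abs=2 / FS)
        assert on1 == pytest.approx(on0 + pad / FS, abs=2 / FS)

    def test_flat_trace_rejected(self):
        with pytest.raises(SegmentationError):
            segment_movement(np.zeros(1000), FS)

    def test_negative_velocity_movement_segments_on_speed(self):
        on, off = segment_movement(-half_sine(), FS)
        assert 0 < on < off


class TestComputeMetrics:
    def test_symmetric_half_sine_rtpv_is_50(self):
        v = half_sine(pad=200)
        a = np.gradient(v, 1 / FS)
        m = compute_metrics(v, a, FS)
        assert m.rtpv == pytest.approx(50.0, abs=0.1)
        assert m.valid

    def test_triangle_profile_closed_form(self):
        """Rise over 0.2 T, fall over 0.8 T.  With the 5% threshold:
        onset = 0.01 T, offset = 0.96 T, t_PV = 0.2 T, so
        rtPV = (0.2-0.01)/(0.96-0.01) = 20.0% exactly."""
        T, n = 1.0, 8000
        t = np.linspace(0, T, n)
        v = np.where(t <= 0.2, t / 0.2, (1 - t) / 0.8)
        v = np.maximum(v, 0.0)
        a = np.gradient(v, t)
        m = compute_metrics(v, a, n / T)
        assert m.rtpv == pytest.approx(20.0, abs=0.1)

    def test_time_reversal_maps_rtpv_to_complement(self):
        t = np.linspace(0, 1, 4000)
        v = np.sin(np.pi * t) ** 2 * (1 + 0.8 * t)  # asymmetric, one peak
        a = np.gradient(v, t)
        m_fwd = compute_metrics(v, a, 4000)
        m_rev = compute_metrics(v[::-1], np.gradient(v[::-1], t), 4000)
        assert m_fwd.rtpv == pytest.approx(100 - m_rev.rtpv, abs=0.2)

    def test_peak_values(self):
        v = 2.5 * half_sine(pad=100)
        a = np.gradient(v, 1 / FS)
        m = compute_metrics(v, a, FS)
        assert m.pv == pytest.approx(2.5, rel=1e-4)
        assert m.pa == pytest.approx(a.max(), rel=5e-2)
        assert m.pa > 0


class TestValidity:
    def test_single_accel_decel_is_valid(self):
        a = np.concatenate([np.ones(50), -np.ones(50)])
        assert check_validity(a)

    def test_two_crossings_boundary_case_is_valid(self):
        a = np.concatenate([np.ones(30), -np.ones(30), np.ones(30)])
        assert check_validity(a)

    def test_more_than_two_crossings_invalid(self):
        a = np.concatenate([np.ones(20), -np.ones(20), np.ones(20),
                            -np.ones(20), np.ones(20)])
        assert not check_validity(a)

    def test_exact_zeros_are_skipped(self):
        a = np.array([0, 1, 1, 0, 0, -1, -1, 0])
        assert check_validity(a)


class TestFlexExtSplit:
    @pytest.mark.parametrize("tau, flex, ext", [
        (2.0, 2.0, 0.0), (-3.0, 0.0, 3.0), (0.0, 0.0, 0.0)])
    def test_scalar_examples(self, tau, flex, ext):
        f, e = flexext_split(np.array([tau]))
        assert f[0] == flex and e[0] == ext

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1,
                    max_size=50))
    def test_reconstruction_and_complementarity(self, vals):
        tau = np.array(vals)
        f, e = flexext_split(tau)
        assert np.all(f >= 0) and np.all(e >= 0)
        assert np.allclose(f - e, tau)
        assert np.allclose(f * e, 0.0)


class TestPhasicTorque:
    def setup_method(self):
        self.params = PlantParams()
        self.cond = GravityCondition(alpha=0.0)

    def test_static_hold_has_zero_phasic(self):
        t = np.linspace(0, 1, 500)
        theta = np.full_like(t, 0.3)
        c = self.params.weight_moment * self.params.g0
        tau = np.full_like(t, c * np.cos(0.3))
        ph = phasic_torque_areas(t, tau, theta, 0.1, 0.9, self.cond,
                                 self.params)
        assert np.allclose(ph.phasic, 0.0, atol=1e-12)
        assert ph.pos_area == 0.0 and ph.neg_area == 0.0

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 1, 400)
        tau = rng.standard_normal(400)
        theta = 0.4 * np.sin(2 * np.pi * t)
        ph = phasic_torque_areas(t, tau, theta, 0.2, 0.8, self.cond,
                                 self.params)
        assert np.allclose(ph.tonic + ph.phasic, ph.tau_h, atol=1e-12)

    def test_microgravity_tonic_is_zero(self):
        cond = GravityCondition(alpha=1.0)
        t = np.linspace(0, 1, 500)
        theta = np.linspace(-0.3, 0.3, 500)
        tau = np.sin(2 * np.pi * t)
        ph = phasic_torque_areas(t, tau, theta, 0.0, 1.0, cond, self.params)
        assert np.allclose(ph.tonic, 0.0, atol=1e-12)
        flex, _ = flexext_split(tau)
        assert ph.pos_area == pytest.approx(np.trapezoid(flex, t), rel=1e-6)

    def test_normalization_requires_nonzero_phasic(self):
        t = np.linspace(0, 1, 100)
        theta = np.zeros_like(t)
        c = self.params.weight_moment * self.params.g0
        tau = np.full_like(t, c)
        ph = phasic_torque_areas(t, tau, theta, 0.1, 0.9, self.cond,
                                 self.params)
        with pytest.raises(ValueError, match="normalize"):
            normalize_phasic_areas([ph])

    def test_normalized_areas_scale_with_set_maximum(self):
        t = np.linspace(0, 1, 1000)
        theta = np.zeros_like(t)
        cond = GravityCondition(alpha=1.0)  # tonic = 0, phasic = tau
        tau_small = 0.5 * np.sin(np.pi * t)
        tau_big = 2.0 * np.sin(np.pi * t)
        phs = [phasic_torque_areas(t, tau, theta, 0.0, 1.0, cond,
                                   self.params)
               for tau in (tau_small, tau_big)]
        normalize_phasic_areas(phs)
        # set maximum is max|phasic| = 2 up to grid sampling of the sine peak
        assert phs[1].pos_area_norm == pytest.approx(
            phs[1].pos_area / 2.0, rel=1e-5)
        assert phs[0].pos_area_norm == pytest.approx(
            phs[0].pos_area / 2.0, rel=1e-5)
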