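import numpy as np
import pytest
from hypothesis import given, strategies as st

from synwalk.kinematics import (
    GaitEvents,
    KeypointTrace,
    cadence,
    cadence_from_events,
    detect_events,
    events_from_ankle_accel,
    interpolate_gaps,
    limb_angle,
    angle_per_stride,
    peak_angles,
    symmetry_index,
)
from synwalk.synth import SynthConfig, synthesize_kinematics


def _trace(hip, ankle, fs=60.0, y_axis="up"):
    return KeypointTrace(hip_xy=np.atleast_2d(hip), ankle_xy=np.atleast_2d(ankle),
                         fs=fs, y_axis=y_axis)


class TestLimbAngle:
    def test_vertical_limb_is_zero(self):
        a = limb_angle(_trace([0.0, 1.0], [0.0, 0.0]), lowpass=None)
        assert a[0] == pytest.approx(0.0)

    def test_30_degree_anterior_ankle(self):
        s, c = np.sin(np.radians(30)), np.cos(np.radians(30))
        a = limb_angle(_trace([0.0, 1.0], [s, 1.0 - c]), lowpass=None)
        assert a[0] == pytest.approx(30.0)

    def test_mirror_x_negates_angle(self):
        hip = np.array([[0.3, 1.0]])
        ankle = np.array([[0.55, 0.1]])
        a = limb_angle(_trace(hip, ankle), lowpass=None)
        b = limb_angle(_trace(hip * [-1, 1], ankle * [-1, 1]), lowpass=None)
        assert b[0] == pytest.approx(-a[0])

    def test_image_coordinates_flip_consistent(self):
        # y-down image frame: ankle below hip has larger y
        a_up = limb_angle(_trace([0.0, 1.0], [0.3, 0.2]), lowpass=None)
        a_down = limb_angle(_trace([0.0, 0.0], [0.3, 0.8], y_axis="down"),
                            lowpass=None)
        assert a_down[0] == pytest.approx(a_up[0])

    def test_zero_length_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            limb_angle(_trace([0.0, 1.0], [0.0, 1.0]), lowpass=None)

    @given(scale=st.floats(0.1, 50.0), dx=st.floats(-5, 5), dy=st.floats(-5, 5))
    def test_scale_and_translation_invariance(self, scale, dx, dy):
        hip = np.array([[0.1, 0.9]])
        ankle = np.array([[0.4, 0.12]])
        a = limb_angle(_trace(hip, ankle), lowpass=None)
        b = limb_angle(_trace(hip * scale + [dx, dy], ankle * scale + [dx, dy]),
                       lowpass=None)
        assert b[0] == pytest.approx(a[0], abs=1e-9)


class TestGapFilling:
    def test_short_gap_filled_linearly(self):
        xy = np.array([[0.0, 0], [1, 1], [np.nan, np.nan], [3, 3], [4, 4]])
        out = interpolate_gaps(xy)
        assert np.allclose(out[2], [2.0, 2.0])

    def test_long_gap_left_as_nan(self):
        xy = np.zeros((20, 2))
        xy[5:12] = np.nan  # 7-frame dropout > 5
        out = interpolate_gaps(xy, max_gap=5)
        assert np.isnan(out[6, 0])


@pytest.fixture(scope="module")
def kin_data():
    return synthesize_kinematics(SynthConfig(n_strides=12, seed=4))


class TestEventDetection:

    def test_heel_contacts_within_one_sample(self, kin_data):
        kd = kin_data
        ev = detect_events(kd.pressure_p, kd.pressure_np, kd.insole_fs)
        true_idx = np.round(kd.true_hc_p * kd.insole_fs)
        errs = [np.min(np.abs(ev.paretic_hc - i)) for i in true_idx]
        assert max(errs) <= 1

    def test_constant_zero_pressure_rejected(self):
        with pytest.raises(ValueError, match="pressure"):
            detect_events(np.zeros(500), np.zeros(500), 100.0)

    def test_keypoint_acceleration_agrees_within_30ms(self, kin_data):
        kd = kin_data
        kp_t = events_from_ankle_accel(kd.ankle_xy, kd.kin_fs) / kd.kin_fs
        interior = kd.true_hc_p[(kd.true_hc_p > 0.3)
                                & (kd.true_hc_p < kd.t_kin[-1] - 0.3)]
        errs = [np.min(np.abs(kp_t - t)) for t in interior]
        assert max(errs) < 0.030

    def test_validators_silent_on_consistent_sources(self, kin_data):
        import warnings
        kd = kin_data
        tr = KeypointTrace(hip_xy=kd.hip_xy, ankle_xy=kd.ankle_xy, fs=kd.kin_fs)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            detect_events(kd.pressure_p, kd.pressure_np, kd.insole_fs,
                          accel_ap=kd.accel[:, 0], ankle_trace=tr)

    def test_event_counts_per_side_balanced(self, kin_data):
        kd = kin_data
        ev = detect_events(kd.pressure_p, kd.pressure_np, kd.insole_fs)
        assert abs(len(ev.paretic_hc) - len(ev.nonparetic_hc)) <= 1
        assert (np.diff(ev.paretic_hc) > 0).all()


class TestPeakAngles:
    def test_sinusoid_peaks(self):
        p = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        tr = peak_angles(15.0 * np.sin(p)[None, :])
        assert tr.peak_flexion_deg == pytest.approx(15.0, abs=0.05)
        assert tr.peak_extension_deg == pytest.approx(-15.0, abs=0.05)

    def test_constant_trace_degenerate(self):
        tr = peak_angles(np.full((1, 100), 5.0))
        assert tr.peak_flexion_deg == 5.0
        assert tr.peak_extension_deg == 5.0

    def test_generator_setpoints_recovered_through_full_chain(self):
        cfg = SynthConfig(n_strides=27, stride_jitter_cv=0.0, seed=0)
        kd = synthesize_kinematics(cfg)
        tr = KeypointTrace(hip_xy=kd.hip_xy, ankle_xy=kd.ankle_xy, fs=kd.kin_fs)
        ev = detect_events(kd.pressure_p, kd.pressure_np, kd.insole_fs)
        ang = limb_angle(tr)
        hc = np.round(ev.times("paretic_hc") * kd.kin_fs).astype(int)
        cycles = angle_per_stride(ang, hc[hc < ang.size])
        pk = peak_angles(cycles)
        assert pk.peak_flexion_deg == pytest.approx(14.5, abs=0.5)
        assert pk.peak_extension_deg == pytest.approx(-14.4, abs=0.5)


class TestSymmetryAndCadence:
    def test_equal_support_times_give_zero(self):
        assert symmetry_index(0.45, 0.45) == 0.0

    def test_known_asymmetry(self):
        assert symmetry_index(0.4, 0.5) == pytest.approx(-100 * 0.1 / 0.45)

    @given(a=st.floats(0.05, 2.0), b=st.floats(0.05, 2.0))
    def test_antisymmetric_under_swap(self, a, b):
        assert symmetry_index(a, b) == pytest.approx(-symmetry_index(b, a))

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            symmetry_index(0.0, 0.5)

    def test_cadence_arithmetic(self):
        # 21 + 21 heel contacts = 40 steps over 24 s -> 100 steps/min
        ev = GaitEvents(fs=100.0,
                        paretic_hc=np.arange(21) * 120,
                        nonparetic_hc=np.arange(21) * 120 + 60,
                        paretic_to=np.array([]), nonparetic_to=np.array([]))
        assert cadence(ev, 24.0) == pytest.approx(100.0)
        assert cadence_from_events(ev) == pytest.approx(100.0)

    def test_cadence_degenerate_inputs(self):
        ev = GaitEvents(fs=100.0, paretic_hc=np.array([5]),
                        nonparetic_hc=np.array([]),
                        paretic_to=np.array([]), nonparetic_to=np.array([]))
        with pytest.raises(ValueError):
            cadence(ev, 10.0)
        with pytest.raises(ValueError):
            cadence(ev, 0.0)

    def test_synthetic_cadence_near_100(self):
        kd = synthesize_kinematics(SynthConfig(n_strides=20, stride_jitter_cv=0.0))
        ev = detect_events(kd.pressure_p, kd.pressure_np, kd.insole_fs)
        assert cadence_from_events(ev) == pytest.approx(100.0, abs=1.0)
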