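import numpy as np
import pytest
from scipy.signal import find_peaks

from straintwin.errors import ConfigurationError
from straintwin.motion import (
    DEFAULT_JOINT_RANGES,
    DOF_NAMES,
    add_sync_squats,
    gait_protocol,
    multijoint_routine,
    pick_place_protocol,
    sample_pose_corpus,
    single_joint_protocol,
)
from straintwin.preprocess import summed_angle_change_rate


def _dominant_freq(x, rate):
    X = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    return freqs[np.argmax(X)]


# ---------------------------------------------------------------------------
# corpus


def test_corpus_respects_ranges_and_seeding():
    a = sample_pose_corpus(n=500, seed=9)
    b = sample_pose_corpus(n=500, seed=9)
    assert a.equals(b)
    for name in a.columns:
        lo, hi = DEFAULT_JOINT_RANGES[name]
        assert a[name].min() >= lo and a[name].max() <= hi
    single = sample_pose_corpus(n=1, seed=0)
    assert len(single) == 1


# ---------------------------------------------------------------------------
# single-joint protocol


def test_single_joint_protocol_structure():
    stream, proto = single_joint_protocol(seed=0)
    assert len(stream.times) == 38_700
    assert stream.duration == pytest.approx(387.0, abs=0.02)
    # printed joint order, axes X, Y, Z in serial
    labels = [s.label for s in proto.segments]
    expected_joints = ["LE", "LS", "RE", "RS", "UB", "LB", "T", "LT", "RT", "LK", "RK"]
    assert labels[:3] == ["LE_X", "LE_Y", "LE_Z"]
    assert [l.split("_")[0] for l in labels[::3]] == expected_joints
    assert len(proto.segments) == 33


def test_single_joint_five_sweeps_per_segment():
    stream, proto = single_joint_protocol(seed=1, reps=5)
    for seg in proto.segments[:4]:
        d = DOF_NAMES.index(seg.label)
        i0 = int(seg.start_s * 100)
        i1 = int(seg.end_s * 100)
        trace = stream.angles[i0:i1, d]
        lo, hi = DEFAULT_JOINT_RANGES[seg.label]
        prom = 0.5 * max(abs(hi), abs(lo))
        n_peaks = len(find_peaks(trace, prominence=prom)[0])
        n_troughs = len(find_peaks(-trace, prominence=prom)[0])
        assert max(n_peaks, n_troughs) == 5


def test_generated_angles_stay_within_ranges():
    for stream in (
        single_joint_protocol(seed=2, segment_s=2.0)[0],
        multijoint_routine(duration=30.0, seed=2),
        gait_protocol(segment_s=5.0, seed=2)[0],
        pick_place_protocol(segment_s=5.0, seed=2)[0],
    ):
        lo = np.array([DEFAULT_JOINT_RANGES[n][0] for n in DOF_NAMES])
        hi = np.array([DEFAULT_JOINT_RANGES[n][1] for n in DOF_NAMES])
        assert np.all(stream.angles >= lo - 1e-9)
        assert np.all(stream.angles <= hi + 1e-9)


# ---------------------------------------------------------------------------
# multijoint routine


def test_multijoint_rate_targets():
    for target in (15.9, 3.9):
        stream = multijoint_routine(duration=120.0, target_rate=target, seed=4)
        _, mean_rate = summed_angle_change_rate(stream)
        assert abs(mean_rate - target) / target < 0.10
    still = multijoint_routine(duration=10.0, target_rate=0.0, seed=4)
    assert summed_angle_change_rate(still)[1] == pytest.approx(0.0)


def test_multijoint_unreachable_rate_errors():
    with pytest.raises(ConfigurationError):
        multijoint_routine(duration=10.0, target_rate=1e4, seed=0)


# ---------------------------------------------------------------------------
# pick and place


def test_pick_place_classes_and_beat_frequency():
    stream, proto = pick_place_protocol(segment_s=30.0, seed=5)
    assert len(proto.class_set) == 15
    # 1.0x class: one reach half-cycle per 90 BPM beat -> 0.75 Hz full cycles
    seg = next(s for s in proto.segments if s.meta["speed"] == 1.0)
    d = DOF_NAMES.index("LS_Y")
    i0, i1 = int(seg.start_s * 100), int(seg.end_s * 100)
    f = _dominant_freq(stream.angles[i0:i1, d], 100.0)
    assert f == pytest.approx(0.75, abs=0.05)
    # frequency ratio across speed classes is the speed ratio (7/3 for 1.4/0.6)
    f14 = _get_class_freq(stream, proto, 1.4)
    f06 = _get_class_freq(stream, proto, 0.6)
    assert f14 / f06 == pytest.approx(7.0 / 3.0, rel=0.06)


def _get_class_freq(stream, proto, speed):
    seg = next(s for s in proto.segments if s.meta["speed"] == speed)
    d = DOF_NAMES.index("LS_Y")
    i0, i1 = int(seg.start_s * 100), int(seg.end_s * 100)
    return _dominant_freq(stream.angles[i0:i1, d], 100.0)


# ---------------------------------------------------------------------------
# gait


def test_gait_classes_and_cadence():
    stream, proto = gait_protocol(segment_s=20.0, seed=6)
    assert len(proto.class_set) == 15
    assert len(set(proto.class_set)) == 15
    d = DOF_NAMES.index("LT_X")
    freqs = {}
    for seg in proto.segments:
        if seg.label.startswith("speed_"):
            i0, i1 = int(seg.start_s * 100), int(seg.end_s * 100)
            freqs[seg.meta["speed"]] = _dominant_freq(stream.angles[i0:i1, d], 100.0)
    speeds = sorted(freqs)
    assert all(freqs[a] < freqs[b] for a, b in zip(speeds, speeds[1:]))


def test_gait_degenerate_config_is_constant():
    stream, _ = gait_protocol(
        segment_s=5.0, seed=0, hip_amp=0.0, knee_amp=0.0,
        amplitude_scale=0.0, session_offset_sd=0.0, jitter_deg=0.0,
    )
    assert np.ptp(stream.angles, axis=0).max() == pytest.approx(0.0, abs=1e-12)


def test_gait_label_frame_consistency():
    stream, proto = gait_protocol(segment_s=5.0, seed=7)
    labels = proto.frame_labels(stream.times)
    # every frame inside a segment carries exactly one label
    assert sum(lab is None for lab in labels) <= 1  # only possibly the last edge frame
    counts = {c: int(np.sum(labels == c)) for c in proto.class_set}
    assert all(abs(v - 500) <= 1 for v in counts.values())


def test_generators_are_seeded():
    a, _ = gait_protocol(segment_s=5.0, seed=8)
    b, _ = gait_protocol(segment_s=5.0, seed=8)
    c, _ = gait_protocol(segment_s=5.0, seed=9)
    assert np.array_equal(a.angles, b.angles)
    assert not np.array_equal(a.angles, c.angles)


# ---------------------------------------------------------------------------
# sync squats


def test_add_sync_squats_peak_counts():
    stream, proto = gait_protocol(segment_s=5.0, seed=1)
    out, proto2 = add_sync_squats(stream, proto, n=5)
    d = DOF_NAMES.index("LK_X")
    lead = int(proto2.segments[0].start_s * 100)
    knee = out.angles[:, d]
    lead_peaks = find_peaks(knee[:lead], prominence=60.0)[0]
    tail_peaks = find_peaks(knee[int(proto2.segments[-1].end_s * 100):], prominence=60.0)[0]
    assert len(lead_peaks) == 5
    assert len(tail_peaks) == 5
    # protocol segments shifted by the lead train
    assert proto2.segments[0].start_s == pytest.approx(proto.segments[0].start_s + lead / 100.0)


def test_add_zero_squats_is_identity():
    stream, proto = gait_protocol(segment_s=5.0, seed=1)
    out, proto2 = add_sync_squats(stream, proto, n=0)
    assert out is stream and proto2 is proto
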