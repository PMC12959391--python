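import numpy as np
import pytest

from straintwin.errors import ContractError, DegenerateInputError, SynchronizationError
from straintwin.motion import AngleStream, add_sync_squats
from straintwin.preprocess import (
    AlignedDataset,
    estimate_clock_map,
    lowpass_reference,
    minmax_normalize,
    resample_linear,
    split_dataset,
    summed_angle_change_rate,
    synchronize_streams,
)
from straintwin.sensors import SensorStream


def _dataset(n=1000, labels=None, seed=0):
    rng = np.random.default_rng(seed)
    return AlignedDataset(
        times=np.arange(n) / 100.0,
        sensors=rng.normal(size=(n, 4)),
        angles=rng.normal(size=(n, 3)),
        channel_names=[f"ch{i:02d}" for i in range(4)],
        dof_names=["A_X", "A_Y", "A_Z"],
        labels=labels,
    )


# ---------------------------------------------------------------------------
# resampling & filtering


def test_resample_constant_and_ramp():
    t = np.arange(0, 1.01, 0.025)
    grid, out = resample_linear(t, np.full((len(t), 1), 3.3), 100.0)
    assert np.allclose(out, 3.3)
    grid, out = resample_linear(np.array([0.0, 1.0]), np.array([[0.0], [1.0]]), 100.0)
    k = np.argmin(np.abs(grid - 0.5))
    assert out[k, 0] == pytest.approx(0.5, abs=1e-9)
    assert out[0, 0] == 0.0 and out[-1, 0] == pytest.approx(1.0)


def test_resample_roundtrip_error_bound():
    """100 -> 40 -> 100 Hz on a 1 Hz sinusoid stays under the linear-interp bound."""
    t_fine = np.arange(0, 5, 0.001)
    x = np.sin(2 * np.pi * 1.0 * t_fine)
    t40, x40 = resample_linear(t_fine, x[:, None], 40.0)
    t100, back = resample_linear(t40, x40, 100.0)
    truth = np.sin(2 * np.pi * 1.0 * t100)
    bound = (1.0 * 0.025) ** 2 * np.pi ** 2 / 2  # linear-interp worst case at 40 Hz
    assert np.abs(back[:, 0] - truth).max() <= bound


def test_resample_rejects_unsorted():
    with pytest.raises(ContractError):
        resample_linear(np.array([0.0, 0.0, 1.0]), np.zeros((3, 1)))


def test_lowpass_dc_passband_and_stopband():
    t = np.arange(0, 10, 0.01)
    assert np.allclose(lowpass_reference(np.full((100, 1), 5.0)), 5.0)
    lo = np.sin(2 * np.pi * 1.0 * t)
    out = lowpass_reference(lo)
    assert np.abs(out - lo)[200:-200].max() < 0.01  # 1 Hz passes
    hi = np.sin(2 * np.pi * 20.0 * t)
    out = lowpass_reference(hi)
    # zero-phase squares the 4th-order magnitude at 2x cutoff: ~0.0624^2
    amp = np.abs(out[200:-200]).max()
    assert amp < 2 * 0.0624 ** 2
    with pytest.raises(ContractError):
        lowpass_reference(lo, rate=15.0)


# ---------------------------------------------------------------------------
# synchronization (full pipeline on a small simulated session)


@pytest.fixture(scope="module")
def sync_session(skeleton, suit):
    from straintwin.motion import single_joint_protocol
    from straintwin.sensors import SensorParams, simulate_stream

    stream, proto = single_joint_protocol(segment_s=6.0, seed=3)
    stream, proto = add_sync_squats(stream, proto)
    sensors = simulate_stream(skeleton, suit, stream, SensorParams(seed=3))
    return sensors, stream


def test_sync_recovers_injected_offsets(sync_session):
    sensors, angles = sync_session
    rng = np.random.default_rng(42)
    offsets = np.concatenate([rng.uniform(-3, 3, size=19), [1.37]])
    for off in offsets:
        shifted = SensorStream(
            times=sensors.times + off, values=sensors.values,
            channel_names=sensors.channel_names,
        )
        cmap = estimate_clock_map(shifted, angles)
        assert abs(cmap["offset"] - (-off)) <= 0.010  # within one 100 Hz frame


def test_sync_zero_offset_is_identity(sync_session):
    sensors, angles = sync_session
    cmap = estimate_clock_map(sensors, angles)
    assert abs(cmap["offset"]) <= 0.010
    assert cmap["scale"] == pytest.approx(1.0, abs=2e-4)
    data = synchronize_streams(sensors, angles)
    # sensors resampled onto the angle clock at 100 Hz
    assert data.n_frames == pytest.approx(len(angles.times), abs=3)
    assert np.allclose(np.diff(data.times), 0.01)


def test_sync_recovers_clock_scale(sync_session):
    sensors, angles = sync_session
    drift = 1.001  # 0.1% clock-rate mismatch
    scaled = SensorStream(
        times=sensors.times * drift, values=sensors.values,
        channel_names=sensors.channel_names,
    )
    cmap = estimate_clock_map(scaled, angles)
    assert cmap["scale"] * drift == pytest.approx(1.0, abs=2e-4)


def test_sync_without_peaks_raises():
    n = 2000
    angles = AngleStream(times=np.arange(n) / 100.0, angles=np.zeros((n, 39)))
    sensors = SensorStream(times=np.arange(n // 2) / 50.0, values=np.full((n // 2, 3), 100.0))
    with pytest.raises(SynchronizationError):
        synchronize_streams(sensors, angles)


# ---------------------------------------------------------------------------
# splitting


def test_split_sizes_match_311():
    data = _dataset(38_700)
    split_dataset(data, mode="random", seed=0)
    counts = {tag: int(np.sum(data.split == tag)) for tag in ("train", "val", "test")}
    assert counts == {"train": 23_220, "val": 7_740, "test": 7_740}


def test_split_partition_and_determinism():
    d1 = split_dataset(_dataset(997), mode="random", seed=5)
    d2 = split_dataset(_dataset(997), mode="random", seed=5)
    assert np.array_equal(d1.split, d2.split)
    assert set(d1.split) == {"train", "val", "test"}
    total = sum(int(np.sum(d1.split == t)) for t in ("train", "val", "test"))
    assert total == 997
    d3 = split_dataset(_dataset(997), mode="random", seed=6)
    assert not np.array_equal(d1.split, d3.split)


def test_sequential_split_is_time_ordered():
    data = split_dataset(_dataset(500), mode="sequential")
    assert data.times[data.mask("train")].max() < data.times[data.mask("val")].min()
    assert data.times[data.mask("val")].max() < data.times[data.mask("test")].min()


def test_sequential_by_class_splits_each_class():
    labels = np.array(["a"] * 500 + ["b"] * 500, dtype=object)
    data = split_dataset(_dataset(1000, labels=labels), mode="sequential_by_class")
    for cls in ("a", "b"):
        m = data.labels == cls
        assert int(np.sum(m & data.mask("train"))) == 300
        assert int(np.sum(m & data.mask("test"))) == 100
        # within a class, train precedes val precedes test
        assert data.times[m & data.mask("train")].max() < data.times[m & data.mask("val")].min()


def test_split_requires_minimum_frames():
    with pytest.raises(ContractError):
        split_dataset(_dataset(4))


# ---------------------------------------------------------------------------
# statistics


def test_minmax_normalize():
    assert np.allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])
    x = np.random.default_rng(0).normal(size=(50, 2))
    out = minmax_normalize(x)
    assert np.allclose(out.min(axis=0), 0) and np.allclose(out.max(axis=0), 1)
    # affine invariance for positive scales
    assert np.allclose(minmax_normalize(3.2 * x + 7.0), out, atol=1e-12)
    with pytest.raises(DegenerateInputError):
        minmax_normalize(np.full(10, 1.0))


def test_summed_angle_change_rate():
    n = 200
    angles = np.zeros((n, 39))
    stream = AngleStream(times=np.arange(n) / 100.0, angles=angles)
    series, mean = summed_angle_change_rate(stream)
    assert mean == 0.0
    angles2 = angles.copy()
    angles2[:, 5] = np.arange(n) * 1.0  # one DoF moving 1 deg per 10 ms frame
    series, mean = summed_angle_change_rate(
        AngleStream(times=np.arange(n) / 100.0, angles=angles2)
    )
    assert mean == pytest.approx(1.0)


def test_aligned_dataset_dir_roundtrip(tmp_path):
    labels = np.array(["x"] * 60 + ["y"] * 40, dtype=object)
    data = split_dataset(_dataset(100, labels=labels), mode="random", seed=1)
    data.to_dir(tmp_path / "ds")
    back = AlignedDataset.from_dir(tmp_path / "ds")
    assert np.allclose(back.sensors, data.sensors, rtol=1e-9)
    assert np.allclose(back.angles, data.angles, rtol=1e-9)
    assert np.array_equal(back.labels, data.labels)
    assert np.array_equal(back.split, data.split)
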