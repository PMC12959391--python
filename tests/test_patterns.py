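import numpy as np
import pytest

from straintwin._lstm import LSTMCore
from straintwin.errors import ContractError
from straintwin.patterns import (
    ClassifierConfig,
    MotionClassifier,
    frequency_profile,
    make_windows,
)
from straintwin.preprocess import AlignedDataset, split_dataset


# ---------------------------------------------------------------------------
# spectra


def test_dominant_frequency_of_sinusoid():
    t = np.arange(0, 10, 0.01)
    spec = frequency_profile(np.sin(2 * np.pi * 1.5 * t), rate=100.0)
    f, a = spec.dominant(1)[0]
    assert f == pytest.approx(1.5, abs=0.1)
    assert a == pytest.approx(1.0, abs=0.05)


def test_constant_series_is_pure_offset():
    spec = frequency_profile(np.full(256, 4.2), rate=100.0)
    assert spec.offset == pytest.approx(4.2)
    assert np.abs(spec.amplitudes).max() < 1e-9


def test_two_component_amplitude_ordering():
    t = np.arange(0, 8, 0.01)
    x = 2.0 * np.sin(2 * np.pi * 1.0 * t) + 1.0 * np.sin(2 * np.pi * 3.0 * t)
    dom = frequency_profile(x, rate=100.0).dominant(2)
    assert dom[0][0] == pytest.approx(1.0, abs=0.1)
    assert dom[1][0] == pytest.approx(3.0, abs=0.1)
    assert dom[0][1] > dom[1][1]


@pytest.mark.parametrize("n", [256, 255])
def test_parseval_energy_identity(n, rng):
    x = rng.normal(size=(n, 2))
    spec = frequency_profile(x, rate=50.0)
    ms_time = (x ** 2).mean(axis=0)
    assert np.allclose(spec.mean_square(), ms_time, rtol=1e-6)


def test_nonuniform_timestamps_rejected(rng):
    x = rng.normal(size=64)
    t = np.sort(rng.uniform(0, 1, size=64))
    with pytest.raises(ContractError):
        frequency_profile(x, rate=64.0, times=t)
    with pytest.raises(ContractError):
        frequency_profile(x[:8], rate=100.0)


# ---------------------------------------------------------------------------
# windowing


def _labeled_dataset(segments, n_channels=3, seed=0):
    """segments: list of (n_frames, label or None)."""
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.full(n, lab, dtype=object) for n, lab in segments])
    n = len(labels)
    return AlignedDataset(
        times=np.arange(n) / 100.0,
        sensors=rng.normal(size=(n, n_channels)),
        angles=np.zeros((n, 1)),
        channel_names=[f"ch{i:02d}" for i in range(n_channels)],
        dof_names=["A_X"],
        labels=labels,
    )


def test_lookback_one_keeps_every_labeled_frame():
    data = _labeled_dataset([(80, "a"), (20, None), (50, "b")])
    X, y, classes = make_windows(data, lookback=1)
    assert len(X) == 130
    assert X.shape[1:] == (1, 3)
    assert classes == ["a", "b"]


def test_lookback_window_counts_and_boundaries():
    data = _labeled_dataset([(100, "a"), (100, "b")])
    X, y, classes = make_windows(data, lookback=10)
    # 91 windows per 100-frame segment; none mixes frames across the boundary
    assert len(X) == 182
    assert int(np.sum(y == 0)) == 91
    first_b = np.nonzero(y == 1)[0][0]
    sensors_b = data.sensors[100:110]
    assert np.allclose(X[first_b], sensors_b)


def test_windows_respect_split_tags():
    data = _labeled_dataset([(100, "a"), (100, "b")])
    split_dataset(data, mode="sequential_by_class")
    X_tr, y_tr, classes = make_windows(data, 1, split_tag="train")
    X_te, y_te, _ = make_windows(data, 1, split_tag="test", class_set=classes)
    assert len(X_tr) == 120 and len(X_te) == 40


# ---------------------------------------------------------------------------
# LSTM core


def test_lstm_gradients_match_finite_differences(rng):
    core = LSTMCore(input_dim=4, n_classes=3, layers=2, hidden=5, seed=1)
    X = rng.normal(size=(6, 3, 4))
    y = rng.integers(0, 3, size=6)
    loss, grads = core.loss_and_grads(X, y)
    eps = 1e-6
    for pi, p in enumerate(core.params):
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, 6)):
            ix = it.multi_index
            old = p[ix]
            p[ix] = old + eps
            lp, _ = core.loss_and_grads(X, y)
            p[ix] = old - eps
            lm, _ = core.loss_and_grads(X, y)
            p[ix] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(grads[pi][ix], abs=1e-7)
            it.iternext()


def test_lstm_config_echo():
    cfg = ClassifierConfig()
    assert cfg.layers == 3 and cfg.hidden == 50 and cfg.lookback == 1
    assert cfg.batch == 64 and cfg.iterations == 1000
    core = LSTMCore(input_dim=38, n_classes=5)
    # 3 stacked layers (Wx, Wh, b each) plus the softmax head
    assert len(core.params) == 3 * 3 + 2
    assert core.params[0].shape == (200, 38)
    assert core.params[-2].shape == (5, 50)
    with pytest.raises(ContractError):
        ClassifierConfig(lookback=0)


def _sinusoid_class_dataset(freqs=(1.0, 3.0), n_per=600, seed=0, offsets=True):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for k, f in enumerate(freqs):
        t = np.arange(n_per) / 100.0
        phase = rng.uniform(0, 2 * np.pi)
        x = np.stack(
            [np.sin(2 * np.pi * f * t + phase), np.cos(2 * np.pi * f * t + phase)], axis=1
        )
        if offsets:  # distinct per-recording baselines
            x = x + (k + 1) * 3.0
        blocks.append(x)
        labels.append(np.full(n_per, f"f{f:g}", dtype=object))
    n = n_per * len(freqs)
    data = AlignedDataset(
        times=np.arange(n) / 100.0,
        sensors=np.vstack(blocks),
        angles=np.zeros((n, 1)),
        channel_names=["ch00", "ch01"],
        dof_names=["A_X"],
        labels=np.concatenate(labels),
    )
    return split_dataset(data, mode="sequential_by_class")


def test_separable_classes_reach_perfect_accuracy():
    """Two periodic classes separable only by frequency: windows long enough
    to resolve the frequency classify perfectly, matching a nearest-centroid
    oracle on the window spectra."""
    L = 32
    data = _sinusoid_class_dataset(freqs=(3.0, 9.0), offsets=False)
    x_tr, y_tr, classes = make_windows(data, L, split_tag="train")
    x_te, y_te, _ = make_windows(data, L, split_tag="test", class_set=classes)

    def spectra(X):
        return np.abs(np.fft.rfft(X[:, :, 0], axis=1))

    s_tr, s_te = spectra(x_tr), spectra(x_te)
    cents = np.stack([s_tr[y_tr == k].mean(axis=0) for k in range(2)])
    oracle = np.argmin(
        np.stack([np.linalg.norm(s_te - c, axis=1) for c in cents], axis=1), axis=1
    )
    assert (oracle == y_te).mean() == 1.0  # spectra separate the classes exactly

    cfg = ClassifierConfig(layers=2, hidden=16, lookback=L, iterations=250,
                           eval_every=50, seed=0)
    results = MotionClassifier(cfg).fit(data)
    acc, conf = results.evaluate(data, tag="test")
    assert acc == 1.0
    assert np.all(np.diag(conf.to_numpy()) > 0)


def test_probabilities_and_confusion_contract():
    data = _sinusoid_class_dataset(n_per=300)
    cfg = ClassifierConfig(iterations=60, eval_every=30, seed=1)
    results = MotionClassifier(cfg).fit(data)
    X, y, _ = make_windows(data, 1, split_tag="test", class_set=results.class_set)
    probs = results.predict_proba(X)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    acc, conf = results.evaluate(data, tag="test")
    # confusion rows sum to the per-class test counts
    counts = {c: int(np.sum(y == k)) for k, c in enumerate(results.class_set)}
    for cls, row_sum in conf.sum(axis=1).items():
        assert row_sum == counts[cls]


def test_single_class_rejected():
    data = _labeled_dataset([(200, "only")])
    split_dataset(data, mode="sequential_by_class")
    with pytest.raises(ContractError):
        MotionClassifier(ClassifierConfig(iterations=10)).fit(data)


def test_accuracy_invariant_to_channel_affine_rescaling():
    """Rescaling every channel (train and test alike) leaves the standardized
    inputs, and hence the fitted classifier's accuracy, unchanged."""
    base = _sinusoid_class_dataset(n_per=300, seed=2)
    cfg = ClassifierConfig(iterations=120, eval_every=60, seed=3)
    acc1, _ = MotionClassifier(cfg).fit(base).evaluate(base, tag="test")

    scaled = _sinusoid_class_dataset(n_per=300, seed=2)
    scaled.sensors = scaled.sensors * np.array([3.7, 0.2]) + np.array([-50.0, 8.0])
    acc2, _ = MotionClassifier(cfg).fit(scaled).evaluate(scaled, tag="test")
    assert acc1 == pytest.approx(acc2, abs=1e-12)


def test_larger_class_separation_never_hurts_on_average(skeleton, suit):
    """Averaged over seeds, growing the generator's class-separation effect
    (session offset scale) does not reduce gait-class accuracy."""
    from straintwin.motion import gait_protocol
    from straintwin.preprocess import align_streams_shared_clock, attach_labels
    from straintwin.sensors import SensorParams, simulate_stream

    def run(sd, seed):
        stream, proto = gait_protocol(
            speeds=(), widths=("narrow", "wide"), slopes=(),
            segment_s=12.0, seed=seed, session_offset_sd=sd,
        )
        sensors = simulate_stream(skeleton, suit, stream, SensorParams(seed=seed))
        data = align_streams_shared_clock(sensors, stream)
        attach_labels(data, proto)
        split_dataset(data, mode="sequential_by_class", seed=seed)
        cfg = ClassifierConfig(iterations=80, eval_every=40, seed=seed)
        results = MotionClassifier(cfg).fit(data)
        acc, _ = results.evaluate(data, tag="test")
        return acc

    seeds = range(5)
    low = np.mean([run(0.5, s) for s in seeds])
    high = np.mean([run(4.0, s) for s in seeds])
    assert high >= low - 0.02
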