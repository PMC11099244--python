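"""Model construction, gradients, training loops and test isolation."""

import numpy as np
import pytest

from eegleak.classifiers import (
    ModelSpec,
    NumpyCNN,
    SurrogateBandPower,
    TrainConfig,
    band_power_features,
    build_model,
    train_and_evaluate,
)
from eegleak.cv_splitting import split_subject_based
from eegleak.preprocessing import SegmentSet, segment_cohort
from eegleak.synthetic_cohort import CohortConfig, generate_cohort


def make_segments(n_per_class=20, m=64, channels=2, fs=64.0, seed=0, separable=True):
    """Tiny synthetic SegmentSet: two classes of sinusoids at distinct bands."""
    rng = np.random.default_rng(seed)
    t = np.arange(m) / fs
    X, y, s = [], [], []
    for cls, freq in enumerate((6.0, 10.0)):
        for i in range(n_per_class):
            f = freq if separable else 8.0
            seg = np.stack(
                [
                    np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                    + 0.3 * rng.standard_normal(m)
                    for _ in range(channels)
                ],
                axis=1,
            )
            X.append(seg)
            y.append(cls)
            s.append(f"s{cls}{i % 4}")
    return SegmentSet(
        X=np.stack(X),
        y=np.array(y),
        s=np.array(s, dtype=object),
        fs=fs,
        segment_s=m / fs,
    )


class TestBandPowerFeatures:
    def test_recovers_sinusoid_power(self):
        """A pure 10 Hz sinusoid of amplitude A has alpha-band power A^2/2."""
        fs, m, A = 250.0, 500, 3.0
        t = np.arange(m) / fs
        X = (A * np.sin(2 * np.pi * 10.0 * t))[None, :, None]
        feats = band_power_features(X, fs)  # (1, 4 bands)
        alpha_log = feats[0, 2]  # bands ordered delta, theta, alpha, beta
        assert alpha_log == pytest.approx(np.log(A**2 / 2), abs=1e-3)

    def test_shape(self):
        X = np.zeros((7, 100, 3))
        assert band_power_features(X, 100.0).shape == (7, 12)


class TestBuildModel:
    def test_cnn1d_on_raw_shape_emits_two_logits(self):
        model = build_model(ModelSpec.cnn1d_raw((500, 19)), seed=0)
        logits = model.forward(np.zeros((3, 500, 19)))
        assert logits.shape == (3, 2)
        assert np.all(np.isfinite(logits))
        assert model.n_parameters > 0

    def test_cnn2d_on_image_shape_emits_two_logits(self):
        model = build_model(ModelSpec.cnn2d_image((224, 224, 3)), seed=0)
        logits = model.forward(np.zeros((2, 224, 224, 3)))
        assert logits.shape == (2, 2)
        assert np.all(np.isfinite(logits))

    def test_shape_mismatch_named_error(self):
        model = build_model(ModelSpec.cnn1d_raw((500, 19)), seed=0)
        with pytest.raises(ValueError, match="expected.*got"):
            model.forward(np.zeros((2, 500, 18)))

    def test_surrogate_is_deterministic_fit(self):
        segments = make_segments()
        idx = np.arange(segments.n_segments)
        accs = []
        for _ in range(2):
            model = build_model(ModelSpec.surrogate(segments.fs))
            model.init_fit(segments, idx, TrainConfig(epochs=5, learning_rate=0.1, seed=3))
            for _ in range(5):
                model.train_epoch()
            accs.append(model.score(segments, idx))
        assert accs[0] == accs[1]


def numeric_gradient(model, x, y, param, index, eps=1e-6):
    def loss():
        logits = model.forward(x, training=False)
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return -np.mean(logp[np.arange(len(y)), y])

    old = param[index]
    param[index] = old + eps
    up = loss()
    param[index] = old - eps
    down = loss()
    param[index] = old
    return (up - down) / (2 * eps)


@pytest.mark.parametrize(
    "spec",
    [
        ModelSpec(
            kind="cnn1d_raw", input_shape=(32, 2), conv_filters=(3,),
            kernel=3, pool=2, dense=(5,),
        ),
        ModelSpec(
            kind="cnn2d_image", input_shape=(10, 10, 2), conv_filters=(3,),
            kernel=3, pool=2, dense=(4,),
        ),
    ],
    ids=["conv1d", "conv2d"],
)
def test_backprop_matches_numeric_gradient(spec, rng):
    """Analytic gradients agree with central differences on a tiny net.

    Batch norm is checked in inference mode (running statistics frozen) so
    the loss is a deterministic function of the parameters.
    """
    model = NumpyCNN(spec, seed=0)
    x = rng.standard_normal((4, *spec.input_shape))
    y = np.array([0, 1, 1, 0])
    # freeze batch-norm stats on a representative batch, then check in eval mode
    model.forward(x, training=True)

    logits = model.forward(x, training=False)
    z = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    grad = probs.copy()
    grad[np.arange(len(y)), y] -= 1.0
    grad /= len(y)
    for layer in reversed(model.layers):
        grad = layer.backward(grad)

    checked = 0
    for layer in model.layers:
        for param, gparam in layer.params:
            flat = param.reshape(-1)
            gflat = gparam.reshape(-1)
            for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                num = numeric_gradient(model, x, y, flat, k)
                assert num == pytest.approx(gflat[k], abs=1e-6, rel=1e-4)
                checked += 1
    assert checked >= 10


class TestTraining:
    def test_surrogate_memorizes_tiny_set(self):
        segments = make_segments(n_per_class=6, seed=1)
        model = build_model(ModelSpec.surrogate(segments.fs))
        idx = np.arange(segments.n_segments)
        train = np.concatenate([idx[:5], idx[6:11]])  # 10 segments
        test = np.setdiff1d(idx, train)
        result = train_and_evaluate(
            model,
            segments,
            (train, test),
            TrainConfig(epochs=40, batch_size=4, learning_rate=0.1, seed=0),
        )
        assert result.train_acc[-1] == 1.0

    def test_small_cnn_memorizes_tiny_set(self):
        segments = make_segments(n_per_class=6, m=32, seed=2)
        spec = ModelSpec(
            kind="cnn1d_raw", input_shape=(32, 2), conv_filters=(4, 8),
            kernel=3, pool=2, dense=(8,),
        )
        model = build_model(spec, seed=0)
        idx = np.arange(segments.n_segments)
        train = np.concatenate([idx[:5], idx[6:11]])
        test = np.setdiff1d(idx, train)
        result = train_and_evaluate(
            model,
            segments,
            (train, test),
            TrainConfig(epochs=40, batch_size=5, learning_rate=0.01, seed=0),
        )
        assert max(result.train_acc) >= 0.9

    def test_permuted_labels_give_chance_test_accuracy(self):
        """No label signal, subject-held-out fold: accuracy in binomial band."""
        config = CohortConfig(
            n_subjects_per_group=5, n_channels=4, duration=60.0,
            fingerprint_strength=0.0, seed=8,
        )
        segments = segment_cohort(generate_cohort(config), 2.0)
        rng = np.random.default_rng(0)
        segments.y = rng.permutation(segments.y)
        plan = split_subject_based(segments.s, 5, seed=8)
        model = build_model(ModelSpec.surrogate(config.fs))
        result = train_and_evaluate(
            model, segments, plan.folds[0],
            TrainConfig(epochs=10, learning_rate=0.1, seed=8),
        )
        band = 1.96 * np.sqrt(0.25 / result.n_test)
        assert abs(result.final_test_acc - 0.5) < 2 * band

    def test_test_labels_cannot_influence_fit(self):
        """Scrambling test labels changes scores but not the learned weights."""
        segments = make_segments(seed=3)
        plan = split_subject_based(segments.s, 2, seed=0)
        fold = plan.folds[0]

        def fit(scramble):
            segs = SegmentSet(
                X=segments.X.copy(), y=segments.y.copy(),
                s=segments.s.copy(), fs=segments.fs, segment_s=segments.segment_s,
            )
            if scramble:
                test_idx = fold[1]
                segs.y[test_idx] = np.random.default_rng(99).permutation(
                    segs.y[test_idx]
                )
            model = build_model(ModelSpec.surrogate(segs.fs))
            train_and_evaluate(
                model, segs, fold, TrainConfig(epochs=5, learning_rate=0.1, seed=1)
            )
            return model.w.copy(), model.b

        w_clean, b_clean = fit(scramble=False)
        w_scrambled, b_scrambled = fit(scramble=True)
        np.testing.assert_array_equal(w_clean, w_scrambled)
        assert b_clean == b_scrambled

    def test_fold_index_validation(self):
        segments = make_segments()
        model = build_model(ModelSpec.surrogate(segments.fs))
        cfg = TrainConfig(epochs=1, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_and_evaluate(model, segments, (np.array([], dtype=int), np.arange(3)), cfg)
        with pytest.raises(ValueError, match="overlap"):
            train_and_evaluate(model, segments, (np.arange(5), np.arange(4, 8)), cfg)
        with pytest.raises(IndexError):
            train_and_evaluate(
                model, segments, (np.arange(5), np.array([10_000])), cfg
            )

    def test_epoch_trajectories_match_config(self):
        segments = make_segments(n_per_class=15)
        model = build_model(ModelSpec.surrogate(segments.fs))
        idx = np.arange(segments.n_segments)
        result = train_and_evaluate(
            model, segments, (idx[:20], idx[20:]),
            TrainConfig(epochs=7, learning_rate=0.1, seed=0),
        )
        assert len(result.train_acc) == 7 and len(result.test_acc) == 7
        assert all(0 <= a <= 1 for a in result.train_acc + result.test_acc)
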