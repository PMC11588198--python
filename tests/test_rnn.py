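import numpy as np
import pytest

from pcgseg.annotation import FrameLabels
from pcgseg.features import SpectroFrames
from pcgseg.pipeline import prepare_example
from pcgseg.rnn import (
    BiGruClassifier,
    RnnConfig,
    build_rnn,
    class_weights,
    frame_accuracy,
    train_rnn,
    weighted_cross_entropy,
)
from pcgseg.synthetic import SimConfig, simulate_pcg


def _tiny_cfg(**kw):
    defaults = dict(input_dim=4, rnn_layers=2, hidden=3, fc_sizes=(5, 4),
                    dropout=0.0, seed=3)
    defaults.update(kw)
    return RnnConfig(**defaults)


class TestArchitecture:
    def test_default_config_matches_published_architecture(self):
        cfg = RnnConfig()
        assert (cfg.rnn_layers, cfg.hidden, cfg.fc_sizes, cfg.dropout) == \
            (3, 60, (60, 40), 0.1)

    def test_seeded_build_reproducible(self):
        a, b = build_rnn(RnnConfig(seed=5)), build_rnn(RnnConfig(seed=5))
        assert a.n_parameters == b.n_parameters > 0
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_rows_sum_to_one(self, rng):
        model = build_rnn(_tiny_cfg())
        probs, _ = model.forward(rng.normal(size=(2, 9, 4)))
        assert probs.shape == (2, 9, 5)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-9)
        assert probs.min() >= 0

    def test_wrong_feature_dim_rejected(self, rng):
        model = build_rnn(_tiny_cfg())
        with pytest.raises(ValueError, match="feature columns"):
            model.forward(rng.normal(size=(1, 9, 7)))

    def test_inference_deterministic(self, rng):
        model = build_rnn(_tiny_cfg())
        X = rng.normal(size=(1, 9, 4))
        a, _ = model.forward(X)
        b, _ = model.forward(X)
        assert np.array_equal(a, b)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_rnn(_tiny_cfg())
        path = tmp_path / "model.npz"
        model.save(path)
        back = BiGruClassifier.load(path)
        X = rng.normal(size=(1, 6, 4))
        assert np.array_equal(model.forward(X)[0], back.forward(X)[0])


def test_gradients_match_finite_differences(rng):
    """Analytic backprop through the full BiGRU + FC stack vs central differences."""
    model = build_rnn(_tiny_cfg())
    X = rng.normal(size=(2, 7, 4))
    Y = rng.integers(0, 5, size=(2, 7))
    w = np.array([1.0, 0.5, 2.0, 1.0, 0.5])

    probs, cache = model.forward(X)
    _, dlogits = weighted_cross_entropy(probs, Y, w)
    grads = model.backward(cache, dlogits)

    eps = 1e-6
    for name, p in model.params.items():
        flat = p.ravel()
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = weighted_cross_entropy(model.forward(X)[0], Y, w)[0]
            flat[i] = orig - eps
            lm = weighted_cross_entropy(model.forward(X)[0], Y, w)[0]
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[name].ravel()[i]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), name


class TestClassWeights:
    def _labels(self, counts):
        states = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
        return [FrameLabels(states=states)]

    def test_uniform_counts(self):
        assert np.allclose(class_weights(self._labels([10] * 5)), 1.0)

    def test_inverse_frequency_normalised(self):
        # 1/counts = (.025, .05, .05, .1, .1), mean .065 -> weights (5, 10,
        # 10, 20, 20)/13 with mean exactly 1
        w = class_weights(self._labels([40, 20, 20, 10, 10]))
        assert np.allclose(w, np.array([5, 10, 10, 20, 20]) / 13)
        assert w.mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = class_weights(self._labels([40, 20, 20, 10, 10]))
        b = class_weights(self._labels([80, 40, 40, 20, 20]))
        assert np.allclose(a, b)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="murmur"):
            class_weights(self._labels([10, 10, 10, 10, 0]))


class TestTraining:
    def test_length_mismatch_rejected(self, rng):
        cfg = _tiny_cfg()
        sf = SpectroFrames(values=rng.normal(size=(10, 4)))
        fl = FrameLabels(states=rng.integers(0, 5, size=9))
        with pytest.raises(ValueError, match="mismatch"):
            train_rnn(build_rnn(cfg), [(sf, fl)], cfg)

    def test_seeded_training_deterministic(self, rng):
        cfg = _tiny_cfg(epochs=3, dropout=0.1)
        sf = SpectroFrames(values=rng.normal(size=(30, 4)))
        states = np.tile([0, 1, 2, 3, 4], 6)
        dataset = [(sf, FrameLabels(states=states))]
        logs = []
        for _ in range(2):
            log = []
            train_rnn(build_rnn(cfg), dataset, cfg, log=log)
            logs.append(log)
        assert logs[0] == logs[1]

    def test_overfits_single_recording(self):
        # early-systolic so all five states occur in the single recording
        cfg = SimConfig(heart_rate_bpm=100.0, murmur="early", murmur_snr_db=0.0,
                        duration_s=8.0, seed=21)
        rec, intervals = simulate_pcg(cfg)
        dataset = [prepare_example(rec, intervals)]
        rcfg = RnnConfig(epochs=60, seed=1, dropout=0.0, patience=60)
        model = train_rnn(build_rnn(rcfg), dataset, rcfg)
        assert frame_accuracy(model, dataset) >= 0.99


def test_murmur_posterior_separation(segmenter, murmur_example):
    """Inside true murmur frames, the murmur posterior dominates its level in
    diastole frames on a held-out loud holosystolic recording."""
    from pcgseg.io_formats import STATE_ORDER

    _, _, sf, fl = murmur_example
    probs = segmenter.predict_posteriors(sf)
    mur = STATE_ORDER.index("murmur")
    dia = STATE_ORDER.index("diastole")
    in_murmur = probs[fl.states == mur, mur].mean()
    in_diastole = probs[fl.states == dia, mur].mean()
    assert in_murmur > in_diastole


def test_heldout_accuracy_beats_prior_baseline(segmenter):
    """Trained frame accuracy far exceeds the majority-class baseline."""
    from pcgseg.synthetic import simulate_recordings

    data = simulate_recordings(12, seed=201)
    dataset = [prepare_example(r, iv) for r, iv, _, _ in data]
    acc = frame_accuracy(segmenter, dataset)
    counts = np.zeros(5)
    for _, fl in dataset:
        counts += np.bincount(fl.states, minlength=5)
    baseline = counts.max() / counts.sum()
    assert baseline <= 0.45
    assert acc >= 0.85
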