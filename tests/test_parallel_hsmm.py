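import numpy as np
import pytest

from pcgseg.heart_rate import HeartRateEstimate
from pcgseg.io_formats import STATE_ORDER
from pcgseg.parallel_hsmm import (
    MODEL_IDS,
    HsmmModel,
    _log_dur_pdf,
    build_model_bank,
    confidence,
    decide,
    duration_support,
    greedy_segmentation,
    viterbi_duration,
)

COLS = list(STATE_ORDER)


def _hr(bpm=90.0):
    return HeartRateEstimate(bpm=bpm, period_s=60.0 / bpm, peak_lag=int(3000 / bpm))


def brute_force_viterbi(probs, model, frame_step=0.02):
    """Exhaustive enumeration over all duration-valid cyclic segmentations.

    Same conventions as the decoder: first and last segments are partial
    (observation cost only, capped at the state's max duration); interior
    segments carry the Gaussian duration penalty and must lie in
    [dmin, dmax].
    """
    obs = model.observations(probs)
    T, S = obs.shape
    logobs = np.log(np.maximum(obs, 1e-12))
    sup = [duration_support(model.duration_mean[s], model.duration_sd[s], frame_step)
           for s in model.state_list]
    best_score, best_path = -np.inf, None

    def recurse(t, s, segs):
        nonlocal best_score, best_path
        dmin, dmax = sup[s]
        for d in range(1, min(dmax, T - t) + 1):
            is_first, is_last = t == 0, t + d == T
            if not (is_first or is_last) and d < dmin:
                continue
            new = segs + [(s, d)]
            if is_last:
                score, pos = 0.0, 0
                for k, (ss, dd) in enumerate(new):
                    score += logobs[pos:pos + dd, ss].sum()
                    if 0 < k < len(new) - 1:
                        name = model.state_list[ss]
                        score += _log_dur_pdf(np.array([dd]),
                                              model.duration_mean[name],
                                              model.duration_sd[name],
                                              frame_step)[0]
                    pos += dd
                if score > best_score:
                    best_score = score
                    best_path = np.concatenate(
                        [np.full(dd, ss) for ss, dd in new])
            else:
                recurse(t + d, (s + 1) % S, new)

    for s0 in range(S):
        recurse(0, s0, [])
    return best_score, best_path


def _toy_model(rng, n_states):
    names = tuple(f"st{i}" for i in range(n_states))
    means = {n: float(rng.uniform(0.04, 0.12)) for n in names}
    sds = {n: 0.3 * means[n] for n in names}
    obs = {n: COLS[i % 5] for i, n in enumerate(names)}
    return HsmmModel("toy", names, means, sds, obs)


class TestGreedy:
    def test_one_hot_recovered(self, rng):
        seq = rng.integers(0, 5, size=30)
        probs = np.eye(5)[seq]
        assert np.array_equal(greedy_segmentation(probs), seq)

    def test_tie_breaks_to_first_state(self):
        row = np.array([[0.3, 0.3, 0.2, 0.1, 0.1]])
        assert greedy_segmentation(row)[0] == 0

    def test_unconstrained_optimality(self, rng):
        probs = rng.dirichlet(np.ones(5), size=40)
        greedy = greedy_segmentation(probs)
        greedy_mass = probs[np.arange(40), greedy].mean()
        other = rng.integers(0, 5, size=40)
        assert greedy_mass >= probs[np.arange(40), other].mean()


class TestModelBank:
    def test_cycle_sums_to_beat_period(self):
        for bpm in (60.0, 95.0, 180.0):
            for model in build_model_bank(_hr(bpm)):
                assert sum(model.duration_mean.values()) == pytest.approx(
                    60.0 / bpm, abs=1e-9)

    def test_state_counts(self):
        bank = {m.model_id: m for m in build_model_bank(_hr())}
        assert bank["omega1"].n_states == 4
        assert bank["omega2"].n_states == 4
        assert bank["omega3"].n_states == 5
        assert bank["omega4"].n_states == 6

    def test_omega2_systole_observes_murmur(self):
        bank = {m.model_id: m for m in build_model_bank(_hr())}
        assert bank["omega2"].obs_source["systole"] == "murmur"
        assert bank["omega3"].state_list[1] == "murmur"  # S1 -> murmur first
        assert bank["omega4"].state_list[1].startswith("sys")  # S1 -> systole first

    def test_omega1_discards_and_renormalises_murmur_mass(self, rng):
        bank = build_model_bank(_hr())
        probs = rng.dirichlet(np.ones(5), size=20)
        obs = bank[0].observations(probs)
        assert obs.shape == (20, 4)
        assert np.allclose(obs.sum(axis=1), 1.0, atol=1e-9)


class TestViterbi:
    def test_one_hot_feasible_path_recovered(self):
        model = HsmmModel(
            "toy", ("a", "b"), {"a": 0.08, "b": 0.08}, {"a": 0.02, "b": 0.02},
            {"a": "S1", "b": "systole"})
        # 4 frames a, 4 frames b, 4 frames a: all durations inside support
        seq = np.array([0] * 4 + [1] * 4 + [0] * 4)
        probs = np.zeros((12, 5))
        probs[seq == 0, 0] = 1.0
        probs[seq == 1, 1] = 1.0
        seg = viterbi_duration(probs, model)
        assert np.array_equal(seg.path, seq)

    @pytest.mark.parametrize("n_states", [2, 3])
    def test_matches_exhaustive_enumeration(self, n_states):
        rng = np.random.default_rng(1234 + n_states)
        for _ in range(15):
            T = int(rng.integers(4, 13))
            model = _toy_model(rng, n_states)
            probs = rng.dirichlet(np.ones(5), size=T)
            seg = viterbi_duration(probs, model)
            bscore, bpath = brute_force_viterbi(probs, model)
            assert seg.score == pytest.approx(bscore, abs=1e-9)
            assert np.array_equal(seg.path, bpath)

    def test_no_forbidden_transitions(self, rng):
        hr = _hr(100.0)
        probs = rng.dirichlet(np.ones(5), size=300)
        for model in build_model_bank(hr):
            seg = viterbi_duration(probs, model)
            changes = np.flatnonzero(np.diff(seg.path) != 0)
            for i in changes:
                assert seg.path[i + 1] == model.next_state(seg.path[i])

    def test_interior_durations_within_support(self, rng):
        hr = _hr(100.0)
        probs = rng.dirichlet(np.ones(5), size=300)
        model = build_model_bank(hr)[0]
        seg = viterbi_duration(probs, model)
        bounds = np.flatnonzero(np.diff(seg.path) != 0)
        runs = np.diff(np.concatenate([[-1], bounds, [len(seg.path) - 1]]))
        for k, L in enumerate(runs):
            if k == 0 or k == len(runs) - 1:
                continue  # partial entry/exit segments
            state = seg.path[np.concatenate([[0], bounds + 1])[k]]
            name = model.state_list[state]
            dmin, dmax = duration_support(model.duration_mean[name],
                                          model.duration_sd[name], 0.02)
            assert dmin <= L <= dmax


class TestConfidence:
    def test_upper_bound_one(self):
        model = HsmmModel("toy", ("a",), {"a": 0.1}, {"a": 0.03}, {"a": "S1"})
        probs = np.zeros((10, 5))
        probs[:, 0] = 1.0
        assert confidence(np.zeros(10, dtype=int), probs, model) == 1.0

    def test_uniform_posteriors(self):
        model = HsmmModel("toy", ("a", "b"), {"a": 0.1, "b": 0.1},
                          {"a": 0.03, "b": 0.03}, {"a": "S1", "b": "murmur"})
        probs = np.full((10, 5), 0.2)
        path = np.array([0] * 5 + [1] * 5)
        assert confidence(path, probs, model) == pytest.approx(0.2)

    def test_bounded_by_greedy(self, rng):
        probs = rng.dirichlet(np.ones(5), size=200)
        hr = _hr(100.0)
        greedy_mass = probs.max(axis=1).mean()
        for model in build_model_bank(hr)[1:]:  # raw-column models
            seg = viterbi_duration(probs, model)
            assert confidence(seg.path, probs, model) <= greedy_mass + 1e-12


class TestDecide:
    def test_confidences_recomputed_match(self, rng):
        probs = rng.dirichlet(np.ones(5), size=250)
        decision, results = decide(probs, _hr(100.0))
        for mid, (model, seg) in results.items():
            assert decision.confidences[mid] == pytest.approx(
                confidence(seg.path, probs, model), abs=1e-12)
        assert decision.chosen == max(MODEL_IDS,
                                      key=lambda m: decision.confidences[m])
        assert decision.c_mn == pytest.approx(
            decision.c_murmur - decision.c_normal)

    def test_murmur_mass_monotonicity(self, rng):
        """Moving systole-frame mass into the murmur column never lowers C(M-N)."""
        hr = _hr(100.0)
        base = rng.dirichlet(np.ones(5), size=250)
        decision0, _ = decide(base, hr)
        sys_col, mur_col = 1, 4
        shifted = base.copy()
        move = 0.5 * shifted[:, sys_col]
        shifted[:, sys_col] -= move
        shifted[:, mur_col] += move
        decision1, _ = decide(shifted, hr)
        assert decision1.c_mn >= decision0.c_mn - 1e-9

    def test_end_to_end_normal_recording(self, segmenter, normal_example):
        from pcgseg.pipeline import analyse_recording

        decision, _, _, _ = analyse_recording(segmenter, normal_example[0])
        assert decision.chosen == "omega1"
        assert decision.c_mn < 0

    def test_end_to_end_loud_murmur(self, segmenter, murmur_example):
        from pcgseg.pipeline import analyse_recording

        decision, _, _, _ = analyse_recording(segmenter, murmur_example[0])
        assert decision.murmur_detected
        assert decision.c_mn > 0
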