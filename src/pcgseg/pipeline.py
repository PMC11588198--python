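"""End-to-end orchestration: recording -> features -> posteriors -> decision.

Thin glue over the stage modules so the command-line interface, the test
suite and experiment scripts all run the identical path.
"""

from __future__ import annotations

import numpy as np

from .annotation import intervals_to_frames
from .features import extract_features
from .heart_rate import estimate_heart_rate_from_posteriors
from .io_formats import PcgRecording, SegmentInterval
from .parallel_hsmm import decide
from .rnn import BiGruClassifier, RnnConfig, build_rnn, train_rnn, frame_accuracy
from .synthetic import simulate_recordings


def prepare_example(rec: PcgRecording,
                    intervals: list[SegmentInterval]):
    """Feature matrix and aligned frame labels for one annotated recording."""
    sf = extract_features(rec)
    fl = intervals_to_frames(intervals, sf.n_frames)
    return sf, fl


def analyse_recording(model: BiGruClassifier, rec: PcgRecording):
    """Full inference path for one recording.

    Returns ``(decision, seg_results, posteriors, hr)`` where ``seg_results``
    maps model ids to (HsmmModel, SegmentationResult).
    """
    sf = extract_features(rec)
    probs = model.predict_posteriors(sf)
    hr = estimate_heart_rate_from_posteriors(probs)
    decision, seg_results = decide(probs, hr)
    return decision, seg_results, probs, hr


def train_segmenter(
    n_train: int = 200,
    seed: int = 0,
    epochs: int = 12,
    duration_s: float = 10.0,
    rnn_config: RnnConfig | None = None,
    log: list | None = None,
) -> BiGruClassifier:
    """Train the frame classifier on simulated recordings."""
    data = simulate_recordings(n_train, seed=seed, duration_s=duration_s)
    dataset = [prepare_example(rec, iv) for rec, iv, _, _ in data]
    cfg = rnn_config or RnnConfig(epochs=epochs, seed=seed)
    model = build_rnn(cfg)
    return train_rnn(model, dataset, cfg, log=log)


def evaluate_segmenter(
    model: BiGruClassifier,
    n_test: int = 100,
    seed: int = 1,
    duration_s: float = 10.0,
) -> dict:
    """Held-out evaluation: frame accuracy and murmur AUROC via C(M-N).

    Returns per-recording C(M-N) values and binary murmur labels along with
    the summary numbers, so callers can draw ROC or reliability plots.
    """
    from .metrics import auroc

    data = simulate_recordings(n_test, seed=seed, duration_s=duration_s)
    correct = total = 0
    c_mns, labels, grades = [], [], []
    for rec, intervals, timing, grade in data:
        sf, fl = prepare_example(rec, intervals)
        probs = model.predict_posteriors(sf)
        pred = np.argmax(probs, axis=1)
        correct += int((pred == fl.states).sum())
        total += len(fl)
        hr = estimate_heart_rate_from_posteriors(probs)
        decision, _ = decide(probs, hr)
        c_mns.append(decision.c_mn)
        labels.append(int(timing != "none"))
        grades.append(grade)
    return {
        "frame_accuracy": correct / total,
        "murmur_auroc": auroc(c_mns, labels),
        "c_mn": c_mns,
        "labels": labels,
        "grades": grades,
        "n": len(data),
    }
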