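"""Parallel duration-explicit hidden semi-Markov segmentation models.

Four competing HSMMs reinterpret the frame classifier's posteriors, each
assuming a different signal type:

* omega1 — normal signal, four states (S1 -> systole -> S2 -> diastole); the
  murmur posterior column is discarded and the rows renormalised.
* omega2 — holosystolic murmur: same four-state cycle, but the systolic
  state observes the murmur posterior column.
* omega3 — early-systolic murmur: five states, S1 -> murmur -> systole ->
  S2 -> diastole.
* omega4 — mid-systolic murmur: six states, S1 -> systole -> murmur ->
  systole -> S2 -> diastole (the systolic interval is split around the
  murmur; both halves observe the systole column).

State dwell times follow Gaussian duration distributions whose means are
scaled by the estimated heart rate so that one full cycle sums to the beat
period.  Each model produces a maximum-score duration-constrained state
path; the mean posterior mass along that path is the model's segmentation
confidence C(omega).  The most confident model wins: a murmur model winning
means a murmur is detected, and the margin C(M-N) between the best murmur
model and the normal model is a calibrated murmur likelihood.  C of the
chosen model doubles as a signal-quality estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FRAME_STEP
from .heart_rate import HeartRateEstimate
from .io_formats import STATE_ORDER, SegmentInterval

MODEL_IDS = ("omega1", "omega2", "omega3", "omega4")
MURMUR_MODELS = ("omega2", "omega3", "omega4")

#: murmur timing implied by each winning model
MODEL_TIMING = {
    "omega1": "none",
    "omega2": "holosystolic",
    "omega3": "early-systolic",
    "omega4": "mid-systolic",
}

#: fixed valve-sound durations (s); the rest of the cycle is split between
#: systole and diastole at 1:1.7 (paediatric resting proportions)
S1_DUR = 0.122
S2_DUR = 0.092
SYS_DIA_RATIO = 1.7
#: duration standard deviation as a fraction of the mean
DUR_SD_FRAC = 0.25
#: duration support is truncated at +/- this many sd around the mean
DUR_TRUNC_SD = 3.0
#: observation floor before taking logs
OBS_FLOOR = 1e-12

_COL = {name: i for i, name in enumerate(STATE_ORDER)}


@dataclass
class HsmmModel:
    """One decoding hypothesis: cyclic state chain + durations + observation map."""

    model_id: str
    state_list: tuple  # decode-state names, cycle order
    duration_mean: dict  # state -> seconds
    duration_sd: dict  # state -> seconds
    obs_source: dict  # decode state -> posterior column name
    renormalise_4col: bool = False  # omega1: drop murmur column, renormalise

    @property
    def n_states(self) -> int:
        return len(self.state_list)

    def next_state(self, i: int) -> int:
        return (i + 1) % self.n_states

    def prev_state(self, i: int) -> int:
        return (i - 1) % self.n_states

    def observations(self, probs: np.ndarray) -> np.ndarray:
        """T x n_states observation probabilities for this model's decode states."""
        probs = np.asarray(probs, dtype=np.float64)
        if self.renormalise_4col:
            four = probs[:, [_COL[s] for s in ("S1", "systole", "S2", "diastole")]]
            four = four / np.maximum(four.sum(axis=1, keepdims=True), OBS_FLOOR)
            base = {"S1": four[:, 0], "systole": four[:, 1],
                    "S2": four[:, 2], "diastole": four[:, 3]}
            return np.stack([base[self.obs_source[s]] for s in self.state_list], axis=1)
        return np.stack(
            [probs[:, _COL[self.obs_source[s]]] for s in self.state_list], axis=1
        )

    def canonical_states(self) -> list[str]:
        """Map decode states to the five canonical names (systole halves -> systole)."""
        return [self.obs_source[s] if s.startswith("sys") else
                ("murmur" if s == "murmur" else s) for s in self.state_list]


@dataclass
class SegmentationResult:
    """Decoded path and its traced-back confidence under one model."""

    model_id: str
    path: np.ndarray  # (T,) indices into model.state_list
    score: float
    confidence: float = 0.0

    def to_intervals(self, model: HsmmModel,
                     frame_step: float = FRAME_STEP) -> list[SegmentInterval]:
        canon = model.canonical_states()
        out = []
        t = 0
        T = len(self.path)
        while t < T:
            s = self.path[t]
            start = t
            while t < T and self.path[t] == s:
                t += 1
            name = canon[s]
            if out and out[-1].state == name:
                out[-1] = SegmentInterval(out[-1].start, t * frame_step, name)
            else:
                out.append(SegmentInterval(start * frame_step, t * frame_step, name))
        return out


@dataclass
class ParallelDecision:
    """Joint outcome of the four-model comparison for one recording."""

    chosen: str
    c_murmur: float  # C(M): best murmur-model confidence
    c_normal: float  # C(N) = C(omega1)
    c_mn: float  # C(M-N) = C(M) - C(N), murmur likelihood
    quality: float  # C of the chosen model: signal quality
    murmur_timing: str = "none"
    confidences: dict = field(default_factory=dict)

    @property
    def murmur_detected(self) -> bool:
        return self.chosen in MURMUR_MODELS


def greedy_segmentation(probs: np.ndarray) -> np.ndarray:
    """Per-frame argmax over the five states; ties break to the earlier state.

    The unconstrained baseline: maximises per-frame posterior but allows
    physically impossible transitions, hence its proneness to spurious
    murmur frames.
    """
    return np.argmax(np.asarray(probs), axis=1)


def build_model_bank(hr: HeartRateEstimate) -> list[HsmmModel]:
    """Instantiate omega1..omega4 with duration means summing to one beat period."""
    cycle = 60.0 / hr.bpm
    rem = cycle - S1_DUR - S2_DUR
    if rem <= 0:
        raise ValueError(f"heart rate {hr.bpm:.0f} bpm leaves no systole/diastole time")
    sys_share = rem / (1.0 + SYS_DIA_RATIO)
    dia_share = rem - sys_share

    def _model(model_id, names, means, obs):
        sds = {s: DUR_SD_FRAC * m for s, m in means.items()}
        return HsmmModel(model_id=model_id, state_list=tuple(names),
                         duration_mean=means, duration_sd=sds, obs_source=obs,
                         renormalise_4col=(model_id == "omega1"))

    four = ("S1", "systole", "S2", "diastole")
    base_means = {"S1": S1_DUR, "systole": sys_share, "S2": S2_DUR,
                  "diastole": dia_share}
    omega1 = _model("omega1", four, dict(base_means),
                    {s: s for s in four})
    omega2 = _model("omega2", four, dict(base_means),
                    {"S1": "S1", "systole": "murmur", "S2": "S2",
                     "diastole": "diastole"})
    omega3 = _model(
        "omega3", ("S1", "murmur", "systole", "S2", "diastole"),
        {"S1": S1_DUR, "murmur": sys_share / 2, "systole": sys_share / 2,
         "S2": S2_DUR, "diastole": dia_share},
        {"S1": "S1", "murmur": "murmur", "systole": "systole", "S2": "S2",
         "diastole": "diastole"})
    omega4 = _model(
        "omega4", ("S1", "sysA", "murmur", "sysB", "S2", "diastole"),
        {"S1": S1_DUR, "sysA": sys_share / 4, "murmur": sys_share / 2,
         "sysB": sys_share / 4, "S2": S2_DUR, "diastole": dia_share},
        {"S1": "S1", "sysA": "systole", "murmur": "murmur", "sysB": "systole",
         "S2": "S2", "diastole": "diastole"})
    return [omega1, omega2, omega3, omega4]


def duration_support(mean: float, sd: float, frame_step: float) -> tuple[int, int]:
    """Frame-count support [dmin, dmax]: mean +/- 3 sd, clipped to >= 1 frame."""
    dmin = max(1, int(np.ceil((mean - DUR_TRUNC_SD * sd) / frame_step - 1e-9)))
    dmax = max(dmin, int(np.floor((mean + DUR_TRUNC_SD * sd) / frame_step + 1e-9)))
    return dmin, dmax


def _log_dur_pdf(d_frames: np.ndarray, mean: float, sd: float,
                 frame_step: float) -> np.ndarray:
    x = d_frames * frame_step
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))


def viterbi_duration(probs: np.ndarray, model: HsmmModel,
                     frame_step: float = FRAME_STEP) -> SegmentationResult:
    """Maximum-score segmentation under explicit Gaussian state durations.

    Score = sum_t log obs(state_t at t) + sum over interior segments of
    log N(duration; mean, sd).  The first and last segments are treated as
    partial (the recording starts and ends at an arbitrary cycle phase):
    they carry observation cost but no duration penalty, and are only
    capped at the state's maximum duration.  Transitions follow the model's
    cycle; no other transition can appear in the output.
    """
    obs = model.observations(probs)
    T, S = obs.shape
    logobs = np.log(np.maximum(obs, OBS_FLOOR))
    # cobs[s][t] = sum of logobs[0:t, s]
    cobs = np.concatenate([np.zeros((1, S)), np.cumsum(logobs, axis=0)], axis=0)

    supports = [duration_support(model.duration_mean[s], model.duration_sd[s],
                                 frame_step) for s in model.state_list]
    logdur = []
    for (dmin, dmax), s in zip(supports, model.state_list):
        ds = np.arange(dmin, dmax + 1)
        logdur.append(_log_dur_pdf(ds, model.duration_mean[s],
                                   model.duration_sd[s], frame_step))

    NEG = -np.inf
    delta = np.full((T, S), NEG)
    bp_len = np.zeros((T, S), dtype=np.int64)  # 0 marks an entry (partial) segment

    prev = [model.prev_state(s) for s in range(S)]
    for t in range(T):
        for s in range(S):
            dmin, dmax = supports[s]
            best, best_d = NEG, 0
            if t + 1 <= dmax:  # partial first segment covering 0..t
                best = cobs[t + 1, s]
            d_hi = min(dmax, t)
            if d_hi >= dmin:
                ds = np.arange(dmin, d_hi + 1)
                vals = (delta[t - ds, prev[s]]
                        + cobs[t + 1, s] - cobs[t - ds + 1, s]
                        + logdur[s][ds - dmin])
                k = int(np.argmax(vals))
                if vals[k] > best:
                    best, best_d = float(vals[k]), int(ds[k])
            delta[t, s] = best
            bp_len[t, s] = best_d

    # close with a partial last segment (or a single segment covering all)
    best_score, best_s, best_L = NEG, -1, 0
    for s in range(S):
        dmin, dmax = supports[s]
        if T <= dmax and cobs[T, s] > best_score:  # single-segment path
            best_score, best_s, best_L = float(cobs[T, s]), s, T
        L_hi = min(dmax, T - 1)
        if L_hi >= 1:
            Ls = np.arange(1, L_hi + 1)
            vals = delta[T - 1 - Ls, prev[s]] + cobs[T, s] - cobs[T - Ls, s]
            k = int(np.argmax(vals))
            if vals[k] > best_score:
                best_score, best_s, best_L = float(vals[k]), s, int(Ls[k])
    if not np.isfinite(best_score):
        raise ValueError("infeasible decoding: recording shorter than any valid path")

    path = np.empty(T, dtype=np.int64)
    t, s, L = T - 1, best_s, best_L
    path[t - L + 1: t + 1] = s
    t -= L
    if L < T:
        s = prev[s]
        while t >= 0:
            d = int(bp_len[t, s])
            if d == 0:  # entry segment covers 0..t
                path[: t + 1] = s
                break
            path[t - d + 1: t + 1] = s
            t -= d
            s = prev[s]

    return SegmentationResult(model_id=model.model_id, path=path, score=best_score)


def confidence(path: np.ndarray, probs: np.ndarray, model: HsmmModel) -> float:
    """Mean posterior mass along the decoded path (each decode state reads
    its own observation column; omega1 reads the renormalised 4-state rows)."""
    obs = model.observations(probs)
    return float(np.mean(obs[np.arange(len(path)), path]))


def decide(probs: np.ndarray, hr: HeartRateEstimate,
           frame_step: float = FRAME_STEP):
    """Decode all four models and pick the most confident interpretation.

    Returns ``(ParallelDecision, {model_id: (HsmmModel, SegmentationResult)})``.
    Ties in the argmax go to the lowest model index.
    """
    bank = build_model_bank(hr)
    results: dict[str, tuple[HsmmModel, SegmentationResult]] = {}
    confs: dict[str, float] = {}
    for model in bank:
        seg = viterbi_duration(probs, model, frame_step)
        seg.confidence = confidence(seg.path, probs, model)
        results[model.model_id] = (model, seg)
        confs[model.model_id] = seg.confidence
    chosen = max(MODEL_IDS, key=lambda m: (confs[m], -MODEL_IDS.index(m)))
    c_m = max(confs[m] for m in MURMUR_MODELS)
    c_n = confs["omega1"]
    decision = ParallelDecision(
        chosen=chosen,
        c_murmur=c_m,
        c_normal=c_n,
        c_mn=c_m - c_n,
        quality=confs[chosen],
        murmur_timing=MODEL_TIMING[chosen],
        confidences=dict(confs),
    )
    return decision, results
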