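"""Frame-level ground-truth labels over the five heart-sound states.

Interval annotations (S1 / systole / S2 / diastole, optionally with murmur
already localised) are rasterised onto the 20 ms frame grid; systolic murmur
locations that are only known through a clinician's timing label
(early-systolic, mid-systolic, holosystolic) are expanded into murmur frames
inside each systolic run.  Diastolic murmurs are not representable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import FRAME_LEN, FRAME_STEP
from .io_formats import STATE_ORDER, SegmentInterval

logger = logging.getLogger(__name__)

MURMUR_TIMINGS = ("early-systolic", "mid-systolic", "holosystolic", "none")


@dataclass
class FrameLabels:
    """Length-T state sequence aligned to a :class:`SpectroFrames` matrix."""

    states: np.ndarray  # (T,) int indices into STATE_ORDER
    frame_step: float = FRAME_STEP

    def __len__(self) -> int:
        return len(self.states)

    def names(self) -> list[str]:
        return [STATE_ORDER[i] for i in self.states]


def intervals_to_frames(intervals: list[SegmentInterval], T: int) -> FrameLabels:
    """Label frame ``t`` with the state of the interval containing its centre.

    The centre of frame t is ``t*step + win/2``.  A frame centre falling
    outside every interval takes the nearest interval's state (with a
    warning); this happens at recording edges where the annotation stops
    short of the audio.
    """
    if not intervals:
        raise ValueError("no intervals to rasterise")
    starts = np.array([iv.start for iv in intervals])
    ends = np.array([iv.end for iv in intervals])
    state_idx = np.array([STATE_ORDER.index(iv.state) for iv in intervals])
    centres = np.arange(T) * FRAME_STEP + FRAME_LEN / 2.0
    labels = np.empty(T, dtype=np.int64)
    n_outside = 0
    for t, c in enumerate(centres):
        inside = np.flatnonzero((starts <= c) & (c < ends))
        if inside.size:
            labels[t] = state_idx[inside[0]]
        else:
            n_outside += 1
            dist = np.minimum(np.abs(starts - c), np.abs(ends - c))
            labels[t] = state_idx[int(np.argmin(dist))]
    if n_outside:
        logger.warning("%d frame centres fell outside all intervals; "
                       "labelled with nearest interval", n_outside)
    return FrameLabels(states=labels)


def _systolic_periods(states: np.ndarray):
    """Yield (start, length) of maximal runs of systole-or-murmur frames.

    Murmur frames only ever live inside systole, so a contiguous block of
    either state is one systolic period; finding periods this way makes the
    murmur expansion idempotent.
    """
    sys_idx = STATE_ORDER.index("systole")
    mur_idx = STATE_ORDER.index("murmur")
    t = 0
    T = len(states)
    while t < T:
        if states[t] in (sys_idx, mur_idx):
            start = t
            while t < T and states[t] in (sys_idx, mur_idx):
                t += 1
            yield start, t - start
        else:
            t += 1


def expand_murmur(labels: FrameLabels, timing: str) -> FrameLabels:
    """Mark part of each systolic period as murmur frames per the timing label.

    With a period of L frames: early-systolic puts the murmur in the first
    ceil(L/2) frames, mid-systolic in the middle ceil(L/2) (starting at
    offset floor(L/4)), holosystolic in all L; "none" leaves the labels
    unchanged.  S1, S2 and diastole frames are never touched, and the
    operation is idempotent.
    """
    if timing not in MURMUR_TIMINGS:
        raise ValueError(f"unknown murmur timing {timing!r}")
    states = labels.states.copy()
    if timing == "none":
        return FrameLabels(states=states, frame_step=labels.frame_step)
    sys_idx = STATE_ORDER.index("systole")
    mur_idx = STATE_ORDER.index("murmur")
    for start, L in _systolic_periods(states):
        half = -(-L // 2)  # ceil(L/2)
        if timing == "holosystolic":
            lo, hi = start, start + L
        elif timing == "early-systolic":
            lo, hi = start, start + half
        else:  # mid-systolic
            lo = start + L // 4
            hi = lo + half
        states[start:start + L] = sys_idx
        states[lo:hi] = mur_idx
    return FrameLabels(states=states, frame_step=labels.frame_step)
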