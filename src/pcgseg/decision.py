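"""Patient-level murmur classification from per-recording decisions.

A patient typically contributes recordings from several auscultation sites.
If any recording is decided to contain a murmur, the patient is labelled
murmur-present.  Otherwise the segmentation quality of the chosen models is
examined: if the aggregate quality falls below 0.65 the recordings are
deemed too poor to rule a murmur out and the patient is labelled unknown;
otherwise murmur-absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parallel_hsmm import ParallelDecision

#: chosen-model confidence below which a murmur-free patient is "unknown"
QUALITY_THRESHOLD = 0.65


@dataclass
class PatientMurmurResult:
    label: str  # present | unknown | absent
    aggregate_quality: float
    max_c_mn: float
    per_recording: list = field(default_factory=list)
    quality_threshold: float = QUALITY_THRESHOLD


def classify_patient(
    decisions: list[ParallelDecision],
    quality_threshold: float = QUALITY_THRESHOLD,
    aggregate: str = "mean",
) -> PatientMurmurResult:
    """Apply the any-murmur rule, then the signal-quality (unknown) rule.

    ``aggregate`` selects how per-recording qualities are combined for the
    unknown rule: "mean" (default) or "min".
    """
    if not decisions:
        raise ValueError("no recording decisions for patient")
    qualities = np.array([d.quality for d in decisions])
    agg = float(qualities.min() if aggregate == "min" else qualities.mean())
    max_c_mn = float(max(d.c_mn for d in decisions))
    if any(d.murmur_detected for d in decisions):
        label = "present"
    elif agg < quality_threshold:
        label = "unknown"
    else:
        label = "absent"
    return PatientMurmurResult(label=label, aggregate_quality=agg,
                               max_c_mn=max_c_mn, per_recording=list(decisions),
                               quality_threshold=quality_threshold)
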