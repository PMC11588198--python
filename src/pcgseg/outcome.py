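"""Patient-level clinical outcome prediction.

The murmur detector only sees audible signatures, yet many abnormal
patients have silent disease.  A gradient-boosted decision tree therefore
combines the per-site murmur likelihood C(M-N) and signal quality C(omega)
with basic biometrics (age band, pregnancy status, number of recordings) to
predict the normal/abnormal outcome.  Multiple recordings at one site are
averaged; sites that were not auscultated are genuinely missing values and
are left to the tree learner's native missing handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

from .io_formats import SITES, PatientRecord, age_group_ordinal
from .parallel_hsmm import ParallelDecision

#: probability above which the outcome is called abnormal
OUTCOME_THRESHOLD = 0.4738
#: loss weight on abnormal examples (normal = 1), prioritising sensitivity
ABNORMAL_WEIGHT = 1.8
#: boosted-tree depth
TREE_DEPTH = 9

#: nearest standard site for non-standard location tags
_SITE_ALIAS = {"AV": "AV", "PV": "PV", "TV": "TV", "MV": "MV"}

FEATURE_NAMES = (
    [f"c_mn_{s}" for s in SITES]
    + [f"quality_{s}" for s in SITES]
    + ["age_group", "pregnant", "n_recordings"]
)


@dataclass
class OutcomeFeatures:
    """Fixed-length feature vector for one patient (NaN = site not recorded)."""

    values: np.ndarray  # (11,), FEATURE_NAMES order
    patient_id: str = ""


def build_features(patient: PatientRecord,
                   decisions: list[tuple[str, ParallelDecision]]) -> OutcomeFeatures:
    """Per-site averages of C(M-N) and quality plus biometrics.

    ``decisions`` pairs each recording's site with its ParallelDecision.
    Recordings from unrecognised sites are pooled into the mitral position
    (the commonest paediatric listening post) with a warning.
    """
    if not decisions:
        raise ValueError("no recording decisions for patient")
    import logging

    per_site: dict[str, list[ParallelDecision]] = {s: [] for s in SITES}
    for site, dec in decisions:
        key = _SITE_ALIAS.get(site)
        if key is None:
            logging.getLogger(__name__).warning(
                "unrecognised site %r pooled into MV", site)
            key = "MV"
        per_site[key].append(dec)
    c_mn = [np.mean([d.c_mn for d in per_site[s]]) if per_site[s] else np.nan
            for s in SITES]
    qual = [np.mean([d.quality for d in per_site[s]]) if per_site[s] else np.nan
            for s in SITES]
    vec = np.array(
        c_mn + qual
        + [age_group_ordinal(patient.age_group), float(patient.pregnant),
           float(len(decisions))],
        dtype=np.float64,
    )
    return OutcomeFeatures(values=vec, patient_id=patient.patient_id)


def train_outcome(
    features: list[OutcomeFeatures],
    labels: list[str],
    seed: int = 0,
    n_estimators: int = 200,
    learning_rate: float = 0.1,
    abnormal_weight: float = ABNORMAL_WEIGHT,
    depth: int = TREE_DEPTH,
) -> LGBMClassifier:
    """Fit the boosted-tree outcome classifier (depth 9, abnormal weight 1.8)."""
    X = np.stack([f.values for f in features])
    y = np.array([1 if l == "abnormal" else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required for training")
    clf = LGBMClassifier(
        objective="binary",
        max_depth=depth,
        num_leaves=63,
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        class_weight={0: 1.0, 1: abnormal_weight},
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        verbosity=-1,
    )
    clf.fit(X, y, feature_name=list(FEATURE_NAMES))
    return clf


def predict_outcome(clf: LGBMClassifier, features: OutcomeFeatures,
                    threshold: float = OUTCOME_THRESHOLD) -> dict:
    """Abnormal-outcome probability and thresholded label for one patient."""
    X = pd.DataFrame(features.values[None, :], columns=list(FEATURE_NAMES))
    p = float(clf.predict_proba(X)[0, 1])
    return {
        "patient_id": features.patient_id,
        "probability": p,
        "label": "abnormal" if p >= threshold else "normal",
    }
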