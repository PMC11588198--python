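"""Seeded synthetic phonocardiograms and patient cohorts.

The generator emulates the signal structure the pipeline assumes: periodic
S1 (~100 ms) and S2 (~80 ms) transient bursts of low-frequency tonal energy,
optional systolic murmurs as band-limited (100-400 Hz) noise occupying the
first half, middle half, or whole of systole, paediatric heart rates up to
180 bpm with per-cycle jitter, additive broadband noise, and patient
encounters with up to four auscultation sites.  Exact ground-truth intervals
accompany every waveform, so every pipeline stage can be trained and scored
without any external data.

It does not attempt physiological detail: no S3/S4 sounds, no diastolic
murmurs, no respiratory modulation, no device coloration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .io_formats import (
    SITES,
    AGE_GROUPS,
    PatientRecord,
    PcgRecording,
    SegmentInterval,
    write_patient_metadata,
    write_recording,
    write_segmentation,
)

#: murmur loudness tiers (dB of murmur RMS relative to S1 burst RMS)
GRADE_SNR_DB = {"quiet": -12.0, "moderate": -6.0, "loud": 0.0}

_TIMING_SHORT = {"early-systolic": "early", "mid-systolic": "mid", "holosystolic": "holo"}
_TIMING_LONG = {v: k for k, v in _TIMING_SHORT.items()}


@dataclass
class SimConfig:
    """Parameters of one synthetic recording.

    ``murmur`` is one of none/holo/early/mid; ``murmur_snr_db`` sets the
    murmur RMS relative to the S1 burst RMS; ``noise_snr_db`` the overall
    signal-to-broadband-noise ratio.
    """

    fs: int = 4000
    heart_rate_bpm: float = 90.0
    s1_dur: float = 0.10
    s2_dur: float = 0.08
    systole_frac: float = 0.30
    murmur: str = "none"
    murmur_snr_db: float = -6.0
    noise_snr_db: float = 20.0
    duration_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0.2 < self.systole_frac < 0.5:
            raise ValueError("systole_frac must lie in (0.2, 0.5)")
        if self.murmur not in ("none", "holo", "early", "mid"):
            raise ValueError(f"unknown murmur kind {self.murmur!r}")


@dataclass
class SimPatient:
    """A synthetic patient encounter: metadata plus per-site recordings."""

    patient_id: str
    age_group: str
    pregnant: bool
    murmur_label: str  # present | absent | unknown
    murmur_timing: str  # long form, or "none"
    murmur_grade: str  # quiet | moderate | loud | none
    outcome: str  # normal | abnormal
    heart_rate_bpm: float
    recordings: list = field(default_factory=list)  # (PcgRecording, intervals, site)

    def to_patient_record(self) -> PatientRecord:
        return PatientRecord(
            patient_id=self.patient_id,
            age_group=self.age_group,
            pregnant=self.pregnant,
            murmur_label=self.murmur_label,
            murmur_timing=self.murmur_timing,
            outcome=self.outcome,
            recordings=[rec.recording_id for rec, _, _ in self.recordings],
        )


def _gauss_burst(n: int, fs: int, freq: float, phase: float) -> np.ndarray:
    """Gaussian-windowed tone burst of n samples."""
    t = np.arange(n) / fs
    centre = (n - 1) / (2 * fs)
    sd = n / fs / 6.0
    window = np.exp(-0.5 * ((t - centre) / sd) ** 2)
    return np.sin(2 * np.pi * freq * t + phase) * window


def _murmur_window(lo_i: int, hi_i: int, band_noise: np.ndarray) -> np.ndarray:
    """Slice of pre-filtered band noise with a 10% cosine taper at both ends."""
    seg = band_noise[lo_i:hi_i].copy()
    n = len(seg)
    ramp = max(2, n // 10)
    taper = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    seg[:ramp] *= taper
    seg[-ramp:] *= taper[::-1]
    return seg


def simulate_pcg(cfg: SimConfig) -> tuple[PcgRecording, list[SegmentInterval]]:
    """Synthesise one recording with its exact ground-truth intervals.

    Cycle lengths are jittered by +/-5% around 60/bpm.  Ground truth follows
    the cyclic order S1 -> systole -> S2 -> diastole, with the murmur portion
    of systole labelled as murmur when a murmur is present.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n_total = round(cfg.duration_s * fs)
    period = 60.0 / cfg.heart_rate_bpm
    sys_dur = cfg.systole_frac * period
    dia_dur = period - cfg.s1_dur - sys_dur - cfg.s2_dur
    if dia_dur <= 0.02:
        raise ValueError("infeasible durations: diastole would be non-positive")

    f_s1 = rng.uniform(60.0, 120.0)
    f_s2 = rng.uniform(100.0, 200.0)
    s1_n = round(cfg.s1_dur * fs)
    ref_rms = float(np.sqrt(np.mean(_gauss_burst(s1_n, fs, f_s1, 0.0) ** 2)))

    # one long band-limited noise track, sliced per murmur window
    band_noise = np.array([])
    if cfg.murmur != "none":
        sos = butter(4, [100.0, 400.0], btype="bandpass", fs=fs, output="sos")
        raw = rng.standard_normal(n_total + fs)
        band_noise = sosfiltfilt(sos, raw)
        band_noise *= (ref_rms * 10 ** (cfg.murmur_snr_db / 20.0)) / np.sqrt(
            np.mean(band_noise**2)
        )

    x = np.zeros(n_total + round(2 * period * fs))
    intervals: list[SegmentInterval] = []
    t = 0.0
    while t < cfg.duration_s:
        jitter = 1.0 + rng.uniform(-0.05, 0.05)
        p = period * jitter
        s_dur = cfg.systole_frac * p
        d_dur = p - cfg.s1_dur - s_dur - cfg.s2_dur

        # S1
        i0 = round(t * fs)
        amp = rng.uniform(0.85, 1.15)
        x[i0:i0 + s1_n] += amp * _gauss_burst(s1_n, fs, f_s1, rng.uniform(0, 2 * np.pi))
        intervals.append(SegmentInterval(t, t + cfg.s1_dur, "S1"))
        t_sys = t + cfg.s1_dur

        # systole, possibly with a murmur portion
        sys_end = t_sys + s_dur
        if cfg.murmur == "none":
            intervals.append(SegmentInterval(t_sys, sys_end, "systole"))
        else:
            if cfg.murmur == "holo":
                m_lo, m_hi = t_sys, sys_end
            elif cfg.murmur == "early":
                m_lo, m_hi = t_sys, t_sys + s_dur / 2
            else:  # mid
                m_lo, m_hi = t_sys + s_dur / 4, t_sys + 3 * s_dur / 4
            if m_lo > t_sys:
                intervals.append(SegmentInterval(t_sys, m_lo, "systole"))
            intervals.append(SegmentInterval(m_lo, m_hi, "murmur"))
            if m_hi < sys_end:
                intervals.append(SegmentInterval(m_hi, sys_end, "systole"))
            lo_i, hi_i = round(m_lo * fs), round(m_hi * fs)
            x[lo_i:hi_i] += _murmur_window(lo_i, hi_i, band_noise) if hi_i <= len(
                band_noise
            ) else 0.0

        # S2
        s2_n = round(cfg.s2_dur * fs)
        i2 = round(sys_end * fs)
        amp2 = 0.7 * rng.uniform(0.85, 1.15)
        x[i2:i2 + s2_n] += amp2 * _gauss_burst(s2_n, fs, f_s2, rng.uniform(0, 2 * np.pi))
        intervals.append(SegmentInterval(sys_end, sys_end + cfg.s2_dur, "S2"))

        # diastole
        dia_end = sys_end + cfg.s2_dur + d_dur
        intervals.append(SegmentInterval(sys_end + cfg.s2_dur, dia_end, "diastole"))
        t = dia_end

    x = x[:n_total]
    sig_rms = np.sqrt(np.mean(x**2))
    noise = rng.standard_normal(n_total)
    x = x + noise * sig_rms * 10 ** (-cfg.noise_snr_db / 20.0)
    x = x / np.max(np.abs(x))

    clipped = []
    for iv in intervals:
        if iv.start >= cfg.duration_s - 1e-12:
            break
        end = min(iv.end, cfg.duration_s)
        if end - iv.start > 1e-9:
            clipped.append(SegmentInterval(iv.start, end, iv.state))
    rec = PcgRecording(samples=x, fs=fs, recording_id=f"sim{cfg.seed:06d}")
    return rec, clipped


def simulate_recordings(
    n: int,
    seed: int,
    murmur_frac: float = 0.5,
    heart_rate_range: tuple[float, float] = (60.0, 180.0),
    duration_s: float = 10.0,
    noise_snr_db: float = 20.0,
):
    """A labelled set of independent recordings for training the frame classifier.

    Returns a list of ``(PcgRecording, intervals, timing, grade)`` where
    ``timing`` is the long-form murmur timing ("none" for normal recordings).
    Murmur timing is uniform over early/mid/holo and grade uniform over the
    loudness tiers.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        has_murmur = rng.random() < murmur_frac
        kind = rng.choice(["early", "mid", "holo"]) if has_murmur else "none"
        grade = rng.choice(list(GRADE_SNR_DB)) if has_murmur else "none"
        cfg = SimConfig(
            heart_rate_bpm=float(rng.uniform(*heart_rate_range)),
            murmur=kind,
            murmur_snr_db=GRADE_SNR_DB.get(grade, -6.0),
            noise_snr_db=noise_snr_db,
            duration_s=duration_s,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, intervals = simulate_pcg(cfg)
        rec = replace(rec, recording_id=f"rec{i:05d}")
        timing = _TIMING_LONG.get(kind, "none")
        out.append((rec, intervals, timing, grade))
    return out


def simulate_cohort(
    n_patients: int,
    murmur_prevalence: float = 0.3,
    outcome_model_params: tuple[float, float, float] = (-1.2, 2.0, 0.5),
    seed: int = 0,
    out_dir=None,
    unknown_frac: float = 0.05,
    duration_s: float = 10.0,
) -> list[SimPatient]:
    """Generate a patient cohort with 1-4 auscultation sites per patient.

    Murmur-positive patients share one timing across their murmur-positive
    sites.  The clinical outcome is drawn with probability
    ``sigmoid(b0 + b1*has_murmur + b2*grade_tier)`` so that a fraction of
    abnormal patients have no audible murmur.  ``unknown_frac`` of patients
    get heavily noise-corrupted recordings and the "unknown" murmur label.
    If ``out_dir`` is given, WAV/TSV/metadata files plus a manifest CSV are
    written in the formats the io module reads.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if not 0.0 < murmur_prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    rng = np.random.default_rng(seed)
    b0, b1, b2 = outcome_model_params
    grades = list(GRADE_SNR_DB)
    patients: list[SimPatient] = []
    for i in range(n_patients):
        pid = f"P{i:04d}"
        age_group = str(rng.choice(AGE_GROUPS, p=[0.05, 0.15, 0.45, 0.25, 0.10]))
        pregnant = bool(
            age_group in ("adolescent", "young adult") and rng.random() < 0.15
        )
        is_unknown = rng.random() < unknown_frac
        has_murmur = (not is_unknown) and rng.random() < murmur_prevalence
        grade_tier = int(rng.integers(0, 3)) if has_murmur else 0
        timing_short = str(rng.choice(["early", "mid", "holo"])) if has_murmur else "none"
        logit = b0 + b1 * float(has_murmur) + b2 * grade_tier
        abnormal = rng.random() < 1.0 / (1.0 + np.exp(-logit))

        hr = float(rng.uniform(60.0, 180.0))
        n_sites = int(rng.integers(1, 5))
        sites = list(rng.choice(SITES, size=n_sites, replace=False))
        recordings = []
        for site in sites:
            # murmur audible at most, not necessarily all, sites
            site_murmur = has_murmur and (rng.random() < 0.8 or len(sites) == 1)
            if has_murmur and site == sites[-1] and not any(
                m for _, _, _, m in recordings
            ):
                site_murmur = True
            cfg = SimConfig(
                heart_rate_bpm=float(np.clip(hr + rng.uniform(-5, 5), 55.0, 185.0)),
                murmur=timing_short if site_murmur else "none",
                murmur_snr_db=GRADE_SNR_DB[grades[grade_tier]] if site_murmur else -6.0,
                noise_snr_db=float(rng.uniform(-3.0, 2.0)) if is_unknown
                else float(rng.uniform(15.0, 25.0)),
                duration_s=duration_s,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec, intervals = simulate_pcg(cfg)
            rec = replace(rec, recording_id=f"{pid}_{site}", site=site)
            recordings.append((rec, intervals, site, site_murmur))

        patients.append(
            SimPatient(
                patient_id=pid,
                age_group=age_group,
                pregnant=pregnant,
                murmur_label="unknown" if is_unknown
                else ("present" if has_murmur else "absent"),
                murmur_timing=_TIMING_LONG.get(timing_short, "none"),
                murmur_grade=grades[grade_tier] if has_murmur else "none",
                outcome="abnormal" if abnormal else "normal",
                heart_rate_bpm=hr,
                recordings=[(r, iv, s) for r, iv, s, _ in recordings],
            )
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for pat in patients:
            write_patient_metadata(out_dir / f"{pat.patient_id}.txt",
                                   pat.to_patient_record())
            for rec, intervals, site in pat.recordings:
                write_recording(out_dir / f"{rec.recording_id}.wav", rec)
                write_segmentation(out_dir / f"{rec.recording_id}.tsv", intervals)
                rows.append({
                    "patient_id": pat.patient_id, "recording_id": rec.recording_id,
                    "site": site, "murmur_label": pat.murmur_label,
                    "murmur_timing": pat.murmur_timing, "outcome": pat.outcome,
                })
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return patients


def simulate_decision_cohort(
    n_patients: int,
    seed: int = 0,
    murmur_prevalence: float = 0.3,
    outcome_coefs: tuple[float, float] = (-1.0, 20.0),
):
    """Feature-level cohort for the outcome classifier: per-recording murmur
    likelihoods and qualities drawn directly, with outcome logistic in the
    patient's best murmur likelihood.  The default coefficients plant a
    strong but noisy relationship (the probability-optimal classifier scores
    about 0.92 AUROC on it).

    Murmur-positive recordings draw C(M-N) ~ N(0.15, 0.08); normal ones
    N(-0.10, 0.06); quality ~ Beta(8, 2).  Returns a list of dicts with keys
    patient_id, age_group, pregnant, outcome and decisions (list of
    (site, c_mn, quality)).
    """
    from .parallel_hsmm import ParallelDecision

    rng = np.random.default_rng(seed)
    a, b = outcome_coefs
    cohort = []
    for i in range(n_patients):
        has_murmur = rng.random() < murmur_prevalence
        n_sites = int(rng.integers(1, 5))
        sites = list(rng.choice(SITES, size=n_sites, replace=False))
        decisions = []
        for site in sites:
            if has_murmur:
                c_mn = float(rng.normal(0.15, 0.08))
            else:
                c_mn = float(rng.normal(-0.10, 0.06))
            quality = float(rng.beta(8, 2))
            chosen = "omega2" if c_mn > 0 else "omega1"
            decisions.append(
                (site, ParallelDecision(
                    chosen=chosen, c_murmur=max(quality + c_mn, 0.0),
                    c_normal=quality, c_mn=c_mn, quality=quality,
                    murmur_timing="holosystolic" if c_mn > 0 else "none"))
            )
        max_cmn = max(d.c_mn for _, d in decisions)
        p_abn = 1.0 / (1.0 + np.exp(-(a + b * max_cmn)))
        cohort.append({
            "patient_id": f"D{i:05d}",
            "age_group": str(rng.choice(AGE_GROUPS)),
            "pregnant": bool(rng.random() < 0.05),
            "outcome": "abnormal" if rng.random() < p_abn else "normal",
            "decisions": decisions,
        })
    return cohort
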