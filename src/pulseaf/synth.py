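"""Synthetic PPG generator for AF and NSR rhythms.

Emulates the statistical structure that separates atrial fibrillation from
normal sinus rhythm in a pulse waveform: AF produces irregularly irregular
inter-beat intervals (high interval CV, no serial correlation) with variable
beat amplitudes, while NSR intervals are quasi-regular and serially
correlated (respiratory sinus arrhythmia).  Each beat is a two-lobe pulse —
a systolic Gaussian peak plus a smaller dicrotic lobe — placed at cumulative
inter-beat intervals, on top of sinusoidal baseline wander and white
measurement noise.

This is a phenomenological simulator, not a hemodynamic model: it reproduces
interval statistics and gross pulse morphology only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .records import PPGRecord, write_record_csv

# Lower physiological bound on an inter-beat interval (200 bpm ceiling).
MIN_IBI_S = 0.3


@dataclass(frozen=True)
class RhythmParams:
    """Parameters of the beat-interval and amplitude model for one rhythm.

    ``ibi_cv`` is the coefficient of variation of inter-beat intervals and
    ``ibi_serial_corr`` their lag-1 autocorrelation; both are the statistics
    an interval-irregularity AF detector keys on.  Amplitude terms are
    fractions of the unit pulse amplitude.
    """

    rhythm_label: str
    mean_ibi_s: float
    ibi_cv: float
    ibi_serial_corr: float = 0.0
    amp_cv: float = 0.05
    baseline_wander_amp: float = 0.1
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.rhythm_label not in ("AF", "NSR"):
            raise ValueError("rhythm_label must be 'AF' or 'NSR'")
        if self.mean_ibi_s <= 0:
            raise ValueError("mean_ibi_s must be positive")
        if self.ibi_cv < 0 or self.amp_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        for name in ("baseline_wander_amp", "noise_sd"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0")


# Presets: AF interval CV is 5x the NSR CV (irregularly irregular), with no
# serial correlation and stronger beat-to-beat amplitude variability.
NSR_PRESET = RhythmParams(
    rhythm_label="NSR", mean_ibi_s=0.8, ibi_cv=0.04, ibi_serial_corr=0.6, amp_cv=0.05
)
AF_PRESET = RhythmParams(
    rhythm_label="AF", mean_ibi_s=0.65, ibi_cv=0.20, ibi_serial_corr=0.0, amp_cv=0.20
)

PRESETS = {"NSR": NSR_PRESET, "AF": AF_PRESET}


def _draw_intervals(params: RhythmParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """AR(1) Gaussian intervals with the stated mean, CV and lag-1 correlation,
    truncated below at MIN_IBI_S."""
    rho = params.ibi_serial_corr
    z = np.empty(n)
    eps = rng.standard_normal(n)
    z[0] = eps[0]
    scale = np.sqrt(max(1.0 - rho * rho, 0.0))
    for k in range(1, n):
        z[k] = rho * z[k - 1] + scale * eps[k]
    ibis = params.mean_ibi_s * (1.0 + params.ibi_cv * z)
    return np.maximum(ibis, MIN_IBI_S)


def _add_pulses(
    samples: np.ndarray,
    fs_hz: float,
    beat_times: np.ndarray,
    ibis: np.ndarray,
    amps: np.ndarray,
) -> None:
    """Superimpose two-lobe pulse templates in place.

    Systolic lobe: Gaussian at the beat time, sigma 0.06*IBI.  Dicrotic lobe:
    Gaussian at +0.25*IBI with 30% amplitude and sigma 0.09*IBI.
    """
    n = samples.size
    t = np.arange(n) / fs_hz
    for bt, ibi, amp in zip(beat_times, ibis, amps):
        sig_s = 0.06 * ibi
        sig_d = 0.09 * ibi
        lo = max(int((bt - 0.5 * ibi) * fs_hz), 0)
        hi = min(int((bt + 1.0 * ibi) * fs_hz) + 1, n)
        if lo >= hi:
            continue
        tt = t[lo:hi]
        samples[lo:hi] += amp * (
            np.exp(-0.5 * ((tt - bt) / sig_s) ** 2)
            + 0.3 * np.exp(-0.5 * ((tt - bt - 0.25 * ibi) / sig_d) ** 2)
        )


def generate_record(
    params: RhythmParams,
    duration_s: float = 120.0,
    fs_hz: float = 125.0,
    seed: int = 0,
    record_id: str = "",
) -> PPGRecord:
    """Generate one labeled synthetic PPG record, deterministic given ``seed``.

    The first beat lands at t=0, so the waveform starts at (near) a systolic
    peak, matching the peak-anchored segmentation convention downstream.
    """
    if duration_s < 10:
        raise ValueError(f"duration_s must be >= 10, got {duration_s}")
    if fs_hz < 25:
        raise ValueError(f"fs_hz must be >= 25, got {fs_hz}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))

    n_beats_max = int(np.ceil(duration_s / MIN_IBI_S)) + 2
    ibis = _draw_intervals(params, n_beats_max, rng)
    beat_times = np.concatenate([[0.0], np.cumsum(ibis)])[:-1]
    keep = beat_times < duration_s
    beat_times, ibis = beat_times[keep], ibis[keep]

    amps = 1.0 + params.amp_cv * rng.standard_normal(beat_times.size)
    amps = np.maximum(amps, 0.1)

    samples = np.zeros(n)
    _add_pulses(samples, fs_hz, beat_times, ibis, amps)

    t = np.arange(n) / fs_hz
    phase = rng.uniform(0, 2 * np.pi)
    samples += params.baseline_wander_amp * np.sin(2 * np.pi * 0.1 * t + phase)
    samples += params.noise_sd * rng.standard_normal(n)

    if not record_id:
        record_id = f"{params.rhythm_label.lower()}-{seed}"
    return PPGRecord(
        samples=samples,
        fs_hz=fs_hz,
        rhythm_label=params.rhythm_label,
        record_id=record_id,
        seed=seed,
    )


def generate_dataset(
    n_af: int,
    n_nsr: int,
    duration_s: float = 120.0,
    fs_hz: float = 125.0,
    seed: int = 0,
    split: bool = False,
    train_frac: float = 2.0 / 3.0,
    af_params: RhythmParams = AF_PRESET,
    nsr_params: RhythmParams = NSR_PRESET,
) -> tuple[list[PPGRecord], pd.DataFrame]:
    """Generate a labeled cohort of AF and NSR records plus its manifest.

    Per-record seeds are derived deterministically from the master seed.  With
    ``split=True`` each class is partitioned into train/test at ``train_frac``
    (default two thirds), preserving label proportions within rounding.
    """
    if n_af < 0 or n_nsr < 0:
        raise ValueError("record counts must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[PPGRecord] = []
    rows: list[dict] = []
    for label, n_cls, params in (("AF", n_af, af_params), ("NSR", n_nsr, nsr_params)):
        n_train = int(round(n_cls * train_frac))
        for k in range(n_cls):
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec_id = f"{label.lower()}-{k:04d}"
            rec = generate_record(params, duration_s, fs_hz, seed=rec_seed, record_id=rec_id)
            records.append(rec)
            rows.append(
                {
                    "record_id": rec_id,
                    "label": label,
                    "split": ("train" if k < n_train else "test") if split else "all",
                    "seed": rec_seed,
                }
            )
    manifest = pd.DataFrame(rows, columns=["record_id", "label", "split", "seed"])
    return records, manifest


def write_dataset(
    records: list[PPGRecord], manifest: pd.DataFrame, out_dir: str | os.PathLike
) -> None:
    """Write per-record CSVs and the manifest under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    rec_dir = os.path.join(out_dir, "records")
    os.makedirs(rec_dir, exist_ok=True)
    for rec in records:
        write_record_csv(rec, os.path.join(rec_dir, f"{rec.record_id}.csv"))
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
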