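"""Power-normalized Gammatone features (CEPNCC) plus time-domain pulse features.

The frequency-domain chain, applied per record:

1. CEEMD the normalized segment and keep the IMFs coherent with the signal.
2. Framed Hann-windowed periodogram of each selected IMF; per-frame spectra
   of the selected IMFs are summed (cross-term-free total power).
3. Gammatone filterbank energies: inner product of each frame spectrum with
   nonnegative spectral weights derived from the order-4 Gammatone impulse
   response t^(n-1) e^(-2 pi w t) cos(2 pi f0 t + phi), log-spaced centers
   over the PPG band.
4. Power normalization: divide by the mean band power of the record, so the
   features are invariant to the overall signal scale.
5. Power-law compression U^theta with 0 < theta < 1 (default 1/15).

Time-domain features are inter-beat-interval statistics computed from
detected peaks — the interval-irregularity signature of AF — appended per
record and broadcast across frames at the network input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.fft import rfft, dct
from scipy.signal.windows import hann

from .records import PPGRecord
from .preprocess import detect_peaks
from .decompose import EmdConfig, EnsembleConfig, ceemd, eemd, select_imfs

logger = logging.getLogger(__name__)

#: Order of the time-domain feature vector.
TIME_FEATURE_NAMES = (
    "ibi_mean_s",
    "ibi_sd_s",
    "rmssd_s",
    "frac_succ_diff_gt_50ms",
    "ibi_entropy_bits",
    "peak_amp_cv",
)


class MissingFeatureError(ValueError):
    """Too few detected beats to compute interval statistics."""


@dataclass(frozen=True)
class FeatureConfig:
    n_filters: int = 32
    f_lo_hz: float = 0.1
    f_hi_hz: float = 20.0
    frame_len_s: float = 4.0
    frame_hop_s: float = 2.0
    power_law_theta: float = 1.0 / 15.0
    include_dct: bool = False
    filter_order: int = 4
    combine: str = "sum"  # "sum" (default) or "stack" of per-IMF spectra
    selection_threshold: float = 0.1
    n_timedomain: int = len(TIME_FEATURE_NAMES)

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if not (0 < self.f_lo_hz < self.f_hi_hz):
            raise ValueError("need 0 < f_lo_hz < f_hi_hz")
        if not (0 < self.power_law_theta < 1):
            raise ValueError("power_law_theta must lie in (0, 1)")
        if self.frame_hop_s > self.frame_len_s or self.frame_hop_s <= 0:
            raise ValueError("need 0 < frame_hop_s <= frame_len_s")
        if self.combine not in ("sum", "stack"):
            raise ValueError("combine must be 'sum' or 'stack'")


@dataclass(frozen=True)
class GammatoneFilter:
    """One bandpass filter realized as nonnegative spectral weights over
    the rfft bins, peak-normalized to 1."""

    center_freq_hz: float
    bandwidth_hz: float
    order: int
    weights: np.ndarray


@dataclass
class FeatureMatrix:
    """frames x bands feature values plus the per-record time-domain vector."""

    values: np.ndarray
    time_features: np.ndarray
    record_id: str = ""
    config: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# spectral chain


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Half-open sample windows [k*hop, k*hop + frame_len); frames that would
    overrun the signal are dropped.  A signal shorter than one frame yields a
    single zero-padded frame."""
    n = x.size
    if n < frame_len:
        logger.warning("signal shorter than one frame (%d < %d); zero-padding", n, frame_len)
        out = np.zeros((1, frame_len))
        out[0, :n] = x
        return out
    n_frames = 1 + (n - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def power_spectrum(
    imf: np.ndarray, fs_hz: float, frame_len_s: float = 4.0, frame_hop_s: float = 2.0
) -> np.ndarray:
    """Framed one-sided periodogram with a Hann window.

    Scaled so that the sum over bins of each row equals the windowed frame
    energy sum_t (w[t] x[t])^2 (discrete Parseval identity; interior bins
    of the one-sided spectrum are counted twice).
    """
    x = np.asarray(imf, dtype=float)
    frame_len = int(round(frame_len_s * fs_hz))
    hop = int(round(frame_hop_s * fs_hz))
    if frame_len < 8:
        raise ValueError("frame must cover at least 8 samples")
    frames = frame_signal(x, frame_len, hop)
    w = hann(frame_len, sym=False)
    spec = np.abs(rfft(frames * w, axis=1)) ** 2 / frame_len
    # one-sided doubling: every bin except DC (and Nyquist for even length)
    scale = np.full(spec.shape[1], 2.0)
    scale[0] = 1.0
    if frame_len % 2 == 0:
        scale[-1] = 1.0
    return spec * scale


def spectrum_bin_freqs(fs_hz: float, frame_len_s: float) -> np.ndarray:
    frame_len = int(round(frame_len_s * fs_hz))
    return np.fft.rfftfreq(frame_len, d=1.0 / fs_hz)


def _gammatone_weights(
    f0: float, w: float, order: int, fs_hz: float, n_bins: int
) -> np.ndarray:
    """|FFT| of the Gammatone impulse response sampled at the frame's rfft
    bins, peak-normalized to 1."""
    frame_len = 2 * (n_bins - 1)
    # impulse response long enough for the envelope t^(n-1) e^(-2 pi w t)
    # to decay below 1e-8 of its peak
    t_end = max((order + 18.0) / (2 * np.pi * w), frame_len / fs_hz)
    n_t = int(np.ceil(t_end * fs_hz))
    t = np.arange(1, n_t + 1) / fs_hz
    g = t ** (order - 1) * np.exp(-2 * np.pi * w * t) * np.cos(2 * np.pi * f0 * t)
    spec = np.abs(np.fft.rfft(g))
    freqs = np.fft.rfftfreq(g.size, d=1.0 / fs_hz)
    bin_freqs = np.fft.rfftfreq(frame_len, d=1.0 / fs_hz)
    weights = np.interp(bin_freqs, freqs, spec)
    peak = float(weights.max())
    if peak == 0.0:
        raise ValueError("degenerate Gammatone filter: zero spectral weight")
    return weights / peak


def build_filterbank(
    cfg: FeatureConfig, fs_hz: float, n_bins: int
) -> list[GammatoneFilter]:
    """Order-n Gammatone filters with log-spaced center frequencies on
    [f_lo, f_hi] and bandwidth proportional to center frequency
    (w = f0/4, floored at 0.05 Hz)."""
    if cfg.f_hi_hz > fs_hz / 2:
        raise ValueError(
            f"f_hi_hz={cfg.f_hi_hz} exceeds the Nyquist frequency {fs_hz / 2}"
        )
    centers = np.geomspace(cfg.f_lo_hz, cfg.f_hi_hz, cfg.n_filters)
    bank = []
    for f0 in centers:
        w = max(f0 / 4.0, 0.05)
        weights = _gammatone_weights(f0, w, cfg.filter_order, fs_hz, n_bins)
        bank.append(
            GammatoneFilter(
                center_freq_hz=float(f0),
                bandwidth_hz=float(w),
                order=cfg.filter_order,
                weights=weights,
            )
        )
    return bank


def apply_filterbank(spec: np.ndarray, bank: list[GammatoneFilter]) -> np.ndarray:
    """Band energies: inner product of each frame spectrum with each filter's
    spectral weights."""
    W = np.stack([f.weights for f in bank], axis=1)
    if spec.shape[1] != W.shape[0]:
        raise ValueError(
            f"spectrum has {spec.shape[1]} bins but filterbank expects {W.shape[0]}"
        )
    return spec @ W


def power_normalize(bands: np.ndarray) -> np.ndarray:
    """Divide by the mean band power over the whole record, making the chain
    invariant to the signal's overall scale; the normalized entries then
    average to exactly 1.  An all-zero input passes through unchanged."""
    mu = float(np.mean(bands))
    if mu == 0.0:
        logger.warning("all-zero band energies; skipping power normalization")
        return bands.copy()
    return bands / mu


def power_law(U: np.ndarray, theta: float) -> np.ndarray:
    """Elementwise compression U^theta, 0 < theta < 1."""
    if not (0 < theta < 1):
        raise ValueError("theta must lie in (0, 1)")
    if np.any(U < 0):
        raise ValueError("power-law input must be nonnegative")
    return np.power(U, theta)


# ---------------------------------------------------------------------------
# time-domain features


def time_domain_features(record: PPGRecord) -> np.ndarray:
    """Inter-beat-interval statistics from detected peaks, in the fixed order
    of TIME_FEATURE_NAMES: mean IBI, SD of IBI, RMSSD, fraction of successive
    differences > 50 ms, Shannon entropy (bits) of the 8-bin IBI histogram,
    and peak-amplitude CV.
    """
    peaks = detect_peaks(record)
    if peaks.size < 4:
        raise MissingFeatureError(
            f"record {record.record_id!r}: {peaks.size} peaks detected, need >= 4"
        )
    ibis = np.diff(peaks) / record.fs_hz
    diffs = np.diff(ibis)
    mean_ibi = float(np.mean(ibis))
    sd_ibi = float(np.std(ibis, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0
    frac50 = float(np.mean(np.abs(diffs) > 0.05)) if diffs.size else 0.0

    counts, _ = np.histogram(ibis, bins=8)
    p = counts[counts > 0] / counts.sum()
    entropy = float(-np.sum(p * np.log2(p)))

    amps = record.samples[peaks]
    amp_mean = float(np.mean(amps))
    amp_cv = float(np.std(amps, ddof=1) / abs(amp_mean)) if amp_mean != 0 else 0.0
    return np.array([mean_ibi, sd_ibi, rmssd, frac50, entropy, amp_cv])


# ---------------------------------------------------------------------------
# full chain


def extract_cepncc(
    record: PPGRecord,
    emd_cfg: EmdConfig = EmdConfig(),
    ens_cfg: EnsembleConfig = EnsembleConfig(),
    feat_cfg: FeatureConfig = FeatureConfig(),
) -> FeatureMatrix:
    """Full feature chain on a segmented, normalized record.

    CEEMD (or EEMD per ``ens_cfg.mode``) -> coherence-based IMF selection ->
    per-IMF framed periodograms, summed (or stacked) across selected IMFs ->
    Gammatone filterbank -> power normalization -> power-law compression ->
    optional DCT along the band axis.  Deterministic given ``ens_cfg.seed``.
    """
    x = record.samples
    if ens_cfg.mode == "ceemd":
        imfset = ceemd(x, emd_cfg, ens_cfg)
    else:
        imfset = eemd(x, emd_cfg, ens_cfg)
    selected, _mus = select_imfs(imfset, x, feat_cfg.selection_threshold)

    specs = [
        power_spectrum(imf, record.fs_hz, feat_cfg.frame_len_s, feat_cfg.frame_hop_s)
        for imf in selected.imfs
    ]
    n_bins = specs[0].shape[1]
    bank = build_filterbank(feat_cfg, record.fs_hz, n_bins)

    if feat_cfg.combine == "sum":
        spec = np.sum(specs, axis=0)
        bands = apply_filterbank(spec, bank)
    else:  # stack per-IMF band energies along the frame axis
        bands = np.concatenate([apply_filterbank(s, bank) for s in specs], axis=0)

    U = power_normalize(bands)
    values = power_law(U, feat_cfg.power_law_theta)
    if feat_cfg.include_dct:
        values = dct(values, type=2, norm="ortho", axis=1)

    return FeatureMatrix(
        values=values,
        time_features=time_domain_features(record),
        record_id=record.record_id,
        config={
            "features": asdict(feat_cfg),
            "emd": asdict(emd_cfg),
            "ensemble": asdict(ens_cfg),
        },
    )


def write_feature_csv(fm: FeatureMatrix, path: str) -> None:
    """frames x bands matrix; footer row carries the time-domain features."""
    with open(path, "w") as fh:
        fh.write("row_type," + ",".join(f"c{j}" for j in range(fm.n_bands)) + "\n")
        for row in fm.values:
            fh.write("frame," + ",".join(repr(float(v)) for v in row) + "\n")
        tf = ",".join(repr(float(v)) for v in fm.time_features)
        pad = "," * (fm.n_bands - fm.time_features.size)
        fh.write("time_features," + tf + pad + "\n")


def read_feature_csv(path: str) -> FeatureMatrix:
    rows: list[list[float]] = []
    tf: np.ndarray | None = None
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("row_type"):
            raise ValueError(f"{path}: not a feature CSV")
        for line in fh:
            parts = line.rstrip("\n").split(",")
            kind, vals = parts[0], [p for p in parts[1:] if p != ""]
            if kind == "frame":
                rows.append([float(v) for v in vals])
            elif kind == "time_features":
                tf = np.array([float(v) for v in vals])
    if not rows or tf is None:
        raise ValueError(f"{path}: incomplete feature CSV")
    return FeatureMatrix(values=np.array(rows), time_features=tf)
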