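"""Empirical mode decomposition and its noise-ensemble drivers.

EMD sifts a signal into intrinsic mode functions (IMFs): oscillatory
components whose extrema and zero-crossing counts differ by at most one and
whose spline-envelope mean is near zero.  Because sifting only ever
subtracts, the decomposition is an exact telescoping identity:
``sum(imfs) + residual == signal`` to machine precision.

Two ensemble drivers reduce mode mixing by adding white noise and
averaging the per-realization decompositions:

* EEMD averages N decompositions of signal + noise_i, so a residual noise
  term of order 1/sqrt(N) survives in the reconstruction.
* CEEMD (complementary EEMD) decomposes each noise realization twice, with
  +noise_i and -noise_i, and averages all 2N decompositions; the added
  noise cancels exactly in the average, so far fewer realizations are
  needed for the same residual error.

IMF selection keeps the modes whose Pearson correlation with the original
signal exceeds a threshold, discarding noise-dominated modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmdConfig:
    """Sifting parameters.

    The stop rule is Huang's Cauchy criterion: stop sifting when
    ``sum((h_prev - h)^2) / sum(h_prev^2)`` drops below
    ``sift_sd_threshold``.  Envelopes are cubic splines through the extrema
    with a mirror extension of two extrema at each boundary.
    """

    max_imfs: int = 12
    max_sift_iters: int = 100
    sift_sd_threshold: float = 0.2
    boundary: str = "mirror"
    spline: str = "cubic"

    def __post_init__(self) -> None:
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be >= 1")
        if self.sift_sd_threshold <= 0:
            raise ValueError("sift_sd_threshold must be > 0")
        if self.boundary != "mirror" or self.spline != "cubic":
            raise ValueError("only mirror boundary with cubic splines is supported")


@dataclass(frozen=True)
class EnsembleConfig:
    """Noise-ensemble parameters.

    ``n_realizations`` is the number N of white-noise vectors; CEEMD runs
    2N EMD decompositions (each noise added and subtracted), EEMD runs N.
    ``noise_sd_frac`` scales the noise SD as a fraction of the signal SD.
    """

    n_realizations: int = 20
    noise_sd_frac: float = 0.2
    seed: int = 0
    mode: str = "ceemd"

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.noise_sd_frac <= 0:
            raise ValueError("noise_sd_frac must be > 0")
        if self.mode not in ("ceemd", "eemd"):
            raise ValueError("mode must be 'ceemd' or 'eemd'")


@dataclass
class IMFSet:
    """Ordered IMFs plus residual from one decomposition."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int
    config: dict = field(default_factory=dict)
    n_emd_calls: int = 1
    mode: str = "emd"

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out

    def to_matrix(self) -> np.ndarray:
        """Columns = IMF1..IMFp, last column = residual."""
        return np.column_stack(self.imfs + [self.residual])


# ---------------------------------------------------------------------------
# extrema and envelopes


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateaus contribute one extremum."""
    d = np.diff(x)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    # carry the previous nonzero slope across plateaus (vectorized forward fill)
    filled = s.copy()
    idx = np.where(s != 0, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    valid = idx >= 0
    filled[valid] = s[idx[valid]]
    chg = np.diff(filled)
    maxima = np.flatnonzero(chg < 0) + 1
    minima = np.flatnonzero(chg > 0) + 1
    return maxima, minima


def _mirror_knots(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to two extrema about each end of the signal for edge control."""
    if idx.size == 0:
        return idx, val
    k = min(2, idx.size)
    left_pos = -idx[:k][::-1]
    left_val = val[:k][::-1]
    right_pos = 2 * (n - 1) - idx[-k:][::-1]
    right_val = val[-k:][::-1]
    pos = np.concatenate([left_pos, idx, right_pos])
    vv = np.concatenate([left_val, val, right_val])
    pos, keep = np.unique(pos, return_index=True)
    return pos, vv[keep]


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the extrema at ``idx`` (mirror boundary)."""
    n = x.size
    pos, val = _mirror_knots(idx, x[idx], n)
    if pos.size == 1:
        return np.full(n, val[0])
    if pos.size < 4:
        # too few knots for a cubic: fall back to linear interpolation
        return np.interp(np.arange(n), pos, val)
    cs = CubicSpline(pos, val)
    return cs(np.arange(n))


def _sift_once(h: np.ndarray) -> np.ndarray | None:
    maxima, minima = _local_extrema(h)
    if maxima.size + minima.size < 3 or maxima.size == 0 or minima.size == 0:
        return None
    upper = _envelope(h, maxima)
    lower = _envelope(h, minima)
    return h - 0.5 * (upper + lower)


def _extract_imf(r: np.ndarray, cfg: EmdConfig) -> np.ndarray | None:
    h = r
    for _ in range(cfg.max_sift_iters):
        h_new = _sift_once(h)
        if h_new is None:
            return None if h is r else h
        denom = float(np.sum(h * h))
        if denom == 0.0:
            return h_new
        sd = float(np.sum((h - h_new) ** 2)) / denom
        h = h_new
        if sd < cfg.sift_sd_threshold:
            break
    return h


# ---------------------------------------------------------------------------
# public operations


def emd(samples: np.ndarray, cfg: EmdConfig = EmdConfig()) -> IMFSet:
    """Plain EMD.  The returned modes and residual reconstruct the input
    exactly (telescoping identity)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 8:
        raise ValueError("signal must have at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or Inf")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < cfg.max_imfs:
        maxima, minima = _local_extrema(residual)
        if maxima.size + minima.size < 3:
            break
        imf = _extract_imf(residual, cfg)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return IMFSet(
        imfs=imfs,
        residual=residual,
        source_length=x.size,
        config=asdict(cfg),
        n_emd_calls=1,
        mode="emd",
    )


def _average_ensemble(
    decomps: list[IMFSet], n: int, mode: str, config: dict, n_calls: int
) -> IMFSet:
    p_max = max(d.n_imfs for d in decomps)
    if len({d.n_imfs for d in decomps}) > 1:
        logger.warning(
            "ensemble realizations produced differing IMF counts %s; "
            "zero-padding shorter decompositions to %d before averaging",
            sorted({d.n_imfs for d in decomps}),
            p_max,
        )
    m = len(decomps)
    imfs = [np.zeros(n) for _ in range(p_max)]
    residual = np.zeros(n)
    for d in decomps:
        for j, imf in enumerate(d.imfs):
            imfs[j] += imf
        residual += d.residual
    imfs = [a / m for a in imfs]
    residual /= m
    return IMFSet(
        imfs=imfs,
        residual=residual,
        source_length=n,
        config=config,
        n_emd_calls=n_calls,
        mode=mode,
    )


def ceemd(
    samples: np.ndarray,
    emd_cfg: EmdConfig = EmdConfig(),
    ens_cfg: EnsembleConfig = EnsembleConfig(),
) -> IMFSet:
    """Complementary EEMD: each of the N noise vectors is both added and
    subtracted, both variants are EMD-decomposed (2N decompositions total),
    and corresponding IMFs are averaged.  The paired noise cancels exactly
    in the average, so the reconstruction identity holds to machine
    precision.  Deterministic given ``ens_cfg.seed``."""
    x = np.asarray(samples, dtype=float)
    rng = np.random.default_rng(ens_cfg.seed)
    noise_sd = ens_cfg.noise_sd_frac * float(np.std(x))
    decomps: list[IMFSet] = []
    for _ in range(ens_cfg.n_realizations):
        noise = noise_sd * rng.standard_normal(x.size)
        decomps.append(emd(x + noise, emd_cfg))
        decomps.append(emd(x - noise, emd_cfg))
    cfg = {"emd": asdict(emd_cfg), "ensemble": asdict(ens_cfg)}
    return _average_ensemble(
        decomps, x.size, "ceemd", cfg, n_calls=2 * ens_cfg.n_realizations
    )


def eemd(
    samples: np.ndarray,
    emd_cfg: EmdConfig = EmdConfig(),
    ens_cfg: EnsembleConfig = EnsembleConfig(mode="eemd", n_realizations=200),
) -> IMFSet:
    """Ensemble EMD: average of N decompositions of signal + noise_i.  The
    reconstruction retains a mean-noise term of order 1/sqrt(N)."""
    x = np.asarray(samples, dtype=float)
    rng = np.random.default_rng(ens_cfg.seed)
    noise_sd = ens_cfg.noise_sd_frac * float(np.std(x))
    decomps = [
        emd(x + noise_sd * rng.standard_normal(x.size), emd_cfg)
        for _ in range(ens_cfg.n_realizations)
    ]
    cfg = {"emd": asdict(emd_cfg), "ensemble": asdict(ens_cfg)}
    return _average_ensemble(decomps, x.size, "eemd", cfg, n_calls=ens_cfg.n_realizations)


def decompose(
    samples: np.ndarray,
    mode: str = "ceemd",
    emd_cfg: EmdConfig = EmdConfig(),
    ens_cfg: EnsembleConfig | None = None,
) -> IMFSet:
    """Dispatch to emd / eemd / ceemd by name."""
    if mode == "emd":
        return emd(samples, emd_cfg)
    if ens_cfg is None:
        ens_cfg = EnsembleConfig(mode=mode, n_realizations=20 if mode == "ceemd" else 200)
    if mode == "ceemd":
        return ceemd(samples, emd_cfg, ens_cfg)
    if mode == "eemd":
        return eemd(samples, emd_cfg, ens_cfg)
    raise ValueError(f"unknown decomposition mode {mode!r}")


def imf_coherence(imfset: IMFSet, original: np.ndarray) -> np.ndarray:
    """Pearson correlation of each IMF with the original signal.

    A zero-variance IMF (or original) gets coherence 0.
    """
    sig = np.asarray(original, dtype=float)
    sig_c = sig - sig.mean()
    sig_ss = float(np.sum(sig_c * sig_c))
    mus = np.empty(imfset.n_imfs)
    for j, imf in enumerate(imfset.imfs):
        imf_c = imf - imf.mean()
        imf_ss = float(np.sum(imf_c * imf_c))
        if imf_ss == 0.0 or sig_ss == 0.0:
            mus[j] = 0.0
        else:
            mus[j] = float(np.sum(imf_c * sig_c)) / np.sqrt(imf_ss * sig_ss)
    return mus


def select_imfs(
    imfset: IMFSet, original: np.ndarray, threshold: float = 0.1
) -> tuple[IMFSet, np.ndarray]:
    """Keep the IMFs whose coherence with the original signal is >= threshold.

    Order is preserved.  If no IMF passes, the single most coherent IMF is
    kept (logged) so downstream feature extraction never sees an empty set.
    """
    if imfset.n_imfs == 0:
        raise ValueError("IMF set is empty")
    mus = imf_coherence(imfset, original)
    keep = np.flatnonzero(mus >= threshold)
    if keep.size == 0:
        keep = np.array([int(np.argmax(mus))])
        logger.warning(
            "no IMF passed coherence threshold %.3g; keeping the most coherent "
            "IMF (index %d, mu=%.3g)",
            threshold,
            keep[0],
            mus[keep[0]],
        )
    subset = IMFSet(
        imfs=[imfset.imfs[j] for j in keep],
        residual=imfset.residual,
        source_length=imfset.source_length,
        config=dict(imfset.config, selection_threshold=threshold),
        n_emd_calls=imfset.n_emd_calls,
        mode=imfset.mode,
    )
    return subset, mus
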