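"""Centroiding of profile spectra: baseline correction, noise estimation and
signal-to-noise-filtered peak picking.

The baseline is a rolling minimum followed by a rolling mean (both over a
window expressed in daltons), which tracks slow chemical background without
eating into peaks.  Noise is the median absolute deviation of the
baseline-subtracted trace scaled by 1.4826, making the SNR threshold robust to
the peaks themselves and free of any intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .spectra_io import PeakList, Spectrum

MAD_TO_SIGMA = 1.4826  # consistency constant for Gaussian noise


class ModeError(ValueError):
    """Operation received a spectrum in the wrong acquisition mode."""


@dataclass
class PickingParams:
    """Peak-picking configuration.

    snr_min : minimum signal-to-noise ratio for a peak to be emitted.
    window_da : half-width (Da) of the local-maximum neighbourhood.
    baseline_win_da : window (Da) of the rolling baseline estimate.
    min_mz, max_mz : retained mass range (Da).
    """

    snr_min: float = 3.0
    window_da: float = 5.0
    baseline_win_da: float = 200.0
    min_mz: float = 1000.0
    max_mz: float = 20000.0

    def __post_init__(self) -> None:
        for name in ("snr_min", "window_da", "baseline_win_da",
                     "min_mz", "max_mz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_mz >= self.max_mz:
            raise ValueError("min_mz must be below max_mz")


def _window_points(mz: np.ndarray, window_da: float) -> int:
    """Convert a window in Da to an odd number of grid points (≥ 1)."""
    if mz.size < 2:
        return 1
    step = np.median(np.diff(mz))
    n = max(1, int(round(window_da / step)))
    return n + 1 if n % 2 == 0 else n


def estimate_baseline(s: Spectrum, baseline_win_da: float = 200.0) -> np.ndarray:
    """Rolling-minimum / rolling-mean baseline of a profile spectrum."""
    if s.mode != "profile":
        raise ModeError("baseline estimation requires a profile spectrum")
    if baseline_win_da <= 0:
        raise ValueError("baseline_win_da must be positive")
    n = _window_points(s.mz, baseline_win_da)
    rolled_min = ndimage.minimum_filter1d(s.intensity, size=n, mode="nearest")
    return ndimage.uniform_filter1d(rolled_min, size=n, mode="nearest")


def _noise_level(residual: np.ndarray) -> float:
    mad = np.median(np.abs(residual - np.median(residual)))
    return float(mad * MAD_TO_SIGMA)


def _centroid_half_max(mz, signal, apex: int) -> float:
    """Intensity-weighted centroid over the contiguous region above half of
    the apex height; stable against point-wise intensity noise."""
    half = signal[apex] / 2.0
    lo = apex
    while lo > 0 and signal[lo - 1] > half:
        lo -= 1
    hi = apex
    while hi < signal.size - 1 and signal[hi + 1] > half:
        hi += 1
    seg = slice(lo, hi + 1)
    weights = np.clip(signal[seg], 0.0, None)
    total = weights.sum()
    if total <= 0:
        return float(mz[apex])
    return float(np.dot(mz[seg], weights) / total)


def pick_peaks(s: Spectrum, p: PickingParams | None = None) -> PeakList:
    """Centroid a profile spectrum into an SNR-filtered peak list.

    A peak is a strict local maximum of the baseline-subtracted trace within
    ±``window_da`` whose SNR reaches ``snr_min``.  Centroid-mode input passes
    through, filtered to the mass range, with SNR taken against a
    baseline-free noise estimate.
    """
    if p is None:
        p = PickingParams()

    if s.mode == "centroid":
        noise = _noise_level(s.intensity)
        keep = (s.mz >= p.min_mz) & (s.mz <= p.max_mz)
        snr = s.intensity[keep] / noise if noise > 0 else np.full(
            int(keep.sum()), np.inf)
        return PeakList(sample_id=s.sample_id, replicate_id=s.replicate_id,
                        mz=s.mz[keep], intensity=s.intensity[keep], snr=snr)

    baseline = estimate_baseline(s, p.baseline_win_da)
    signal = s.intensity - baseline
    # the rolling minimum sits below the noise band by construction; recentre
    # the residual on its median so that noise-only points have SNR ≈ 0
    signal = signal - np.median(signal)
    noise = _noise_level(signal)

    n = _window_points(s.mz, 2 * p.window_da)  # ±window_da neighbourhood
    local_max = ndimage.maximum_filter1d(signal, size=n, mode="nearest")
    # strict maximum: the apex value must be unique within the window
    is_apex = (signal >= local_max) & (signal > 0)
    apex_idx = np.flatnonzero(is_apex)

    mzs, intens, snrs = [], [], []
    for i in apex_idx:
        # reject plateau duplicates: keep only the first index of a tie run
        if i > 0 and is_apex[i - 1] and signal[i] == signal[i - 1]:
            continue
        snr_i = signal[i] / noise if noise > 0 else np.inf
        if snr_i < p.snr_min:
            continue
        c = _centroid_half_max(s.mz, signal, i)
        if not (p.min_mz <= c <= p.max_mz):
            continue
        mzs.append(c)
        intens.append(float(signal[i]))
        snrs.append(float(snr_i))

    if not mzs:
        return PeakList(sample_id=s.sample_id, replicate_id=s.replicate_id,
                        mz=np.array([]), intensity=np.array([]),
                        snr=np.array([]))
    order = np.argsort(mzs)
    mz_arr = np.array(mzs)[order]
    int_arr = np.array(intens)[order]
    snr_arr = np.array(snrs)[order]
    # two apexes can centroid to the same position; keep the more intense
    keep = np.ones(mz_arr.size, dtype=bool)
    for j in range(1, mz_arr.size):
        if mz_arr[j] - mz_arr[j - 1] <= 0:
            keep[j if int_arr[j] <= int_arr[j - 1] else j - 1] = False
    return PeakList(sample_id=s.sample_id, replicate_id=s.replicate_id,
                    mz=mz_arr[keep], intensity=int_arr[keep], snr=snr_arr[keep])
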