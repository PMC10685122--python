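"""Collective-activity estimation from nest-interior frame stacks.

Frames sampled every 30 s are binarized by local adaptive thresholding (ants
are darker than the background), and the activity at each frame pair is the
fraction of ant pixels that newly appear: count(0 -> 1) / count(ants in the
first frame).  Pixels that vanish (1 -> 0) are ignored to avoid double
counting.  The series is smoothed with a 15-point Gaussian-weighted moving
average before wavelet period estimation; cycle segmentation and event
cross-correlation operate on the series directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt
from scipy.signal import find_peaks
from skimage.filters import threshold_local


@dataclass
class CycleSegmentation:
    """Start / peak / end indices of each collective activity cycle."""

    starts: np.ndarray
    peaks: np.ndarray
    ends: np.ndarray

    def __len__(self) -> int:
        return len(self.peaks)

    def flow_window_start(self, i: int, dt: float, pre_s: float = 30.0) -> int:
        """Frame index where cycle i's flow-analysis window begins.

        The window starts ``pre_s`` seconds (default 30 s) before the cycle
        midpoint, midpoint = floor((start + end) / 2).
        """
        mid = (int(self.starts[i]) + int(self.ends[i])) // 2
        return max(mid - int(round(pre_s / dt)), 0)


@dataclass
class PeriodEstimate:
    """Dominant oscillation period with its wavelet magnitude and metadata."""

    period_min: float
    magnitude: float
    wavelet: str
    time_index: int


def load_stack(path: str | Path) -> np.ndarray:
    """Load an ordered frame stack: a directory of PNG/TIFF frames (sorted by
    name) or a multi-page TIFF, as a (T, H, W) grayscale array."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
    else:
        arr = np.asarray(iio.imread(path))
        frames = list(arr) if arr.ndim == 3 else [arr]
    stack = np.stack([f if f.ndim == 2 else f.mean(axis=-1) for f in frames])
    if stack.shape[0] < 2:
        raise ValueError("frame stack needs at least 2 frames")
    return stack


def binarize_frame(
    frame: np.ndarray,
    block_size: int = 35,
    offset: float | None = None,
    ants_bright: bool = False,
) -> np.ndarray:
    """Segment ants from the lighter background by local adaptive thresholding.

    The frame is inverted (unless ``ants_bright``) so ants become the bright
    foreground, then compared against the local neighbourhood mean plus a
    margin.  ``block_size`` defaults to roughly twice an ant's length in
    pixels; ``offset`` is the intensity margin above the local mean a pixel
    must clear (default 10% of the frame's dynamic range, which maps a uniform
    frame to an all-zero mask).
    """
    frame = np.asarray(frame, dtype=float)
    work = frame if ants_bright else frame.max() - frame
    rng = np.ptp(work)
    if rng == 0:
        warnings.warn("uniform frame: no ants segmented", stacklevel=2)
        return np.zeros(frame.shape, dtype=bool)
    if offset is None:
        offset = 0.1 * rng
    local_mean = threshold_local(work, block_size=block_size, method="mean")
    return work > local_mean + offset


def binarize_stack(stack: np.ndarray, **kwargs) -> np.ndarray:
    return np.stack([binarize_frame(f, **kwargs) for f in stack])


def pairwise_activity(mask_t: np.ndarray, mask_t1: np.ndarray) -> float:
    """Fraction of ant pixels that newly appear between two binary masks.

    Returns count(0 -> 1) / count(mask_t == 1); 1 -> 0 transitions are
    ignored.  An empty first mask makes the ratio undefined and yields NaN
    with a warning so downstream statistics can skip the interval.
    """
    mask_t = np.asarray(mask_t, dtype=bool)
    mask_t1 = np.asarray(mask_t1, dtype=bool)
    if mask_t.shape != mask_t1.shape:
        raise ValueError("masks must have equal shape")
    denom = int(mask_t.sum())
    if denom == 0:
        warnings.warn("no ants detected in first frame: activity undefined",
                      stacklevel=2)
        return float("nan")
    return float((mask_t1 & ~mask_t).sum() / denom)


def activity_series(
    stack: np.ndarray, dt: float = 30.0, **binarize_kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """(times_s, activity) from a grayscale stack via frame differencing."""
    masks = binarize_stack(stack, **binarize_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = np.array(
            [pairwise_activity(masks[t], masks[t + 1]) for t in range(len(masks) - 1)]
        )
    return np.arange(len(vals)) * dt, vals


def gaussian_smooth(series, window: int = 15) -> np.ndarray:
    """Gaussian-weighted moving average with truncated-edge renormalization.

    The kernel spans ``window`` points with sigma = (window - 1) / 5 (the
    common moving-average convention); at the edges the truncated kernel is
    renormalized to sum to 1, so a constant series is returned unchanged.
    """
    x = np.asarray(series, dtype=float)
    if window > x.size:
        raise ValueError("window larger than series")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    half = window // 2
    sigma = (window - 1) / 5.0 if window > 1 else 1.0
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def dominant_period(
    series,
    dt: float,
    wavelet: str = "morl",
    n_scales: int = 200,
) -> PeriodEstimate:
    """Dominant oscillation period via the continuous wavelet transform.

    The scalogram is computed over a geometric grid of scales spanning periods
    from 4*dt to half the record length, and the period of the global maximum
    magnitude (across all times and scales) is returned in minutes.  The
    series is demeaned first; smooth beforehand (``gaussian_smooth``) when the
    input is noisy.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n * dt < 8 * dt or n < 16:
        raise ValueError("series too short for wavelet period estimation")
    min_period, max_period = 4 * dt, n * dt / 2
    fc = pywt.central_frequency(wavelet)
    scales = np.geomspace(fc * min_period / dt, fc * max_period / dt, n_scales)
    coefs, freqs = pywt.cwt(x - x.mean(), scales, wavelet, sampling_period=dt)
    mag = np.abs(coefs)
    i, t = np.unravel_index(mag.argmax(), mag.shape)
    return PeriodEstimate(
        period_min=float(1.0 / freqs[i] / 60.0),
        magnitude=float(mag[i, t]),
        wavelet=wavelet,
        time_index=int(t),
    )


def segment_cycles(smoothed, prominence: float | None = None) -> CycleSegmentation:
    """Identify start / peak / end points of collective activity cycles.

    Peaks are local maxima with a minimum prominence (default 0.25 x the
    series interquartile range); each cycle's start and end are the nearest
    flanking troughs (local minima of the series, with the record boundaries
    admitted as troughs).  Returns an empty segmentation, with a warning, when
    no peak qualifies.
    """
    x = np.asarray(smoothed, dtype=float)
    if prominence is None:
        q1, q3 = np.percentile(x, [25, 75])
        prominence = 0.25 * (q3 - q1)
    peaks, _ = find_peaks(x, prominence=prominence if prominence > 0 else None)
    if peaks.size == 0:
        warnings.warn("no activity peaks found", stacklevel=2)
        empty = np.array([], dtype=int)
        return CycleSegmentation(empty, empty, empty)
    troughs, _ = find_peaks(-x)
    troughs = np.unique(np.concatenate([[0], troughs, [x.size - 1]]))
    starts = np.array([troughs[troughs < p].max() for p in peaks])
    ends = np.array([troughs[troughs > p].min() for p in peaks])
    return CycleSegmentation(starts, peaks, ends)


def event_cross_correlation(
    activity,
    events,
    window: int | None = 15,
    max_lag: int | None = None,
) -> tuple[float, int]:
    """Max normalized cross-correlation between activity and an event series.

    The event series (e.g. larval-interaction counts per interval) is smoothed
    with a ``window``-point Gaussian moving average first (``window=None``
    disables this); both series must share the sampling cadence.  Returns
    (r at the maximizing lag, lag); positive lag means events trail activity.
    """
    a = np.asarray(activity, dtype=float)
    e = np.asarray(events, dtype=float)
    if a.shape != e.shape:
        raise ValueError("series must have equal length")
    if window is not None:
        e = gaussian_smooth(e, window)
    n = a.size
    if max_lag is None:
        max_lag = n // 2
    best_r, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[: n - lag], e[lag:]
        else:
            x, y = a[-lag:], e[: n + lag]
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if r > best_r:
            best_r, best_lag = r, lag
    return float(best_r), int(best_lag)
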