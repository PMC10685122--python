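"""Dense optical-flow quantification of motion around inactive ants.

For a short clip at 1 fps, per-pixel displacement magnitudes M_t are estimated
for every consecutive frame pair with a dense iterative Lucas-Kanade flow,
magnitudes below a noise floor (1.5 px/frame) are zeroed, and the cumulative
map sigma_px = sum_t M_t measures the total motion that passed through each
pixel.  Pixels classified as ant in at least 90% of the clip's frames (after
small-component removal) form the inactive-ant mask; comparing sigma_px on
that mask against random pixels, and on the mask against its morphological
adjacency ring, tests whether active ants detour around immobile nest-mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu, wilcoxon
from skimage.registration import optical_flow_ilk

from .sync_metrics import SectorGrid
from .video_activity import binarize_stack

DEFAULT_NOISE_FLOOR = 1.5  # px/frame; flow below this is imaging noise
BROOD_CROP_SHAPES = {(100, 150), (150, 100)}


@dataclass
class FlowField:
    """Per-pair dense displacement magnitudes (T-1, H, W), noise-floored."""

    magnitudes: np.ndarray
    noise_floor: float
    params: dict = field(default_factory=dict)


@dataclass
class SigmaPxMap:
    """Cumulative per-pixel displacement magnitude over a clip."""

    sigma: np.ndarray
    n_pairs: int


@dataclass
class InactiveMask:
    """Pixels ant-classified in >= persistence of frames, small blobs removed."""

    mask: np.ndarray
    persistence: float
    min_component: int


@dataclass
class RankSumReport:
    """Inactive-pixel vs random-pixel sigma_px comparison (rank-sum test)."""

    statistic: float
    pvalue: float
    median_inactive: float
    median_random: float
    inactive_values: np.ndarray
    random_values: np.ndarray
    degenerate: bool = False


@dataclass
class PairedTestReport:
    """Mask-vs-ring summed-flow comparison (signed-rank test) over windows."""

    statistic: float
    pvalue: float
    mask_sums: np.ndarray
    ring_sums: np.ndarray
    no_difference: bool = False


def _texture_gate(frame: np.ndarray, radius: int) -> np.ndarray:
    """Smallest eigenvalue of the local structure tensor.

    A local-window flow estimate is only reliable where the window contains
    two-dimensional image structure; in textureless regions (the flat nest
    background plus sensor noise) the least-squares system is ill-conditioned
    and produces arbitrary large vectors.  Gating on the minimum eigenvalue is
    the classic Lucas-Kanade reliability criterion.
    """
    gy, gx = np.gradient(ndimage.gaussian_filter(frame, 1.0))
    size = 2 * radius + 1
    jxx = ndimage.uniform_filter(gx * gx, size)
    jyy = ndimage.uniform_filter(gy * gy, size)
    jxy = ndimage.uniform_filter(gx * gy, size)
    tr, det = jxx + jyy, jxx * jyy - jxy**2
    return tr / 2 - np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))


def dense_flow(
    stack: np.ndarray,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    radius: int = 7,
    num_warp: int = 10,
    texture_threshold: float = 2.0,
) -> FlowField:
    """Dense per-pixel displacement magnitudes for each consecutive frame pair.

    Iterative Lucas-Kanade flow over a ``radius``-px window, designed for
    1 fps sampling so displacements stay small.  Magnitudes are zeroed where
    the reference frame lacks local texture (see ``_texture_gate``) and where
    they fall below ``noise_floor`` (default 1.5 px/frame, the scale of flow
    noise measured over a static nest region).
    """
    frames = [np.asarray(f, dtype=float) for f in stack]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for optical flow")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share the same dimensions")
    mags = np.empty((len(frames) - 1, *shape))
    for t in range(len(frames) - 1):
        v, u = optical_flow_ilk(
            frames[t], frames[t + 1], radius=radius, num_warp=num_warp
        )
        m = np.hypot(v, u)
        if texture_threshold > 0:
            m[_texture_gate(frames[t], radius) < texture_threshold] = 0.0
        m[m < noise_floor] = 0.0
        mags[t] = m
    return FlowField(
        magnitudes=mags,
        noise_floor=noise_floor,
        params={
            "method": "ilk",
            "radius": radius,
            "num_warp": num_warp,
            "texture_threshold": texture_threshold,
        },
    )


def accumulate_sigma(flow: FlowField | np.ndarray) -> SigmaPxMap:
    """sigma_px = sum over frame pairs of M_t (elementwise; additive over
    concatenated clips)."""
    mags = flow.magnitudes if isinstance(flow, FlowField) else np.asarray(flow)
    if mags.size == 0:
        raise ValueError("empty flow field")
    return SigmaPxMap(sigma=mags.sum(axis=0), n_pairs=mags.shape[0])


def classify_inactive(
    binary_stack: np.ndarray,
    persistence: float = 0.90,
    min_component: int = 62,
) -> InactiveMask:
    """Pixels that are ant-classified in >= ``persistence`` of the frames.

    Connected components smaller than ``min_component`` pixels (default 62,
    the smallest single-ant body area in the study species) are removed: they
    are fragments of partly-moving ants or segmentation speckle, not whole
    inactive ants.
    """
    binary_stack = np.asarray(binary_stack, dtype=bool)
    if binary_stack.ndim != 3 or binary_stack.shape[0] == 0:
        raise ValueError("binary_stack must be a non-empty (T, H, W) stack")
    frac = binary_stack.mean(axis=0)
    mask = frac >= persistence
    if min_component > 1 and mask.any():
        labels, n_lab = ndimage.label(mask)
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_component)
        mask[np.isin(labels, small[small > 0])] = False
    return InactiveMask(mask=mask, persistence=persistence, min_component=min_component)


def inactive_vs_random(
    sigma: SigmaPxMap | np.ndarray,
    mask: InactiveMask | np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> RankSumReport:
    """Compare sigma_px on inactive-ant pixels with an equal number of random
    pixels (uniform, without replacement, whole frame) by Wilcoxon rank-sum.

    If active ants do not avoid walking over inactive ants, the two samples
    should be exchangeable; lower inactive-pixel sigma_px indicates detouring.
    """
    s = sigma.sigma if isinstance(sigma, SigmaPxMap) else np.asarray(sigma)
    m = mask.mask if isinstance(mask, InactiveMask) else np.asarray(mask, dtype=bool)
    if m.shape != s.shape:
        raise ValueError("mask and sigma map must share shape")
    n = int(m.sum())
    if n == 0:
        raise ValueError("inactive mask is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = rng.choice(s.size, size=n, replace=False)
    inactive_vals = s[m]
    random_vals = s.ravel()[idx]
    pooled = np.concatenate([inactive_vals, random_vals])
    if np.ptp(pooled) == 0:
        return RankSumReport(
            statistic=float("nan"), pvalue=float("nan"),
            median_inactive=float(np.median(inactive_vals)),
            median_random=float(np.median(random_vals)),
            inactive_values=inactive_vals, random_values=random_vals,
            degenerate=True,
        )
    stat, p = mannwhitneyu(inactive_vals, random_vals, alternative="two-sided")
    return RankSumReport(
        statistic=float(stat), pvalue=float(p),
        median_inactive=float(np.median(inactive_vals)),
        median_random=float(np.median(random_vals)),
        inactive_values=inactive_vals, random_values=random_vals,
    )


def adjacent_ring(mask: InactiveMask | np.ndarray, thickness: int = 10) -> np.ndarray:
    """Pixels immediately adjacent to inactive ants, by morphological dilation.

    The mask is dilated with a square structuring element of side ``thickness``
    (default 10), adding a ring around each inactive ant while preserving its
    shape; the ring is the dilated area minus the original mask, so it is
    always disjoint from the mask, with overlapping rings merged (binary
    union, no double counting).
    """
    m = mask.mask if isinstance(mask, InactiveMask) else np.asarray(mask, dtype=bool)
    dil = ndimage.binary_dilation(m, structure=np.ones((thickness, thickness)))
    return dil & ~m


def adjacency_paired_test(mask_sums, ring_sums) -> PairedTestReport:
    """Wilcoxon signed-rank test of per-window summed flow on inactive ants
    versus on their adjacency ring (two-sided); requires >= 5 paired windows."""
    mask_sums = np.asarray(mask_sums, dtype=float)
    ring_sums = np.asarray(ring_sums, dtype=float)
    if mask_sums.shape != ring_sums.shape:
        raise ValueError("paired sums must have equal length")
    if mask_sums.size < 5:
        raise ValueError("need at least 5 paired windows")
    diffs = ring_sums - mask_sums
    if np.all(diffs == 0):
        return PairedTestReport(
            statistic=float("nan"), pvalue=1.0,
            mask_sums=mask_sums, ring_sums=ring_sums, no_difference=True,
        )
    stat, p = wilcoxon(mask_sums, ring_sums, alternative="two-sided")
    return PairedTestReport(
        statistic=float(stat), pvalue=float(p),
        mask_sums=mask_sums, ring_sums=ring_sums,
    )


def coverage_proportion(window_mags: np.ndarray, region_px: int = 10) -> float:
    """Proportion of fixed region_px x region_px grid regions containing any
    nonzero flow during a window of frame pairs."""
    sigma = np.asarray(window_mags).sum(axis=0)
    grid = SectorGrid.for_image(sigma.shape, sector_px=region_px)
    return float((grid.sector_sums(sigma > 0) > 0).mean())


def brood_pile_metrics(
    crop_stack: np.ndarray,
    per_ant_area: float = 80.0,
    window: int = 30,
    persistence: float = 0.90,
    min_component: int = 62,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    ring_thickness: int = 10,
    binary: bool = False,
    **binarize_kwargs,
) -> pd.DataFrame:
    """Per-30-s-window accessibility metrics for a brood-pile crop.

    The crop must be 100 x 150 px (or 150 x 100 for horizontal piles), tiled
    by 150 fixed 10 x 10 px regions.  For each window of ``window`` frames
    (30 s at 1 fps): the inactive-ant count estimate (inactive pixels divided
    by ``per_ant_area``), the coverage (proportion of the 150 regions with any
    supra-floor flow), and the summed flow on inactive-ant pixels and on their
    adjacency ring.  Pass ``binary=True`` when the stack is already binarized.
    """
    crop_stack = np.asarray(crop_stack)
    shape = crop_stack.shape[1:]
    if shape not in BROOD_CROP_SHAPES:
        raise ValueError(
            f"brood crop must be 100x150 or 150x100 pixels, got {shape[0]}x{shape[1]}"
        )
    n_windows = crop_stack.shape[0] // window
    if n_windows == 0:
        raise ValueError("stack shorter than one window")
    rows = []
    for w in range(n_windows):
        clip = crop_stack[w * window : (w + 1) * window]
        bin_clip = clip.astype(bool) if binary else binarize_stack(clip, **binarize_kwargs)
        inact = classify_inactive(bin_clip, persistence, min_component)
        ring = adjacent_ring(inact, ring_thickness)
        mags = dense_flow(clip.astype(float), noise_floor=noise_floor).magnitudes
        sigma = mags.sum(axis=0)
        rows.append(
            {
                "window": w,
                "inactive_count": inact.mask.sum() / per_ant_area,
                "coverage": coverage_proportion(mags),
                "mask_flow_sum": float(sigma[inact.mask].sum()),
                "ring_flow_sum": float(sigma[ring].sum()),
            }
        )
    return pd.DataFrame(rows)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance level alpha / n_tests."""
    return alpha / n_tests
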