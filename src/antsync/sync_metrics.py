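"""Phase-synchrony and spatial-inaccessibility metrics.

The Kuramoto order parameter R measures how aligned a population of phase
oscillators is; the maximum local density (MLD) counts the inactive agents
(or the inactive-ant pixel mass) in the fullest sector of a regular grid
partition of the nest, quantifying the largest cluster of immobile obstacles
an active individual might encounter.  pMLD is MLD divided by colony size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr


@dataclass(frozen=True)
class SectorGrid:
    """Regular partition of a rectangular region into n_rows x n_cols sectors.

    Sector membership uses half-open intervals [edge, next_edge); the top/right
    boundary is closed on the last sector, and — for pixel grids whose extent
    is not an exact multiple of the sector size — trailing pixels join the last
    row/column sector, preserving the nominal sector size elsewhere.
    """

    n_rows: int
    n_cols: int
    width: float
    height: float
    sector_w: float
    sector_h: float

    @classmethod
    def for_region(
        cls, width: float, height: float, n_rows: int = 4, n_cols: int = 4
    ) -> "SectorGrid":
        """Exact n_rows x n_cols tiling of a continuous region (default 4x4)."""
        return cls(n_rows, n_cols, width, height, width / n_cols, height / n_rows)

    @classmethod
    def for_image(cls, shape: tuple[int, int], sector_px: int = 68) -> "SectorGrid":
        """As many whole sector_px sectors as fit; remainders join the last."""
        h, w = shape
        n_rows = max(h // sector_px, 1)
        n_cols = max(w // sector_px, 1)
        return cls(n_rows, n_cols, float(w), float(h), float(sector_px), float(sector_px))

    @property
    def n_sectors(self) -> int:
        return self.n_rows * self.n_cols

    def sector_of(self, positions: np.ndarray) -> np.ndarray:
        """Flat sector index (row-major) for (n, 2) array of (x, y) points."""
        positions = np.asarray(positions, dtype=float).reshape(-1, 2)
        col = np.clip((positions[:, 0] // self.sector_w).astype(int), 0, self.n_cols - 1)
        row = np.clip((positions[:, 1] // self.sector_h).astype(int), 0, self.n_rows - 1)
        return row * self.n_cols + col

    def sector_sums(self, image: np.ndarray) -> np.ndarray:
        """Per-sector sums of a 2D array, shape (n_rows, n_cols)."""
        image = np.asarray(image)
        re = np.zeros((self.n_rows, self.n_cols))
        sh, sw = int(self.sector_h), int(self.sector_w)
        for i in range(self.n_rows):
            r1 = (i + 1) * sh if i < self.n_rows - 1 else image.shape[0]
            for j in range(self.n_cols):
                c1 = (j + 1) * sw if j < self.n_cols - 1 else image.shape[1]
                re[i, j] = image[i * sh : r1, j * sw : c1].sum()
        return re


@dataclass
class MLDSeries:
    """Per-interval maximum local density and its proportional variant."""

    times: np.ndarray
    mld: np.ndarray
    colony_size: int

    @property
    def pmld(self) -> np.ndarray:
        return self.mld / self.colony_size


def kuramoto_order(phases, degrees: bool = True) -> float:
    """Kuramoto order parameter |N^-1 sum_j exp(i * theta_j)| in [0, 1].

    ``phases`` are angles in degrees by default (``degrees=False`` for
    radians).  0 means no phase synchrony, 1 complete synchrony.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("kuramoto_order requires at least one phase")
    if degrees:
        phases = np.radians(phases)
    return float(np.abs(np.exp(1j * phases).mean()))


def mld_points(positions, inactive_flags, grid: SectorGrid) -> int:
    """Inactive-agent count in the fullest sector (point-based MLD)."""
    inactive_flags = np.asarray(inactive_flags, dtype=bool)
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    if not inactive_flags.any():
        return 0
    idx = grid.sector_of(positions[inactive_flags])
    return int(np.bincount(idx, minlength=grid.n_sectors).max())


def mld_image(sector_pixel_counts, per_ant_area: float) -> float:
    """Image-based MLD: max per-sector inactive-pixel count / per-ant area.

    ``per_ant_area`` is the typical whole-body pixel area of one ant (62 px for
    L. retractus, 80 px for L. canadensis at the study's scale).  The result is
    a (possibly fractional) estimated number of ants and is not rounded.
    """
    if per_ant_area <= 0:
        raise ValueError("per_ant_area must be positive")
    counts = np.asarray(sector_pixel_counts, dtype=float)
    return float(counts.max() / per_ant_area) if counts.size else 0.0


def mld_from_mask(mask: np.ndarray, grid: SectorGrid, per_ant_area: float) -> float:
    """Image MLD straight from a binary inactive-ant mask."""
    return mld_image(grid.sector_sums(np.asarray(mask, dtype=bool)), per_ant_area)


def activity_mld_correlation(activity, mld) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between activity and MLD series."""
    activity = np.asarray(activity, dtype=float)
    mld = np.asarray(mld, dtype=float)
    if activity.shape != mld.shape:
        raise ValueError("activity and mld must have equal length")
    if activity.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(activity) == 0 or np.ptp(mld) == 0:
        warnings.warn("constant series: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = pearsonr(activity, mld)
    return float(r), float(p)
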