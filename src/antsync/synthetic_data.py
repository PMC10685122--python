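"""Synthetic nest imagery with exact ground truth.

Renders simulator trajectories as dark oriented ellipses on a light, noisy
background — the geometry the segmentation and flow stages assume (dark ants,
lighter background, instantaneous frame samples) — and emits per-frame
ground-truth label maps, activity and MLD series.  A separate brood-scene
generator builds 100 x 150 px crops in which movers perform correlated random
walks that treat a central cluster of resting blobs as hard obstacles,
emulating detouring around an inaccessible brood pile.  Toy sinusoid series
support the smoothing / wavelet stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .oscillator_sim import SimulationResult
from .sync_metrics import SectorGrid, mld_points


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry and photometry.

    ``px_per_unit`` scales simulation length units to pixels: 4 px/unit keeps
    test frames small (a 30-unit arena becomes 120 px); the 'realistic' preset
    uses 12 px/unit, giving a ~360 px nest with ~36 px ants, the scale the
    default segmentation window (35 px) is sized for.  Ant bodies are 3.0 x
    0.4 unit ellipses (the approximate L. canadensis body footprint at 1 unit
    = 1 mm).  Noise is additive Gaussian, default 2% of the 8-bit range.
    """

    px_per_unit: float = 4.0
    ant_length: float = 3.0
    ant_width: float = 0.4
    background: float = 200.0
    ant_intensity: float = 60.0
    noise_sd: float = 5.1
    steps_per_frame: int = 1
    supersample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ant_intensity >= self.background:
            raise ValueError("ants must be darker than the background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def realistic(cls, **overrides) -> "RenderConfig":
        overrides.setdefault("px_per_unit", 12.0)
        return cls(**overrides)


@dataclass
class GroundTruth:
    """Exact per-frame truth for a rendered clip.

    ``label_maps[t]`` assigns every rendered ant pixel (>= 50% subpixel
    coverage) to exactly one agent id (1-based; 0 = background), so the
    per-agent masks partition the ant pixels.  ``activity`` and ``mld`` are
    the simulator's own series at the rendered steps.
    """

    steps: np.ndarray
    label_maps: np.ndarray  # (T, H, W) int16
    active: np.ndarray  # (T, N) bool
    activity: np.ndarray
    mld: np.ndarray
    positions_px: np.ndarray  # (T, N, 2) (col, row)

    def agent_mask(self, t: int, agent: int) -> np.ndarray:
        return self.label_maps[t] == agent + 1

    def ant_mask(self, t: int) -> np.ndarray:
        return self.label_maps[t] > 0


def _block_reduce(arr: np.ndarray, ss: int, how: str) -> np.ndarray:
    h, w = arr.shape[0] // ss, arr.shape[1] // ss
    blocks = arr.reshape(h, ss, w, ss)
    return blocks.mean(axis=(1, 3)) if how == "mean" else blocks.max(axis=(1, 3))


def _render_ellipses(
    centers_px: np.ndarray,
    headings_deg: np.ndarray,
    semi_major_px: float,
    semi_minor_px: float,
    shape: tuple[int, int],
    ss: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Supersampled ellipse rasterization.

    Returns (coverage in [0, 1], label map) at native resolution; the label of
    a pixel with >= 50% coverage is the highest agent id touching it (a
    deterministic tie-break for overlapping bodies).
    """
    H, W = shape
    canvas = np.zeros((H * ss, W * ss), dtype=np.int16)
    for j, ((cx, cy), hdg) in enumerate(zip(centers_px, headings_deg)):
        rr, cc = draw_ellipse(
            cy * ss, cx * ss, semi_minor_px * ss, semi_major_px * ss,
            shape=canvas.shape, rotation=math.radians(hdg),
        )
        canvas[rr, cc] = j + 1
    coverage = _block_reduce((canvas > 0).astype(float), ss, "mean")
    labels = _block_reduce(canvas.astype(float), ss, "max").astype(np.int16)
    labels[coverage < 0.5] = 0
    return coverage, labels


def render_video(
    sim: SimulationResult,
    cfg: RenderConfig | None = None,
    start: int = 0,
    stop: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a simulation as a grayscale uint8 frame stack with ground truth.

    One frame per ``cfg.steps_per_frame`` simulation steps from ``start`` to
    ``stop``.  Resting agents are pixel-identical across frames (up to the
    i.i.d. additive noise); each agent is an oriented dark ellipse centred on
    its disc.
    """
    cfg = cfg or RenderConfig()
    rng = np.random.default_rng(cfg.seed)
    L = sim.config.arena_side
    H = W = int(round(L * cfg.px_per_unit))
    stop = sim.config.n_steps if stop is None else stop
    steps = np.arange(start, stop, cfg.steps_per_frame)
    if np.any(sim.positions[steps] * cfg.px_per_unit > max(H, W)):
        raise ValueError("agent positions fall outside the rendered frame")
    semi_major = cfg.ant_length / 2 * cfg.px_per_unit
    semi_minor = cfg.ant_width / 2 * cfg.px_per_unit

    frames = np.empty((len(steps), H, W), dtype=np.uint8)
    labels = np.empty((len(steps), H, W), dtype=np.int16)
    positions_px = np.empty((len(steps), sim.config.n_agents, 2))
    headings = _headings_from_positions(sim.positions, rng)
    for i, t in enumerate(steps):
        centers = sim.positions[t] * cfg.px_per_unit
        cov, lab = _render_ellipses(
            centers, headings[t], semi_major, semi_minor, (H, W), cfg.supersample
        )
        img = cfg.background + cov * (cfg.ant_intensity - cfg.background)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
        labels[i] = lab
        positions_px[i] = centers
    gt = GroundTruth(
        steps=steps,
        label_maps=labels,
        active=sim.active[steps],
        activity=sim.activity[steps],
        mld=sim.mld[steps],
        positions_px=positions_px,
    )
    return frames, gt


def _headings_from_positions(
    positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-step body orientations: direction of the last displacement, held
    through rests (a resting ant keeps its posture); random at t = 0."""
    n_steps, n, _ = positions.shape
    headings = np.empty((n_steps, n))
    headings[0] = rng.uniform(0, 360, n)
    for t in range(1, n_steps):
        d = positions[t] - positions[t - 1]
        moved = np.hypot(d[:, 0], d[:, 1]) > 1e-9
        headings[t] = headings[t - 1]
        headings[t, moved] = np.degrees(np.arctan2(d[moved, 1], d[moved, 0]))
    return headings


@dataclass
class BroodScene:
    """A rendered brood-pile crop with its exact ground truth."""

    frames: np.ndarray  # (T, H, W) uint8
    resting_mask: np.ndarray  # union of resting-blob pixels
    resting_labels: np.ndarray  # (H, W) int16, 0 background
    mover_positions: np.ndarray  # (T, n_movers, 2) px (col, row)
    per_ant_area: float  # mean rendered pixel area of one resting blob


def make_brood_scene(
    n_resting: int,
    n_movers: int,
    n_frames: int = 90,
    shape: tuple[int, int] = (100, 150),
    seed: int = 0,
    body_length_px: float = 12.0,
    body_width_px: float = 4.0,
    step_px: float = 3.0,
    clearance_px: float = 16.0,
    background: float = 200.0,
    ant_intensity: float = 60.0,
    noise_sd: float = 3.0,
    max_attempts: int = 5000,
) -> BroodScene:
    """Brood-pile crop: central cluster of resting blobs plus detouring movers.

    Resting blobs are clustered around the crop centre and never move; movers
    perform correlated random walks (heading jitter 45 degrees, uniform
    redraws on blocked moves) that treat resting blobs and each other as hard
    obstacles with ``clearance_px`` centre-to-centre keep-out — roughly one
    body length, emulating ants skirting a pile rather than brushing it.
    Frames are 1 fps samples; ``step_px`` of 3 px/frame keeps mover flow above
    the 1.5 px/frame noise floor.
    """
    if shape not in {(100, 150), (150, 100)}:
        raise ValueError("brood crops are 100x150 or 150x100 px")
    rng = np.random.default_rng(seed)
    H, W = shape
    margin = body_length_px / 2 + 1

    def place(n, center_sd, existing, min_dist):
        pts = list(existing)
        out = []
        for _ in range(n):
            for _ in range(max_attempts):
                p = rng.normal([W / 2, H / 2], center_sd)
                if not (margin <= p[0] <= W - margin and margin <= p[1] <= H - margin):
                    continue
                if pts and np.min(
                    np.hypot(*(np.array(pts) - p).T)
                ) < min_dist:
                    continue
                pts.append(p)
                out.append(p)
                break
            else:
                raise RuntimeError(
                    f"could not pack {n} blobs into the {H}x{W} crop"
                )
        return np.array(out).reshape(-1, 2)

    resting = place(n_resting, [18.0, 14.0], [], body_length_px * 0.75)
    resting_headings = rng.uniform(0, 360, n_resting)
    movers = place(n_movers, [W / 3, H / 3], list(resting), clearance_px)
    mover_headings = rng.uniform(0, 360, n_movers)

    _, resting_labels = _render_ellipses(
        resting, resting_headings, body_length_px / 2, body_width_px / 2,
        shape, ss=2,
    )
    resting_mask = resting_labels > 0
    per_ant_area = resting_mask.sum() / max(n_resting, 1)

    frames = np.empty((n_frames, H, W), dtype=np.uint8)
    mover_positions = np.empty((n_frames, n_movers, 2))
    pos = movers.copy()
    for t in range(n_frames):
        mover_positions[t] = pos
        all_centers = np.vstack([resting, pos]) if n_resting or n_movers else pos
        all_headings = np.concatenate([resting_headings, mover_headings])
        cov, _ = _render_ellipses(
            all_centers, all_headings, body_length_px / 2, body_width_px / 2,
            shape, ss=2,
        )
        img = background + cov * (ant_intensity - background)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)
        # advance movers (correlated random walk with keep-out)
        for j in range(n_movers):
            hdg = mover_headings[j] + rng.uniform(-45, 45)
            for attempt in range(50):
                if attempt > 0:
                    hdg = rng.uniform(0, 360)
                rad = math.radians(hdg)
                cand = pos[j] + step_px * np.array([math.cos(rad), math.sin(rad)])
                if not (margin <= cand[0] <= W - margin and margin <= cand[1] <= H - margin):
                    continue
                others = np.vstack([resting, np.delete(pos, j, axis=0)]) if (
                    n_resting or n_movers > 1
                ) else np.empty((0, 2))
                if others.size and np.min(
                    np.hypot(*(others - cand).T)
                ) < clearance_px:
                    continue
                pos[j] = cand
                mover_headings[j] = hdg % 360
                break
    return BroodScene(
        frames=frames,
        resting_mask=resting_mask,
        resting_labels=resting_labels,
        mover_positions=mover_positions,
        per_ant_area=float(per_ant_area),
    )


def make_toy_series(
    period_s: float,
    amplitude: float = 0.3,
    noise_sd: float = 0.05,
    n: int = 1080,
    dt: float = 30.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sinusoidal activity series (baseline 0.5) plus Gaussian noise, clipped
    to [0, 1].  The period must be resolvable: 2*dt < period_s < n*dt/2."""
    if not 2 * dt < period_s < n * dt / 2:
        raise ValueError(
            f"period {period_s}s not resolvable with n={n}, dt={dt}"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    x = 0.5 + amplitude * np.sin(2 * np.pi * t / period_s)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, n)
    return t, np.clip(x, 0.0, 1.0)


def true_mld_series(gt: GroundTruth, grid: SectorGrid) -> np.ndarray:
    """Point-based MLD recomputed from ground truth on an arbitrary grid in
    pixel coordinates (for like-for-like comparison with image-based MLD)."""
    return np.array(
        [
            mld_points(gt.positions_px[t], ~gt.active[t], grid)
            for t in range(len(gt.steps))
        ]
    )
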