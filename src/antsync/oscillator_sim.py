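"""Confined mobile phase-oscillator model of within-nest activity cycles.

N non-interpenetrating circular agents (diameter 1) live in an L x L square
arena.  Each agent carries an internal clock whose phase advances by 1 degree
per time step.  When the phase passes 350 degrees the agent becomes active and
performs a correlated random walk for A + 1 steps (phases 350 ... 350+A mod
360), then rests for the remaining 360 - (A + 1) steps of the cycle.  With
A = 100 an agent therefore spends (360 - 101)/360 = 71.9% of its time inactive.

Population synchrony is controlled at initialization: phases are resampled
until the Kuramoto order parameter R = |N^-1 sum_j exp(i * theta_j)| lies
within a tolerance of the requested value.  Because every clock advances by
the same increment, R is conserved for the whole run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .sync_metrics import SectorGrid, kuramoto_order, mld_points

logger = logging.getLogger(__name__)

ACTIVATION_PHASE = 350  # degrees; agents switch on when the clock passes this


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the mobile-oscillator model.

    ``n_agents`` (N), ``active_span`` (A, degrees of the 360-degree clock spent
    active, minus one), ``arena_side`` (L, length units) and ``r_target`` (R)
    are the four parameters varied in the study; the remainder are fixed model
    constants exposed for completeness.
    """

    n_agents: int = 120
    active_span: int = 100
    arena_side: float = 30.0
    r_target: float = 0.5
    r_tol: float = 0.01
    n_steps: int = 4000
    seed: int = 0
    agent_diameter: float = 1.0
    step_length: float = 1.0
    heading_jitter: float = 45.0
    retry_cap: int = 50
    max_phase_draws: int = 1_000_000
    max_place_attempts: int = 2000

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not 0 <= self.active_span <= 359:
            raise ValueError("active_span must lie in [0, 359]")
        if self.arena_side < self.agent_diameter:
            raise ValueError("arena_side must be >= agent_diameter")
        if not 0.0 <= self.r_target <= 1.0:
            raise ValueError("r_target must lie in [0, 1]")
        if self.r_tol <= 0:
            raise ValueError("r_tol must be positive")

    @property
    def density(self) -> float:
        """Number density Da = N / L**2 (agents per squared length unit)."""
        return self.n_agents / self.arena_side**2


@dataclass
class AgentState:
    """One agent: continuous position, heading, integer clock phase, activity.

    ``has_activated`` stays False until the phase first *passes* 350 degrees;
    agents whose initial phase already sits inside the active window remain
    inactive until that first transition (all agents start inactive).
    """

    position: np.ndarray
    heading: float
    phase: int
    active: bool = False
    has_activated: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not 0 <= self.phase < 360:
            raise ValueError("phase must lie in [0, 360)")


@dataclass
class SimulationResult:
    """Per-step trajectories plus derived activity and MLD series."""

    config: SimConfig
    positions: np.ndarray  # (n_steps, N, 2)
    phases: np.ndarray  # (n_steps, N) int16
    active: np.ndarray  # (n_steps, N) bool
    activity: np.ndarray  # (n_steps,) proportion of agents active
    mld: np.ndarray  # (n_steps,) max local density (inactive count)
    initial_r: float = 0.0

    @property
    def pmld(self) -> np.ndarray:
        return self.mld / self.config.n_agents

    def states_at(self, step: int) -> list[AgentState]:
        """Materialize the AgentState list for one recorded step."""
        return [
            AgentState(
                position=self.positions[step, j].copy(),
                heading=float("nan"),
                phase=int(self.phases[step, j]),
                active=bool(self.active[step, j]),
                has_activated=True,
            )
            for j in range(self.config.n_agents)
        ]

    def agent_table(self):
        """Long-format per-step agent table (step, id, x, y, phase, active)."""
        import pandas as pd

        n_steps, n = self.phases.shape
        steps = np.repeat(np.arange(n_steps), n)
        ids = np.tile(np.arange(n), n_steps)
        return pd.DataFrame(
            {
                "step": steps,
                "id": ids,
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "phase": self.phases.ravel(),
                "active": self.active.ravel().astype(int),
            }
        )


class PlacementError(RuntimeError):
    pass


class PhaseSamplingError(RuntimeError):
    pass


def _vonmises_kappa(r: float) -> float:
    """Concentration kappa of a von Mises density with mean resultant r."""
    if r <= 0.0:
        return 0.0
    # A(kappa) = I1(kappa)/I0(kappa) is monotone; bracket and invert.
    f = lambda k: i1e(k) / i0e(k) - r
    hi = 2.0
    while f(hi) < 0 and hi < 1e6:
        hi *= 2.0
    return brentq(f, 1e-12, hi)


def sample_phases(
    n: int,
    r_target: float,
    r_tol: float,
    rng: np.random.Generator,
    max_draws: int = 1_000_000,
) -> np.ndarray:
    """Draw integer-degree phases whose measured order parameter hits R.

    Proposal phases come from a von Mises distribution whose concentration is
    matched to the target R (uniform for R = 0), then whole populations are
    rejected until |R_measured - r_target| <= r_tol.  R = 1 is satisfied
    exactly by a shared random phase.
    """
    if r_target >= 1.0:
        return np.full(n, rng.integers(0, 360), dtype=np.int64)
    kappa = _vonmises_kappa(r_target)
    for _ in range(max_draws):
        mu = rng.uniform(0, 2 * math.pi)
        if kappa == 0.0:
            phases = rng.integers(0, 360, size=n)
        else:
            raw = rng.vonmises(mu, kappa, size=n)
            phases = np.round(np.degrees(raw)).astype(np.int64) % 360
        if abs(kuramoto_order(phases) - r_target) <= r_tol:
            return phases
    raise PhaseSamplingError(
        f"no phase assignment with |R - {r_target}| <= {r_tol} "
        f"found in {max_draws} draws"
    )


def place_agents(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform rejection placement of non-overlapping discs, fully in-bounds."""
    r = config.agent_diameter / 2.0
    lo, hi = r, config.arena_side - r
    d2 = config.agent_diameter**2
    positions = np.empty((config.n_agents, 2))
    for i in range(config.n_agents):
        for _ in range(config.max_place_attempts):
            p = rng.uniform(lo, hi, size=2)
            if i == 0 or np.min(np.sum((positions[:i] - p) ** 2, axis=1)) >= d2:
                positions[i] = p
                break
        else:
            max_density = 0.9069 / (math.pi * r**2)  # hexagonal packing bound
            raise PlacementError(
                f"could not place agent {i + 1}/{config.n_agents} after "
                f"{config.max_place_attempts} attempts; requested density "
                f"{config.density:.3f} approaches the achievable maximum "
                f"~{max_density:.3f} agents per unit^2"
            )
    return positions


def initialize_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[AgentState]:
    """Non-overlapping, in-bounds, all-inactive agents at the target synchrony."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    phases = sample_phases(
        config.n_agents, config.r_target, config.r_tol, rng, config.max_phase_draws
    )
    positions = place_agents(config, rng)
    headings = rng.uniform(0.0, 360.0, size=config.n_agents)
    return [
        AgentState(position=positions[i], heading=headings[i], phase=int(phases[i]))
        for i in range(config.n_agents)
    ]


def _in_active_window(phase: int, active_span: int) -> bool:
    return (phase - ACTIVATION_PHASE) % 360 <= active_span


def advance_clock(agent: AgentState, active_span: int) -> AgentState:
    """Advance the internal clock one degree and update the activity state.

    Activation is triggered by the transition into 350 degrees, never by mere
    membership of the active window, so agents initialized inside the window
    stay inactive until their first full pass.
    """
    phase = (agent.phase + 1) % 360
    has_activated = agent.has_activated or phase == ACTIVATION_PHASE
    active = has_activated and _in_active_window(phase, active_span)
    return replace(agent, phase=phase, active=active, has_activated=has_activated)


def attempt_move(
    agent: AgentState,
    occupancy: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> AgentState:
    """One correlated-random-walk step with hard-core exclusion.

    The first candidate heading lies within +/-45 degrees of the current one;
    each of up to ``retry_cap`` retries redraws a heading uniformly on the full
    circle.  A fully blocked agent keeps its position (and the last attempted
    heading).
    """
    occupancy = np.asarray(occupancy, dtype=float).reshape(-1, 2)
    r = config.agent_diameter / 2.0
    lo, hi = r, config.arena_side - r
    d2 = config.agent_diameter**2
    heading = agent.heading + rng.uniform(-config.heading_jitter, config.heading_jitter)
    for attempt in range(config.retry_cap + 1):
        if attempt > 0:
            heading = rng.uniform(0.0, 360.0)
        rad = math.radians(heading)
        new = agent.position + config.step_length * np.array(
            [math.cos(rad), math.sin(rad)]
        )
        ok = lo <= new[0] <= hi and lo <= new[1] <= hi
        if ok and occupancy.size:
            ok = np.min(np.sum((occupancy - new) ** 2, axis=1)) >= d2
        if ok:
            return replace(agent, position=new, heading=heading % 360.0)
    logger.debug("agent fully blocked; staying put")
    return replace(agent, heading=heading % 360.0)


def run_simulation(
    config: SimConfig, grid: SectorGrid | None = None
) -> SimulationResult:
    """Run the model for ``config.n_steps`` steps, recording every state.

    Per step all clocks advance first, then the active agents move once each
    in a freshly shuffled order.  Activity is the active fraction; MLD is the
    inactive-agent count in the fullest sector of a 4 x 4 partition of the
    arena.
    """
    rng = np.random.default_rng(config.seed)
    agents = initialize_population(config, rng)
    if grid is None:
        grid = SectorGrid.for_region(config.arena_side, config.arena_side)
    n, steps = config.n_agents, config.n_steps
    positions = np.empty((steps, n, 2))
    phases = np.empty((steps, n), dtype=np.int16)
    active = np.empty((steps, n), dtype=bool)
    activity = np.empty(steps)
    mld = np.empty(steps)
    initial_r = kuramoto_order([a.phase for a in agents])
    pos = np.array([a.position for a in agents])

    for t in range(steps):
        for j in range(n):
            agents[j] = advance_clock(agents[j], config.active_span)
        movers = [j for j in range(n) if agents[j].active]
        rng.shuffle(movers)
        mask = np.ones(n, dtype=bool)
        for j in movers:
            mask[j] = False
            agents[j] = attempt_move(agents[j], pos[mask], config, rng)
            pos[j] = agents[j].position
            mask[j] = True
        positions[t] = pos
        phases[t] = [a.phase for a in agents]
        active[t] = [a.active for a in agents]
        activity[t] = active[t].mean()
        mld[t] = mld_points(pos, ~active[t], grid)
    return SimulationResult(
        config=config,
        positions=positions,
        phases=phases,
        active=active,
        activity=activity,
        mld=mld,
        initial_r=initial_r,
    )


def density_calibration(
    n_agents: int = 120,
    arena_side: float = 30.0,
    agent_diameter: float = 1.0,
    ant_length_mm: float = 3.0,
    ant_width_mm: float = 0.4,
    nest_radius_mm: float = 19.0,
) -> dict[str, float]:
    """Density identities linking the model arena to real circular nests.

    Assumes 1 length unit = 1 mm.  Returns the model number density
    Da = N / L**2, the disc area of one agent, the rectangular body area of a
    real ant, and the density of an equally-populated circular nest.
    """
    return {
        "model_density": n_agents / arena_side**2,
        "agent_disc_area_mm2": math.pi * (agent_diameter / 2.0) ** 2,
        "real_ant_area_mm2": ant_length_mm * ant_width_mm,
        "circular_nest_density": n_agents / (math.pi * nest_radius_mm**2),
    }
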