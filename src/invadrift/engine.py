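"""Cellular-automaton engine: spawning, drift, settlement, demography.

Each monthly cycle every breeding adult releases a fixed number of
transport kernels (packets standing in for ~750 larvae each).  A kernel
performs a stochastic walk over the 8-neighborhood: the probability of
stepping into a neighbor is a weighted sum of (a) the alignment of the
cell's current vector with the bearing to that neighbor, scaled by current
speed relative to the grid-wide monthly maximum, and (b) the neighbor's
binary habitat suitability (SST, chlorophyll, depth).  Dwell time in a
cell is its physical width divided by current speed; the walk ends when
the cumulative drift time reaches the larval duration D.  The kernel then
survives with probability exp(−Z_p·D) and settles if the final cell is
habitable that month; settled kernels age, suffer the monthly adult
mortality draw, and are promoted to breeding at the maturation age.

All randomness flows through one seeded generator per simulation in a
fixed draw order (per spawning adult in list order: one kernel-survival
vector; then the surviving kernels walk as one batch, one uniform per
still-drifting kernel per hop; then one adult-mortality vector over the
settled pool), so runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig, per_cycle_hazards
from .environment import EnvironmentStack, EnvironmentError, suitability_rasters

__all__ = [
    "Kernel",
    "PopulationKernel",
    "SimulationState",
    "SimulationResult",
    "EngineError",
    "neighbor_scores",
    "trace_transit",
    "attempt_settlement",
    "step_month",
    "run_simulation",
]

SECONDS_PER_DAY = 86_400.0
CYCLE_DAYS = 30.0

# neighbor order: NW, N, NE, W, E, SW, S, SE (row 0 = north)
NEIGHBOR_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)
# compass bearing from a cell to each neighbor, degrees clockwise from north
NEIGHBOR_BEARINGS = np.degrees(
    np.arctan2(NEIGHBOR_OFFSETS[:, 1], -NEIGHBOR_OFFSETS[:, 0])
) % 360.0


class EngineError(ValueError):
    pass


@dataclass
class Kernel:
    """A drifting propagule packet (one walk from spawn to settlement)."""

    current_cell: tuple[int, int]
    elapsed_transit: float = 0.0       # days
    spawn_cycle: int = 0
    trajectory: list | None = None     # retained only on request


@dataclass
class PopulationKernel:
    """A settled kernel: juvenile until ``breeding_age``, then an adult
    contributing kernels every breeding-window cycle until killed by the
    adult mortality draw."""

    cell: tuple[int, int]
    settlement_cycle: int
    age: int = 0                # months since settlement
    breeding: bool = False
    alive: bool = True
    is_founder: bool = False


@dataclass
class Event:
    cycle: int
    calendar_month: int
    cell: tuple[int, int]
    kind: str  # spawn | settle | death | promote


@dataclass
class CycleStats:
    cycle: int
    calendar_month: int
    alive_start: int
    kernels_released: int
    settled: int
    deaths: int
    promotions: int
    alive_end: int


class TransitFields:
    """Per-month scoring fields precomputed once per (stack, config).

    ``probs[m, r, c]`` is the 8-neighbor step distribution for a kernel in
    (r, c) during month index m; ``cum`` its cumulative sum for sampling;
    ``dwell[m, r, c]`` the days spent in (r, c) at that month's floored
    current speed; ``dead_end`` marks marine cells with no marine neighbor.
    """

    def __init__(self, stack: EnvironmentStack, config: ModelConfig):
        self.stack = stack
        self.config = config
        grid = stack.grid
        R, C = grid.n_rows, grid.n_cols
        marine = stack.marine_mask

        suit = suitability_rasters(stack, config)        # (12, R, C, 3)
        static = (config.sst_weight * suit[..., 0]
                  + config.cc_weight * suit[..., 1]
                  + config.depth_weight * suit[..., 2])  # (12, R, C)
        self.suitable_all = (suit > 0).all(axis=-1)      # (12, R, C) habitability

        speed = stack.current_speed
        max_speed = np.array([
            speed[m][marine].max() if marine.any() else 0.0 for m in range(12)
        ])
        with np.errstate(invalid="ignore", divide="ignore"):
            speed_norm = np.where(max_speed[:, None, None] > 0,
                                  speed / np.where(max_speed[:, None, None] > 0,
                                                   max_speed[:, None, None], 1.0),
                                  0.0)
        dir_rad = np.radians(stack.current_direction)

        scores = np.zeros((12, R, C, 8))
        valid = np.zeros((R, C, 8), dtype=bool)
        for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
            nb_marine = _shift(marine, dr, dc, fill=False)
            nb_static = _shift3(static, dr, dc)
            align = np.maximum(0.0, np.cos(dir_rad - np.radians(NEIGHBOR_BEARINGS[k])))
            s = config.current_weight * align * speed_norm + nb_static
            scores[..., k] = np.where(nb_marine[None, :, :], s, 0.0)
            valid[..., k] = nb_marine
        n_valid = valid.sum(axis=-1)
        self.dead_end = marine & (n_valid == 0)

        total = scores.sum(axis=-1, keepdims=True)
        uniform = valid[None, :, :, :] / np.maximum(n_valid, 1)[None, :, :, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(total > 0, scores / np.where(total > 0, total, 1.0), uniform)
        probs = np.where(marine[None, :, :, None], probs, 0.0)
        self.probs = probs
        self.cum = np.cumsum(probs, axis=-1)

        widths = np.array([grid.cell_width_m(r) for r in range(R)])
        floored = np.maximum(speed, config.min_current_speed)
        self.dwell = widths[None, :, None] / (floored * SECONDS_PER_DAY)

        self.survival, self.adult_death = per_cycle_hazards(config)


def _shift(arr: np.ndarray, dr: int, dc: int, fill=0.0) -> np.ndarray:
    """arr[r+dr, c+dc] with out-of-grid values replaced by ``fill``."""
    out = np.full_like(arr, fill)
    R, C = arr.shape
    rs = slice(max(dr, 0), R + min(dr, 0))
    cs = slice(max(dc, 0), C + min(dc, 0))
    rd = slice(max(-dr, 0), R + min(-dr, 0))
    cd = slice(max(-dc, 0), C + min(-dc, 0))
    out[rd, cd] = arr[rs, cs]
    return out


def _shift3(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Month-stacked variant of :func:`_shift` (fill 0)."""
    out = np.zeros_like(arr)
    _, R, C = arr.shape
    rs = slice(max(dr, 0), R + min(dr, 0))
    cs = slice(max(dc, 0), C + min(dc, 0))
    rd = slice(max(-dr, 0), R + min(-dr, 0))
    cd = slice(max(-dc, 0), C + min(-dc, 0))
    out[:, rd, cd] = arr[:, rs, cs]
    return out


def neighbor_scores(stack: EnvironmentStack, cell: tuple[int, int],
                    calendar_month: int, config: ModelConfig,
                    fields: TransitFields | None = None) -> np.ndarray:
    """Step probabilities over the 8 neighbors (order NW,N,NE,W,E,SW,S,SE).

    Raises :class:`EngineError` for land or isolated (all-land-neighbor)
    cells.  The vector sums to one.
    """
    row, col = cell
    if stack.land_mask[row, col]:
        raise EngineError(f"cell {cell} is land")
    fields = fields or TransitFields(stack, config)
    if fields.dead_end[row, col]:
        raise EngineError(f"cell {cell} has no marine neighbor")
    m = stack.month_index(calendar_month)
    return fields.probs[m, row, col].copy()


def trace_transit_batch(stack: EnvironmentStack, origins: np.ndarray,
                        spawn_calendar_month: int, config: ModelConfig,
                        rng: np.random.Generator,
                        fields: TransitFields | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Walk a batch of kernels simultaneously until each duration clock D
    expires.

    ``origins`` is an (B, 2) integer array of start cells.  Returns
    ``(final_cells, elapsed, ok)`` where ``ok`` is False for kernels that
    became trapped with no marine neighbor.  One uniform is drawn per
    still-drifting kernel per hop, in batch order, so a batch of one
    consumes the stream exactly like the scalar path.
    """
    fields = fields or TransitFields(stack, config)
    origins = np.asarray(origins, dtype=np.int64).reshape(-1, 2)
    B = origins.shape[0]
    month0 = stack.month_index(spawn_calendar_month)
    D = config.propagule_duration
    r = origins[:, 0].copy()
    c = origins[:, 1].copy()
    t = np.zeros(B)
    active = np.ones(B, dtype=bool)
    trapped = np.zeros(B, dtype=bool)
    while active.any():
        idx = np.nonzero(active)[0]
        m = (month0 + (t[idx] // CYCLE_DAYS).astype(np.int64)) % 12
        dead = fields.dead_end[r[idx], c[idx]]
        if dead.any():
            trapped[idx[dead]] = True
            active[idx[dead]] = False
            idx, m = idx[~dead], m[~dead]
            if idx.size == 0:
                break
        u = rng.random(idx.size)
        cum = fields.cum[m, r[idx], c[idx]]          # (k, 8)
        gt = cum > u[:, None]
        k = gt.argmax(axis=1)
        k[~gt.any(axis=1)] = 7                       # guard fp edge u >= cum[-1]
        r[idx] += NEIGHBOR_OFFSETS[k, 0]
        c[idx] += NEIGHBOR_OFFSETS[k, 1]
        t[idx] += fields.dwell[m, r[idx], c[idx]]
        done = t[idx] >= D
        active[idx[done]] = False
    return np.stack([r, c], axis=1), t, ~trapped


def trace_transit(stack: EnvironmentStack, origin: tuple[int, int],
                  spawn_calendar_month: int, config: ModelConfig,
                  rng: np.random.Generator,
                  fields: TransitFields | None = None) -> Kernel | None:
    """Walk one kernel from ``origin`` until the larval-duration clock D
    expires; returns the settled-position :class:`Kernel`, or None if the
    kernel is trapped with no marine neighbor.

    The running drift-time sum advances the monthly fields at each 30-day
    boundary; per-cell dwell uses the destination cell's width at its
    latitude and its floored current speed.
    """
    fields = fields or TransitFields(stack, config)
    if stack.land_mask[origin]:
        raise EngineError(f"origin {origin} is land")
    cells, elapsed, ok = trace_transit_batch(
        stack, np.array([origin]), spawn_calendar_month, config, rng, fields)
    if not ok[0]:
        return None
    return Kernel(current_cell=(int(cells[0, 0]), int(cells[0, 1])),
                  elapsed_transit=float(elapsed[0]))


def settlement_month(spawn_calendar_month: int, config: ModelConfig) -> int:
    """Calendar month in which the duration clock D expires."""
    return ((spawn_calendar_month - 1 + int(config.propagule_duration // CYCLE_DAYS)) % 12) + 1


def attempt_settlement(final_cell: tuple[int, int], calendar_month: int,
                       stack: EnvironmentStack, config: ModelConfig,
                       rng: np.random.Generator,
                       fields: TransitFields | None = None) -> str:
    """One transport-survival Bernoulli (p = exp(−Z_p·D)) followed by the
    habitability check of the final cell; returns ``"settled"`` or
    ``"dead"``."""
    fields = fields or TransitFields(stack, config)
    if rng.random() >= fields.survival:
        return "dead"
    r, c = final_cell
    m = stack.month_index(calendar_month)
    if stack.land_mask[r, c] or not fields.suitable_all[m, r, c]:
        return "dead"
    return "settled"


@dataclass
class SimulationState:
    """Mutable state advanced by :func:`step_month`."""

    config: ModelConfig
    stack: EnvironmentStack
    fields: TransitFields
    rng: np.random.Generator
    populations: list[PopulationKernel]
    cycle: int = 0  # completed cycles
    events: list[Event] = field(default_factory=list)
    settled_count: np.ndarray | None = None
    establishment_cycle: np.ndarray | None = None
    cycle_stats: list[CycleStats] = field(default_factory=list)

    def __post_init__(self):
        shape = (self.stack.grid.n_rows, self.stack.grid.n_cols)
        if self.settled_count is None:
            self.settled_count = np.zeros(shape, dtype=np.int64)
        if self.establishment_cycle is None:
            self.establishment_cycle = np.full(shape, np.nan)

    @property
    def calendar_month(self) -> int:
        """Calendar month of the *next* cycle to run."""
        return ((self.config.starting_month - 1 + self.cycle) % 12) + 1

    def alive(self) -> list[PopulationKernel]:
        return [p for p in self.populations if p.alive]


def step_month(state: SimulationState) -> SimulationState:
    """Advance one 30-day cycle in place (also returns the state).

    Order within a cycle: breeding adults spawn; kernels drift and settle;
    the whole settled pool (including this cycle's recruits) takes the
    adult-mortality draw; survivors age and those reaching the maturation
    age are promoted, breeding from the next cycle on.
    """
    cfg, stack, fields, rng = state.config, state.stack, state.fields, state.rng
    cycle = state.cycle + 1
    month = state.calendar_month
    m_idx = month - 1
    alive_start = [p for p in state.populations if p.alive]

    released = 0
    settled_new: list[PopulationKernel] = []
    if cfg.month_in_breeding_window(month):
        settle_cal = settlement_month(month, cfg)
        settle_idx = settle_cal - 1
        surviving_origins: list[tuple[int, int]] = []
        for adult in alive_start:
            if not adult.breeding:
                continue
            for _ in range(cfg.spawns_per_cycle):
                state.events.append(Event(cycle, month, adult.cell, "spawn"))
                released += cfg.kernel_count
                survive = rng.random(cfg.kernel_count) < fields.survival
                surviving_origins.extend([adult.cell] * int(survive.sum()))
        if surviving_origins:
            cells, _, ok = trace_transit_batch(
                stack, np.array(surviving_origins), month, cfg, rng, fields)
            for (r, c), good in zip(cells, ok):
                if not good:
                    continue
                r, c = int(r), int(c)
                if stack.land_mask[r, c] or not fields.suitable_all[settle_idx, r, c]:
                    continue
                settled_new.append(PopulationKernel(
                    cell=(r, c), settlement_cycle=cycle))
                state.settled_count[r, c] += 1
                state.events.append(Event(cycle, settle_cal, (r, c), "settle"))

    state.populations.extend(settled_new)

    pool = [p for p in state.populations if p.alive]
    deaths = 0
    if pool:
        draws = rng.random(len(pool))
        for p, u in zip(pool, draws):
            if p.is_founder and cfg.founder_immortal:
                continue
            if u < fields.adult_death:
                p.alive = False
                deaths += 1
                state.events.append(Event(cycle, month, p.cell, "death"))

    promotions = 0
    for p in state.populations:
        if not p.alive:
            continue
        p.age += 1
        if not p.breeding and p.age >= cfg.breeding_age:
            p.breeding = True
            promotions += 1
            state.events.append(Event(cycle, month, p.cell, "promote"))
            r, c = p.cell
            if np.isnan(state.establishment_cycle[r, c]):
                state.establishment_cycle[r, c] = cycle

    state.cycle_stats.append(CycleStats(
        cycle=cycle, calendar_month=month,
        alive_start=len(alive_start), kernels_released=released,
        settled=len(settled_new), deaths=deaths, promotions=promotions,
        alive_end=sum(p.alive for p in state.populations),
    ))
    state.cycle = cycle
    return state


@dataclass
class SimulationResult:
    """Event log and per-cell settlement/establishment record of one run."""

    grid: "object"
    events: list[Event]
    settled_count: np.ndarray
    establishment_cycle: np.ndarray  # NaN where never established
    cycle_stats: list[CycleStats]
    months: int
    seed: int | None
    config_hash: str
    origin: tuple[int, int]

    def settle_events(self) -> list[Event]:
        return [e for e in self.events if e.kind == "settle"]

    def total_settled(self) -> int:
        return int(self.settled_count.sum())

    def events_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            lat, lon = self.grid.cell_center(*e.cell)
            rows.append((e.cycle, e.calendar_month, lat, lon, e.kind))
        return pd.DataFrame(rows, columns=["cycle", "calendar_month", "lat", "lon", "event"])

    def write_events_csv(self, path) -> None:
        self.events_dataframe().to_csv(path, index=False)


def run_simulation(config: ModelConfig, stack: EnvironmentStack,
                   origin, months: int | None = None,
                   seed: int | None = None,
                   fields: TransitFields | None = None) -> SimulationResult:
    """Run a full simulation from a single founding breeding adult.

    ``origin`` is a grid cell ``(row, col)`` of ints, or a ``(lat, lon)``
    pair of floats.  The founder is created breeding-eligible (a breeding
    population is assumed to persist at the origin) but is subject to the
    adult mortality draw like every other kernel unless
    ``config.founder_immortal``.  ``months=0`` returns just the founder.
    """
    if months is None:
        months = config.cycles
    if months < 0:
        raise EngineError("months must be >= 0")
    origin_cell = _resolve_origin(stack, origin)
    if stack.land_mask[origin_cell]:
        raise EngineError(f"origin {origin} is on land")
    if seed is None:
        seed = config.rng_seed if config.rng_seed is not None else 0
    rng = np.random.default_rng(seed)
    fields = fields or TransitFields(stack, config)

    founder = PopulationKernel(cell=origin_cell, settlement_cycle=0,
                               age=config.breeding_age, breeding=True,
                               is_founder=True)
    state = SimulationState(config=config, stack=stack, fields=fields,
                            rng=rng, populations=[founder])
    state.establishment_cycle[origin_cell] = 0

    for _ in range(months):
        step_month(state)

    return SimulationResult(
        grid=stack.grid,
        events=state.events,
        settled_count=state.settled_count,
        establishment_cycle=state.establishment_cycle,
        cycle_stats=state.cycle_stats,
        months=months,
        seed=seed,
        config_hash=config.config_hash(),
        origin=origin_cell,
    )


def _resolve_origin(stack: EnvironmentStack, origin) -> tuple[int, int]:
    r, c = origin
    if isinstance(r, (int, np.integer)) and isinstance(c, (int, np.integer)):
        R, C = stack.grid.n_rows, stack.grid.n_cols
        if not (0 <= r < R and 0 <= c < C):
            raise EngineError(f"origin cell {origin} outside grid")
        return int(r), int(c)
    return stack.grid.cell_of(float(r), float(c))
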