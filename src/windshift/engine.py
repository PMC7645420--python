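"""Stochastic cellular range-shift simulation.

Annual time steps on a raster: every suitable-but-empty cell gathers all
occupied cells within the short-distance search radius, combines their
per-diaspore landing probabilities into a colonization probability, and is
colonized by a single Bernoulli draw. Rare long-distance dispersal (LDD) can
colonize cells farther than a minimum distance from any source. Every
``period_length`` years the climatic-suitability map is updated: occupied
cells turning unsuitable are lost, cells turning suitable become empty
targets, and the per-pixel dispersal kernels are rebuilt from that period's
wind field. After the projection horizon, the simulation can be continued
under frozen conditions to measure the colonization time-lag.

Probabilities combine as

    P_disp = 1 − (1 − P_seed)^SuccessfulSeeds          (per source)
    P_col  = 1 − Π_i (1 − P_disp,i · P_mat,i)          (over sources)

with P_seed the source kernel's ring mass for the pair's distance class
divided by the class cell count. Newly colonized cells act as sources only
from the next step (synchronous update, demography ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .kernels import KernelField, SpeciesTraits, build_kernel_field, ring_offsets, surface_count
from .landscape import SuitabilityStack
from .micromet import DEFAULT_CONSTANTS, WindProfileConstants

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "ReplicateResult",
    "RunResult",
    "TimelagResult",
    "p_disp",
    "p_col",
    "dispersal_step",
    "ldd_step",
    "apply_environment_update",
    "run_simulation",
    "run_timelag",
    "run_timelag_single",
]

WIND_MODES = ("monthly_average", "daily_maximum")


def p_disp(p_seed: float, successful_seeds: int) -> float:
    """Per-source colonization probability from one diaspore's landing probability."""
    if successful_seeds < 1:
        raise ValueError("successful_seeds must be >= 1")
    if not 0.0 <= p_seed <= 1.0:
        raise ValueError("p_seed must be a probability")
    return -math.expm1(successful_seeds * math.log1p(-p_seed)) if p_seed < 1.0 else 1.0


def p_col(contributions: Sequence[tuple[float, float]]) -> float:
    """Combined colonization probability over (P_disp, P_mat) contributions."""
    log_miss = 0.0
    for pd_i, pm_i in contributions:
        if not (0.0 <= pd_i <= 1.0 and 0.0 <= pm_i <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        p = pd_i * pm_i
        if p >= 1.0:
            return 1.0
        log_miss += math.log1p(-p)
    return -math.expm1(log_miss)


@dataclass
class SimulationConfig:
    """Everything a run needs.

    wind_mean/wind_max hold one 10-m wind grid per climatic period;
    ``wind_mode`` selects which is used to build kernels. Distances
    (``ldd_min_distance``) are in map units; ``d_max`` is the short-distance
    search radius in cells.
    """

    suitability: SuitabilityStack
    wind_mean: list[np.ndarray]
    wind_max: list[np.ndarray]
    canopy: np.ndarray
    traits: SpeciesTraits
    wind_mode: str = "monthly_average"
    constants: WindProfileConstants = DEFAULT_CONSTANTS
    p_mat: float = 1.0
    n_disp: int = 1
    years: int = 40
    replicates: int = 30
    seed: int = 0
    ldd_min_distance: float = 10000.0
    d_max: int = 10

    def __post_init__(self) -> None:
        if self.wind_mode not in WIND_MODES:
            raise ValueError(f"wind_mode must be one of {WIND_MODES}")
        if not 0.0 < self.p_mat <= 1.0:
            raise ValueError("p_mat must lie in (0, 1]")
        if self.n_disp < 1 or self.replicates < 1:
            raise ValueError("n_disp and replicates must be >= 1")
        if self.years < 0:
            raise ValueError("years must be >= 0")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")
        shape = self.suitability.landscape.shape
        for name, grids in (("wind_mean", self.wind_mean), ("wind_max", self.wind_max)):
            if not grids:
                raise ValueError(f"{name} needs at least one grid")
            for g in grids:
                if np.asarray(g).shape != shape:
                    raise ValueError(f"{name} grid shape does not match the landscape")
        if np.asarray(self.canopy).shape != shape:
            raise ValueError("canopy grid shape does not match the landscape")
        n_periods = self.years // self.suitability.period_length
        if self.years % self.suitability.period_length:
            raise ValueError("years must be a multiple of the period length")
        if len(self.suitability) < n_periods + 1:
            raise ValueError(
                f"{self.years}-year run needs {n_periods + 1} suitability slices, "
                f"got {len(self.suitability)}"
            )

    @property
    def n_periods(self) -> int:
        return self.years // self.suitability.period_length

    def wind_grid(self, period: int) -> np.ndarray:
        grids = self.wind_mean if self.wind_mode == "monthly_average" else self.wind_max
        return np.asarray(grids[min(period, len(grids) - 1)], dtype=float)

    def echo(self) -> dict:
        ls = self.suitability.landscape
        return {
            "landscape": {"n_rows": ls.n_rows, "n_cols": ls.n_cols,
                          "cell_size": float(ls.cell_size)},
            "slices": self.suitability.labels,
            "period_length": self.suitability.period_length,
            "wind_mode": self.wind_mode,
            "traits": {"Vt": self.traits.Vt, "H": self.traits.H,
                       "spore_class": self.traits.spore_class,
                       "successful_seeds": self.traits.successful_seeds,
                       "p_ldd": self.traits.p_ldd},
            "p_mat": self.p_mat, "n_disp": self.n_disp, "years": self.years,
            "replicates": self.replicates, "seed": self.seed,
            "ldd_min_distance": self.ldd_min_distance, "d_max": self.d_max,
        }


@dataclass
class SimulationState:
    """Per-cell state of one replicate.

    ``colonized_year`` is −1 for cells never colonized during the run
    (initially occupied cells keep −1: occupying the start map is not a
    colonization event). ``newly_suitable_slice`` records the first slice at
    which a cell turned suitable, −1 otherwise.
    """

    suitable: np.ndarray
    occupied: np.ndarray
    nodata: np.ndarray
    initially_suitable: np.ndarray
    colonized_year: np.ndarray
    ever_colonized: np.ndarray
    newly_suitable: np.ndarray
    newly_suitable_slice: np.ndarray
    lost_ever: np.ndarray
    colonized_then_extinct: np.ndarray
    year: int = 0
    rng: np.random.Generator | None = None

    @classmethod
    def initial(cls, stack: SuitabilityStack, rng: np.random.Generator | None = None):
        grid0 = stack.grid(0).astype(bool) & ~stack.landscape.nodata_mask
        shape = stack.landscape.shape
        return cls(
            suitable=grid0.copy(),
            occupied=grid0.copy(),
            nodata=stack.landscape.nodata_mask.copy(),
            initially_suitable=grid0.copy(),
            colonized_year=np.full(shape, -1, dtype=np.int32),
            ever_colonized=np.zeros(shape, dtype=bool),
            newly_suitable=np.zeros(shape, dtype=bool),
            newly_suitable_slice=np.full(shape, -1, dtype=np.int32),
            lost_ever=np.zeros(shape, dtype=bool),
            colonized_then_extinct=np.zeros(shape, dtype=bool),
            year=0,
            rng=rng,
        )

    def copy(self) -> "SimulationState":
        return SimulationState(
            **{f: getattr(self, f).copy() for f in (
                "suitable", "occupied", "nodata", "initially_suitable",
                "colonized_year", "ever_colonized", "newly_suitable",
                "newly_suitable_slice", "lost_ever", "colonized_then_extinct")},
            year=self.year,
            rng=self.rng,
        )

    @property
    def targets(self) -> np.ndarray:
        """Cells open to colonization: suitable, empty, inside the study area."""
        return self.suitable & ~self.occupied & ~self.nodata

    def colonize(self, new: np.ndarray) -> None:
        self.occupied |= new
        self.colonized_year[new] = self.year
        self.ever_colonized |= new


def _log_miss_stack(kernel_field: KernelField, traits: SpeciesTraits, p_mat: float) -> np.ndarray:
    """Per-pixel, per-class log(1 − P_disp·P_mat) of the *source* pixel.

    Shape (d_max, n_rows, n_cols). NoData/calm pixels contribute 0.
    """
    masses = kernel_field.mass_grids()
    surfaces = np.array(
        [surface_count(j, kernel_field.d_max) for j in range(1, kernel_field.d_max + 1)],
        dtype=float,
    ).reshape(-1, 1, 1)
    p_seed = masses / surfaces
    with np.errstate(divide="ignore"):
        disp = -np.expm1(traits.successful_seeds * np.log1p(-p_seed))
        return np.log1p(-np.clip(disp * p_mat, 0.0, 1.0))


def _shift_add(acc: np.ndarray, src: np.ndarray, dr: int, dc: int) -> None:
    # Source cell (r, c) contributes to target (r + dr, c + dc).
    n_rows, n_cols = acc.shape
    r0, r1 = max(dr, 0), n_rows + min(dr, 0)
    c0, c1 = max(dc, 0), n_cols + min(dc, 0)
    if r0 >= r1 or c0 >= c1:
        return
    acc[r0:r1, c0:c1] += src[r0 - dr:r1 - dr, c0 - dc:c1 - dc]


def colonization_probability(
    state: SimulationState, log_miss: np.ndarray, d_max: int
) -> np.ndarray:
    """Analytic one-step P_col of every cell given the current sources."""
    acc = np.zeros(state.occupied.shape)
    offsets = ring_offsets(d_max)
    occ = state.occupied
    if occ.any():
        for j, offs in enumerate(offsets, start=1):
            lj = np.where(occ, log_miss[j - 1], 0.0)
            if not lj.any():
                continue
            for dr, dc in offs:
                _shift_add(acc, lj, dr, dc)
    pcol = -np.expm1(acc)
    pcol[~state.targets] = 0.0
    return pcol


def dispersal_step(
    state: SimulationState,
    log_miss: np.ndarray,
    d_max: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous short-distance dispersal step; returns the new-colonization mask.

    A uniform draw is made for *every* cell so that runs with matched seeds
    remain aligned draw-for-draw whatever the occupancy pattern — this makes
    monotonicity comparisons across parameter values a true coupling.
    """
    pcol = colonization_probability(state, log_miss, d_max)
    u = rng.random(state.occupied.shape)
    new = state.targets & (u < pcol)
    state.colonize(new)
    return new


def ldd_step(
    state: SimulationState,
    p_ldd: float,
    ldd_min_distance: float,
    cell_size: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Long-distance dispersal: per-target Bernoulli beyond the minimum range.

    A cell is eligible when its nearest occupied cell (centroid distance)
    lies farther than ``ldd_min_distance`` and at least one source exists;
    the maximum LDD distance is unlimited.
    """
    if not 0.0 <= p_ldd <= 1.0:
        raise ValueError("p_ldd must be a probability")
    u = rng.random(state.occupied.shape)  # always drawn: keeps streams aligned
    if p_ldd == 0.0 or not state.occupied.any():
        return np.zeros(state.occupied.shape, dtype=bool)
    dist = distance_transform_edt(~state.occupied) * cell_size
    new = state.targets & (dist > ldd_min_distance) & (u < p_ldd)
    state.colonize(new)
    return new


def apply_environment_update(
    state: SimulationState, next_grid: np.ndarray, slice_index: int
) -> None:
    """Switch to the next climatic period's suitability map.

    Occupied cells turning unsuitable are lost (and, if colonized during the
    run, flagged extinct-after-colonization — they still count as effective
    colonization events). Cells turning suitable become empty targets tagged
    newly suitable with this slice index.
    """
    nxt = np.asarray(next_grid).astype(bool) & ~state.nodata
    if nxt.shape != state.suitable.shape:
        raise ValueError("next suitability slice does not match the landscape")
    turning_unsuitable = state.occupied & ~nxt
    state.lost_ever |= turning_unsuitable
    state.colonized_then_extinct |= turning_unsuitable & (state.colonized_year >= 0)
    state.occupied &= nxt
    newly = nxt & ~state.suitable
    first = newly & (state.newly_suitable_slice < 0)
    state.newly_suitable_slice[first] = slice_index
    state.newly_suitable |= newly
    state.suitable = nxt


@dataclass
class ReplicateResult:
    """Counters of one replicate (plus its final state for continuation runs)."""

    replicate: int
    effective_colonizations: int
    newly_suitable_total: int
    initially_suitable_total: int
    lost_total: int
    occupied_at_end: int
    colonized_then_extinct: int
    state: SimulationState | None = None

    def counters(self) -> dict:
        return {
            "replicate": self.replicate,
            "effective_colonizations": self.effective_colonizations,
            "newly_suitable_total": self.newly_suitable_total,
            "initially_suitable_total": self.initially_suitable_total,
            "lost_total": self.lost_total,
            "occupied_at_end": self.occupied_at_end,
            "colonized_then_extinct": self.colonized_then_extinct,
        }


@dataclass
class RunResult:
    """All replicates of one configuration."""

    config: SimulationConfig
    replicates: list[ReplicateResult]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([r.counters() for r in self.replicates])

    def config_echo(self) -> dict:
        return self.config.echo()

    @property
    def newly_suitable_total(self) -> int:
        return self.replicates[0].newly_suitable_total

    @property
    def initially_suitable_total(self) -> int:
        return self.replicates[0].initially_suitable_total

    @property
    def lost_total(self) -> int:
        return self.replicates[0].lost_total

    def mean_effective_colonizations(self) -> float:
        return float(np.mean([r.effective_colonizations for r in self.replicates]))


def _replicate_rng(seed: int, replicate: int, purpose: int = 0) -> np.random.Generator:
    # One independent stream per replicate: order-independent and parallel-safe.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(purpose, replicate)))


def _census(state: SimulationState, replicate: int, keep_state: bool) -> ReplicateResult:
    effective = int((state.ever_colonized & state.newly_suitable).sum())
    lost = int((state.initially_suitable & ~state.suitable).sum())
    return ReplicateResult(
        replicate=replicate,
        effective_colonizations=effective,
        newly_suitable_total=int(state.newly_suitable.sum()),
        initially_suitable_total=int(state.initially_suitable.sum()),
        lost_total=lost,
        occupied_at_end=int(state.occupied.sum()),
        colonized_then_extinct=int(state.colonized_then_extinct.sum()),
        state=state if keep_state else None,
    )


def _period_log_miss(config: SimulationConfig) -> list[np.ndarray]:
    """Per-period log(1 − P_disp·P_mat) stacks (kernels rebuilt per wind slice)."""
    ls = config.suitability.landscape
    out = []
    for period in range(max(config.n_periods, 1)):
        kf = build_kernel_field(
            config.wind_grid(period),
            config.canopy,
            config.traits,
            config.constants,
            cell_size=ls.cell_size,
            d_max=config.d_max,
            nodata_mask=ls.nodata_mask,
        )
        out.append(_log_miss_stack(kf, config.traits, config.p_mat))
    return out


def run_simulation(config: SimulationConfig, keep_states: bool = True) -> RunResult:
    """Run all replicates of one configuration.

    Initial occupancy is every suitable cell of slice 0. Each climatic
    period: kernels from that period's wind grid, ``period_length`` annual
    steps (each ``n_disp`` × short-distance dispersal then LDD), then the
    suitability update. Results are a pure function of (config, seed).
    """
    stack = config.suitability
    cell = stack.landscape.cell_size
    period_len = stack.period_length
    log_miss = _period_log_miss(config) if config.years > 0 else []

    results = []
    for rep in range(config.replicates):
        rng = _replicate_rng(config.seed, rep)
        state = SimulationState.initial(stack, rng)
        for year in range(1, config.years + 1):
            period = (year - 1) // period_len
            state.year = year
            for _ in range(config.n_disp):
                dispersal_step(state, log_miss[period], config.d_max, rng)
                ldd_step(state, config.traits.p_ldd, config.ldd_min_distance, cell, rng)
            if year % period_len == 0:
                slice_idx = year // period_len
                if slice_idx < len(stack):
                    apply_environment_update(state, stack.grid(slice_idx), slice_idx)
        results.append(_census(state, rep, keep_states))
    return RunResult(config=config, replicates=results)


@dataclass
class TimelagResult:
    """Years past the projection horizon to full colonization, per replicate."""

    lags: list[int]
    censored: list[bool]
    max_years: int = 500


def run_timelag_single(
    config: SimulationConfig,
    state: SimulationState,
    max_years: int = 500,
    log_miss: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, bool]:
    """Continue one replicate under frozen final conditions.

    Runs annual steps with the final suitability map and the final period's
    kernels until every newly-suitable cell (still suitable at the horizon)
    has been effectively colonized at least once; returns (years, censored).
    """
    if log_miss is None:
        log_miss = _period_log_miss(config)[-1]
    pending = lambda s: s.newly_suitable & s.suitable & ~s.ever_colonized
    work = state.copy()
    if rng is None:
        rng = _replicate_rng(config.seed, 0, purpose=1)
    if not pending(work).any():
        return 0, False
    cell = config.suitability.landscape.cell_size
    for extra in range(1, max_years + 1):
        work.year = config.years + extra
        for _ in range(config.n_disp):
            dispersal_step(work, log_miss, config.d_max, rng)
            ldd_step(work, config.traits.p_ldd, config.ldd_min_distance, cell, rng)
        if not pending(work).any():
            return extra, False
    return max_years, True


def run_timelag(config: SimulationConfig, result: RunResult, max_years: int = 500) -> TimelagResult:
    """Time-lag continuation for every replicate of a completed run."""
    log_miss = _period_log_miss(config)[-1]
    lags, censored = [], []
    for rep in result.replicates:
        if rep.state is None:
            raise ValueError("run_simulation must keep states for a time-lag continuation")
        rng = _replicate_rng(config.seed, rep.replicate, purpose=1)
        lag, cens = run_timelag_single(config, rep.state, max_years, log_miss, rng)
        lags.append(lag)
        censored.append(cens)
    return TimelagResult(lags=lags, censored=censored, max_years=max_years)
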