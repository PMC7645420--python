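"""Synthetic landscapes: suitability bands, wind fields, canopy, trait presets.

Emulates the statistical structure of the real inputs (gridded climatic
suitability projections, 10-m wind surfaces, a canopy-height map, species
trait tables) so every pipeline stage runs without downloads. The default
fixture is a 100×100 grid of 1-km cells with the initial map plus four
decadal slices, a horizontal suitable band shifting poleward (toward row 0)
each decade — the canonical climate-tracking scenario in which loss and gain
per transition are exact set arithmetic.

All generators are deterministic functions of the spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import ALLOWED_P_LDD, ALLOWED_RELEASE_HEIGHTS, SpeciesTraits
from .landscape import Landscape, SuitabilityStack

__all__ = ["SynthSpec", "make_landscape", "make_suitability_stack",
           "make_wind_fields", "make_canopy", "trait_preset", "TRAIT_PRESETS"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic study landscape.

    ``wind_mean``/``wind_max`` are either constants (m/s) or ``(north,
    south)`` pairs defining a linear north–south gradient. ``canopy`` is a
    constant height (m) or ``(north_value, south_value, split_row)`` for a
    two-zone map. The suitable band starts at the southern edge and shifts
    ``shift_per_slice`` rows poleward per slice.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1000.0
    band_width: int = 20
    shift_per_slice: int = 5
    n_slices: int = 5
    wind_mean: float | tuple[float, float] = 5.0
    wind_max: float | tuple[float, float] = 10.0
    canopy: float | tuple[float, float, int] = 0.3
    seed: int = 0
    trait_preset: str = "medium"

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.band_width, self.n_slices) < 1:
            raise ValueError("grid dimensions, band width and slice count must be >= 1")
        if self.shift_per_slice < 0:
            raise ValueError("shift_per_slice must be >= 0")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.band_width + self.shift_per_slice * (self.n_slices - 1) > self.n_rows:
            raise ValueError("the shifting band leaves the grid before the last slice")


def make_landscape(spec: SynthSpec) -> Landscape:
    return Landscape(spec.n_rows, spec.n_cols, spec.cell_size, origin=(0.0, 0.0))


def make_suitability_stack(spec: SynthSpec) -> SuitabilityStack:
    """Horizontal suitable band shifting poleward by ``shift_per_slice`` rows per slice."""
    landscape = make_landscape(spec)
    base_top = spec.n_rows - spec.band_width  # band initially at the southern edge
    slices = []
    for s in range(spec.n_slices):
        top = base_top - s * spec.shift_per_slice
        grid = np.zeros((spec.n_rows, spec.n_cols), dtype=np.uint8)
        grid[top:top + spec.band_width, :] = 1
        label = f"{2010 + 10 * s}" if s == 0 else f"{2000 + 10 * s}-{2010 + 10 * s}"
        slices.append((label, grid))
    return SuitabilityStack(landscape=landscape, slices=slices, period_length=10)


def _field(value: float | tuple[float, float], spec: SynthSpec) -> np.ndarray:
    shape = (spec.n_rows, spec.n_cols)
    if np.isscalar(value):
        if value < 0:
            raise ValueError("wind speed must be non-negative")
        return np.full(shape, float(value))
    north, south = value
    if north < 0 or south < 0:
        raise ValueError("wind speed must be non-negative")
    rows = np.linspace(north, south, spec.n_rows).reshape(-1, 1)
    return np.broadcast_to(rows, shape).copy()


def make_wind_fields(spec: SynthSpec) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """One (mean, max) pair of 10-m wind grids per climatic period.

    Constant or linear north–south gradient; the max field is pointwise ≥
    the mean field (raised to the mean where the inputs would violate that).
    """
    n_periods = max(spec.n_slices - 1, 1)
    mean = _field(spec.wind_mean, spec)
    vmax = np.maximum(_field(spec.wind_max, spec), mean)
    return [mean.copy() for _ in range(n_periods)], [vmax.copy() for _ in range(n_periods)]


def make_canopy(spec: SynthSpec) -> np.ndarray:
    """Constant or two-zone canopy-height map (m)."""
    shape = (spec.n_rows, spec.n_cols)
    if np.isscalar(spec.canopy):
        if spec.canopy <= 0:
            raise ValueError("canopy height must be positive")
        return np.full(shape, float(spec.canopy))
    north, south, split = spec.canopy
    if north <= 0 or south <= 0:
        raise ValueError("canopy height must be positive")
    grid = np.full(shape, float(south))
    grid[: int(split), :] = float(north)
    return grid


# Settling velocities are Stokes-law estimates for unit-density spheres at the
# class-typical diameters (~13, 30, 75 and 150 µm); they increase with spore
# size, and the asexual class stands for large vegetative propagules. Release
# heights pair each class with its typical habitat stratum.
TRAIT_PRESETS: dict[str, SpeciesTraits] = {
    "small": SpeciesTraits(Vt=0.005, H=10.0, spore_class="small",
                           successful_seeds=1, p_ldd=1e-3),
    "medium": SpeciesTraits(Vt=0.03, H=1.0, spore_class="medium",
                            successful_seeds=1, p_ldd=1e-3),
    "large": SpeciesTraits(Vt=0.17, H=0.03, spore_class="large",
                           successful_seeds=1, p_ldd=1e-3),
    "asexual": SpeciesTraits(Vt=0.68, H=0.03, spore_class="asexual",
                             successful_seeds=1, p_ldd=1e-3),
}


def trait_preset(name: str) -> SpeciesTraits:
    """Named trait preset; Vt increases small < medium < large < asexual."""
    try:
        traits = TRAIT_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown trait preset {name!r}; "
                         f"choose from {sorted(TRAIT_PRESETS)}") from None
    assert traits.H in ALLOWED_RELEASE_HEIGHTS
    assert traits.p_ldd in ALLOWED_P_LDD
    return traits
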