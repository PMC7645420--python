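"""WALD (inverse-Gaussian) wind-dispersal kernels and their ring discretization.

The WALD model gives the probability density of a wind-borne diaspore
travelling a horizontal distance x before deposition as an inverse-Gaussian
distribution

    P(x) = sqrt(λ′ / (2π x³)) · exp(−λ′ (x − μ′)² / (2 μ′² x)),

with location μ′ = H·Ū/Vt and shape λ′ = (H/σ)², σ² = 2·K·h·σ_w/Ū, where H is
the release height, Ū the mean horizontal wind at H, Vt the diaspore settling
velocity, h the canopy height and σ_w the vertical-turbulence scale. The
model assumes tight coupling between particle and air parcel and instant
attainment of terminal velocity — good approximations for spores and other
small, low-Reynolds-number particles.

On a raster, dispersal from a source cell is isotropic, so the density is
folded into *distance classes*: class j contains every cell whose centroid
lies at Euclidean distance in ((j−0.5)·cell, (j+0.5)·cell] from the source
centroid; Surface_j counts those cells. The probability that a single
diaspore lands in one particular cell of class j is the ring mass
(a closed-form CDF difference) divided by Surface_j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import invgauss

from . import micromet
from .micromet import WindProfileConstants, DEFAULT_CONSTANTS

__all__ = [
    "SpeciesTraits",
    "WaldParams",
    "Kernel",
    "KernelField",
    "ring_offsets",
    "surface_count",
    "wald_params",
    "wald_pdf",
    "wald_cdf",
    "sample_wald",
    "discretize_kernel",
    "build_kernel_field",
]

SPORE_CLASSES = ("small", "medium", "large", "asexual")
ALLOWED_RELEASE_HEIGHTS = (0.03, 1.0, 10.0)
ALLOWED_P_LDD = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)


@dataclass(frozen=True)
class SpeciesTraits:
    """Dispersal traits of one species.

    Vt: settling velocity (m/s), increasing with spore size. H: release
    height (m); 0.03, 1 and 10 m correspond to ground-dwelling, saxicolous
    and epiphytic habitats. successful_seeds: number of independently
    dispersing diaspores a source cell contributes per step. p_ldd:
    probability of a long-distance colonization event per eligible cell and
    year.
    """

    Vt: float
    H: float
    spore_class: str = "medium"
    successful_seeds: int = 1
    p_ldd: float = 0.0

    def __post_init__(self) -> None:
        if not self.Vt > 0:
            raise ValueError("settling velocity Vt must be positive")
        if not self.H > 0:
            raise ValueError("release height H must be positive")
        if self.spore_class not in SPORE_CLASSES:
            raise ValueError(f"unknown spore class {self.spore_class!r}")
        if self.successful_seeds < 1:
            raise ValueError("successful_seeds must be >= 1")
        if not 0.0 <= self.p_ldd <= 1.0:
            raise ValueError("p_ldd must be a probability")


@dataclass(frozen=True)
class WaldParams:
    """Inverse-Gaussian parameters of one kernel: location μ′ and shape λ′ (m)."""

    mu: float
    lam: float

    @property
    def degenerate(self) -> bool:
        """True for calm/invalid conditions: the kernel carries no mass."""
        return not (
            math.isfinite(self.mu) and math.isfinite(self.lam) and self.mu > 0 and self.lam > 0
        )


def wald_params(H, U_H, Vt, h, sigma_w, K: float = 0.4) -> WaldParams:
    """WALD parameters from release height, wind, settling velocity and canopy.

    μ′ = H·Ū_H/Vt; σ² = 2·K·h·σ_w/Ū_H; λ′ = (H/σ)² = H²·Ū_H/(2·K·h·σ_w).
    Calm conditions (Ū_H = 0 or σ_w = 0) give a degenerate, massless kernel
    rather than an error: a calm cell simply contributes no dispersal.
    """
    if U_H <= 0 or sigma_w <= 0:
        return WaldParams(mu=0.0, lam=0.0)
    mu = H * U_H / Vt
    lam = H * H * U_H / (2.0 * K * h * sigma_w)
    return WaldParams(mu=mu, lam=lam)


def wald_pdf(x, params: WaldParams):
    """Inverse-Gaussian density of dispersal distance, per metre."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("distance must be positive")
    if params.degenerate:
        out = np.zeros_like(x)
        return float(out) if out.ndim == 0 else out
    mu, lam = params.mu, params.lam
    out = np.sqrt(lam / (2.0 * np.pi * x**3)) * np.exp(
        -lam * (x - mu) ** 2 / (2.0 * mu**2 * x)
    )
    return float(out) if out.ndim == 0 else out


def wald_cdf(x, params: WaldParams):
    """Closed-form inverse-Gaussian CDF (scipy parameterization μ′/λ′, scale λ′)."""
    x = np.asarray(x, dtype=float)
    if params.degenerate:
        out = np.zeros_like(x)
        return float(out) if out.ndim == 0 else out
    out = invgauss.cdf(x, mu=params.mu / params.lam, scale=params.lam)
    return float(out) if out.ndim == 0 else out


def sample_wald(params: WaldParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw dispersal distances by the Michael–Schucany–Haas transform."""
    if params.degenerate:
        raise ValueError("cannot sample a degenerate kernel")
    mu, lam = params.mu, params.lam
    y = rng.standard_normal(size) ** 2
    x = mu + mu * mu * y / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * y + (mu * y) ** 2
    )
    z = rng.random(size)
    return np.where(z <= mu / (mu + x), x, mu * mu / x)


@lru_cache(maxsize=None)
def ring_offsets(d_max: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Cell offsets of each distance class j = 1..d_max.

    Class j holds offsets whose centroid distance lies in (j−0.5, j+0.5]
    cell units. (No integer-offset distance falls exactly on a half-integer
    boundary, so nearest-integer rounding classifies exactly.)
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    rings: list[list[tuple[int, int]]] = [[] for _ in range(d_max)]
    r = d_max + 1
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if dr == 0 and dc == 0:
                continue
            j = int(round(math.hypot(dr, dc)))
            if 1 <= j <= d_max:
                rings[j - 1].append((dr, dc))
    return tuple(tuple(ring) for ring in rings)


def surface_count(j: int, d_max: int | None = None) -> int:
    """Number of cells in distance class j (Surface_j)."""
    if j < 1:
        raise ValueError("distance class must be >= 1")
    d = d_max if d_max is not None and d_max >= j else j
    return len(ring_offsets(d)[j - 1])


@dataclass(frozen=True)
class Kernel:
    """A discretized kernel: per-class ring masses on one cell geometry."""

    cell_size: float
    masses: np.ndarray  # shape (d_max,), masses[j-1] = ring mass of class j
    params: WaldParams

    @property
    def d_max(self) -> int:
        return len(self.masses)

    @property
    def surfaces(self) -> np.ndarray:
        return np.array([surface_count(j, self.d_max) for j in range(1, self.d_max + 1)])

    def p_seed(self) -> np.ndarray:
        """Per-cell single-diaspore landing probability for each class."""
        return self.masses / self.surfaces


def discretize_kernel(params: WaldParams, cell_size: float, d_max: int) -> Kernel:
    """Fold the continuous kernel into per-class ring masses.

    mass_j integrates the density over ((j−0.5)·cell, (j+0.5)·cell], via
    closed-form CDF differences; the cumulative sum therefore telescopes to
    F((d_max+0.5)·cell) − F(0.5·cell).
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    if params.degenerate:
        return Kernel(cell_size, np.zeros(d_max), params)
    if not (math.isfinite(params.mu) and math.isfinite(params.lam)):
        raise ValueError("non-finite kernel parameters")
    bounds = (np.arange(d_max + 1) + 0.5) * cell_size
    cdf = wald_cdf(bounds, params)
    return Kernel(cell_size, np.diff(cdf), params)


@dataclass
class KernelField:
    """Per-pixel kernels for one time slice, deduplicated.

    ``class_index[r, c]`` indexes into ``kernels``; −1 marks NoData pixels.
    Pixels sharing identical wind and canopy values share one kernel entry.
    """

    shape: tuple[int, int]
    cell_size: float
    d_max: int
    class_index: np.ndarray
    kernels: list[Kernel] = field(default_factory=list)

    @property
    def n_unique(self) -> int:
        return len(self.kernels)

    def kernel_at(self, row: int, col: int) -> Kernel | None:
        idx = int(self.class_index[row, col])
        return None if idx < 0 else self.kernels[idx]

    def mass_grids(self) -> np.ndarray:
        """Dense (d_max, n_rows, n_cols) array of ring masses (0 at NoData)."""
        table = np.zeros((self.n_unique + 1, self.d_max))
        for i, k in enumerate(self.kernels):
            table[i] = k.masses
        return np.moveaxis(table[self.class_index], -1, 0)

    def to_frame(self):
        """Human-readable table of the distinct (μ′, λ′, masses) tuples."""
        import pandas as pd

        rows = []
        for i, k in enumerate(self.kernels):
            row = {"kernel": i, "mu_m": k.params.mu, "lambda_m": k.params.lam,
                   "n_pixels": int((self.class_index == i).sum())}
            row.update({f"mass_{j}": k.masses[j - 1] for j in range(1, self.d_max + 1)})
            rows.append(row)
        return pd.DataFrame(rows)


def build_kernel_field(
    wind_grid: np.ndarray,
    canopy_grid: np.ndarray,
    traits: SpeciesTraits,
    constants: WindProfileConstants = DEFAULT_CONSTANTS,
    *,
    cell_size: float = 1000.0,
    d_max: int = 10,
    nodata_mask: np.ndarray | None = None,
) -> KernelField:
    """Chain micrometeorology → WALD parameters → discretization per pixel.

    The kernel of a pixel is parameterized by that pixel's own (source) wind
    and canopy values. Pixels with identical (wind, canopy) pairs share one
    discretized kernel.
    """
    wind = np.asarray(wind_grid, dtype=float)
    canopy = np.asarray(canopy_grid, dtype=float)
    if wind.shape != canopy.shape:
        raise ValueError("wind and canopy grids must share one geometry")
    if nodata_mask is None:
        nodata_mask = np.zeros(wind.shape, dtype=bool)
    nodata_mask = nodata_mask | ~np.isfinite(wind) | ~np.isfinite(canopy)

    pairs = np.stack([wind.ravel(), canopy.ravel()], axis=1)
    pairs[nodata_mask.ravel()] = np.nan
    unique, inverse = np.unique(pairs, axis=0, return_inverse=True)
    class_index = np.full(wind.shape, -1, dtype=np.int64)
    kernels: list[Kernel] = []
    remap = np.full(len(unique), -1, dtype=np.int64)
    for i, (u_s, h) in enumerate(unique):
        if not (np.isfinite(u_s) and np.isfinite(h)):
            continue
        site = micromet.derive_site_wind(float(u_s), float(h), traits.H, constants)
        params = wald_params(traits.H, site.U_H, traits.Vt, site.h, site.sigma_w, constants.K)
        remap[i] = len(kernels)
        kernels.append(discretize_kernel(params, cell_size, d_max))
    class_index.ravel()[:] = remap[inverse]
    return KernelField(wind.shape, cell_size, d_max, class_index, kernels)
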