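"""Grid geometry, suitability stacks and threshold-based binarization.

A :class:`Landscape` fixes the geometry every raster in a study must share:
a regular grid of square cells, row 0 northernmost, indexed row-major from 0,
with distances measured between cell centroids in map units. Cells flagged in
``nodata_mask`` are permanently outside the study area and never change state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Landscape",
    "SuitabilityStack",
    "EvaluationSet",
    "GeometryMismatchError",
    "binarize_max_tss",
    "max_tss_threshold",
]


class GeometryMismatchError(ValueError):
    """Raised when two rasters are not registered on the same grid."""


@dataclass(frozen=True)
class Landscape:
    """Georeferenced grid geometry.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    cell_size
        Square cell edge length in map units (metres; 1000 m in the default
        1-km² study design).
    origin
        ``(x, y)`` map coordinates of the *top-left corner* of cell (0, 0).
    nodata_mask
        Boolean grid, ``True`` where the cell is outside the study area.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            object.__setattr__(
                self, "nodata_mask", np.zeros((self.n_rows, self.n_cols), dtype=bool)
            )
        else:
            mask = np.asarray(self.nodata_mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("nodata_mask shape does not match grid shape")
            object.__setattr__(self, "nodata_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def congruent(self, other: "Landscape", *, rtol: float = 1e-6) -> bool:
        """Whether two geometries coincide within ``rtol`` of a cell size."""
        tol = rtol * self.cell_size
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def require_congruent(self, other: "Landscape") -> None:
        if not self.congruent(other):
            raise GeometryMismatchError(
                f"grid geometry mismatch: {self.n_rows}x{self.n_cols} cell "
                f"{self.cell_size} origin {self.origin} vs {other.n_rows}x"
                f"{other.n_cols} cell {other.cell_size} origin {other.origin}"
            )

    def validate_grid(self, grid: np.ndarray) -> np.ndarray:
        arr = np.asarray(grid)
        if arr.shape != self.shape:
            raise GeometryMismatchError(
                f"grid shape {arr.shape} does not match landscape {self.shape}"
            )
        return arr


@dataclass
class SuitabilityStack:
    """Time-ordered binary climatic-suitability grids on one geometry.

    ``slices[0]`` is the initial (present-day) map; each subsequent slice is
    the projection for one climatic period of ``period_length`` years. The
    default study design is the initial map plus four decadal projections
    (2010–2020 … 2040–2050).
    """

    landscape: Landscape
    slices: list[tuple[str, np.ndarray]]
    period_length: int = 10

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a suitability stack needs at least one slice")
        checked = []
        for label, grid in self.slices:
            arr = np.asarray(self.landscape.validate_grid(grid), dtype=np.uint8)
            values = np.unique(arr[~self.landscape.nodata_mask])
            if not np.isin(values, (0, 1)).all():
                raise ValueError(f"slice {label!r} is not binary")
            arr = np.where(self.landscape.nodata_mask, 0, arr).astype(np.uint8)
            checked.append((label, arr))
        self.slices = checked

    def __len__(self) -> int:
        return len(self.slices)

    def grid(self, index: int) -> np.ndarray:
        return self.slices[index][1]

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.slices]


@dataclass(frozen=True)
class EvaluationSet:
    """Model scores at known presences and absences, for threshold search."""

    presence_scores: tuple[float, ...]
    absence_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.presence_scores) == 0 or len(self.absence_scores) == 0:
            raise ValueError("evaluation set needs presence and absence scores")
        for s in (*self.presence_scores, *self.absence_scores):
            if not 0.0 <= s <= 1.0:
                raise ValueError("scores must lie in [0, 1]")


def max_tss_threshold(eval_set: EvaluationSet) -> tuple[float, float]:
    """Threshold maximizing the True Skill Statistic.

    TSS = sensitivity + specificity − 1, with a cell predicted present when
    its score is ≥ the threshold. Candidate thresholds are the distinct
    observed scores; among candidates attaining the maximal TSS the *largest*
    is returned (the conservative choice: fewest predicted presences).

    Returns
    -------
    (threshold, tss)
    """
    pres = np.asarray(eval_set.presence_scores, dtype=float)
    abs_ = np.asarray(eval_set.absence_scores, dtype=float)
    candidates = np.unique(np.concatenate([pres, abs_]))
    best_t, best_tss = candidates[0], -np.inf
    for t in candidates:
        sens = float(np.mean(pres >= t))
        spec = float(np.mean(abs_ < t))
        tss = sens + spec - 1.0
        if tss >= best_tss:  # >= keeps the largest threshold on ties
            best_t, best_tss = float(t), tss
    return best_t, best_tss


def binarize_max_tss(
    continuous_grid: np.ndarray, eval_set: EvaluationSet
) -> tuple[float, np.ndarray]:
    """Reclassify a continuous suitability surface at the max-TSS threshold.

    Cells with value ≥ threshold become 1, all others 0. NaN cells (NoData)
    become 0; masking is the caller's concern.
    """
    threshold, _ = max_tss_threshold(eval_set)
    grid = np.asarray(continuous_grid, dtype=float)
    binary = np.where(np.isnan(grid), 0, (grid >= threshold).astype(np.uint8))
    return threshold, binary.astype(np.uint8)
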