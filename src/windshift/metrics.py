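"""Summary metrics of a range-shift run.

Four summaries: the colonization rate (effective colonization events —
including those later lost to climate — as a percentage of the pixels
becoming newly suitable), the climate-only loss and gain of suitable area,
the E/C ratio between climate-driven range loss and realized colonization,
and the equilibrium classification of the post-horizon time-lag.

Undefined ratios (no newly suitable cells, or zero realized colonization)
are reported as explicit flags, never as numeric sentinels: downstream
tables must distinguish "no opportunity" from "no success".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import RunResult, TimelagResult
from .landscape import SuitabilityStack

__all__ = [
    "LossGain",
    "EcRatio",
    "EquilibriumClass",
    "CohortSummary",
    "colonization_rate",
    "loss_gain_climate_only",
    "ec_ratio",
    "classify_equilibrium",
    "summarize_cohort",
]


def colonization_rate(result: RunResult) -> float:
    """Mean over replicates of effective colonizations / newly suitable, ×100.

    Effective colonization events include cells colonized during the run that
    later turned unsuitable.
    """
    newly = result.newly_suitable_total
    if newly <= 0:
        raise ValueError("no newly suitable cells: colonization rate undefined")
    fracs = [r.effective_colonizations / newly for r in result.replicates]
    return 100.0 * float(np.mean(fracs))


@dataclass(frozen=True)
class LossGain:
    """Climate-only change of the suitable area between first and last slice."""

    loss_pct: float
    gain_pct: float
    ratio: float | None  # None when no cells were gained

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


def loss_gain_climate_only(stack: SuitabilityStack) -> LossGain:
    """Suitable-area loss and gain from the suitability maps alone.

    Loss = cells suitable initially and unsuitable at the final slice; gain =
    the reverse; both as percentages of the initially suitable count.
    """
    if len(stack) < 2:
        raise ValueError("need at least two slices to compare")
    valid = ~stack.landscape.nodata_mask
    first = stack.grid(0).astype(bool) & valid
    last = stack.grid(len(stack) - 1).astype(bool) & valid
    n0 = int(first.sum())
    if n0 == 0:
        raise ValueError("no initially suitable cells")
    lost = int((first & ~last).sum())
    gained = int((~first & last).sum())
    loss_pct = 100.0 * lost / n0
    gain_pct = 100.0 * gained / n0
    ratio = (lost / gained) if gained > 0 else None
    return LossGain(loss_pct, gain_pct, ratio)


@dataclass(frozen=True)
class EcRatio:
    """E/C: climate-driven loss fraction over realized colonization fraction."""

    value: float | None
    unbounded: bool = False  # E > 0 with zero realized colonization

    @property
    def defined(self) -> bool:
        return self.value is not None


def ec_ratio(result: RunResult) -> EcRatio:
    """Ratio of averages: E = lost/initially suitable, C = mean colonized fraction."""
    n0 = result.initially_suitable_total
    if n0 == 0:
        raise ValueError("no initially suitable cells")
    e = result.lost_total / n0
    newly = result.newly_suitable_total
    if newly == 0:
        raise ValueError("no newly suitable cells: C undefined")
    c = result.mean_effective_colonizations() / newly
    if c == 0.0:
        return EcRatio(value=None, unbounded=e > 0)
    return EcRatio(value=e / c)


@dataclass(frozen=True)
class EquilibriumClass:
    """Outcome of one time-lag run: at equilibrium, lagged by n years, or censored."""

    kind: str  # "at_equilibrium" | "lag_years" | "censored"
    years: int | None = None

    def __str__(self) -> str:
        if self.kind == "lag_years":
            return f"lag_years({self.years})"
        return self.kind


def classify_equilibrium(lag: int, censored: bool, max_years: int = 500) -> EquilibriumClass:
    """0 years → at equilibrium; otherwise a lag, censored at ``max_years``."""
    if censored:
        return EquilibriumClass("censored", max_years)
    if lag == 0:
        return EquilibriumClass("at_equilibrium", 0)
    return EquilibriumClass("lag_years", int(lag))


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level time-lag summary.

    Percent censored, percent already at equilibrium, and — among the
    remaining lagged members — mean ± SD and median lag in years.
    """

    pct_censored: float
    pct_at_equilibrium: float
    mean_lag: float | None
    sd_lag: float | None
    median_lag: float | None
    n: int


def summarize_cohort(result: TimelagResult) -> CohortSummary:
    classes = [
        classify_equilibrium(lag, cens, result.max_years)
        for lag, cens in zip(result.lags, result.censored)
    ]
    n = len(classes)
    if n == 0:
        raise ValueError("empty cohort")
    n_cens = sum(c.kind == "censored" for c in classes)
    n_eq = sum(c.kind == "at_equilibrium" for c in classes)
    lags = [c.years for c in classes if c.kind == "lag_years"]
    if lags:
        mean = float(np.mean(lags))
        sd = float(np.std(lags, ddof=1)) if len(lags) > 1 else 0.0
        median = float(np.median(lags))
    else:
        mean = sd = median = None
    return CohortSummary(
        pct_censored=100.0 * n_cens / n,
        pct_at_equilibrium=100.0 * n_eq / n,
        mean_lag=mean,
        sd_lag=sd,
        median_lag=median,
        n=n,
    )
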