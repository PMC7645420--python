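# Methods

## Model overview

`windshift` couples three components on a shared raster geometry (square
cells, row 0 northernmost, centroid distances in map units):

1. **Micrometeorological chain** (`windshift.micromet`). Measured 10-m wind
   speed over reference short vegetation (h_s = 0.3 m) is converted to the
   friction velocity u*_s = K·Ū_s/ln(w/Z0_s) with Z0_s = 0.1·h_s, matched to
   the canopy of height h through
   u* = u*_s·(ln 200 − ln(h_s/10))/(ln 200 − ln(h/10)) (equal mean velocity
   at the ~200-m surface-layer top), and turned into the vertical turbulence
   σ_w = 1.25·u* and the mean wind at the release height H: the log profile
   u*·ln((H−d)/Z0)/K with Z0 = 0.1·h, d = 0.7·h for H ≥ h, and the
   exponential in-canopy profile Ū_h·exp(α(H/h − 1)),
   α = 0.24 + 0.096·Z0 + 0.016·ln²Z0, below. All logarithms are natural; the
   chain is linear in the measured wind speed and continuous at H = h.

2. **WALD kernels** (`windshift.kernels`). Dispersal distance is
   inverse-Gaussian with location μ′ = H·Ū_H/Vt and shape λ′ = (H/σ)²,
   σ² = 2·K·h·σ_w/Ū_H. The density carries the standard negative exponent
   (the positive-exponent form diverges and cannot be a density). The model
   assumes particles tightly coupled to air parcels that reach terminal
   velocity instantly — good approximations for spores. Ring masses are
   closed-form CDF differences over annuli of one cell width; the mass of
   class j is split equally over its Surface_j cells (isotropy). Kernels are
   parameterized by the *source* pixel's wind and canopy, since diaspores
   are released there; pixels with identical (wind, canopy) pairs share one
   discretized kernel. Calm pixels (Ū_H = 0) get a massless kernel rather
   than raising an error: a calm cell simply contributes no dispersal.

3. **Cellular simulation** (`windshift.engine`). Initial occupancy is every
   suitable cell of the first slice. Each year (n_disp = 1 dispersal episode
   by default) every suitable-empty cell receives one Bernoulli draw at
   P_col = 1 − Π(1 − P_disp·P_mat) over occupied cells within the d_max-cell
   search radius, then an LDD draw at probability p_ldd if its nearest
   source is farther than 10 km (maximum LDD distance unlimited). Newly
   colonized cells become sources from the next step (synchronous update;
   demography is ignored, P_mat = 1 by default but the maturity hook is
   kept). Every period (10 years) the suitability map advances: occupied →
   unsuitable cells are lost (flagged extinct-after-colonization when they
   were colonized during the run — they still count as effective
   colonization events), unsuitable → suitable cells become tagged targets,
   and kernels are rebuilt from the period's wind grid.

## Parameters and defaults

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| cell_size | 1000 | m | grid resolution (1-km² pixels) |
| K | 0.4 | – | von Kármán constant |
| h_s / w / asl_top | 0.3 / 10 / 200 | m | reference vegetation, anemometer, surface-layer top |
| H | {0.03, 1, 10} | m | release height: ground-dwelling / saxicolous / epiphytic |
| Vt | preset | m/s | settling velocity (see below) |
| successful_seeds | 1 | – | diaspores per source per step (calibration is out of scope) |
| p_mat | 1 | – | maturity probability of a source |
| p_ldd | {0, 1e-4, 1e-3, 1e-2, 1e-1} | 1/yr | LDD probability per eligible cell |
| ldd_min_distance | 10 000 | m | LDD eligibility floor |
| d_max | 10 | cells | short-distance search radius (the 10-km LDD boundary) |
| years / period | 40 / 10 | yr | 2010–2050 horizon, decadal updates |
| replicates | 30 | – | stochastic replicates |

Settling-velocity presets are Stokes-law estimates for unit-density spheres
at class-typical diameters: small (<20 µm) 0.005 m/s, medium (20–50 µm)
0.03 m/s, large (>50 µm) 0.17 m/s, asexual propagules (~150 µm) 0.68 m/s.
They are ordered constants chosen for realism, not species measurements.

## Numerical choices

- Ring masses use the closed-form inverse-Gaussian CDF (scipy); tests
  cross-check them against adaptive quadrature of the density to 1e-8 and
  the density itself against an independent implementation.
- Distance classes: class j = (j−0.5, j+0.5] cell units; integer offsets
  never fall exactly on a class boundary, so nearest-integer rounding is an
  exact classifier.
- P_col is accumulated in log space (Σ log(1 − p)) by shifting per-class
  source grids over each ring offset — exact, vectorized, and O(offsets)
  per step.
- One uniform draw is made for *every* cell in each dispersal and LDD step,
  whether needed or not: matched-seed runs stay aligned draw-for-draw, so
  parameter sweeps are true monotone couplings.
- Replicates use independent RNG streams spawned from the master seed
  (spawn key = replicate index); results are a pure function of
  (config, seed) and replicates are order-independent. The time-lag
  continuation derives its own per-replicate streams, so it is reproducible
  regardless of how often it is invoked.
- Max-TSS binarization searches all observed scores as thresholds and, on
  ties, keeps the largest (fewest predicted presences).
- Geometry equality uses a tolerance of 1e-6 of a cell size on origin and
  resolution (floating-point raster metadata).
- Canopy heights below h_s are floored to h_s so profile matching never
  amplifies wind below the reference vegetation.
- σ² = 2·K·h·σ_w/Ū is implemented exactly as written even though its units
  are mixed; λ′ is treated as a length, consistent with μ′.

## Time-lag runs

After the horizon, conditions (suitability and kernels) are frozen at their
final-slice values and annual steps continue until every cell that became
newly suitable during the run *and is still suitable at the horizon* has
been effectively colonized at least once, censored at 500 years. The
restriction matters only for non-monotone scenarios: a cell that was newly
suitable mid-run but unsuitable again by the horizon could never be
colonized under frozen conditions and would force censoring by
construction. Classification: lag 0 = at equilibrium; otherwise lag in
years or censored. Cohort summaries report percent censored, percent at
equilibrium, and mean ± SD (plus median) of the lag among the remainder.

## The synthetic landscape

`windshift.synth` generates the study conditions: a 100×100 grid of 1-km
cells, a 20-row suitable band starting at the southern edge and shifting 5
rows poleward per decade over the initial map plus four decadal slices,
constant (or north–south gradient) mean/maximum 10-m wind of 5/10 m/s, and
constant (or two-zone) canopy of 0.3 m. It emulates the *structure* of real
inputs — registered suitability/wind/canopy stacks with decadal updates —
not their content: real landscapes have fragmented suitability, correlated
wind–topography structure, and coastlines (NoData). Passing tests on the
band fixture therefore validate the mechanics and bookkeeping of the
method, not continental-scale predictions.

Two consequences of the band geometry are worth naming. First, the
climate-only loss and gain are exact set arithmetic (shift × width per
transition), which the metrics tests exploit. Second, every newly suitable
cell appears adjacent to the occupied band, so no cell is ever farther than
10 km from a source and LDD is inert on this fixture; LDD behaviour is
exercised separately on gapped landscapes where the newly suitable area
lies beyond the 10-km floor.

## Scaling of shipped analyses

The summary script and test suite run the full pipeline at the default
100×100 extent with 10 replicates (script) or 6–8 replicates (parameter
sweeps in tests), and Monte-Carlo checks use 30 000 one-step replicates on a
5×5 grid and 1e5 kernel samples. These sizes were chosen so the whole
analysis reruns in minutes on one CPU while keeping binomial/moment
intervals tight; the engine itself handles larger grids (cost grows
linearly in cells × ring offsets).

## Known limitations

- Dispersal is isotropic: wind *speed* shapes the kernel, wind *direction*
  is ignored.
- No demography, competition or Allee effects: newly colonized cells are
  full-strength sources one year later, so colonization rates are upper
  bounds.
- SuccessfulSeeds is a supplied integer (default 1); empirical calibration
  against spore-trap data is out of scope.
- The kernel uses the source pixel's conditions for the entire trajectory;
  heterogeneous canopy along the path is not tracked.
- Climatic suitability is binary; no gradual establishment probability.
- Reprojection/resampling is out of scope: all rasters must share one grid.
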