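# Methods

## Model and assumptions

The simulator predicts a workplace noise map as the time-average of a
stochastic process in a flat 2-D plane (metres, origin at the mapping
area's lower-left corner; all receivers implicitly at the 1.5 m
measurement height — there is no vertical coordinate).  Three sources of
randomness are modelled:

1. **Duty cycles.**  Every machine is, at each step, "Off", "Idle" or at
   "Full" power with fixed probabilities (p_off, p_idle, p_on).  States
   are drawn independently per machine per step, with no temporal
   persistence — the framework describes per-step probabilistic states
   and nothing in it couples consecutive steps.  Off machines emit zero
   power (the background remains); Idle machines emit at `lwa_idle`,
   which defaults to 10 dB below `lwa_full` because measured idle levels
   are rarely reported; it is an explicit per-machine input.
2. **Machine movement.**  Moving machines take an isotropic Pearson
   random walk confined to a rectangular subarea: direction uniform on
   [0, 2π), step length uniform on (0, `max_step`] (default 5 m) or
   fixed at `max_step` for analytic comparisons.  The uniform length
   density is the simplest choice consistent with a walk specified only
   through an arbitrary step-length density.  Walkers may cross barrier
   footprints; nothing in the model restricts their paths around
   obstacles.
3. **Worker movement.**  Workers walk the same way inside their group's
   subarea and read their exposure off the current step's field.

Propagation is hemispherical over hard ground, I = W/(2πr²), with no air
absorption, ground absorption, meteorology or directivity: levels are
single A-weighted scalars.  Barrier effects use the screening
approximation common in construction-noise prediction: −5 dB for a
partially screened (still visible) source, −10 dB for a hidden source,
+3 dB for receivers within 1 m of a reflective façade.  Corrections are
applied per source path in the level domain, then the corrected
per-source levels are summed energetically with the spatially uniform
background intensity (which barriers do not affect).

## Geometry decisions

- Region boundaries are **closed** (edge points are inside) so a walker
  clamped to a subarea edge remains legal.
- In a heights-free 2-D model there is no way to compute visibility over
  a barrier top, so the screening class (full/partial) is a **per-barrier
  attribute** (default full).  This is this package's resolution of an
  otherwise under-determined rule.
- Blocking tests use the **open** source→receiver segment (endpoints
  excluded), so a source standing exactly on a barrier edge is not
  screened by that barrier; the test is symmetric in source and
  receiver.  The vectorised field path uses a numpy Liang–Barsky slab
  test; an independent shapely box/segment intersection serves as an
  oracle in the test suite.
- The façade +3 dB is a **receiver property** (applied to every source
  path at that receiver, once, not once per nearby façade): the rule is
  phrased in terms of the receiver's position.
- Receivers inside a barrier footprint are still computed — buildings
  are obstacles, not exclusion zones — and are *not* treated as near a
  façade.
- A distance clamp `min_r` (default: the grid spacing) keeps nodes that
  coincide with a source finite; the propagation law is silent on r → 0.

## Step loop, time and RNG

Each step is one equal slice of the working period
(`working_period / n_steps` minutes), which is what lets per-step worker
levels accumulate into a dose.  Within a step the fixed order is: duty
sampling (stationary then moving, list order) → moving-machine steps →
field computation → worker steps and exposure reads from the *current*
field.  One seeded `numpy.random.Generator` serves a run, with the draw
order documented in `engine.py`; identical inputs give bit-identical
results.  The sweep harness derives one independent child seed per
(step-setting, repeat) cell from the base seed via
`numpy.random.SeedSequence`.

Workers default to one walker per group; with several, walkers are
independent and the group series is the per-step energetic mean.

## Exposure conventions

Dose uses T_allowed(L) = T_c · 2^((CL − L)/Q) with defaults Q = 3 dB,
CL = 90 dBA, T_c = 480 min — the convention under which the reference
dosimeter sessions (85.9 dBA and 88.5 dBA over 30 min → 2.4 % and
4.4 %) reproduce to one decimal.  The reference exposure table's
*predicted*-dose column is not reproducible from its predicted LAeq
values under any single (Q, CL) pair — its 8-hour dose figures sit
closer to a 5-dB exchange rate — so both Q values remain one argument
away in `ExposureConfig` and the package standardises on Q = 3.
TWA = CL + Q·log2(D/100), the exact inverse of the constant-level dose.

L10/L50/L90 are exceedance percentiles (L10 = 90th percentile) with
linear interpolation between order statistics — a convention the package
documents because none is standard-enough to assume.  Risk zones band
LAeq at 66/71/76/81/86 dBA; the published banding overlaps at every
breakpoint, resolved here as left-closed right-open intervals with
≥ 86 dBA as the top class.  Limit checks use strict `>`; permissible
limits are user configuration, not constants.

## Numerical choices

- LAeq aggregation accumulates linear intensities per node; per-node
  standard deviation of the dB levels accumulates deviations from the
  first step's field to avoid the catastrophic cancellation of
  `E[x²] − E[x]²` at ~100 dB magnitudes.
- Grid meshing uses `floor(extent/Δ + 1e-9) + 1` nodes per axis; the
  epsilon guards float division jitter for non-integer spacings.
- Boundary handling of walks defaults to reject-resampling (redraw
  (θ, a) until the proposal is inside; preserves isotropy away from the
  walls) with a 1,000-draw budget before clipping — reachable only for
  pathological geometry and logged when it happens.
- Bilinear interpolation reads contour-plot values and worker exposures
  between nodes; points outside the grid are errors, not extrapolated.

## Synthetic scenarios and what tests show

`generate_synthetic_scenario` draws sound powers uniformly on
[95, 120] dBA — the span of the built-in machine inventory — random
duty-probability vectors, and random subareas/barriers inside the area,
reproducibly from a seed.  It emulates the *structure* of real
workplaces (source counts, level ranges, confinement geometry), not
their spatial organisation: real sites cluster machines along process
lines, have correlated duty cycles, and their barriers are walls with
heights.  Passing tests therefore demonstrate the simulator's internal
correctness (propagation arithmetic, confinement, reproducibility,
convergence), not predictive accuracy on any particular real site,
which requires field measurement.

The built-in case-study fixtures carry measured machine inventories,
area dimensions and background levels; machine *placements* are
illustrative reconstructions (the original layouts exist only as
drawings) and nothing downstream should depend on them.

## Problem sizes

The default test and sweep sizes — e.g. the 42-receiver × 7-step-setting
× 3-repeat sweep on the 144 × 87 mill grid, 10⁵ duty draws, 10⁴-walker
displacement ensembles — were chosen as the smallest sizes at which the
statistical assertions are stable, and run in a couple of minutes on a
single core.

## Known limitations

- No temporal autocorrelation in duty cycles or walks beyond position
  persistence; no shift patterns or breaks.
- 2-D only: no barrier heights, diffraction path lengths or terrain.
- Single-number A-weighted emission: no spectra, so no
  frequency-dependent screening.
- Workers never leave their subarea, so predicted doses describe the
  risk of spending the whole period in that area, not a commuting
  worker's day.
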