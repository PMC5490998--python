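# Methods

## Observation model

Raw archival-tag records (depth in m, ambient water temperature in °C,
sampled every 10–300 s) are screened for deployment quality — at least 30
days of data and no missing interval longer than one hour — and reduced to
3-hour bins on a grid anchored at 00:00 UTC of the release day.  Each bin
yields two summaries: *diving amplitude*, the sample standard deviation of
depth (n−1 denominator), and *thermal habitat*, the arithmetic mean of
water temperature.  Bins with fewer than half the expected sample count
(expected = bin width / median sampling interval), or fewer than two
samples, are kept on the grid but flagged invalid so the chain is never
split: short gaps are bridged, not censored out of the time axis.

The anchor and the 50 % coverage floor are conventions, configurable in
`RunConfig`; the sampling cadence makes results insensitive to both.

## Behavioural classification

Each fish gets its own two-state hidden Markov model with full-covariance
bivariate normal emissions over (diving amplitude, thermal habitat).
Parameters are estimated by Baum–Welch EM:

* **Initialization** — observations are split at the median thermal
  habitat, and state means/covariances taken as the group moments; the
  remaining `em_restarts − 1` (default 2) restarts perturb those means
  with seeded Gaussian noise (half the per-channel SD) and draw transition
  self-probabilities uniformly in [0.7, 0.98].
* **Missing bins** — invalid bins contribute emission likelihood 1 to both
  states (censored-observation treatment), so smoothed probabilities are
  model-propagated across gaps.
* **Numerics** — the forward–backward recursions run in log space
  (stable beyond 10⁴ bins); smoothed marginals are renormalized per bin.
  Emission covariances are floored at eigenvalue 1e-6 so zero-variance
  synthetic input cannot produce singular emissions.
* **Convergence and collapse** — EM stops when the relative log-likelihood
  change falls below `em_tol` (1e-6) or after `em_max_iter` (500)
  iterations.  A restart is discarded when a state's total responsibility
  over observed bins drops below 2 or a covariance degenerates; if every
  restart collapses, fitting raises with diagnostics.  Fitting requires at
  least 64 valid bins (eight windows' worth), mirroring the 30-day
  eligibility floor.
* **Labelling** — the state with the warmer mean thermal habitat is
  *shallow*; if the temperature means agree within 0.01 °C the state with
  the smaller diving amplitude is taken, and an exact tie on both raises
  so the fit is inspected rather than silently labelled.

Emissions are fitted on untransformed diving amplitude by default; a
`log_depth_sd` switch applies log1p first for strongly skewed amplitudes.

## Surface-association probability and events

The surface-association probability is a running mean of the smoothed
shallow-state probability over `window_bins` = 8 bins (24 h).  The window
is *trailing* — the value at bin t averages bins t−7…t — so an event is
declared only after a full day of accumulated shallow behaviour; a
centered alignment is available (`centered_window`) since the definition
does not disambiguate.  The mean is undefined for the first seven bins.

Events are maximal runs of bins with probability strictly above the
threshold (default 0.75; ties at exactly the threshold do not count, which
matters for hard-classified fixtures).  A single above-threshold bin
qualifies by default; `min_event_bins` raises that floor if a stricter
reading of "concurrent time-steps" is wanted.  Under pure diel switching
the running mean is exactly 0.5 — half of any 24-h window is shallow — so
the default threshold finds no events in diel behaviour.

Per-fish metrics: mean probability at the start/end/whole of the series
(start/end = first/last eight defined values, i.e. one day); proportion of
the series inside events, with a variant excluding release events from the
numerator; first/last/longest/total event durations; events per
month-at-liberty with month = 30.4375 days (mean Gregorian month); a
release event starts within 24 h of release; a recapture event overlaps
the final 24 h before recapture.  Final-week probabilities are means over
seven trailing 24-h blocks ending at recapture.  Truncated series (tag
failed before recapture) skip all recapture-window metrics but join every
other analysis.  Proportions use the full bin grid as denominator, not
only the bins where the running mean is defined.

Unusually long events are flagged by the Tukey rule — duration above
Q3 + 1.5 × IQR of the cohort's durations, quartiles by linear
interpolation — computed with and without release events; fewer than four
events leaves the fences undefined (warning, nothing flagged).

## Dip test

Bimodality of the final-24-hour probabilities is assessed with Hartigan's
dip: the sup-distance between the empirical CDF and the nearest unimodal
CDF (convex left of the mode, concave right, an atom only at the mode).
The statistic is computed from that definition directly: candidate modes
are the distinct data points; for a trial band width the side corridors
are checked via greatest-convex-minorant / least-concave-majorant
deviations and the two branches must join monotonically at the mode
(chord-extrapolation bounds); the minimal feasible band is found by
bisection (52 iterations, ~1e-15 resolution).  The implementation is
verified in the test suite against an independent linear-programming
oracle that solves the same shape-constrained fitting problem exactly for
small n, and against closed-form cases (equally spaced samples give
1/(2n); an even two-point mixture gives 1/4; constant input gives 0).
The p-value is the fraction of `n_boot` = 2000 uniform(0, 1) bootstrap
samples of the same size whose dip is at least the observed one — the
standard calibration null.

## Spatial combination

Geolocation estimates (three per day) carry axis-aligned 95 % confidence
ellipses.  "Axes equal to the 95 % CI" is read as full axis length = CI
width, i.e. semi-axis = half-width; the alternative reading is available
via `ellipse_full_width=False`.  Each estimate inherits the probability of
the temporally nearest defined bin (midpoint convention; exact ties go to
the earlier bin); estimates more than half a bin outside the span of
defined bins are dropped with a warning — this routinely removes the
handful of first-day estimates that precede the first defined 24-h window.

Ellipses are discretised on a grid with cell edges at multiples of 0.1°
from the 0° meridian/equator, longitude normalised to [0°, 360°) so the
western-central Pacific study region does not straddle a seam.  A cell
belongs to an ellipse iff its centre lies inside or on the ellipse
(boundary inclusive); a sub-cell ellipse still claims the cell containing
its centre.  The map cell value is the mean over every (ellipse, cell)
observation — equal weight per observation, not per fish — accumulated as
streaming (sum, count), which conserves total probability mass exactly
(sum of mean × count equals the summed attached probabilities) and leaves
untouched cells undefined rather than zero.

## Synthetic data

The generator emulates the structure the analysis assumes, with defaults
chosen to mirror the published scale of real deployments:

* deployments of 40–60 whole days sampled every 120 s;
* shallow state: swimming depth 15 m, across-bin diving amplitude
  5 ± 1.5 m, thermal habitat 28.0 ± 0.8 °C (inside the reported 24–30.7 °C
  warm-state band); deep state: 150 m, amplitude 45 ± 8 m, 16.0 ± 1.2 °C;
  within-state amplitude–temperature correlation 0 by default
  (configurable, since full covariances are fitted);
* baseline diel cycle, shallow 18:00–06:00 UTC;
* surface bouts at 2.5 per month with lognormal durations (median 2 days,
  log-SD 0.6, capped at 14 days) and at least 2 days between bouts; a
  release-anchored bout in 60 % of fish with duration ~N(7.5, 4²) days
  (between the reported species means), clipped to ≥ 1.5 days;
* optional gap injection (45-minute gaps by default — below the
  eligibility limit) and per-fish bounded random-walk tracks, three
  estimates per day, latitude CI (1.2°) wider than longitude CI (0.5°) as
  in equatorial light-based geolocation.

Raw samples realise a per-bin target drawn from the state's bivariate
normal: depths ~N(state depth, target amplitude) truncated at 0, and
temperatures ~N(target, 0.3 °C) within the bin.  Every fish retains full
truth: the per-bin state sequence, the planted bouts, and the event
schedule the 24-h/0.75 definition implies for the true states — the
reference that recovery tests and the acceptance script compare against.
Schedules and samples are deterministic functions of (scenario seed, fish
index); `fixed_bouts` plants an explicit schedule for targeted tests.

What the generator does **not** emulate: oceanographic thermal profiles,
intermediate or transitional behaviours, thermocline association, depth
sensor drift, or any FAD field.  One consequence: the two synthetic states
are well separated, so smoothed posteriors are nearly hard 0/1 and the
running mean inside a genuine bout exceeds 0.99.  In a threshold sweep the
0.99 end therefore retains the planted bout time rather than falling to
zero as softer real-data posteriors do; the sweep acceptance check anchors
the 0.99 end against each fish's true bout coverage instead of against
zero.  Passing tests demonstrate correct recovery of planted structure
under the assumed model, not robustness to behaviours outside it.

## Problem sizes

The test suite and acceptance script run at sizes chosen to exercise every
code path at comfortable precision: exhaustive-enumeration checks on
chains of ≤ 10 bins; EM recovery on 2000-bin series (20 replicates in the
suite, 10 in the acceptance script); pipeline recovery on a 10-fish cohort
of 40–60-day deployments; 1000 random vectors for event-scan equivalence
and 100 random ellipses for rasterization equivalence; dip bootstrap of
2000 resamples.  The forward–backward and dip kernels are numba-compiled
when numba is importable, with identical pure-Python fallbacks.

## Known limitations

* Exactly two behavioural states; no covariate-dependent transition
  probabilities and no Viterbi decoding (classification is probabilistic
  by design).
* Plate carrée geometry only: raster cells are 0.1° in both axes
  regardless of latitude; membership is centre-containment, not
  area-weighted.
* The dip bootstrap uses the uniform null; no interpolation of published
  critical-value tables.
* Geolocation positions are consumed, never estimated: light-based
  geolocation model fitting is out of scope.
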