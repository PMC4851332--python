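# Methods

## The demographic proxy

The package treats the density of radiocarbon dates through time as a
relative proxy for past population: more people leave more datable
archaeological contexts ("more people = more sites = more dates").  The
proxy is the summed probability distribution (SPD): each conventional
radiocarbon age (CRA, in ¹⁴C yr BP with a 1σ lab error) is calibrated into
a probability mass function over calendar years BP (cal BP, before AD
1950), per-site clusters of dates are pooled into bins, and bin densities
are summed year-wise.  The SPD is never interpreted at face value: the
calibration curve's wiggles, sampling error and taphonomic loss all produce
structure that only simulation-based tests can separate from genuine
demographic signal.

## Calibration

For a CRA *y* with lab error σ_lab and a curve (μ(t), σ_curve(t)) on an
annual calendar grid,

    p(t) ∝ φ(y; μ(t), sqrt(σ_lab² + σ_curve(t)²)),

the normal density evaluated year by year (direct numerical integration),
then normalised to unit mass on the calendar grid.  Masses are per calendar
year, not per ¹⁴C year: every downstream statistic lives on the calendar
axis.

Numerical choices:

- Curves are linearly interpolated from their distributed knots to the
  annual grid (for μ and σ_curve alike); curvature between knots is
  negligible at this precision.
- Years carrying less than `eps` (default 1e-5) of the per-date maximum
  mass are zeroed and the support trimmed to the smallest contiguous window
  holding the remainder, then renormalised.  This bounds the support length
  so SPD accumulation stays proportional to the grid size; `eps` is
  exposed on every calibrating entry point.
- Grids are stored in decreasing cal BP (older first), the IntCal file
  convention; curves supplied in increasing order are normalised on input.
- Back-calibrated (simulated) CRAs are rounded to integer ¹⁴C years,
  matching how determinations are reported; the effect is far below any
  lab error.

## Binning and the SPD

Dates from intensively excavated sites would otherwise dominate the sum
(wealth/ascertainment bias).  Within each site, CRAs are clustered by
complete-linkage agglomeration cut at height `h` (default 200 ¹⁴C years;
scipy's hierarchical clustering does the linkage); each cluster is a bin,
and a bin contributes the arithmetic mean of its members' calibrated
densities.  `h = 0` separates distinct CRAs, `h = ∞` gives one bin per
site.  Dates are sorted by (CRA, lab id) within a site and sites are
processed in site-id order, so the partition and bin ids are deterministic
and independent of row order and of how sets are labelled; at exact
distance ties the merge order is scipy's, which is platform-stable.

The analysis range defaults to 7,000–3,000 cal BP while dates are admitted
over the wider 7,500–2,500 ¹⁴C BP window, buffering the range edges;
calibrated mass falling outside the range is retained (the SPD sums to at
most the bin count) but excluded from every statistic.  The 200-year
rolling mean (odd, centred window; truncated at the edges) exists for
display only — tests always run on the raw annual SPD.

## Null-model test

The observed SPD is compared against a fitted null density of calendar
dates:

- **uniform** — constant over the range; a pure "no change" reference.
- **exponential** — density ∝ exp(b·t), t in cal BP, absorbing both
  long-term background growth and the roughly exponential survival decay of
  archaeological material (taphonomic loss).  The rate is fit by ordinary
  least squares of log(density + δ) on the calendar year, δ the smallest
  positive double: deterministic and adequate for a smooth monotone null,
  in place of an iteratively reweighted GLM.

Each of `nsim` iterations draws as many calendar years as there are
observed *bins* (bins, not dates — the exchangeable unit after de-biasing),
back-calibrates each through the curve with a lab error resampled from the
observed pool, calibrates, and sums single-date bins into a simulated SPD.
Per year, observed and simulated SPDs are z-scored against the simulation
mean and standard deviation — removing the null's trend and the
curve-induced wiggles so that only shape deviations remain.  Years where
the sd vanishes contribute zero to every statistic and are counted in the
result (`n_zero_sd`).

The 95% envelope is the per-year 2.5th/97.5th percentile band of the
z-scored series.  The percentiles are taken over the simulated series *and*
the observed one: with the observed excluded, each simulation's statistic
is measured against a band containing itself while the observed is not,
and the global test measurably exceeds its nominal size (≈11% at α = 0.05
on exchangeable input with nsim = 200).  Including all series restores
exchangeability and the nominal rate; at nsim = 10,000 the two bands are
indistinguishable.  Observed excursions above/below the band are reported
as significant positive/negative intervals (runs shorter than `min_run`
years, default 1, are dropped).  The global statistic is the total area
outside the envelope, Σ_t max(0, z(t) − hi(t)) + max(0, lo(t) − z(t)); the
p-value is (1 + #{simulations with statistic ≥ observed}) / (nsim + 1),
which can never return zero.

A raw-scale mode (`scale="raw"`) computes envelope and statistic on
unstandardised densities for visual comparison with raw-scale plots; the
z-scored mode is the default and the one whose size is calibrated.

## Permutation test

To compare k ≥ 2 regional sets, the null hypothesis is that all sets'
dates come from identically shaped calendar densities, making bin-to-set
labels exchangeable.  Whole bins (never individual dates) are relabelled
uniformly at random, preserving each set's observed bin count exactly; each
permutation rebuilds every set's SPD.  Per set, the machinery above is
reused with two differences: the reference mean/sd include the observed
arrangement (guaranteeing nonzero sd wherever any arrangement puts mass,
slightly conservative), and the comparison is against the aggregate of the
sets actually supplied — pass a two-set table for a strictly pairwise
comparison, or all sets for the k-set mode.  Because z-scoring removes
scale, the test compares SPD *shapes* and is insensitive to inter-regional
differences in research intensity or sample size.  Restricting the range
clips the grid before any statistic is computed, so envelopes and p-values
refer to the clipped window.

## Synthetic data

`synthetic_data` draws calendar years from a known demographic density
(uniform; exponential; rise-and-fall, a piecewise-linear tent with a 10%
floor; step; or custom), back-calibrates them through any curve with lab
errors resampled from a pool (default {20, 25, 30, 40, 50} ¹⁴C yr, typical
AMS magnitudes), and assigns dates to sites multinomially.
`two_region_scenario` derives a second region from a shared density with a
windowed multiplier (0 = gap, >1 = boom) for power studies.

What the generator emulates: the sampling mechanism the tests assume —
known calendar density, curve distortion, lab error, site clustering.  What
it does not: real curve plateaus' exact geometry (the test-fixture curve is
a sinusoid around the identity), heterogeneous per-site dating intensity,
material- and method-dependent error structure, and any spatial
organisation.  Passing tests therefore validate the statistical machinery
under its own assumptions, not the archaeological faithfulness of any
particular dataset.

The shipped toy curves are synthetic; real analyses must supply a
calibration curve file (e.g. IntCal13) in the IntCal plain-text dialect —
the package deliberately does not bundle or download one.

## Test sizes and tolerances

Stochastic checks run at sizes chosen to keep the whole suite quick while
leaving comfortable statistical margins: type-I error at 200 replicates of
nsim = 200 with 100 bins (binomial 95% band around α = 0.05), power at 50
replicates of nsim = 500 with 400 dates/region, rate recovery at n = 1,000
over 20 replicates.  Calibration agreement with a 0.2-yr brute-force
integration is required to ±1 yr for the median and 95%-interval years;
normalisation to 1e-9; aggregate-SPD label invariance to 1e-12.  All
random checks are seeded and reproducible.

## Known limitations

- No marine or mixed-curve calibration, reservoir offsets, or post-bomb
  curves; no Bayesian sequence modelling or wiggle-matching.
- The exponential null subsumes taphonomic loss rather than modelling it
  explicitly; no separate de-trending step.
- Bin membership is decided on uncalibrated CRAs (standard practice), so
  dates straddling steep curve sections can share a bin while their
  calendar densities differ.
- Global p-values for multiple pairwise comparisons are reported raw, with
  no multiplicity correction.
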