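# Methods

This note documents the statistical conventions, defaults and numerical
choices of `mobiscale`, the assumptions behind its synthetic-data
generators and simulators, and the known limitations of both.

## Staypoint detection

A staypoint ("effective staying position") is a maximal sub-sequence of
GPS records that stays within a distance resolution `d_max` (default
10 m, the spatial resolution of a handheld GPS unit) for longer than a
time resolution `t_min` (default 120 s, a typical traffic-signal
interval).  The scan is greedy left-to-right: from each start index the
sub-sequence is extended as far as the spatial criterion allows; if its
time span strictly exceeds `t_min` it is accepted and the scan resumes at
the first record after it, otherwise the start advances by one record.
An accepted sub-sequence always has at least two records (a duration
needs two timestamps).  The staypoint center is the arithmetic mean of
the member coordinates in raw degrees — clusters are at most tens of
meters wide, so spherical averaging would change centers by far less
than the GPS noise floor.

Two spatial criteria are provided because the informal description of
"confined within 10 m" is genuinely ambiguous:

* `consecutive` (default): every pair of *consecutive* member records is
  closer than `d_max` (strict `<`);
* `all_pairs`: every pair of member records is within `d_max` (`≤`).

The two agree on compact dwell clusters and differ on slow drifts, where
the consecutive rule will follow a walk of small steps indefinitely.
Both are exposed in the library, the CLI and the config file.

Distances are great-circle (haversine) with Earth radius 6 371 000 m.
Altitude is parsed from PLT files but ignored everywhere: all analysis is
planar.

The *recording time* of a trajectory file is last minus first timestamp
(gaps are not subtracted), and files recording less than 6 hours
(`min_file_duration`) are dropped before analysis — shorter files rarely
contain enough 120 s dwells for usable statistics.  Files are never split
at internal gaps; a multi-day file stays one series.

## Movement series

For staypoints S₁…S_N of one file, the series has N−1 movement records:
displacement Δr (center-to-center haversine distance), elapsed time
Δt_e (departure of Sᵢ to arrival of Sᵢ₊₁ — the dwell time at both ends is
excluded, since Δt_e is time *on the way*), speed v = Δr/Δt_e, and the
staying time Δt of the origin staypoint.  Relative displacements
Δr′ = Δr/⟨Δr⟩ use the user's mean displacement pooled over all of that
user's files, so the per-user mean of Δr′ is exactly 1.

Zero displacements (identical centers) are kept in the series but are
excluded from logarithm-domain statistics.  Population pooling
concatenates samples but retains per-file ordering; index pairs used by
any lagged statistic never span a file boundary.

The speed–displacement pattern is computed per movement by default (one
(Δr, v) point per record) with a log-binned median-speed curve and a
two-segment log-log OLS slope split at 1 km; a per-user mode (mean Δr vs
mean v per user) is also available since either reading of "average
speed" is defensible.

## Distribution fitting

* **Log-binning**: geometric bins, 10 per decade by default, densities
  normalized per unit (linear) width so they integrate to 1 over the
  binned range.  Zero-count bins are dropped from any log-log regression
  (log 0 is undefined).
* **Two-regime power law**: every interior nonzero-bin edge is a break
  candidate; an OLS line is fitted on each side in log-log space
  (each side keeps ≥ 3 points) and the break minimizing total SSE wins.
  By construction the SSE never exceeds that of a single line.
* **KS/MLE tail fit**: continuous power-law MLE
  α̂ = 1 + n/Σln(xᵢ/x_min).  With `x_min="estimate"` the lower bound
  minimizes the KS distance between the tail ECDF and the fitted law;
  the candidate set is the unique sample values, decimated to ≈100
  quantile-spaced candidates to bound the scan, and a fit needs at least
  50 tail samples (configurable).  The confidence probability p comes
  from a semiparametric bootstrap (default 1000 replicates; 200 in the
  pipeline default for runtime): each replicate draws tail samples from
  the fitted Pareto and body samples from the empirical distribution
  below x_min, refits with the same protocol, and p is the fraction of
  replicates whose KS distance is at least the observed one.  p is
  seed-reproducible.  A fixed-bound variant (e.g. x_min = 10 m) tests
  whether the *whole* range is power-law-like rather than only an
  escaped tail; both are useful because the estimated bound frequently
  runs far into the tail on non-power-law data.
* **Log-log Pearson R**: the correlation of (log bin center, log
  density) pairs; −1 for an exact decaying power law.  This is the
  fit-quality measure that is robust on small per-user samples where the
  bootstrap p is noisy.

## Correlation statistics

Kendall's Tau is computed in its tau-a form with sgn(0) = 0, so tied
pairs contribute zero to the numerator while the denominator stays
n(n−1)/2; displacements are effectively continuous and ties are rare.
For n ≤ 4000 the concordant-minus-discordant count is computed exactly
by chunked pairwise sign products (integer arithmetic, no rounding).
For larger n it is recovered from the tie-corrected tau-b of
`scipy.stats.kendalltau` by multiplying back the tie terms and rounding
to the exact integer; the two paths agree exactly and are cross-checked
in the tests.

τ(Δn) pools the (Δrₙ, Δrₙ₊Δₙ) index pairs of every file before applying
the statistic (the alternative — a weighted average of per-file taus —
is not used; pooling weights every pair equally).  The decay exponent is
the OLS slope of log τ vs log Δn over positive taus, requiring at least
4 points.  The lagged log-Pearson curve uses pooled (ln Δrₙ, ln Δrₙ₊Δₙ)
pairs; if its decay exponent is γ, the implied Hurst-type exponent
H = 1 − γ/2 is reported alongside the DFA estimate.

The null 95% confidence half-width uses the large-sample variance of
tau-a under independence, var τ = 2(2n+5)/(9n(n−1)), giving
z·sqrt(·) ≈ 0.0414 at n = 1000.  A permutation alternative (default
2000 seeded shuffles, |τ| quantile) is provided; the two agree within a
few percent at moderate n.  At small n the normal approximation is
crude — e.g. the half-width is 0.244 at n = 32 and 0.262 at n = 28 — so
small-cohort cross-user correlations should be read with the permutation
CI when they are near the boundary.

r_Δ is the Pearson correlation of *consecutive log-displacement* pairs
computed with the series' own mean μ and population variance σ² of
ln Δr: r_Δ = Σ(ln Δrₙ − μ)(ln Δrₙ₊₁ − μ)/((N−1)σ²).  Logarithms are used
because raw displacements span several orders of magnitude and a
linear-scale Pearson coefficient would be dominated by the few largest
trips.  A constant series (variance zero up to round-off) raises an
error rather than returning a spurious value.

## Detrended fluctuation analysis

The series is mean-subtracted and integrated; the profile is cut into
⌊N/l⌋ disjoint boxes of size l, a k-order polynomial trend (k = 1
default) is removed per box by least squares, F²(l) averages the squared
residuals, and H is the OLS slope of log F(l) vs log l.  Box sizes are
~20 log-spaced values in [4, N/4] (the series must be at least 4× the
smallest box; each box must hold ≥ k+2 points).  The trailing remainder
(N mod l) is discarded by default; a `both_ends` mode averages each
F²(l) with a pass anchored at the series end instead.  A constant series
gives F ≡ 0 and is flagged degenerate (H undefined) rather than fitted.
Per-user H in the summary table is computed on the raw displacement
series; DFA on log-displacements is available and gives the same H for
the generators used here (the scaling exponent is insensitive to smooth
monotone transforms at the amplitudes involved).

On length-10⁴ series the single-estimate standard deviation of Ĥ is
about 0.02, which is why recovery checks average a handful of seeds.

## Mobility simulators

All simulators are deterministic given their config (the seed is part of
it) and emit the same series container as empirical data.

* **Lévy flight**: iid Pareto move lengths (density exponent α, default
  2.0, x_min = 1), uniform headings.  Successive displacements are
  independent by construction.
* **CTRW**: Lévy flight plus iid Pareto waiting times (exponent 1.8);
  introduces no displacement correlation and no wait–displacement
  correlation.
* **EPR** (exploration/preferential return): explore a new location with
  probability ρS^(−γ) (S = distinct locations so far; defaults ρ = 0.6,
  γ = 0.21, the literature-standard values — a package choice, since the
  model family does not fix them), with a Pareto jump from the current
  position; otherwise return to a known location with probability
  proportional to its visit count.  The current location is excluded
  from returns so every step moves.  Returns retrace recent jumps, which
  correlates successive displacements (τ₁ ≈ 0.12 at the defaults) while
  τ(Δn ≥ 2) stays within the null band, and S(t) grows sublinearly
  (≈ t^(1/(1+γ))).
* **SLAW**: a least-action walk — the next waypoint is chosen among
  waypoints not yet visited in the current sweep with probability
  ∝ 1/dᵢ^β (β = 1 default; the sweep resets when all waypoints are
  visited; per-trip waypoint subsets of the original formulation are
  omitted — a single continuous walk).  The waypoint landscape is this
  package's construction: a recursive multiplicative cascade in which
  each cell splits into four quadrants with Dirichlet(a,a,a,a) mass
  fractions, a = H/(1−H), to depth 12 with 2000 waypoints.  H → 1 gives
  a near-uniform partition; lower H gives a strongly multi-scale,
  clustered point set, larger typical neighbor distances, and stronger
  consecutive-displacement correlation — the walker then performs long
  runs of similar-magnitude hops inside a cluster scale before changing
  scale.  τ₁ decreases monotonically in H across {0.6, 0.75, 0.9} and
  the τ(Δn) decay is faster than a power law.
* **HTS** (hierarchical traffic system): L layers of nodes placed
  uniformly on a square (top layer smallest); each node links to its
  nearest node in the layer above, top-layer nodes are mutually linked,
  and a layer-l node (l = 1 at the top) has weight A^(L−l).  A walker
  steps to a network neighbor with probability proportional to the
  neighbor's weight, one edge per step, so long displacements occur only
  on hub–hub edges and displacement magnitudes change gradually —
  positive, power-law-like decaying τ(Δn).

  The defaults — layers (2, 8, 32, 128), A = 3.3, 10⁴ steps — were
  selected by the calibration sweep in `scripts/calibrate_hts.py`
  targeting a mean consecutive tau of 0.39 over 10 seeded runs, the
  reference value for this model class; the hierarchy parameters are not
  identifiable from that value alone, so the layer layout was fixed
  first and A calibrated (measured means: A = 2 → 0.487, A = 3 → 0.412,
  A = 3.3 → 0.394, A = 4 → 0.361).

## Synthetic data: what it emulates, and what it does not

`generate_trajectory` realizes an itinerary (planted centers, dwell
durations > t_min, travel legs) as GPS records at a 3 s sampling
interval (handheld units log every 2–5 s).  Dwell jitter bounds the
distance between *consecutive* dwell samples — offsets are drawn in a
disc of radius jitter/2 (default 5 m) — so any jitter below `d_max`
keeps a cluster intact under the consecutive criterion, which is what
makes 100% planted-staypoint recall a theorem about the generator rather
than a tuning outcome.  Travel points are spaced farther apart than
`d_max` (travel speed 20 m/s) so travel never pollutes dwells.  Ground
truth (exact member means and arrival/departure times) is returned with
the trajectory.

`generate_series` produces positive displacement series through a
Gaussian engine mapped by exp: iid (null case), AR(1) with coefficient φ
(consecutive Kendall's Tau exactly (2/π)arcsin φ under the Gaussian
copula), fractional Gaussian noise with Hurst H (circulant-embedding
synthesis; negative FFT eigenvalues from round-off are clipped), or a
dyadic multiplicative cascade (heavy tails and persistence jointly).

`generate_cohort` builds users whose *rank* structure is the AR(1)
copula (φ spread over [0.1, 0.8]) and whose *marginal* is a strictly
monotone quantile map: the geometric blend, with clean-tail weight
w ∈ [0, 1], of a Pareto(α = 2, x_min = 10 m) quantile function and a
bimodal two-lognormal one (modes near 80 m and 8 km — errands vs
commutes).  Monotonicity means the measured τ₁ depends only on φ and the
fit quality only on w, so coupling (w tied to φ) and decoupling (w
randomly permuted) are exact by construction — the decoupled cohort is a
true negative control.

None of the generators emulate road networks, GPS dropouts and outliers,
daily/weekly rhythms, transport-mode switching, or the inter-user
sharing of places.  Passing tests therefore demonstrate that the
*estimators and pipeline* behave correctly on series with known
structure; they do not validate substantive claims about any particular
empirical data set, for which the PLT ingestion path exists.

## Problem sizes and runtime choices

Tests and the acceptance script use series of 2 000–10 000 movements,
cohorts of 10–12 users × 1 200 records, 200 bootstrap replicates and
10-seed averages for stochastic checks — sizes at which every estimator
is comfortably in its working regime (null CI half-widths of ~0.01–0.04)
while the full suite runs in about a minute.  The per-user bootstrap
default inside the pipeline is 200 replicates (p resolution 0.005);
raise `n_bootstrap` to 1000 for publication-grade p values.

## Known limitations

* The consecutive-distance staypoint criterion follows slow drifts; use
  `all_pairs` where dwells must be spatially bounded in diameter.
* The estimated KS lower bound frequently escapes deep into the tail on
  non-power-law data, yielding a high p for a tiny range; always read p
  together with x_min, n_tail, and the fixed-bound variant.
* The normal-approximation tau CI is anticonservative at n ≲ 30; use the
  permutation CI there.
* DFA assumes stationary increments; strong nonstationarity (e.g. a
  regime switch between files) biases H upward.  Per-user DFA
  concatenates that user's files, which treats file boundaries as
  contiguous time — acceptable when files are many and long, crude
  otherwise.
* The EPR, SLAW and HTS implementations are deliberately minimal
  versions of their model families; they reproduce correlation
  signatures, not geographic realism.
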