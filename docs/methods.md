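# Methods

## The null model: polarization as a random phasor sum

For N fish whose unit velocity directors point in independent, uniform
directions, the group polarization P = |(1/N) Σ e^{iθ_k}| is the scaled
resultant of a Pearson random walk, the same mathematics that governs
the amplitude of fully developed optical speckle. Everything about the
null model follows from this identification.

Exact moments of P² need no integration. Writing
P² = (1/N²)[N + Σ_{i≠j} cos θ_ij] and using E[cos θ_ij] = 0 for
independent uniform headings gives ⟨P²⟩ = 1/N for every N, and from the
fourth moment SD(P²) = (1/N)√(1 − 1/N), hence ⟨P²⟩/SD = 1/√(1 − 1/N)
(√2 at N = 2, → 1 as N → ∞).

The density of P is the Kluyver inversion of the two-dimensional
characteristic function J₀(t)^N:

    f_P(p) = N² p ∫₀^∞ t J₀(t)^N J₀(N p t) dt ,   p ∈ [0, 1],

with f_{P²}(x) = f_P(√x)/(2√x) by change of variables. Closed forms
bracket the family:

- N = 2: f_P(p) = 2/(π√(1−p²)) and f_{P²}(x) = 1/(π√(x(1−x))), with
  ⟨P⟩ = 2/π ≈ 0.6366, SD = √((π²−8)/(2π²)) ≈ 0.3078, ratio ≈ 2.0686.
  Both densities diverge (integrably) at the support edges; the peaks at
  P = 1 and P² ∈ {0, 1} are purely combinatorial, not behavioral.
- N ≫ 1: the central limit theorem gives Gaussian components of variance
  1/2N, hence Rayleigh f_P(p) = 2Np e^{−Np²} and exponential
  f_{P²}(x) = N e^{−Nx}, with ⟨P⟩ = √(π/4N) ≈ 0.886 N^{−1/2},
  SD = √((4−π)/4N) ≈ 0.463 N^{−1/2} and ⟨P⟩/SD → 1.913.

`method="auto"` selects the exact form at N = 2, quadrature of the
Bessel integral for 2 < N < 64, and the limiting laws above that. The
threshold 64 is deliberately conservative — the Rayleigh shape is a good
description well below it — and is an explicit parameter everywhere.
Mean P in the quadrature regime is the first moment of the density by
composite Gauss–Legendre quadrature; its SD uses the exact second moment
1/N, so no second quadrature is involved.

## Evaluating the oscillatory Bessel integral

The integrand t J₀(t)^N J₀(bt) decays only like t^{1−(N+1)/2} and
oscillates with the incommensurate frequencies of its two factors, so
naive truncation is hopeless at small N. The scheme used here:

1. integrate over uniform panels of length π/(1+b) with a 24-point
   Gauss–Legendre rule (vectorized over panels);
2. if the integrand has numerically vanished (large N: J₀^N is
   Gaussian-concentrated near t = 0), stop — plain truncation is exact
   to 1e-14 there;
3. otherwise accelerate the sequence of partial sums with Wynn's epsilon
   algorithm, which extrapolates superpositions of decaying oscillations
   with several frequencies (an Euler transform would require a strictly
   alternating tail and does not apply);
4. for N ≤ 8, asymptotically J₀(t)^N contains the harmonics
   k ∈ {N, N−2, ...}; when b lies within 1 of a harmonic the product has
   a slowly beating component at frequency |k − b| that defeats panel-level
   extrapolation. The panels are then grouped into blocks of half a beat
   period before applying the epsilon algorithm, restoring an
   alternating-like block sequence. The block length is capped near exact
   resonance, where some densities are genuinely singular — the N = 3
   density has an integrable logarithmic divergence at p = 1/3 (and the
   N = 4 density of P² at x = 0).

Accuracy, validated against an independent recursive-convolution oracle
(adding one unit step at a time, no Bessel functions involved; see the
test suite): ~1e-8 to 1e-12 at generic points, ~1e-4 near the N = 3
support edge, worst case ~1.4e-3 exactly at the N = 4, p = 0.5
resonance. The conditionally convergent N = 2 case reproduces the
arcsine closed form to 1e-4, but `auto` never uses quadrature there.

Two points where this implementation deliberately deviates from naive
expectations:

- The finite-N density at N = 200 differs from the Rayleigh limit by up
  to 1.7e-2 in absolute sup-norm on p ∈ [0, 0.5] (verified against
  30-digit arbitrary-precision quadrature). This is not quadrature
  error: the relative correction is O(1/N) on a density whose peak grows
  like √N, so the absolute deviation shrinks only like N^{−1/2}.
- Densities are reported on open midpoint grids; the integrable endpoint
  divergences of the N = 2 forms are invisible to trapezoids, so curve
  normalization for closed-form methods is asserted through analytic
  CDFs rather than quadrature across the singularity. For N = 3 the
  interior log point costs a finite midpoint grid a few 1e-3 of mass.

## Monte Carlo engine

The sampler draws N uniform headings per configuration and records P and
P²; 10⁶ configurations is the default scale, at which all quantifier
standard errors are ≲ 5e-4. The bit generator is Philox (counter-based),
so the stream is a pure function of the seed and the draw count; batching
bounds memory and provably does not alter the stream (tested). Ratio
standard errors use the delta method with the sample's third and fourth
central moments — checked empirically against replicate scatter.
Histograms use 50 equal-width bins on [0, 1] by default (a convention,
matched by the empirical-PDF code so curves are comparable).

## Synthetic shoals

The generator produces the heading structure the analysis is meant to
detect, at the data shape of the recording protocol it emulates: shoal
sizes N ∈ {2, 3, 5, 8, 10, 13, 15, 18, 20, 25, 30}, five trials per
size, 8.5 min per trial at 30 frames/s with the first and last minute
trimmed downstream, in a 50 cm circular arena.

- *uncorrelated*: i.i.d. uniform headings; E[P²] = 1/N.
- *domain*: fish partitioned into groups of n_domain sharing one uniform
  heading per frame, groups independent. E[P²] = Σ n_k²/N² — equal to
  n/N when n divides N; otherwise the remainder forms a smaller last
  domain and the exact expectation is reported by
  `RegimeSpec.expected_P2` (for the default n = 3 this biases the fitted
  n low by ~2% when sizes like 13 or 20 are included).
- *schooling*: one common uniform heading per frame plus per-fish von
  Mises noise whose mean resultant length is √ρ, so that
  E[cos θ_ij] = ρ exactly and E[P²] = 1/N + (1 − 1/N)ρ. The
  concentration κ solves I₁(κ)/I₀(κ) = √ρ by safeguarded root finding.
  `rho_for_sqrt_scaling(N) = (√N − 1)/(N − 1)` is the unique ρ putting
  E[P²] on the N^{−1/2} schooling law.

`persistence` adds a keep-or-redraw Markov carryover per independent
heading stream: E[cos(θ_{t+1} − θ_t)] equals the persistence parameter
while every single-frame marginal — and hence every E[P²] target — is
untouched. It exists so temporal-correlation effects on effective sample
sizes can be studied; the statistical defaults keep it at 0.

Trajectories integrate headings at constant speed (default 3 cm/s,
about one adult body length per second; dt = 1/30 s — neither is imposed
by the protocol being emulated, both are explicit parameters). Near the
wall the wall-normal heading component is reflected; affected frames and
all frames within 1 cm of the wall are flagged invalid so that
statistics and round-trip checks can exclude them. On unflagged frames
the forward-difference directors reproduce the input headings to
< 1e-12 rad (file round trip: < 1e-9 with 12-decimal CSV output).

What the generator does *not* emulate: wall-following and thigmotaxis,
speed variability, fish-fish avoidance/attraction, identity swaps and
tracking dropouts, and any emergent mechanism for the crossover —
regimes are imposed per size class, not produced by interactions. Tests
passing on synthetic data therefore validate the statistical machinery,
not any behavioral model of real fish.

## Polarization extraction

Directors come from forward differences, v_i(t) = (x_i(t+1) − x_i(t))/dt
— chosen over central differences because it makes the
generator-to-analysis round trip exact; users of real data can smooth or
switch upstream. A director is valid only when both frames are tracked
and |v| ≥ min_speed (default 0.1 cm/s; a stationary fish has no
heading). Frames average over the valid subset, recording n_effective;
frames with fewer than 2 valid fish are flagged rather than silently
dropped, since 1/N-type baselines must be interpreted against the actual
fish count. Trimming removes director frames whose underlying positions
fall in the protocol's cut windows: an 8.5 min trial at 30 fps trimmed
by 60 s per side leaves 11699 = 6.5·60·30 − 1 frames (one lost to
differencing). dt is never guessed: it comes from the metadata sidecar
or an explicit argument.

## Quantifiers, PDFs and scaling fits

Per-trial quantifiers are time averages over valid frames; the SD is the
time-series standard deviation (a noise estimator). Across trials both
the unweighted mean with between-trial standard error and the
frame-weighted pooled alternative are reported, since either convention
is defensible. Empirical PDFs pool all trials of a size (per-trial
curves remain available by passing single series) and are compared to
the null via the Kolmogorov–Smirnov distance twice: at the nominal N and
at the effective size N* = N/n̂, n̂ = N⟨P²⟩ — the number of fish per
internally aligned, mutually independent cluster consistent with the
observed variance (n̂ = 1 uncorrelated, n_domain for domains,
1 + (N−1)ρ for uniform correlation).

Scaling fits are weighted least squares on log value vs log N (relative
standard errors become additive log-scale weights; delegated to
statsmodels WLS). The two-regime fit imposes the canonical exponents
(1/2 small N, 1 large N), fits the two coefficients on every admissible
split with at least 3 points per side, and keeps the split with the
lowest total weighted residual; free-exponent fits per side are reported
alongside. The crossover is the intersection of the two fitted laws,
N_c = (n/c_small)^{1/(β_large−β_small)} — exactly n² when c_small = 1 —
and a `no_crossover` flag is raised when a single large-N law explains
all points at least as well or the intersection falls outside the data
range. Locating the crossover by intersection (rather than joint
segmented regression) mirrors how the two laws are actually compared:
they must predict the same ⟨P²⟩ at the boundary.

## Numerical and design notes

- Quantifier ratios of degenerate (constant) series are flagged NaN, not
  infinity; an SD below 1e-12 counts as degenerate.
- The empirical-PDF histogram normalization is exact by construction
  (trapezoid over bin centers plus the two half-bin edge wedges).
- Master seeds fan out to per-trial seeds through `SeedSequence([master,
  N, trial])`; identical manifests yield bit-identical output tables.
- Problem sizes in the test suite (10⁵–10⁶ draws or frames, 2–5 trials)
  are chosen so every stochastic assertion sits at ≥3 estimated standard
  errors from its target under the stated conditions.

## Known limitations

- The schooling generator matches the ⟨P²⟩ = N^{−1/2} law exactly but
  reproduces the companion small-shoal law ⟨P⟩ ∝ N^{−1/4} only
  approximately; no generative model enforcing both simultaneously is
  known here, and the package fits the P law when present in data rather
  than guaranteeing it in synthesis.
- The two-regime residual comparison between the one-law and two-law
  models ignores parameter-count differences; with ≤ 11 sizes a formal
  model-selection criterion would be underpowered anyway.
- KS comparisons assume independent frames; with heading persistence the
  effective sample size shrinks and the stated critical values are
  anticonservative. Statistical defaults therefore use persistence 0.
- Exact small-N resonances of the Bessel quadrature (e.g. N = 4,
  p = 1/2) carry ~1e-3 absolute error; grids and bin centers avoid these
  points by construction.
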