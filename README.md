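# shoalpol

Speckle statistics of fish-shoal polarization.

Group polarization — the magnitude of the mean unit velocity director,

    P(t) = | (1/N) Σᵢ uᵢ(t) | ,   uᵢ = vᵢ / |vᵢ| ,

is the standard order parameter separating *shoaling* (aggregation
without heading correlations) from *schooling* (synchronized headings)
in fish groups. Its fluctuations are routinely over-interpreted: even N
fish with completely independent, uniformly distributed headings produce
structured polarization distributions, because P is then the length of a
random phasor sum — mathematically identical to the amplitude of an
optical speckle / a Pearson random walk. This package provides that null
model exactly, plus everything needed to measure polarization from
trajectory data and to read off correlation structure from how its
statistics scale with shoal size N.

For quantitative ethologists and physicists analyzing multi-animal
tracking exports (e.g. idTracker-style CSVs), it implements:

- **null model** (`shoalpol.null_model`) — exact closed forms at N = 2
  (PDF(P) = 2/(π√(1−P²)), ⟨P⟩ = 2/π, SD = √((π²−8)/(2π²))), the
  Kluyver/Bessel-integral density f_P(p) = N²p ∫ t J₀(t)^N J₀(Npt) dt for
  intermediate N, and the Rayleigh (P) / exponential (P²) limits for
  N ≫ 1; always exact ⟨P²⟩ = 1/N and SD(P²) = (1/N)√(1−1/N).
- **Monte Carlo engine** (`shoalpol.monte_carlo`) — seeded, counter-based
  sampling of the null model (10⁶ configurations by default) with
  delta-method standard errors; the oracle for every quantity without a
  closed form.
- **synthetic shoals** (`shoalpol.synthetic_data`) — heading generators in
  three regimes (uncorrelated; domains of n aligned fish, ⟨P²⟩ = n/N;
  uniform pairwise correlation ρ, ⟨P²⟩ = 1/N + (1−1/N)ρ) and
  arena-confined trajectory synthesis in a 50 cm circular tank.
- **polarization extraction** (`shoalpol.polarization`) — trajectory CSV
  parsing (wide/long dialects), forward-difference directors, per-frame
  P(t) with validity accounting and protocol trimming.
- **statistics & scaling** (`shoalpol.shoal_stats`, `shoalpol.scaling`) —
  per-trial/per-size quantifiers, empirical PDFs with KS comparison
  against the matched null, effective cluster size n̂ = N⟨P²⟩, and
  two-regime finite-size fits with the crossover identity N_c = n².

## Worked example

```python
from shoalpol import closed_form_quantifiers
from shoalpol.cli import RunConfig, run_pipeline

q = closed_form_quantifiers(2)
print(f"N=2  <P>={q.mean_P:.4f}  SD={q.sd_P:.4f}  "
      f"<P>/SD={q.ratio_P:.4f}  <P2>/SD={q.ratio_P2:.4f}")

# a reduced synthetic experiment: 2 trials x 2 min per shoal size,
# pairwise-correlated headings below N=11, aligned triplets above
cfg = RunConfig(trials_per_n=2, trial_seconds=120.0,
                trim_start=10.0, trim_end=10.0, seed=42)
manifest = run_pipeline(cfg, "runs/demo")
print(open("runs/demo/scaling_summary.txt").read())
```

prints

```
N=2  <P>=0.6366  SD=0.3078  <P>/SD=2.0686  <P2>/SD=1.4142
Two-regime scaling fit: mean_P2 vs N (11 points)
--------------------------------------------------------------
small-N law : 0.9984 * N^-0.5   (c_small se 0.0011)
large-N law : 2.962 * N^-1   (n se 0.027)
split at N  : 11.5
crossover   : N_c = 8.8
n^2 identity: n^2 = 8.77  (equals N_c when c_small = 1)
weighted rss: 229
free small-N exponent: 0.505 +- 0.003
free large-N exponent: 0.959 +- 0.058
```

The N=2 numbers are the exact two-fish null statistics: a mean
polarization of 2/π ≈ 0.64 and a peak of the PDF at P = 1 arise from
pure chance alignment, not schooling. The scaling fit recovers the
structure that was built into the synthetic shoals: below the crossover
the mean squared polarization follows the schooling law N^(−1/2) with
unit coefficient; above it, shoals behave as independent domains of
n ≈ 3 aligned fish (⟨P²⟩ = n/N), and the two laws intersect at
N_c ≈ n² ≈ 9 — the characteristic size separating the two regimes.

The same workflow is scriptable from the shell:

```
shoalpol null -n 2 -n 30 -o null.tsv        # null-model quantifiers
shoalpol mc -n 5 --samples 1000000 -o mc.tsv
shoalpol simulate -n 12 --regime domain --n-domain 3 -o traj.csv
shoalpol polarize traj.csv -o pol.tsv
shoalpol run -c manifest.yaml -o runs/full  # simulate -> polarize -> fit
```

## Documentation

See `docs/methods.md` for the statistical model, the numerical scheme
behind the oscillatory Bessel integrals, the synthetic-data design, and
known limitations.
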