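"""Polarization statistics of shoals with fully uncorrelated velocity directions.

The polarization P of N fish whose unit velocity directors point in
independent, uniformly distributed directions is the length of a random
phasor sum: P = |(1/N) Σ exp(i θ_k)| with θ_k ~ U[0, 2π).  This is the
classic Pearson random walk / optical-speckle problem.  The density of P
follows from the Kluyver inversion of the 2-D characteristic function,

    f_P(p) = N² p ∫_0^∞ t J0(t)^N J0(N p t) dt ,        p ∈ [0, 1],

with closed forms at N = 2 (arcsine-type) and in the N >> 1 limit
(Rayleigh for P, exponential for P²).  Moments of P² are exact for every
N:  <P²> = 1/N and SD(P²) = (1/N)√(1 − 1/N).

The semi-infinite Bessel integral is highly oscillatory; it is evaluated
by fixed-length panel Gauss–Legendre quadrature accelerated with Wynn's
epsilon algorithm on the partial sums, with plain truncation once the
integrand envelope is negligible (fast for large N, where J0(t)^N decays
like a Gaussian in t).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import special

from .exceptions import NumericError

__all__ = [
    "NullQuantifiers",
    "PdfCurve",
    "closed_form_quantifiers",
    "null_pdf",
    "null_cdf",
    "pdf_curve",
    "quantifier_rows",
    "write_quantifiers",
    "write_curve",
]

Variable = Literal["P", "P_squared"]
Method = Literal["auto", "exact_n2", "asymptotic", "bessel_integral"]

#: default shoal size above which the Rayleigh/exponential limiting laws
#: replace quadrature in ``method="auto"``; conservative, configurable.
ASYMPTOTIC_THRESHOLD = 64

# N = 2 closed-form constants
MEAN_P_N2 = 2.0 / math.pi
SD_P_N2 = math.sqrt((math.pi**2 - 8.0) / (2.0 * math.pi**2))
RATIO_P_N2 = math.sqrt(8.0 / (math.pi**2 - 8.0))

# large-N coefficients of the N^{-1/2} laws
MEAN_P_COEF = math.sqrt(math.pi / 4.0)
SD_P_COEF = math.sqrt((4.0 - math.pi) / 4.0)
RATIO_P_LIMIT = math.sqrt(math.pi / (4.0 - math.pi))


@dataclass(frozen=True)
class NullQuantifiers:
    """Mean, SD and mean/SD ratio of P and P² under the uncorrelated null."""

    N: int
    mean_P: float
    sd_P: float
    ratio_P: float
    mean_P2: float
    sd_P2: float
    ratio_P2: float
    method_P: str = "closed_form_exact"
    method_P2: str = "closed_form_exact"


@dataclass(frozen=True)
class PdfCurve:
    """A probability density sampled on an ordered grid in [0, 1].

    ``tail_mass`` carries analytic probability mass lying outside the grid
    (used for the integrable endpoint divergences of the N=2 closed forms,
    where trapezoids cannot represent the spike).
    """

    variable: str
    N: int
    grid: np.ndarray
    density: np.ndarray
    method: str
    tail_mass: float = 0.0
    meta: dict = field(default_factory=dict)

    def normalization(self) -> float:
        """Trapezoidal mass over the grid plus any analytic tail mass."""
        return float(np.trapezoid(self.density, self.grid)) + self.tail_mass


def _check_n(N) -> int:
    if not (isinstance(N, (int, np.integer)) and not isinstance(N, bool)) or N < 1:
        raise ValueError(f"N must be an integer >= 1, got {N!r}")
    return int(N)


# ---------------------------------------------------------------------------
# oscillatory Kluyver integral
# ---------------------------------------------------------------------------

_GL_X, _GL_W = leggauss(24)


def _wynn_epsilon(S: np.ndarray) -> float:
    """Accelerate a sequence of partial sums with Wynn's epsilon algorithm.

    Returns the deepest finite even-column entry.  Suitable for tails that
    are superpositions of decaying oscillations with several frequencies,
    where the Euler transform (alternating series only) fails.
    """
    n = len(S)
    e_prev = np.zeros(n)
    e_curr = np.asarray(S, dtype=float).copy()
    best = e_curr[-1]
    for k in range(1, n):
        m = n - k
        with np.errstate(divide="ignore", invalid="ignore"):
            diff = e_curr[1 : m + 1] - e_curr[:m]
            e_next = e_prev[1 : m + 1] + 1.0 / diff
        e_prev, e_curr = e_curr, e_next
        if k % 2 == 0 and np.isfinite(e_curr[m - 1]):
            best = e_curr[m - 1]
    return float(best)


def _panel_integrals(N: int, b: float, h: float, n_panels: int) -> np.ndarray:
    edges = h * np.arange(n_panels + 1)
    mid = 0.5 * (edges[1:] + edges[:-1])
    t = mid[:, None] + (0.5 * h) * _GL_X[None, :]
    f = t * special.j0(t) ** N * special.j0(b * t)
    return (0.5 * h) * (f @ _GL_W)


def kluyver_integral(
    N: int, b: float, n_panels: int = 240, tail_from: int = 40
) -> float:
    """``∫_0^∞ t J0(t)^N J0(b t) dt`` for integer N >= 2 and b >= 0.

    Panels of length π/(1+b) resolve both oscillation scales; the partial
    sums are extrapolated with Wynn's epsilon algorithm unless the tail has
    already vanished below 1e-14 (typical for N >~ 10, where |J0|^N decays
    rapidly away from t = 0).

    Near the resonances b ≈ k of the cos^N harmonics k ∈ {N, N−2, ...}
    the large-t integrand contains a component oscillating at the slow
    beat frequency |k − b|; for small N (weak t^{-(N-1)/2} decay) plain
    panel sums then converge too slowly for the accelerator.  There the
    panels are grouped into blocks of half a beat period, which restores
    an alternating-like block sequence that Wynn's algorithm handles.
    """
    h = math.pi / (1.0 + b)
    if N <= 8:
        harmonics = np.arange(N, -1, -2, dtype=float)
        beat = float(np.min(np.abs(harmonics - b)))
        if beat < 1.0:
            # block length = half beat period (capped near exact resonance,
            # where the density may be genuinely singular, e.g. N=3 at b=1)
            block_len = math.pi / max(beat, 2e-3)
            per_block = max(int(math.ceil(block_len / h)), 1)
            n_blocks = 24
            panel = _panel_integrals(N, b, h, per_block * n_blocks)
            S = np.cumsum(panel)[per_block - 1 :: per_block]
            value = _wynn_epsilon(S)
            if not math.isfinite(value):
                raise NumericError(
                    f"Kluyver integral failed to converge (N={N}, b={b})",
                    residual=float(abs(panel[-1])),
                )
            return value
    panel = _panel_integrals(N, b, h, n_panels)
    S = np.cumsum(panel)
    if np.all(np.abs(panel[-20:]) < 1e-14):
        return float(S[-1])
    value = _wynn_epsilon(S[tail_from:])
    if not math.isfinite(value):
        raise NumericError(
            f"Kluyver integral failed to converge (N={N}, b={b})",
            residual=float(abs(panel[-1])),
        )
    return value


def _bessel_pdf_P(N: int, p: float) -> float:
    if p == 0.0:
        return 0.0
    return N * N * p * kluyver_integral(N, N * p)


def _bessel_pdf_P2(N: int, x: float) -> float:
    # change of variables: f_{P²}(x) = f_P(√x) / (2√x)
    return 0.5 * N * N * kluyver_integral(N, N * math.sqrt(x))


# ---------------------------------------------------------------------------
# pointwise densities and CDFs
# ---------------------------------------------------------------------------


def _resolve_method(N: int, method: str, threshold: int) -> str:
    if method != "auto":
        return method
    if N == 2:
        return "exact_n2"
    if N < threshold:
        return "bessel_integral"
    return "asymptotic"


def null_pdf(
    variable: Variable,
    N: int,
    x: float,
    method: Method = "auto",
    asymptotic_threshold: int = ASYMPTOTIC_THRESHOLD,
) -> float:
    """Pointwise null-model density of P or P² at ``x`` in [0, 1].

    ``method="auto"`` picks the exact N=2 closed form, the Bessel-integral
    quadrature for 2 < N < ``asymptotic_threshold``, and the Rayleigh /
    exponential limiting law above it.
    """
    N = _check_n(N)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1], got {x}")
    if variable not in ("P", "P_squared"):
        raise ValueError(f"unknown variable {variable!r}")
    method = _resolve_method(N, method, asymptotic_threshold)
    if method == "exact_n2":
        if N != 2:
            raise ValueError("method='exact_n2' requires N=2")
        if variable == "P":
            if x == 1.0:
                return math.inf
            return 2.0 / (math.pi * math.sqrt(1.0 - x * x))
        if x in (0.0, 1.0):
            return math.inf
        return 1.0 / (math.pi * math.sqrt(x * (1.0 - x)))
    if method == "asymptotic":
        if variable == "P":
            return 2.0 * N * x * math.exp(-N * x * x)
        return N * math.exp(-N * x)
    if method == "bessel_integral":
        if variable == "P":
            return _bessel_pdf_P(N, x)
        return _bessel_pdf_P2(N, x)
    raise ValueError(f"unknown method {method!r}")


@lru_cache(maxsize=64)
def _bessel_cdf_table(variable: str, N: int, n_grid: int = 1024):
    grid = (np.arange(n_grid) + 0.5) / n_grid
    dens = np.array([null_pdf(variable, N, float(g), "bessel_integral") for g in grid])
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))))
    cum += grid[0] * dens[0] * 0.5  # leading wedge from x=0
    total = cum[-1] + (1.0 - grid[-1]) * dens[-1] * 0.5
    return grid, cum / total


def null_cdf(
    variable: Variable,
    N: int,
    x,
    method: Method = "auto",
    asymptotic_threshold: int = ASYMPTOTIC_THRESHOLD,
):
    """Null-model CDF of P or P² (vectorized in ``x``)."""
    N = _check_n(N)
    method = _resolve_method(N, method, asymptotic_threshold)
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    if method == "exact_n2":
        if variable == "P":
            out = (2.0 / math.pi) * np.arcsin(x)
        else:
            out = (2.0 / math.pi) * np.arcsin(np.sqrt(x))
    elif method == "asymptotic":
        if variable == "P":
            out = 1.0 - np.exp(-N * x * x)
        else:
            out = 1.0 - np.exp(-N * x)
    else:
        grid, cum = _bessel_cdf_table(variable, N)
        out = np.interp(x, grid, cum, left=0.0, right=1.0)
    return out if out.ndim else float(out)


def pdf_curve(
    variable: Variable,
    N: int,
    n_grid: int = 512,
    method: Method = "auto",
    asymptotic_threshold: int = ASYMPTOTIC_THRESHOLD,
) -> PdfCurve:
    """Sample the null density on an open midpoint grid of ``n_grid`` points.

    Open endpoints keep the integrable divergences of the N=2 forms (at
    P = 1, and at P² = 0 and 1) off the grid; their analytic mass beyond the
    outermost grid points is carried in ``tail_mass`` so that the curve's
    ``normalization()`` is exact for the closed forms.
    """
    N = _check_n(N)
    if n_grid < 16:
        raise ValueError("n_grid must be >= 16")
    method = _resolve_method(N, method, asymptotic_threshold)
    grid = (np.arange(n_grid) + 0.5) / n_grid
    dens = np.array(
        [null_pdf(variable, N, float(g), method, asymptotic_threshold) for g in grid]
    )
    tail = 0.0
    if method == "exact_n2":
        # endpoint divergences are integrable but invisible to trapezoids;
        # assert normalization through the analytic arcsine CDF instead
        inner = float(np.trapezoid(dens, grid))
        tail = 1.0 - inner
    elif method == "asymptotic":
        lo = null_cdf(variable, N, float(grid[0]), method)
        hi = null_cdf(variable, N, float(grid[-1]), method)
        cdf_at_1 = null_cdf(variable, N, 1.0, method)
        tail = lo + (cdf_at_1 - hi)
    return PdfCurve(variable=variable, N=N, grid=grid, density=dens, method=method, tail_mass=tail)


# ---------------------------------------------------------------------------
# quantifiers
# ---------------------------------------------------------------------------

_MOM_PANELS = 96
_MOM_X, _MOM_W = leggauss(6)


@lru_cache(maxsize=256)
def _numeric_mean_P(N: int) -> float:
    """First moment of the Bessel-integral density by composite quadrature."""
    edges = np.linspace(0.0, 1.0, _MOM_PANELS + 1)
    mid = 0.5 * (edges[1:] + edges[:-1])
    half = 0.5 * (edges[1] - edges[0])
    total = 0.0
    for m in mid:
        pts = m + half * _MOM_X
        vals = np.array([p * _bessel_pdf_P(N, float(p)) for p in pts])
        total += half * float(vals @ _MOM_W)
    return total


def closed_form_quantifiers(
    N: int, asymptotic_threshold: int = ASYMPTOTIC_THRESHOLD
) -> NullQuantifiers:
    """Null-model mean/SD/ratio of P and P² for a shoal of ``N`` fish.

    P² statistics are exact at every N (<P²> = 1/N).  P statistics are exact
    at N in {1, 2}, Rayleigh-moment asymptotics at N >= the threshold, and
    quadrature of the Bessel-integral density otherwise.
    """
    N = _check_n(N)
    mean_P2 = 1.0 / N
    sd_P2 = mean_P2 * math.sqrt(1.0 - 1.0 / N)
    ratio_P2 = 1.0 / math.sqrt(1.0 - 1.0 / N) if N > 1 else math.nan
    if N == 1:
        return NullQuantifiers(1, 1.0, 0.0, math.nan, 1.0, 0.0, math.nan)
    if N == 2:
        return NullQuantifiers(
            2, MEAN_P_N2, SD_P_N2, RATIO_P_N2, mean_P2, sd_P2, ratio_P2
        )
    if N >= asymptotic_threshold:
        mean_P = MEAN_P_COEF / math.sqrt(N)
        sd_P = SD_P_COEF / math.sqrt(N)
        method = "asymptotic"
    else:
        mean_P = _numeric_mean_P(N)
        # second moment of P is exactly 1/N, so SD needs no extra quadrature
        sd_P = math.sqrt(max(mean_P2 - mean_P * mean_P, 0.0))
        method = "numeric"
    return NullQuantifiers(
        N,
        mean_P,
        sd_P,
        mean_P / sd_P,
        mean_P2,
        sd_P2,
        ratio_P2,
        method_P=method,
        method_P2="closed_form_exact",
    )


# ---------------------------------------------------------------------------
# table output
# ---------------------------------------------------------------------------


def quantifier_rows(q: NullQuantifiers) -> list[dict]:
    """Flatten quantifiers into variable/N/statistic/value/method rows."""
    rows = []
    for var, stats, meth in (
        ("P", (("mean", q.mean_P), ("sd", q.sd_P), ("ratio", q.ratio_P)), q.method_P),
        (
            "P_squared",
            (("mean", q.mean_P2), ("sd", q.sd_P2), ("ratio", q.ratio_P2)),
            q.method_P2,
        ),
    ):
        for stat, value in stats:
            rows.append(
                {"variable": var, "N": q.N, "statistic": stat, "value": value, "method": meth}
            )
    return rows


def write_quantifiers(quants, tsv_path, json_path=None) -> None:
    """Write quantifiers as a TSV table and an optional JSON summary."""
    import pandas as pd

    rows = [r for q in quants for r in quantifier_rows(q)]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=1)


def write_curve(curve: PdfCurve, tsv_path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "variable": curve.variable,
            "N": curve.N,
            "x": curve.grid,
            "value": curve.density,
            "method": curve.method,
        }
    ).to_csv(tsv_path, sep="\t", index=False)
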