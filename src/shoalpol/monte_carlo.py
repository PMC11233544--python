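"""Seeded Monte Carlo sampling of the uncorrelated-shoal null model.

Each configuration draws N independent headings uniform on [0, 2π) and
records the polarization P = |(1/N) Σ (cos θ, sin θ)| and its square.
The sampler is the designated oracle for finite-N quantities without
closed forms, and for validating the Bessel-integral quadrature.

The bit generator is Philox (counter based), so the sample stream depends
only on the seed and the number of draws — batching exists purely to bound
memory and provably does not change the stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .null_model import PdfCurve

__all__ = ["McConfig", "SampleSet", "McQuantifiers", "sample_null", "summarize_samples"]


@dataclass(frozen=True)
class McConfig:
    """Sampling configuration; the default scale is 10⁶ configurations."""

    n_samples: int = 1_000_000
    seed: int = 0
    batch_size: int = 100_000

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class SampleSet:
    N: int
    values_P: np.ndarray
    values_P2: np.ndarray
    config: McConfig


@dataclass(frozen=True)
class McQuantifiers:
    """Sample quantifiers with Monte Carlo standard errors.

    Ratios mean/SD carry delta-method standard errors; a degenerate
    (constant) sample leaves SD = 0 and flags the ratio as NaN rather
    than emitting an infinity.
    """

    N: int
    n_samples: int
    mean_P: float
    se_mean_P: float
    sd_P: float
    se_sd_P: float
    ratio_P: float
    se_ratio_P: float
    mean_P2: float
    se_mean_P2: float
    sd_P2: float
    se_sd_P2: float
    ratio_P2: float
    se_ratio_P2: float
    method: str = "monte_carlo"


def sample_null(N: int, config: McConfig) -> SampleSet:
    """Draw ``config.n_samples`` polarizations of N uncorrelated unit directors."""
    if not (isinstance(N, (int, np.integer)) and N >= 1):
        raise ValueError(f"N must be an integer >= 1, got {N!r}")
    rng = np.random.Generator(np.random.Philox(config.seed))
    out = np.empty(config.n_samples)
    done = 0
    while done < config.n_samples:
        m = min(config.batch_size, config.n_samples - done)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(m, N))
        out[done : done + m] = (
            np.hypot(np.cos(theta).sum(axis=1), np.sin(theta).sum(axis=1)) / N
        )
        done += m
    np.clip(out, 0.0, 1.0, out=out)
    return SampleSet(N=int(N), values_P=out, values_P2=out * out, config=config)


def _moment_stats(x: np.ndarray):
    """mean, sd and ratio of a sample with standard errors.

    SE of the SD and the delta-method SE of mean/SD use the sample's
    second and fourth central moments; adequate at the 10⁶-draw scale.
    """
    n = x.size
    mean = float(x.mean())
    dev = x - mean
    m2 = float((dev**2).mean())
    m3 = float((dev**3).mean())
    m4 = float((dev**4).mean())
    sd = math.sqrt(m2)
    se_mean = sd / math.sqrt(n)
    if sd == 0.0:
        return mean, se_mean, 0.0, 0.0, math.nan, math.nan
    var_var = max(m4 - m2 * m2, 0.0) / n
    se_sd = 0.5 * math.sqrt(var_var) / sd
    ratio = mean / sd
    # delta method on (mean, sd): grad = (1/sd, -mean/sd²); cov(mean, sd) ≈ m3/(2 sd n)
    cov_mean_sd = m3 / (2.0 * sd * n)
    var_ratio = (
        (se_mean / sd) ** 2
        + (mean * se_sd / m2) ** 2
        - 2.0 * mean * cov_mean_sd / (sd**3)
    )
    se_ratio = math.sqrt(max(var_ratio, 0.0))
    return mean, se_mean, sd, se_sd, ratio, se_ratio


def summarize_samples(
    samples: SampleSet, n_bins: int = 50
) -> tuple[McQuantifiers, PdfCurve, PdfCurve]:
    """Quantifiers with standard errors plus histogram density curves for P and P²."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sP = _moment_stats(samples.values_P)
    sP2 = _moment_stats(samples.values_P2)
    quant = McQuantifiers(
        samples.N, samples.values_P.size, *sP, *sP2, method="monte_carlo"
    )
    curves = []
    for var, vals in (("P", samples.values_P), ("P_squared", samples.values_P2)):
        hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0), density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        curves.append(
            PdfCurve(
                variable=var,
                N=samples.N,
                grid=centers,
                density=hist,
                method="monte_carlo",
                # histogram mass is exactly 1 by construction; the trapezoid
                # over bin centers misses the half-bin wedges at both ends
                tail_mass=float(
                    0.5 * (hist[0] + hist[-1]) * (edges[1] - edges[0])
                ),
                meta={"n_samples": samples.values_P.size, "seed": samples.config.seed},
            )
        )
    return quant, curves[0], curves[1]


def mc_quantifier_rows(q: McQuantifiers) -> list[dict]:
    """Rows in the shared variable/N/statistic/value/method table layout."""
    rows = []
    for var, trips in (
        ("P", (("mean", q.mean_P, q.se_mean_P), ("sd", q.sd_P, q.se_sd_P), ("ratio", q.ratio_P, q.se_ratio_P))),
        ("P_squared", (("mean", q.mean_P2, q.se_mean_P2), ("sd", q.sd_P2, q.se_sd_P2), ("ratio", q.ratio_P2, q.se_ratio_P2))),
    ):
        for stat, value, se in trips:
            rows.append(
                {
                    "variable": var,
                    "N": q.N,
                    "statistic": stat,
                    "value": value,
                    "se": se,
                    "method": "monte_carlo",
                    "n_samples": q.n_samples,
                }
            )
    return rows
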