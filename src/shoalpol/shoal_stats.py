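"""Per-trial and per-shoal-size quantifiers and empirical PDFs of P and P².

The quantifiers mirror the null model's: time-averaged mean, SD and
mean/SD ratio of the polarization and its square, aggregated over the
five trials of each shoal size.  Empirical histograms are compared to the
null model through the Kolmogorov–Smirnov distance, both at the nominal N
and at the effective size N* = N / n̂, where n̂ = N <P²> is the effective
cluster size: the number of fish per internally aligned, mutually
independent domain consistent with the observed variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import null_model
from .null_model import PdfCurve
from .polarization import PolarizationSeries

__all__ = [
    "TrialSummary",
    "GroupSummary",
    "trial_quantifiers",
    "aggregate_trials",
    "empirical_pdf",
    "NullComparison",
]


@dataclass(frozen=True)
class TrialSummary:
    N: int
    trial_id: str
    mean_P: float
    sd_P: float
    ratio_P: float
    mean_P2: float
    sd_P2: float
    ratio_P2: float
    n_frames: int


@dataclass(frozen=True)
class GroupSummary:
    """Across-trial aggregate for one shoal size.

    ``mean_*``/``sd_*`` are unweighted across-trial means of the trial
    quantifiers (the SD is the average time-series SD, i.e. a noise
    estimator); ``se_*`` are between-trial standard errors; ``pooled_*``
    are the frame-weighted alternatives.
    """

    N: int
    n_trials: int
    n_frames: int
    mean_P: float
    se_mean_P: float
    sd_P: float
    se_sd_P: float
    ratio_P: float
    mean_P2: float
    se_mean_P2: float
    sd_P2: float
    se_sd_P2: float
    ratio_P2: float
    pooled_mean_P: float
    pooled_mean_P2: float


@dataclass(frozen=True)
class NullComparison:
    """KS distances of pooled data against the uncorrelated null."""

    variable: str
    N: int
    n_hat: float
    se_n_hat: float
    N_star: float
    ks_same_N: float
    ks_effective: float
    n_frames: int
    meta: dict = field(default_factory=dict)


def _series_values(series: PolarizationSeries) -> np.ndarray:
    return series.P[series.valid]


def trial_quantifiers(series: PolarizationSeries, trial_id: str = "") -> TrialSummary:
    """Time-averaged moments of P and P² over the valid frames of one trial."""
    P = _series_values(series)
    if P.size < 2:
        raise ValueError("need at least 2 valid frames")
    P2 = P * P
    out = {}
    for name, x in (("P", P), ("P2", P2)):
        mean = float(x.mean())
        sd = float(x.std())
        if sd <= 1e-12:  # constant series up to round-off: ratio undefined
            sd = 0.0
        out[f"mean_{name}"] = mean
        out[f"sd_{name}"] = sd
        out[f"ratio_{name}"] = mean / sd if sd > 0.0 else math.nan
    N = int(series.meta.get("N", series.n_effective.max()))
    return TrialSummary(
        N=N,
        trial_id=trial_id or str(series.meta.get("trial_id", "")),
        n_frames=int(P.size),
        **out,
    )


def aggregate_trials(summaries: list[TrialSummary]) -> GroupSummary:
    """Across-trial mean, between-trial SE and pooled alternative for one N."""
    if not summaries:
        raise ValueError("no trial summaries given")
    Ns = {s.N for s in summaries}
    if len(Ns) > 1:
        raise ValueError(f"mixed shoal sizes in aggregate: {sorted(Ns)}")
    k = len(summaries)
    frames = np.array([s.n_frames for s in summaries], dtype=float)
    w = frames / frames.sum()

    def across(attr):
        vals = np.array([getattr(s, attr) for s in summaries])
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / math.sqrt(k)) if k > 1 else 0.0
        return mean, se, float(w @ vals)

    mP, seP, pooled_P = across("mean_P")
    sdP, se_sdP, _ = across("sd_P")
    mP2, seP2, pooled_P2 = across("mean_P2")
    sdP2, se_sdP2, _ = across("sd_P2")
    return GroupSummary(
        N=summaries[0].N,
        n_trials=k,
        n_frames=int(frames.sum()),
        mean_P=mP,
        se_mean_P=seP,
        sd_P=sdP,
        se_sd_P=se_sdP,
        ratio_P=mP / sdP if sdP > 0 else math.nan,
        mean_P2=mP2,
        se_mean_P2=seP2,
        sd_P2=sdP2,
        se_sd_P2=se_sdP2,
        ratio_P2=mP2 / sdP2 if sdP2 > 0 else math.nan,
        pooled_mean_P=pooled_P,
        pooled_mean_P2=pooled_P2,
    )


def _ks_distance(values: np.ndarray, cdf) -> float:
    x = np.sort(values)
    n = x.size
    c = np.asarray(cdf(x))
    lo = np.max(np.abs(c - np.arange(n) / n))
    hi = np.max(np.abs(c - np.arange(1, n + 1) / n))
    return float(max(lo, hi))


def empirical_pdf(
    series: PolarizationSeries | list[PolarizationSeries],
    variable: str = "P",
    n_bins: int = 50,
    nominal_N: int | None = None,
) -> tuple[PdfCurve, NullComparison]:
    """Pooled histogram density plus a comparison against the matched null.

    The comparison reports the KS distance of the pooled sample against
    the null CDF at the nominal N and at the effective shoal size
    N* = N / n̂ (nearest integer >= 1), with n̂ = N <P²> and its
    between-frame standard error.
    """
    if isinstance(series, PolarizationSeries):
        series = [series]
    P = np.concatenate([_series_values(s) for s in series])
    if P.size < 10 * n_bins:
        raise ValueError("need at least 10 frames per bin for a stable histogram")
    vals = P if variable == "P" else P * P
    N = int(nominal_N or series[0].meta.get("N", series[0].n_effective.max()))
    hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0), density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    curve = PdfCurve(
        variable="P" if variable == "P" else "P_squared",
        N=N,
        grid=centers,
        density=hist,
        method="monte_carlo",
        tail_mass=float(0.5 * (hist[0] + hist[-1]) * (edges[1] - edges[0])),
        meta={"empirical": True, "n_frames": int(P.size)},
    )
    P2 = P * P
    n_hat = N * float(P2.mean())
    se_n_hat = N * float(P2.std() / math.sqrt(P2.size))
    N_star = N / n_hat if n_hat > 0 else math.inf
    var = curve.variable
    ks_same = _ks_distance(vals, lambda x: null_model.null_cdf(var, N, x))
    N_eff = max(2, int(round(N_star)))
    ks_eff = _ks_distance(vals, lambda x: null_model.null_cdf(var, N_eff, x))
    comparison = NullComparison(
        variable=var,
        N=N,
        n_hat=n_hat,
        se_n_hat=se_n_hat,
        N_star=N_star,
        ks_same_N=ks_same,
        ks_effective=ks_eff,
        n_frames=int(P.size),
        meta={"N_effective_used": N_eff},
    )
    return curve, comparison


def group_rows(g: GroupSummary) -> list[dict]:
    """Summary rows mirroring the null-model quantifier table, plus n̂."""
    n_hat = g.N * g.mean_P2
    rows = []
    for var, mean, se, sd, se_sd, ratio in (
        ("P", g.mean_P, g.se_mean_P, g.sd_P, g.se_sd_P, g.ratio_P),
        ("P_squared", g.mean_P2, g.se_mean_P2, g.sd_P2, g.se_sd_P2, g.ratio_P2),
    ):
        rows.append(
            {
                "variable": var,
                "N": g.N,
                "mean": mean,
                "se_mean": se,
                "sd": sd,
                "se_sd": se_sd,
                "ratio": ratio,
                "n_trials": g.n_trials,
                "n_frames": g.n_frames,
                "n_hat": n_hat,
            }
        )
    return rows
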