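"""Finite-size scaling fits of polarization quantifiers versus shoal size.

Two laws organize the data.  Large shoals behave as N* = N/n independent
domains of n aligned fish, so <P²> = n/N (exponent 1, coefficient n > 1);
small shoals develop genuine schooling correlations, empirically
<P²> = 1/N^{1/2} (exponent 1/2, unit coefficient).  The crossover size is
where the two laws meet: with the small-N coefficient fixed at 1,
c_small N^{-1/2} = n N^{-1} gives N_c = n² exactly.

Fits are weighted least squares in log–log coordinates (relative errors
become additive weights there); the crossover is located by intersecting
the two independently fitted laws, and the split between regimes is
chosen by total weighted residual over all admissible splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .shoal_stats import GroupSummary

__all__ = [
    "ScalingDataset",
    "PowerLawFit",
    "ScalingFit",
    "fit_power_law",
    "fit_fixed_exponent",
    "two_regime_fit",
    "effective_cluster_size",
]


@dataclass(frozen=True)
class ScalingDataset:
    """(N, value, standard error) points for one quantifier."""

    N: np.ndarray
    value: np.ndarray
    se: np.ndarray
    quantifier: str = ""

    def __post_init__(self):
        N = np.asarray(self.N, dtype=float)
        v = np.asarray(self.value, dtype=float)
        se = np.asarray(self.se, dtype=float)
        if len({N.shape, v.shape, se.shape}) != 1 or N.ndim != 1:
            raise ValueError("N, value and se must be 1-D arrays of equal length")
        if len(np.unique(N)) != len(N) or np.any(N < 2):
            raise ValueError("N values must be distinct and >= 2")
        if np.any(v <= 0):
            raise ValueError("values must be positive (log-domain fit)")
        order = np.argsort(N)
        object.__setattr__(self, "N", N[order])
        object.__setattr__(self, "value", v[order])
        object.__setattr__(self, "se", se[order])

    @classmethod
    def from_group_summaries(
        cls, groups: list[GroupSummary], quantifier: str = "mean_P2"
    ) -> "ScalingDataset":
        se_attr = {"mean_P2": "se_mean_P2", "mean_P": "se_mean_P",
                   "sd_P2": "se_sd_P2", "sd_P": "se_sd_P"}[quantifier]
        return cls(
            N=np.array([g.N for g in groups], dtype=float),
            value=np.array([getattr(g, quantifier) for g in groups]),
            se=np.array([getattr(g, se_attr) for g in groups]),
            quantifier=quantifier,
        )

    def restrict(self, n_min=-math.inf, n_max=math.inf) -> "ScalingDataset":
        m = (self.N >= n_min) & (self.N <= n_max)
        return ScalingDataset(self.N[m], self.value[m], self.se[m], self.quantifier)


@dataclass(frozen=True)
class PowerLawFit:
    """value = coefficient · N^(−exponent); exponent reported decay-positive."""

    exponent: float
    coefficient: float
    exponent_se: float
    coefficient_se: float
    sign: int  # +1 if the quantity decays with N, −1 if it grows
    n_points: int
    n_range: tuple[float, float]
    resid_wss: float  # weighted sum of squared log residuals

    def exponent_ci(self, z: float = 1.96) -> tuple[float, float]:
        return (self.exponent - z * self.exponent_se, self.exponent + z * self.exponent_se)

    def coefficient_ci(self, z: float = 1.96) -> tuple[float, float]:
        return (
            self.coefficient - z * self.coefficient_se,
            self.coefficient + z * self.coefficient_se,
        )


def _log_weights(data: ScalingDataset) -> np.ndarray:
    rel = np.where(data.se > 0, data.se / data.value, np.nan)
    if np.all(np.isnan(rel)) or np.nanmax(rel) == 0:
        return np.ones_like(data.value)
    rel = np.where(np.isnan(rel) | (rel == 0), np.nanmin(rel[rel > 0]), rel)
    return 1.0 / rel**2


def fit_power_law(
    data: ScalingDataset, n_min: float = -math.inf, n_max: float = math.inf
) -> PowerLawFit:
    """Weighted least squares of log value on log N.

    Weights are inverse squared relative standard errors (the delta-method
    variance of a log); with no usable errors the fit is unweighted.
    """
    sub = data.restrict(n_min, n_max)
    if sub.N.size < 3:
        raise ValueError("need at least 3 points in range for a power-law fit")
    X = sm.add_constant(np.log(sub.N))
    w = _log_weights(sub)
    res = sm.WLS(np.log(sub.value), X, weights=w).fit()
    slope = float(res.params[1])
    coef = float(math.exp(res.params[0]))
    return PowerLawFit(
        exponent=abs(slope),
        coefficient=coef,
        exponent_se=float(res.bse[1]),
        coefficient_se=coef * float(res.bse[0]),
        sign=+1 if slope <= 0 else -1,
        n_points=int(sub.N.size),
        n_range=(float(sub.N.min()), float(sub.N.max())),
        resid_wss=float((w * res.resid**2).sum()),
    )


def fit_fixed_exponent(data: ScalingDataset, beta: float):
    """Fit the coefficient of an imposed power law value = c N^{-beta}.

    Weighted mean in log space; returns (c, se_c, weighted rss).  This is
    the one-parameter fit behind the two-regime laws (e.g. <P²> = n/N
    with the exponent fixed at 1 and n free).
    """
    w = _log_weights(data)
    y = np.log(data.value) + beta * np.log(data.N)
    logc = float((w * y).sum() / w.sum())
    resid = y - logc
    wss = float((w * resid**2).sum())
    k = data.N.size
    se_logc = math.sqrt(wss / ((k - 1) * w.sum())) if k > 1 else 0.0
    c = math.exp(logc)
    return c, c * se_logc, wss


@dataclass(frozen=True)
class ScalingFit:
    """Two-regime finite-size scaling fit of one quantifier.

    ``n`` is the large-N coefficient (effective domain size) of the
    n·N^{-beta_large} law, ``c_small`` the small-N coefficient, and ``N_c``
    the crossover where the two fitted laws intersect; with the canonical
    exponents (1/2, 1) and c_small = 1 this is exactly n².
    """

    quantifier: str
    beta_small: float
    beta_large: float
    c_small: float
    c_small_se: float
    n: float
    n_se: float
    N_c: float
    split_N: float
    no_crossover: bool
    small_fit_free: PowerLawFit | None
    large_fit_free: PowerLawFit | None
    resid_wss: float
    n_points: int
    meta: dict = field(default_factory=dict)

    def N_star_map(self, N) -> np.ndarray:
        """Effective number of independent domains N* = N / n."""
        return np.asarray(N, dtype=float) / self.n

    def summary(self) -> str:
        lines = [
            f"Two-regime scaling fit: {self.quantifier or 'quantifier'} vs N "
            f"({self.n_points} points)",
            "-" * 62,
            f"small-N law : {self.c_small:.4g} * N^-{self.beta_small:g}"
            f"   (c_small se {self.c_small_se:.2g})",
            f"large-N law : {self.n:.4g} * N^-{self.beta_large:g}"
            f"   (n se {self.n_se:.2g})",
            f"split at N  : {self.split_N:g}",
            f"crossover   : "
            + ("none within data range" if self.no_crossover else f"N_c = {self.N_c:.3g}"),
            f"n^2 identity: n^2 = {self.n**2:.3g}"
            + ("  (equals N_c when c_small = 1)" if not self.no_crossover else ""),
            f"weighted rss: {self.resid_wss:.3g}",
        ]
        if self.small_fit_free is not None:
            f = self.small_fit_free
            lines.append(
                f"free small-N exponent: {f.exponent:.3f} +- {f.exponent_se:.3f}"
            )
        if self.large_fit_free is not None:
            f = self.large_fit_free
            lines.append(
                f"free large-N exponent: {f.exponent:.3f} +- {f.exponent_se:.3f}"
            )
        return "\n".join(lines)


def two_regime_fit(
    data: ScalingDataset,
    candidate_exponents: tuple[float, float] = (0.5, 1.0),
    min_points: int = 3,
) -> ScalingFit:
    """Fit the two-regime crossover by intersecting independently fitted laws.

    Coefficients of the two imposed-exponent laws are fitted on every
    admissible split of the (sorted) N values with at least ``min_points``
    per side; the split with the lowest total weighted residual wins.
    The crossover N_c solves c_small N^{-β_small} = n N^{-β_large}.  If a
    single large-N law over all points explains the data at least as well,
    or the intersection falls outside the data range, ``no_crossover`` is
    flagged and n comes from the all-points fit.
    """
    beta_small, beta_large = candidate_exponents
    k = data.N.size
    if k < 2 * min_points:
        raise ValueError(
            f"need at least {2 * min_points} points for two regimes of {min_points}"
        )
    best = None
    for i in range(min_points, k - min_points + 1):
        split = 0.5 * (data.N[i - 1] + data.N[i])
        small = data.restrict(n_max=split)
        large = data.restrict(n_min=split)
        c_s, se_s, wss_s = fit_fixed_exponent(small, beta_small)
        c_l, se_l, wss_l = fit_fixed_exponent(large, beta_large)
        tot = wss_s + wss_l
        if best is None or tot < best[0]:
            best = (tot, split, (c_s, se_s), (c_l, se_l))
    tot, split, (c_s, se_s), (c_l, se_l) = best
    # single-regime alternative: the large-N law over all points
    c_all, se_all, wss_all = fit_fixed_exponent(data, beta_large)
    if beta_large != beta_small:
        N_c = (c_l / c_s) ** (1.0 / (beta_large - beta_small))
    else:
        N_c = math.inf
    in_range = data.N.min() <= N_c <= data.N.max()
    no_crossover = (wss_all <= tot) or not in_range
    if no_crossover:
        c_l, se_l = c_all, se_all
        tot = wss_all
        N_c = math.nan
        split = math.nan
    small_free = large_free = None
    if not no_crossover:
        try:
            small_free = fit_power_law(data, n_max=split)
        except ValueError:
            pass
        try:
            large_free = fit_power_law(data, n_min=split)
        except ValueError:
            pass
    return ScalingFit(
        quantifier=data.quantifier,
        beta_small=beta_small,
        beta_large=beta_large,
        c_small=c_s,
        c_small_se=se_s,
        n=c_l,
        n_se=se_l,
        N_c=N_c,
        split_N=split,
        no_crossover=bool(no_crossover),
        small_fit_free=small_free,
        large_fit_free=large_free,
        resid_wss=tot,
        n_points=k,
        meta={"theory_split_Nc_equals_n2": c_l**2},
    )


def effective_cluster_size(group: GroupSummary) -> tuple[float, float, float]:
    """n̂ = N <P²> with propagated SE, and N* = N / n̂."""
    if not group.mean_P2 > 0:
        raise ValueError("mean_P2 must be positive")
    n_hat = group.N * group.mean_P2
    se = group.N * group.se_mean_P2
    return n_hat, se, group.N / n_hat
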