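"""Synthetic heading sets and arena-confined trajectories.

Three heading regimes span the correlation structures seen in shoaling
experiments:

``uncorrelated``
    every fish draws an independent uniform heading each frame, the
    speckle null model; E[P²] = 1/N.
``domain``
    the shoal splits into groups of ``n_domain`` fish (remainder in a
    final smaller group); all members of a group share one uniform
    heading per frame and groups are independent; E[P²] = Σ n_k² / N²,
    equal to n/N when n divides N.
``schooling``
    each frame has one common uniform heading; every fish adds
    independent von Mises angular noise whose mean resultant length is
    √ρ, so the pairwise directional correlation E[cos θ_ij] equals ρ for
    i ≠ j and E[P²] = 1/N + (1 − 1/N) ρ.

``persistence`` adds frame-to-frame carryover: each independent heading
stream keeps its previous value with that probability, else redraws.
This leaves all single-frame distributions (and hence all E[P²] targets)
untouched while giving each heading stream an autocorrelation
E[cos(θ_{t+1} − θ_t)] = ``persistence``.

Trajectories integrate the headings at constant speed inside a circular
arena (default radius 25 cm, i.e. a 50 cm tank), with a smooth reflection
of the wall-normal heading component near the boundary; frames where the
wall interfered are flagged in the validity mask so statistics can
exclude them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import optimize, special

__all__ = [
    "RegimeSpec",
    "DirectionSet",
    "TrajectorySet",
    "draw_directions",
    "rho_for_sqrt_scaling",
    "kappa_from_resultant_length",
    "synthesize_trial",
]

#: trial shape mirroring the recording protocol: 8.5 min at 30 fps in a
#: 50 cm circular tank, five trials per shoal size
DEFAULT_DT = 1.0 / 30.0
DEFAULT_TRIAL_SECONDS = 8.5 * 60.0
DEFAULT_ARENA_RADIUS = 25.0
DEFAULT_SPEED = 3.0  # cm/s, about one adult-zebrafish body length per second
TRIALS_PER_N = 5
PROTOCOL_N_VALUES = (2, 3, 5, 8, 10, 13, 15, 18, 20, 25, 30)


@dataclass(frozen=True)
class RegimeSpec:
    kind: Literal["uncorrelated", "domain", "schooling"]
    n_domain: int = 1
    rho: float = 0.0
    persistence: float = 0.0

    def __post_init__(self):
        if self.kind not in ("uncorrelated", "domain", "schooling"):
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.kind == "domain" and self.n_domain < 1:
            raise ValueError("n_domain must be >= 1")
        if self.kind == "schooling" and not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")

    def expected_P2(self, N: int) -> float:
        """Closed-form E[P²] for a shoal of N fish under this regime."""
        if self.kind == "uncorrelated":
            return 1.0 / N
        if self.kind == "domain":
            sizes = _domain_sizes(N, self.n_domain)
            return float(sum(s * s for s in sizes)) / (N * N)
        return 1.0 / N + (1.0 - 1.0 / N) * self.rho


@dataclass(frozen=True)
class DirectionSet:
    """T × N headings in radians with the regime that generated them."""

    headings: np.ndarray
    regime: RegimeSpec
    seed: int

    @property
    def T(self) -> int:
        return self.headings.shape[0]

    @property
    def N(self) -> int:
        return self.headings.shape[1]

    def polarization(self) -> np.ndarray:
        """Per-frame P computed directly from the headings."""
        z = np.exp(1j * self.headings).mean(axis=1)
        return np.abs(z)


@dataclass(frozen=True)
class TrajectorySet:
    """T × N × 2 positions (cm) integrated from a DirectionSet."""

    positions: np.ndarray
    dt: float
    arena_radius: float
    speed: float
    valid: np.ndarray  # (T, N) mask; False where the wall deflected the heading
    directions: DirectionSet | None = None
    meta: dict = field(default_factory=dict)


def _domain_sizes(N: int, n_domain: int) -> list[int]:
    if n_domain > N:
        raise ValueError(f"n_domain={n_domain} exceeds N={N}")
    full, rem = divmod(N, n_domain)
    return [n_domain] * full + ([rem] if rem else [])


def kappa_from_resultant_length(r: float) -> float:
    """Von Mises concentration κ with mean resultant length I1(κ)/I0(κ) = r.

    Safeguarded root find on the monotone ratio; r = 0 maps to κ = 0
    (uniform) and r → 1 to κ ≈ 1/(2(1 − r)).
    """
    if not 0.0 <= r < 1.0:
        raise ValueError("mean resultant length must lie in [0, 1)")
    if r == 0.0:
        return 0.0
    if r > 1.0 - 1e-12:
        return 0.5 / (1.0 - r)

    def f(k):
        return special.i1e(k) / special.i0e(k) - r

    # bracket: A(κ) ≈ κ/2 small κ, ≈ 1 − 1/(2κ) large κ
    lo, hi = 1e-8, max(4.0, 1.0 / (1.0 - r))
    while f(hi) < 0.0:
        hi *= 2.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def rho_for_sqrt_scaling(N: int) -> float:
    """Pairwise correlation giving E[P²] = N^{-1/2} under the schooling model.

    Solves 1/N + (1 − 1/N) ρ = N^{-1/2}, i.e. ρ = (√N − 1)/(N − 1).
    """
    if not N >= 2:
        raise ValueError("N must be >= 2")
    return (math.sqrt(N) - 1.0) / (N - 1.0)


def _persist(fresh: np.ndarray, persistence: float, rng: np.random.Generator) -> np.ndarray:
    """Markov carryover along axis 0: keep previous value with prob ``persistence``.

    Marginals are untouched (each kept value was itself a fresh draw), so
    all single-frame expectations survive; only temporal correlation is added.
    """
    if persistence == 0.0:
        return fresh
    T = fresh.shape[0]
    refresh = rng.random(fresh.shape) >= persistence
    refresh[0] = True
    idx = np.where(refresh, np.arange(T).reshape((T,) + (1,) * (fresh.ndim - 1)), 0)
    idx = np.maximum.accumulate(idx, axis=0)
    return np.take_along_axis(fresh, idx, axis=0)


def draw_directions(N: int, T: int, regime: RegimeSpec, seed: int) -> DirectionSet:
    """Generate a T × N heading array under the given correlation regime."""
    if not N >= 2:
        raise ValueError("N must be >= 2")
    if not T >= 1:
        raise ValueError("T must be >= 1")
    rng = np.random.Generator(np.random.Philox(seed))
    two_pi = 2.0 * np.pi
    if regime.kind == "uncorrelated":
        headings = _persist(rng.uniform(0.0, two_pi, (T, N)), regime.persistence, rng)
    elif regime.kind == "domain":
        sizes = _domain_sizes(N, regime.n_domain)
        group = _persist(
            rng.uniform(0.0, two_pi, (T, len(sizes))), regime.persistence, rng
        )
        headings = np.repeat(group, sizes, axis=1)
    else:  # schooling
        common = _persist(rng.uniform(0.0, two_pi, (T, 1)), regime.persistence, rng)
        kappa = kappa_from_resultant_length(math.sqrt(regime.rho))
        if kappa == 0.0:
            noise = rng.uniform(-np.pi, np.pi, (T, N))
        else:
            noise = rng.vonmises(0.0, kappa, (T, N))
        noise = _persist(noise, regime.persistence, rng)
        headings = np.mod(common + noise, two_pi)
    return DirectionSet(headings=headings, regime=regime, seed=int(seed))


def synthesize_trial(
    directions: DirectionSet,
    arena_radius: float = DEFAULT_ARENA_RADIUS,
    speed: float = DEFAULT_SPEED,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    out_path: str | Path | None = None,
) -> TrajectorySet:
    """Integrate headings into positions inside the circular arena.

    Fish start at positions drawn uniformly in the inner half-radius disk
    (seeded; defaults to the DirectionSet seed) and take steps of length
    ``speed * dt`` along their headings.  A step that would exit the
    arena margin reflects the wall-normal component of the heading; such
    frames — and the frame before them, whose forward difference is
    affected — are flagged invalid, as are frames within 1 cm of the wall.
    Unflagged frames satisfy the round trip: directors recomputed by
    forward differencing reproduce the input headings.
    """
    step = speed * dt
    if not step < arena_radius / 10.0:
        raise ValueError("speed * dt must stay below arena_radius / 10")
    T, N = directions.T, directions.N
    rng = np.random.Generator(
        np.random.Philox(directions.seed if seed is None else seed)
    )
    r0 = 0.5 * arena_radius * np.sqrt(rng.random(N))
    a0 = rng.uniform(0.0, 2.0 * np.pi, N)
    pos = np.empty((T, N, 2))
    pos[0] = np.stack([r0 * np.cos(a0), r0 * np.sin(a0)], axis=1)
    valid = np.ones((T, N), dtype=bool)
    margin = arena_radius - 1.0  # flag anything within 1 cm of the wall
    limit = arena_radius - 1e-9
    headings = directions.headings
    for t in range(T - 1):
        hx, hy = np.cos(headings[t]), np.sin(headings[t])
        nxt = pos[t] + step * np.stack([hx, hy], axis=1)
        rad = np.hypot(nxt[:, 0], nxt[:, 1])
        out = rad > limit
        if np.any(out):
            # reflect the wall-normal component of the heading and retake the step
            px, py = pos[t, out, 0], pos[t, out, 1]
            rr = np.hypot(px, py)
            rr = np.where(rr == 0.0, 1.0, rr)
            nx, ny = px / rr, py / rr
            dot = hx[out] * nx + hy[out] * ny
            rx = hx[out] - 2.0 * dot * nx
            ry = hy[out] - 2.0 * dot * ny
            nxt[out, 0] = px + step * rx
            nxt[out, 1] = py + step * ry
            # a reflected step can still exit for grazing geometry; clamp inward
            rad2 = np.hypot(nxt[out, 0], nxt[out, 1])
            over = rad2 > limit
            if np.any(over):
                scale = (limit - 1e-6) / rad2[over]
                idx = np.flatnonzero(out)[over]
                nxt[idx, 0] *= scale
                nxt[idx, 1] *= scale
            valid[t, out] = False  # forward difference at t no longer matches
            valid[t + 1, out] = False
        pos[t + 1] = nxt
    near_wall = np.hypot(pos[:, :, 0], pos[:, :, 1]) > margin
    valid &= ~near_wall
    traj = TrajectorySet(
        positions=pos,
        dt=dt,
        arena_radius=arena_radius,
        speed=speed,
        valid=valid,
        directions=directions,
        meta={
            "N": N,
            "T": T,
            "seed": directions.seed,
            "regime": directions.regime.kind,
        },
    )
    if out_path is not None:
        write_trial(traj, out_path)
    return traj


def write_trial(traj: TrajectorySet, out_path: str | Path) -> None:
    """Write the wide trajectory CSV dialect plus a JSON metadata sidecar."""
    import pandas as pd

    out_path = Path(out_path)
    T, N, _ = traj.positions.shape
    data = {"frame": np.arange(T)}
    for i in range(N):
        data[f"x{i + 1}"] = traj.positions[:, i, 0]
        data[f"y{i + 1}"] = traj.positions[:, i, 1]
    pd.DataFrame(data).to_csv(out_path, index=False, float_format="%.12f")
    regime = traj.directions.regime if traj.directions is not None else None
    sidecar = {
        "N": N,
        "T": T,
        "dt": traj.dt,
        "arena_radius": traj.arena_radius,
        "speed": traj.speed,
        "seed": traj.meta.get("seed"),
        "regime": (
            {
                "kind": regime.kind,
                "n_domain": regime.n_domain,
                "rho": regime.rho,
                "persistence": regime.persistence,
            }
            if regime is not None
            else None
        ),
    }
    out_path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=1))
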