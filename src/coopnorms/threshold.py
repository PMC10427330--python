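"""One-dimensional conditional-cooperation threshold dynamics.

Norm sensitivities (the perceived cooperation level above which an
individual cooperates) are normally distributed on the probability scale.
Writing ``F`` for the cumulative distribution function, ``F(p)`` is the
fraction of the population willing to cooperate when a fraction ``p``
already does, and the cooperation frequency follows ``dp/dt = F(p) - p``.

Depending on the location and spread of the distribution the dynamic is
bistable — a *coordination* regime with stable low- and high-cooperation
states separated by an unstable one — or monostable, a *cooperation*
regime with a single stable low-cooperation state.  The distribution is
the untruncated normal CDF restricted to [0, 1], so ``F(0) > 0`` and
``F(1) < 1``: some individuals cooperate unconditionally and some never
do.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr

__all__ = [
    "NormSensitivity",
    "FixedPoint1D",
    "Stability",
    "Dilemma",
    "TangencyPoint",
    "rhs_basic",
    "fixed_points",
    "classify_dilemma",
    "naive_belief",
    "critical_variance",
    "tangency_point",
]

#: Uniform grid resolution used to bracket roots of F(p) = p.
GRID_SIZE = 2001
ROOT_XTOL = 1e-12
#: |f(p*) - 1| below this means the stability test is inconclusive.
MARGINAL_TOL = 1e-8
#: Residual ceiling for a grid touch-point to count as a tangency root.
TANGENCY_RESIDUAL = 1e-10

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class Stability(enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    MARGINAL = "marginal"


class Dilemma(enum.Enum):
    """Regime of the one-dimensional dynamic: bistable vs monostable."""

    COORDINATION = "coordination"
    COOPERATION = "cooperation"
    MARGINAL = "marginal"


def _check_unit_interval(p):
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    return arr


@dataclass(frozen=True)
class NormSensitivity:
    """Normal distribution of cooperation thresholds on the probability scale.

    Parameters
    ----------
    mean
        Location of the threshold distribution, in (0, 1).
    variance
        Spread of the threshold distribution (probability scale squared).
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ValueError(f"mean must lie in (0, 1), got {self.mean}")
        if self.variance <= 0.0:
            raise ValueError(f"variance must be positive, got {self.variance}")

    @property
    def sigma(self) -> float:
        """Standard deviation of the threshold distribution."""
        return math.sqrt(self.variance)

    def cdf(self, p):
        """Fraction cooperating given that a fraction ``p`` cooperates.

        The untruncated normal CDF evaluated on [0, 1]; no renormalisation,
        so ``cdf(0) > 0`` and ``cdf(1) < 1``.
        """
        arr = _check_unit_interval(p)
        out = ndtr((arr - self.mean) / self.sigma)
        return float(out) if out.ndim == 0 else out

    def cdf_clipped(self, p):
        """CDF with the argument clipped into [0, 1].

        Used by ODE right-hand sides, where roundoff can push the mean
        cooperation level marginally outside the unit interval.
        """
        arr = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
        out = ndtr((arr - self.mean) / self.sigma)
        return float(out) if out.ndim == 0 else out

    def pdf(self, p):
        """Density of the threshold distribution at ``p``."""
        arr = _check_unit_interval(p)
        z = (arr - self.mean) / self.sigma
        out = np.exp(-0.5 * z * z) / (self.sigma * _SQRT_2PI)
        return float(out) if out.ndim == 0 else out

    def pdf_unchecked(self, p):
        z = (np.asarray(p, dtype=float) - self.mean) / self.sigma
        out = np.exp(-0.5 * z * z) / (self.sigma * _SQRT_2PI)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FixedPoint1D:
    """A root of F(p) = p with its linear stability."""

    location: float
    stability: Stability


def rhs_basic(ns: NormSensitivity, p):
    """Rate of change of the cooperation frequency, ``F(p) - p``."""
    cdf = ns.cdf(p)
    return cdf - (np.asarray(p, dtype=float) if np.ndim(p) else float(p))


def _stability_of(ns: NormSensitivity, root: float) -> Stability:
    slope = ns.pdf(root)
    if abs(slope - 1.0) < MARGINAL_TOL:
        return Stability.MARGINAL
    return Stability.STABLE if slope < 1.0 else Stability.UNSTABLE


def fixed_points(ns: NormSensitivity, grid_size: int = GRID_SIZE) -> list[FixedPoint1D]:
    """All roots of F(p) = p on [0, 1], ascending, with stabilities.

    Roots are bracketed by a sign-change scan on a uniform grid and
    polished by bisection (``brentq``) to ``ROOT_XTOL``.  A grid point
    where ``|F(p) - p|`` dips below ``TANGENCY_RESIDUAL`` without a sign
    change is reported as a (marginal) tangency root.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    g = ns.cdf(grid) - grid

    def fun(p: float) -> float:
        return ns.cdf(p) - p

    roots: list[float] = []
    for i in np.nonzero(g == 0.0)[0]:
        roots.append(float(grid[i]))
    sign = np.sign(g)
    for i in np.nonzero((sign[:-1] * sign[1:]) < 0)[0]:
        try:
            r = optimize.brentq(fun, grid[i], grid[i + 1], xtol=ROOT_XTOL)
        except RuntimeError as exc:  # pragma: no cover - brentq is robust here
            raise RuntimeError(
                f"root refinement failed in [{grid[i]}, {grid[i + 1]}]: {exc}"
            ) from exc
        roots.append(float(r))

    # Tangency: |g| touches ~0 at an interior local minimum without a sign
    # change; refine the touch point by minimising g**2.
    absg = np.abs(g)
    interior = np.arange(1, grid_size - 1)
    touch = interior[
        (absg[interior] < TANGENCY_RESIDUAL)
        & (absg[interior] <= absg[interior - 1])
        & (absg[interior] <= absg[interior + 1])
        & (sign[interior - 1] * sign[interior + 1] >= 0)
    ]
    for i in touch:
        res = optimize.minimize_scalar(
            lambda p: fun(p) ** 2, bounds=(grid[i - 1], grid[i + 1]), method="bounded"
        )
        roots.append(float(res.x))

    roots = sorted(roots)
    deduped: list[float] = []
    for r in roots:
        if not deduped or r - deduped[-1] > 1e-9:
            deduped.append(r)
    return [FixedPoint1D(r, _stability_of(ns, r)) for r in deduped]


def classify_dilemma(ns: NormSensitivity) -> Dilemma:
    """Coordination (3 roots of F(p)=p), cooperation (1), or marginal (tangency)."""
    pts = fixed_points(ns)
    if any(pt.stability is Stability.MARGINAL for pt in pts):
        return Dilemma.MARGINAL
    if len(pts) == 3:
        return Dilemma.COORDINATION
    if len(pts) == 1:
        return Dilemma.COOPERATION
    return Dilemma.MARGINAL


def naive_belief(reference: NormSensitivity) -> float:
    """High-cooperation root of F(p) = p for a bistable reference distribution.

    This is the cooperation level that newly joining (naive) community
    members believe prevails inside the community.
    """
    pts = fixed_points(reference)
    stable = [pt for pt in pts if pt.stability is Stability.STABLE]
    if len(pts) < 3 or len(stable) < 2:
        raise ValueError(
            "no high-cooperation solution: the reference distribution is "
            f"monostable (found {len(pts)} fixed point(s))"
        )
    return stable[-1].location


@dataclass(frozen=True)
class TangencyPoint:
    """Solution of the saddle-node system F(p) = p, f(p) = 1."""

    p: float
    sigma: float

    @property
    def variance(self) -> float:
        return self.sigma**2


def _tangency_system(mu: float, p: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    z = (p - mu) / sigma
    phi = math.exp(-0.5 * z * z) / _SQRT_2PI
    g = np.array([ndtr(z) - p, phi / sigma - 1.0])
    jac = np.array(
        [
            [phi / sigma - 1.0, -z * phi / sigma],
            [-z * phi / sigma**2, (z * z - 1.0) * phi / sigma**2],
        ]
    )
    return g, jac


def tangency_point(
    mu: float,
    sigma_bracket: tuple[float, float] = (0.02, 0.6),
    grid_size: int = 80,
) -> TangencyPoint:
    """Saddle-node point of the threshold dynamic as the variance grows.

    For a mean above 0.5 the upper two roots of F(p) = p coalesce as the
    variance increases; this solves F(p) = p and f(p) = 1 simultaneously
    for (p, sigma) with damped Newton iteration, initialised from a coarse
    bisection on the root count.
    """
    if not 0.5 < mu < 1.0:
        raise ValueError(f"mean must lie in (0.5, 1) for the upper tangency, got {mu}")

    def count(sigma: float) -> int:
        return len(fixed_points(NormSensitivity(mu, sigma * sigma)))

    sigmas = np.linspace(sigma_bracket[0], sigma_bracket[1], grid_size)
    counts = [count(s) for s in sigmas]
    lo = hi = None
    for a, b, ca, cb in zip(sigmas[:-1], sigmas[1:], counts[:-1], counts[1:]):
        if ca >= 3 and cb == 1:
            lo, hi = a, b
            break
    if lo is None:
        raise ValueError(f"no tangency found for mean {mu} in sigma bracket {sigma_bracket}")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if count(mid) >= 3:
            lo = mid
        else:
            hi = mid

    pts = fixed_points(NormSensitivity(mu, lo * lo))
    p0 = 0.5 * (pts[-1].location + pts[-2].location)
    x = np.array([p0, 0.5 * (lo + hi)])
    g, jac = _tangency_system(mu, *x)
    for _ in range(100):
        if np.max(np.abs(g)) < 1e-14:
            break
        step = np.linalg.solve(jac, -g)
        scale = 1.0
        norm0 = np.linalg.norm(g)
        for _ in range(40):
            trial = x + scale * step
            if trial[1] > 0:
                g_new, jac_new = _tangency_system(mu, *trial)
                if np.linalg.norm(g_new) < norm0:
                    x, g, jac = trial, g_new, jac_new
                    break
            scale *= 0.5
        else:
            raise RuntimeError("damped Newton failed to reduce the tangency residual")
    if np.max(np.abs(g)) > 1e-10:
        raise RuntimeError(f"tangency solve did not converge, residual {g}")
    return TangencyPoint(p=float(x[0]), sigma=float(x[1]))


def critical_variance(mu: float) -> float:
    """Variance at which the threshold dynamic loses bistability (mean > 0.5)."""
    return tangency_point(mu).variance
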