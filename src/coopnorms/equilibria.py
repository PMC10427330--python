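"""Equilibria of the community model: closed forms, roots and stability.

At a mixed (insider/outsider) equilibrium the savvy fraction is
``y* = learning/(learning + outflow)`` and the savvy cooperation level
solves ``p = F(y*'p + (1 - y*)F(p_tilde))``.  Each such root defines a
reproduction ratio ``R = inflow / (outflow * gap * y*)`` — the per-capita
joining rate over the per-capita discouragement rate — and a mixed
population equilibrium exists for that root iff R > 1:

    S* = K / R
    I* = K (1 - 1/R) / (1 + outflow*gap*y*/phi)
    D* = (outflow*gap*y*/phi) * I*

The all-outsider (crash) state always exists, with the residual belief
dynamics settling on a boundary attractor (y0, p0); its invadability is
decided by the per-capita growth rate ``r = inflow - outflow*gap0*y0`` of
a vanishingly small community.  When the naive belief is itself a fixed
point of the threshold map (coordination regime), the all-insider
high-cooperation state exists as a line of equilibria neutral in y.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .community import CommunityParams, CommunityState, _rhs_vec, integrate

__all__ = [
    "EquilibriumKind",
    "StabilityClass",
    "StabilityResult",
    "Equilibrium",
    "CrashAnalysis",
    "savvy_fraction_eq",
    "savvy_coop_equilibria",
    "crash_analyses",
    "reproduction_ratio",
    "population_equilibrium",
    "enumerate_equilibria",
    "stability",
    "jacobian",
    "crash_boundary_attractor",
    "crash_invasion_rate",
    "equilibria_to_json",
]

RESIDUAL_TOL = 1e-8
EIG_DEADBAND = 1e-8
#: Belief gaps below this count as zero (the all-insider / no-leaving case).
GAP_TOL = 1e-10


class EquilibriumKind(enum.Enum):
    MIXED = "mixed"
    ALL_OUTSIDER_CRASH = "all_outsider_crash"
    ALL_INSIDER_HIGH = "all_insider_high"


class StabilityClass(enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    MARGINAL_LINE = "marginal_line"


@dataclass(frozen=True)
class StabilityResult:
    eigenvalues: np.ndarray
    classification: StabilityClass
    #: For a marginal_line spectrum, whether the non-neutral directions attract.
    attracting: bool


@dataclass(frozen=True)
class Equilibrium:
    state: CommunityState
    kind: EquilibriumKind
    eigenvalues: np.ndarray
    stability: StabilityClass
    attracting: bool
    reproduction_ratio: float | None = None

    @property
    def p_star(self) -> float:
        return self.state.p

    @property
    def y_star(self) -> float:
        return self.state.y


def savvy_fraction_eq(outflow_rate: float, learning_rate: float) -> float:
    """Equilibrium savvy fraction ``1/(1 + outflow/learning)``."""
    if learning_rate <= 0.0:
        raise ValueError("learning_rate must be positive: without learning the "
                         "equilibrium savvy fraction is undefined")
    return learning_rate / (learning_rate + outflow_rate)


def _p_residual(params: CommunityParams, p: float, y_star: float) -> float:
    c_naive = params.naive_cooperation
    p_bar = y_star * p + (1.0 - y_star) * c_naive
    return params.norms.cdf_clipped(p_bar) - p


def savvy_coop_equilibria(
    params: CommunityParams, grid_size: int = 2001
) -> list[tuple[float, str]]:
    """Roots on [0, p_tilde] of p = F(y* p + (1 - y*) F(p_tilde)).

    Returns (p*, stability) pairs, ascending; a root is stable in the
    p-direction iff ``y* f(p_bar*) < 1``.  In the coordination regime the
    naive belief itself (gap 0) is always a root and is reported last.
    """
    y_star = savvy_fraction_eq(params.outflow_rate, params.learning_rate)
    pt = params.p_tilde
    grid = np.linspace(0.0, pt, grid_size)
    c_naive_ = params.naive_cooperation
    g = params.norms.cdf_clipped(y_star * grid + (1.0 - y_star) * c_naive_) - grid
    roots: list[float] = []
    sign = np.sign(g)
    for i in np.nonzero((sign[:-1] * sign[1:]) < 0)[0]:
        r = optimize.brentq(
            lambda p: _p_residual(params, p, y_star), grid[i], grid[i + 1], xtol=1e-14
        )
        roots.append(float(r))
    for endpoint in (0.0, pt):
        if abs(_p_residual(params, endpoint, y_star)) < 1e-12:
            roots.append(endpoint)
    roots = sorted(roots)
    deduped: list[float] = []
    for r in roots:
        if not deduped or r - deduped[-1] > 1e-9:
            deduped.append(r)

    out = []
    c_naive = params.naive_cooperation
    for r in deduped:
        p_bar = y_star * r + (1.0 - y_star) * c_naive
        slope = y_star * params.norms.pdf_unchecked(p_bar)
        if abs(slope - 1.0) < 1e-8:
            stab = "marginal"
        else:
            stab = "stable" if slope < 1.0 else "unstable"
        out.append((r, stab))
    return out


def reproduction_ratio(params: CommunityParams, p_star: float, y_star: float) -> float:
    """Joining-over-discouragement ratio at a candidate equilibrium.

    Returns ``inf`` when the discouragement rate vanishes (no leaving:
    the community absorbs everyone).
    """
    gap = params.p_tilde - (y_star * p_star + (1.0 - y_star) * params.naive_cooperation)
    denom = params.outflow_rate * gap * y_star
    if denom <= GAP_TOL * params.outflow_rate or denom == 0.0:
        return math.inf
    return params.inflow_rate / denom


def population_equilibrium(
    params: CommunityParams, p_star: float, y_star: float
) -> tuple[float, float, float]:
    """Mixed-population equilibrium (S*, I*, D*) for a given (p*, y*).

    Requires a reproduction ratio above 1 and a positive resusceptibility
    rate; the triple sums to K by construction.
    """
    if params.resusceptibility <= 0.0:
        raise ValueError("resusceptibility must be positive for a mixed equilibrium")
    ratio = reproduction_ratio(params, p_star, y_star)
    if not ratio > 1.0:
        raise ValueError(
            f"no interior equilibrium: reproduction ratio {ratio} <= 1 "
            "(the all-outsider state is the only stable equilibrium)"
        )
    if math.isinf(ratio):
        raise ValueError("reproduction ratio is infinite (zero discouragement); "
                         "the all-insider state applies instead")
    K = params.K
    gap = params.p_tilde - (y_star * p_star + (1.0 - y_star) * params.naive_cooperation)
    q = params.outflow_rate * gap * y_star / params.resusceptibility
    S = K / ratio
    I = K * (1.0 - 1.0 / ratio) / (1.0 + q)
    D = q * I
    return S, I, D


def jacobian(params: CommunityParams, state: CommunityState, rel_step: float = 1e-7) -> np.ndarray:
    """Central-difference Jacobian of the reduced right-hand side."""
    u = state.as_array()
    n = u.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(u[j]), 1.0)
        up, um = u.copy(), u.copy()
        up[j] += h
        um[j] -= h
        J[:, j] = (_rhs_vec(params, up) - _rhs_vec(params, um)) / (2.0 * h)
    return J


def stability(
    params: CommunityParams,
    state: CommunityState,
    equilibrium_tol: float = 1e-6,
    deadband: float = EIG_DEADBAND,
) -> StabilityResult:
    """Eigenvalue classification of an equilibrium of the reduced system.

    A single eigenvalue inside the dead-band (a neutral direction, as along
    the all-insider line) yields ``marginal_line``, with the remaining
    spectrum deciding whether the state attracts.
    """
    res = _rhs_vec(params, state.as_array())
    nrm = float(np.linalg.norm(res))
    if nrm > equilibrium_tol * max(params.K, 1.0):
        raise ValueError(f"state is not an equilibrium: |rhs| = {nrm:.3g}")
    eig = np.linalg.eigvals(jacobian(params, state))
    re = np.real(eig)
    n_zero = int(np.sum(np.abs(re) <= deadband))
    if np.max(re) > deadband:
        cls = StabilityClass.UNSTABLE
        attracting = False
    elif n_zero >= 1:
        cls = StabilityClass.MARGINAL_LINE
        attracting = bool(np.all(re[np.abs(re) > deadband] < 0.0)) and n_zero == 1
    else:
        cls = StabilityClass.STABLE
        attracting = True
    return StabilityResult(eigenvalues=eig, classification=cls, attracting=attracting)


def _boundary_rhs(params: CommunityParams, v: np.ndarray) -> np.ndarray:
    """(y, p) dynamics on the invariant boundary S = K, I -> 0."""
    y, p = v
    c_naive = params.naive_cooperation
    p_bar = y * p + (1.0 - y) * c_naive
    gap = params.p_tilde - p_bar
    if gap < 0.0:
        gap = 0.0
    dy = (
        params.learning_rate * gap * (1.0 - y)
        - params.outflow_rate * gap * y * (1.0 - y)
        - params.inflow_rate * y
    )
    dp = params.norms.cdf_clipped(p_bar) - p
    return np.array([dy, dp])


@dataclass(frozen=True)
class CrashAnalysis:
    """Invasion analysis of the all-outsider state."""

    rate: float
    y_boundary: float
    p_boundary: float
    converged: bool
    #: Per-variable boundary residual when converged.
    residual: float


def crash_boundary_attractor(
    params: CommunityParams,
    v0: tuple[float, float] | None = None,
    t_relax: float = 2000.0,
    tol: float = 1e-10,
) -> tuple[float, float, bool, float]:
    """Attractor (y0, p0) of the belief dynamics at the empty-community boundary.

    Found by relaxation integration followed by a root polish; returns
    (y0, p0, converged, residual).  Non-convergence (e.g. a boundary
    cycle) is flagged rather than raised.
    """
    if v0 is None:
        v0 = (0.5, params.naive_cooperation)
    sol = solve_ivp(
        lambda t, v: _boundary_rhs(params, v),
        (0.0, t_relax),
        np.asarray(v0, dtype=float),
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    v = np.clip(sol.y[:, -1], 0.0, 1.0)
    res = optimize.root(lambda w: _boundary_rhs(params, w), v, tol=1e-13)
    if res.success and np.all(res.x >= -1e-12) and np.all(res.x <= 1.0 + 1e-12):
        v = np.clip(res.x, 0.0, 1.0)
    residual = float(np.linalg.norm(_boundary_rhs(params, v)))
    return float(v[0]), float(v[1]), residual < tol, residual


def crash_invasion_rate(
    params: CommunityParams, v0: tuple[float, float] | None = None
) -> CrashAnalysis:
    """Per-capita growth rate of a vanishingly small community.

    ``r = inflow - outflow * gap0 * y0`` at the boundary attractor reached
    from ``v0``; the crash state there is stable iff r < 0.  If the
    boundary dynamics do not settle, r is estimated from a direct
    simulation seeded at I = 1e-6 K.
    """
    y0, p0, converged, residual = crash_boundary_attractor(params, v0=v0)
    if converged:
        c_naive = params.naive_cooperation
        gap = max(params.p_tilde - (y0 * p0 + (1.0 - y0) * c_naive), 0.0)
        r = params.inflow_rate - params.outflow_rate * gap * y0
        return CrashAnalysis(rate=r, y_boundary=y0, p_boundary=p0,
                             converged=True, residual=residual)
    K = params.K
    eps = 1e-6 * K
    traj = integrate(
        params,
        CommunityState(S=K - eps, I=eps, y=y0, p=p0),
        t_end=20.0,
        n_samples=201,
    )
    with np.errstate(divide="ignore"):
        growth = np.diff(np.log(np.maximum(traj.I, 1e-300))) / np.diff(traj.times)
    r = float(np.median(growth[: len(growth) // 2]))
    return CrashAnalysis(rate=r, y_boundary=y0, p_boundary=p0,
                         converged=False, residual=residual)


def crash_analyses(params: CommunityParams) -> list[CrashAnalysis]:
    """Invasion analysis at every distinct boundary attractor.

    The residual belief dynamics on the empty-community boundary can be
    bistable (a naive high-cooperation attractor and a savvy disillusioned
    one); relaxation is run from starts biased toward each and the
    resulting attractors deduplicated.  The crash state is stable against
    some invasion histories iff any attractor has a negative rate.
    """
    starts = ((0.5, params.naive_cooperation), (0.95, 0.0))
    out: list[CrashAnalysis] = []
    for v0 in starts:
        analysis = crash_invasion_rate(params, v0=v0)
        if any(
            abs(analysis.y_boundary - a.y_boundary) < 1e-6
            and abs(analysis.p_boundary - a.p_boundary) < 1e-6
            for a in out
        ):
            continue
        out.append(analysis)
    return out


def enumerate_equilibria(params: CommunityParams) -> list[Equilibrium]:
    """All equilibria of the community model with stability.

    Returns one all-outsider crash state per distinct boundary attractor,
    the all-insider high state when the naive belief is a fixed point of
    the threshold map, and one mixed equilibrium per savvy-cooperation
    root whose reproduction ratio exceeds 1.
    """
    K = params.K
    out: list[Equilibrium] = []

    for crash in crash_analyses(params):
        crash_state = CommunityState(S=K, I=0.0, y=crash.y_boundary, p=crash.p_boundary)
        if crash.converged:
            stab = stability(params, crash_state)
            out.append(
                Equilibrium(
                    state=crash_state,
                    kind=EquilibriumKind.ALL_OUTSIDER_CRASH,
                    eigenvalues=stab.eigenvalues,
                    stability=stab.classification,
                    attracting=stab.attracting,
                )
            )
        else:
            cls = StabilityClass.UNSTABLE if crash.rate > 0 else StabilityClass.STABLE
            out.append(
                Equilibrium(
                    state=crash_state,
                    kind=EquilibriumKind.ALL_OUTSIDER_CRASH,
                    eigenvalues=np.array([crash.rate]),
                    stability=cls,
                    attracting=crash.rate < 0,
                )
            )

    y_star = savvy_fraction_eq(params.outflow_rate, params.learning_rate)
    c_naive = params.naive_cooperation
    if abs(c_naive - params.p_tilde) < 1e-9:
        high = CommunityState(S=0.0, I=K, y=y_star, p=params.p_tilde)
        stab = stability(params, high)
        out.append(
            Equilibrium(
                state=high,
                kind=EquilibriumKind.ALL_INSIDER_HIGH,
                eigenvalues=stab.eigenvalues,
                stability=stab.classification,
                attracting=stab.attracting,
                reproduction_ratio=math.inf,
            )
        )

    for p_star, _ in savvy_coop_equilibria(params):
        gap = params.p_tilde - (y_star * p_star + (1.0 - y_star) * c_naive)
        if gap <= GAP_TOL:
            continue  # zero-gap root: the all-insider state, handled above
        ratio = reproduction_ratio(params, p_star, y_star)
        if not ratio > 1.0 or math.isinf(ratio):
            continue
        S, I, D = population_equilibrium(params, p_star, y_star)
        state = CommunityState(S=S, I=I, y=y_star, p=p_star)
        stab = stability(params, state)
        out.append(
            Equilibrium(
                state=state,
                kind=EquilibriumKind.MIXED,
                eigenvalues=stab.eigenvalues,
                stability=stab.classification,
                attracting=stab.attracting,
                reproduction_ratio=ratio,
            )
        )
    return out


def equilibria_to_json(equilibria: list[Equilibrium], params: CommunityParams) -> str:
    """Serialise an equilibrium set to a JSON report."""
    payload = []
    for eq in equilibria:
        payload.append(
            {
                "kind": eq.kind.value,
                "state": {
                    "S": eq.state.S,
                    "I": eq.state.I,
                    "D": eq.state.D(params.K),
                    "y": eq.state.y,
                    "p": eq.state.p,
                },
                "eigenvalues_real": [float(np.real(v)) for v in eq.eigenvalues],
                "eigenvalues_imag": [float(np.imag(v)) for v in eq.eigenvalues],
                "stability": eq.stability.value,
                "attracting": eq.attracting,
                "reproduction_ratio": (
                    None
                    if eq.reproduction_ratio is None
                    else ("inf" if math.isinf(eq.reproduction_ratio) else eq.reproduction_ratio)
                ),
            }
        )
    return json.dumps(payload, indent=2)
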