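"""Coupled community-membership and belief dynamics.

A population of fixed size ``K`` is split into susceptible outsiders
``S``, community insiders ``I`` and discouraged outsiders ``D = K - S - I``.
Insiders are either naive — they believe the community cooperates at the
advertised level ``p_tilde`` and cooperate at rate ``F(p_tilde)`` — or
savvy, having learned the true mean cooperation.  The state carries the
savvy fraction ``y`` and the savvy cooperation frequency ``p``; the mean
cooperation among insiders is ``p_bar = y*p + (1 - y)*F(p_tilde)`` and the
belief gap ``delta = p_tilde - p_bar`` drives both learning (naive ->
savvy) and disillusioned leaving (savvy -> discouraged):

    dS/dt = phi*D - iota*S*I/K
    dI/dt = iota*S*I/K - omega*delta*y*I
    dy/dt = lam*delta*(1 - y) - omega*delta*y*(1 - y) - (iota*S/K)*y
    dp/dt = F(p_bar) - p

A raw five-compartment formulation (susceptible, naive, savvy, discouraged,
plus the savvy-cooperator count) is provided as an independent derivation
oracle; its reduction must match the four-variable system exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .threshold import NormSensitivity

__all__ = [
    "CommunityParams",
    "CommunityState",
    "Trajectory",
    "RawTrajectory",
    "mean_cooperation",
    "belief_gap",
    "total_cooperation",
    "rhs",
    "raw_rhs",
    "integrate",
    "integrate_raw",
]

logger = logging.getLogger(__name__)

#: Integration tolerances (adaptive, stiff-capable solver).
RTOL = 1e-9
ATOL = 1e-12
#: Negative values larger than this (times max(K, 1)) abort the run.
CLIP_TOL = 1e-8


@dataclass(frozen=True)
class CommunityParams:
    """Rates and constants of the community/belief model.

    Parameters
    ----------
    inflow_rate
        Contact/joining coefficient: susceptibles join at ``inflow_rate*S*I/K``.
    learning_rate
        Speed at which naive insiders learn the true cooperation level.
    outflow_rate
        Speed at which disillusioned savvy insiders leave.
    resusceptibility
        Rate at which discouraged outsiders become susceptible again.
    K
        Total population size.
    p_tilde
        Naive belief: the advertised cooperation level newcomers expect.
    norms
        Distribution of cooperation thresholds.
    """

    inflow_rate: float
    learning_rate: float
    outflow_rate: float
    resusceptibility: float
    K: float
    p_tilde: float
    norms: NormSensitivity

    def __post_init__(self) -> None:
        for name in ("inflow_rate", "learning_rate", "outflow_rate", "resusceptibility"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.K <= 0.0:
            raise ValueError(f"K must be positive, got {self.K}")
        if not 0.0 < self.p_tilde <= 1.0:
            raise ValueError(f"p_tilde must lie in (0, 1], got {self.p_tilde}")

    @cached_property
    def naive_cooperation(self) -> float:
        """Cooperation rate of naive insiders, ``F(p_tilde)``."""
        return self.norms.cdf(self.p_tilde)

    def with_(self, **kwargs) -> "CommunityParams":
        """Copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CommunityState:
    """State (S, I, y, p) of the four-variable system."""

    S: float
    I: float
    y: float
    p: float

    def validate(self, K: float, tol: float = 1e-9) -> None:
        if self.S < -tol * K or self.I < -tol * K:
            raise ValueError(f"S and I must be non-negative, got S={self.S}, I={self.I}")
        if self.S + self.I > K * (1.0 + tol):
            raise ValueError(f"S + I = {self.S + self.I} exceeds K = {K}")
        if not -tol <= self.y <= 1.0 + tol:
            raise ValueError(f"y must lie in [0, 1], got {self.y}")
        if not -tol <= self.p <= 1.0 + tol:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")

    def D(self, K: float) -> float:
        """Discouraged count, carried as the residual K - S - I."""
        return K - self.S - self.I

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.y, self.p], dtype=float)

    @classmethod
    def from_array(cls, u) -> "CommunityState":
        return cls(S=float(u[0]), I=float(u[1]), y=float(u[2]), p=float(u[3]))


def mean_cooperation(state: CommunityState, params: CommunityParams) -> float:
    """Mean actual cooperation among insiders: ``y*p + (1 - y)*F(p_tilde)``."""
    return state.y * state.p + (1.0 - state.y) * params.naive_cooperation


def belief_gap(state: CommunityState, params: CommunityParams) -> float:
    """Gap between the naive belief and reality, ``p_tilde - p_bar``, clamped at 0.

    The model's flows assume rosy beliefs (p_bar <= p_tilde); a negative
    gap can only arise from inadmissible initial conditions and is clamped
    to zero with a warning.
    """
    gap = params.p_tilde - mean_cooperation(state, params)
    if gap < 0.0:
        if gap < -1e-12:
            logger.warning(
                "belief gap is negative (%.3g); learning and leaving clamped to 0", gap
            )
        return 0.0
    return gap


def total_cooperation(state: CommunityState, params: CommunityParams) -> float:
    """Total cooperation mass in the population, ``p_bar * I``."""
    return mean_cooperation(state, params) * state.I


def _rhs_vec(params: CommunityParams, u: np.ndarray) -> np.ndarray:
    """Unvalidated vector right-hand side in (S, I, y, p)."""
    S, I, y, p = u
    K = params.K
    c_naive = params.naive_cooperation
    p_bar = y * p + (1.0 - y) * c_naive
    gap = params.p_tilde - p_bar
    if gap < 0.0:
        gap = 0.0
    join = params.inflow_rate * S * I / K
    leave = params.outflow_rate * gap
    dS = params.resusceptibility * (K - S - I) - join
    dI = join - leave * y * I
    dy = (
        params.learning_rate * gap * (1.0 - y)
        - leave * y * (1.0 - y)
        - params.inflow_rate * (S / K) * y
    )
    dp = params.norms.cdf_clipped(p_bar) - p
    return np.array([dS, dI, dy, dp])


def rhs(params: CommunityParams, state: CommunityState) -> CommunityState:
    """Time derivatives of (S, I, y, p)."""
    state.validate(params.K)
    return CommunityState.from_array(_rhs_vec(params, state.as_array()))


def _raw_rhs_vec(params: CommunityParams, u: np.ndarray, p_limit: float) -> np.ndarray:
    """Right-hand side of the raw five-compartment system (S, N, V, D, C).

    N and V are the naive and savvy insider counts, C <= V the savvy
    cooperator count.  Newly savvy individuals adopt the current savvy
    mean behaviour and leavers are an unbiased sample, which makes the
    reduction (I, y, p) = (N + V, V/(N + V), C/V) satisfy the reduced
    system exactly.  When V = 0 the ratio C/V is taken as ``p_limit``.
    """
    S, N, V, D, C = u
    K = params.K
    I = N + V
    p = C / V if V > 1e-300 else p_limit
    y = V / I if I > 1e-300 else 0.0
    c_naive = params.naive_cooperation
    p_bar = y * p + (1.0 - y) * c_naive
    gap = params.p_tilde - p_bar
    if gap < 0.0:
        gap = 0.0
    join = params.inflow_rate * S * I / K
    dS = params.resusceptibility * D - join
    dN = join - params.learning_rate * gap * N
    dV = params.learning_rate * gap * N - params.outflow_rate * gap * V
    dD = params.outflow_rate * gap * V - params.resusceptibility * D
    dC = (
        params.learning_rate * gap * N * p
        + V * (params.norms.cdf_clipped(p_bar) - p)
        - params.outflow_rate * gap * C
    )
    return np.array([dS, dN, dV, dD, dC])


def raw_rhs(params: CommunityParams, raw_state, p_limit: float | None = None) -> np.ndarray:
    """Derivatives of the raw five-compartment state (S, N, V, D, C)."""
    u = np.asarray(raw_state, dtype=float)
    if u.shape != (5,):
        raise ValueError("raw state must be a 5-vector (S, N, V, D, C)")
    if u[4] > u[2] * (1.0 + 1e-9) + 1e-12:
        raise ValueError(f"savvy cooperators C={u[4]} exceed savvy count V={u[2]}")
    return _raw_rhs_vec(params, u, params.p_tilde if p_limit is None else p_limit)


def reduce_raw(raw_state, p_limit: float | None = None) -> CommunityState:
    """Map a raw (S, N, V, D, C) state to reduced coordinates (S, I, y, p)."""
    S, N, V, D, C = np.asarray(raw_state, dtype=float)
    I = N + V
    return CommunityState(
        S=S,
        I=I,
        y=V / I if I > 0 else 0.0,
        p=C / V if V > 0 else (0.0 if p_limit is None else p_limit),
    )


@dataclass
class Trajectory:
    """Sampled solution of the four-variable system."""

    times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    y: np.ndarray
    p: np.ndarray
    params: CommunityParams = field(repr=False)

    @property
    def D(self) -> np.ndarray:
        return self.params.K - self.S - self.I

    @property
    def p_bar(self) -> np.ndarray:
        return self.y * self.p + (1.0 - self.y) * self.params.naive_cooperation

    @property
    def total_cooperation(self) -> np.ndarray:
        return self.p_bar * self.I

    def state_at(self, i: int) -> CommunityState:
        return CommunityState(S=self.S[i], I=self.I[i], y=self.y[i], p=self.p[i])

    def final_state(self) -> CommunityState:
        return self.state_at(-1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "S": self.S,
                "I": self.I,
                "D": self.D,
                "y": self.y,
                "p": self.p,
                "p_bar": self.p_bar,
                "total_cooperation": self.total_cooperation,
            }
        )


@dataclass
class RawTrajectory:
    """Sampled solution of the raw five-compartment system."""

    times: np.ndarray
    S: np.ndarray
    N: np.ndarray
    V: np.ndarray
    D: np.ndarray
    C: np.ndarray
    params: CommunityParams = field(repr=False)

    def reduced(self) -> Trajectory:
        I = self.N + self.V
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.where(I > 0, self.V / np.where(I > 0, I, 1.0), 0.0)
            p = np.where(self.V > 0, self.C / np.where(self.V > 0, self.V, 1.0), np.nan)
        return Trajectory(times=self.times, S=self.S, I=I, y=y, p=p, params=self.params)


def _clip_solution(values: np.ndarray, lo: float, hi: float, scale: float, what: str) -> np.ndarray:
    tol = CLIP_TOL * max(scale, 1.0)
    if np.any(values < lo - tol) or np.any(values > hi + tol):
        raise RuntimeError(
            f"integration produced {what} outside [{lo}, {hi}] beyond tolerance "
            f"(range [{values.min()}, {values.max()}])"
        )
    return np.clip(values, lo, hi)


def integrate(
    params: CommunityParams,
    state0: CommunityState,
    t_end: float,
    n_samples: int = 1001,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the four-variable system on [0, t_end].

    Uses an adaptive stiff-capable solver (LSODA); negative excursions
    below the solver tolerance are clipped to the domain, larger ones
    raise.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    state0.validate(params.K)
    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(
        lambda t, u: _rhs_vec(params, u),
        (0.0, t_end),
        state0.as_array(),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message}; last state {sol.y[:, -1] if sol.y.size else None}"
        )
    K = params.K
    S = _clip_solution(sol.y[0], 0.0, K, K, "S")
    I = _clip_solution(sol.y[1], 0.0, K, K, "I")
    y = _clip_solution(sol.y[2], 0.0, 1.0, 1.0, "y")
    p = _clip_solution(sol.y[3], 0.0, 1.0, 1.0, "p")
    return Trajectory(times=sol.t, S=S, I=I, y=y, p=p, params=params)


def integrate_raw(
    params: CommunityParams,
    raw_state0,
    t_end: float,
    n_samples: int = 1001,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> RawTrajectory:
    """Integrate the raw five-compartment system on [0, t_end]."""
    u0 = np.asarray(raw_state0, dtype=float)
    if u0.shape != (5,):
        raise ValueError("raw state must be a 5-vector (S, N, V, D, C)")
    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(
        lambda t, u: _raw_rhs_vec(params, u, params.p_tilde),
        (0.0, t_end),
        u0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"raw integration failed: {sol.message}")
    K = params.K
    cols = [_clip_solution(sol.y[i], 0.0, K, K, name) for i, name in enumerate("SNVDC")]
    return RawTrajectory(
        times=sol.t, S=cols[0], N=cols[1], V=cols[2], D=cols[3], C=cols[4], params=params
    )
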