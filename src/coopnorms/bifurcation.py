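"""Parameter scans, fold detection, regime diagrams and cycle detection.

Equilibria are cheap one-dimensional roots, so continuation is plain grid
enumeration with nearest-neighbour branch matching; folds are refined by
bisection on the (integer) equilibrium count.  The ratio of outflow to
learning rates acts only through the equilibrium savvy fraction
``y* = 1/(1 + ratio)``, so fold ratios can be solved directly from the
tangency system ``p = F(y p + (1 - y) F(p_tilde))``, ``y f(.) = 1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from .community import CommunityParams, Trajectory
from .equilibria import (
    Equilibrium,
    crash_analyses,
    enumerate_equilibria,
    savvy_coop_equilibria,
    savvy_fraction_eq,
)
from .threshold import Dilemma, NormSensitivity, classify_dilemma

__all__ = [
    "ScanBranch",
    "FoldPoint",
    "AttractorClass",
    "CycleSummary",
    "RegimeRecord",
    "scan",
    "critical_ratio",
    "fold_ratios",
    "regime_diagram",
    "classify_attractor",
]

#: Parameters that can be scanned; "ratio" is outflow/learning with the
#: learning rate held fixed.
SCAN_PARAMETERS = (
    "ratio",
    "inflow_rate",
    "learning_rate",
    "outflow_rate",
    "resusceptibility",
    "variance",
)

FOLD_XTOL = 1e-8


def _apply(params: CommunityParams, name: str, value: float) -> CommunityParams:
    if name == "ratio":
        return params.with_(outflow_rate=value * params.learning_rate)
    if name == "variance":
        return params.with_(norms=NormSensitivity(params.norms.mean, value))
    if name in ("inflow_rate", "learning_rate", "outflow_rate", "resusceptibility"):
        return params.with_(**{name: value})
    raise ValueError(f"unknown scan parameter {name!r}; expected one of {SCAN_PARAMETERS}")


def _signature(params: CommunityParams) -> tuple[int, int, bool]:
    """(root count, mixed count, crash stable) — the discrete scan invariants."""
    roots = savvy_coop_equilibria(params)
    y_star = savvy_fraction_eq(params.outflow_rate, params.learning_rate)
    c_naive = params.naive_cooperation
    n_mixed = 0
    for p_star, _ in roots:
        gap = params.p_tilde - (y_star * p_star + (1.0 - y_star) * c_naive)
        if gap > 1e-10:
            denom = params.outflow_rate * gap * y_star
            if denom > 0 and params.inflow_rate / denom > 1.0:
                n_mixed += 1
    crash_stable = any(a.rate < 0.0 for a in crash_analyses(params))
    return len(roots), n_mixed, crash_stable


@dataclass(frozen=True)
class FoldPoint:
    """A refined qualitative change along a scan axis."""

    parameter: str
    value: float
    left_signature: tuple[int, int, bool]
    right_signature: tuple[int, int, bool]


@dataclass
class ScanBranch:
    """Equilibria along one parameter axis with branch ids and fold points."""

    parameter: str
    values: np.ndarray
    #: One list of equilibrium records per grid value.
    records: list[list[dict]]
    folds: list[FoldPoint]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for value, eqs in zip(self.values, self.records):
            for rec in eqs:
                rows.append({"parameter": self.parameter, "value": value, **rec})
        return pd.DataFrame(
            rows,
            columns=[
                "parameter",
                "value",
                "branch_id",
                "kind",
                "p_star",
                "y_star",
                "S_star",
                "I_star",
                "D_star",
                "total_cooperation",
                "stability",
            ],
        )

    def stable_branch(self, branch_id: int) -> pd.DataFrame:
        df = self.to_frame()
        return df[df.branch_id == branch_id]


def _equilibrium_record(eq: Equilibrium, params: CommunityParams) -> dict:
    p_bar = eq.state.y * eq.state.p + (1.0 - eq.state.y) * params.naive_cooperation
    return {
        "kind": eq.kind.value,
        "p_star": eq.state.p,
        "y_star": eq.state.y,
        "S_star": eq.state.S,
        "I_star": eq.state.I,
        "D_star": eq.state.D(params.K),
        "total_cooperation": p_bar * eq.state.I,
        "stability": eq.stability.value,
    }


def _match_branches(
    prev: list[tuple[int, str, float]], recs: list[dict], next_id: int
) -> tuple[list[tuple[int, str, float]], int]:
    """Greedy nearest-neighbour matching on (kind, p*) across grid steps."""
    assigned: list[tuple[int, str, float]] = []
    used = set()
    for rec in recs:
        best = None
        for k, (bid, kind, p) in enumerate(prev):
            if k in used or kind != rec["kind"]:
                continue
            d = abs(p - rec["p_star"])
            if best is None or d < best[1]:
                best = (k, d)
        if best is not None:
            used.add(best[0])
            rec["branch_id"] = prev[best[0]][0]
        else:
            rec["branch_id"] = next_id
            next_id += 1
        assigned.append((rec["branch_id"], rec["kind"], rec["p_star"]))
    return assigned, next_id


def scan(params: CommunityParams, parameter: str, values) -> ScanBranch:
    """Enumerate equilibria along a parameter grid and refine fold points."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty scan grid")
    if np.any(np.diff(values) <= 0):
        raise ValueError("scan grid must be strictly increasing")

    records: list[list[dict]] = []
    signatures: list[tuple[int, int, bool]] = []
    prev: list[tuple[int, str, float]] = []
    next_id = 0
    for v in values:
        pv = _apply(params, parameter, v)
        eqs = enumerate_equilibria(pv)
        recs = [_equilibrium_record(eq, pv) for eq in eqs]
        recs.sort(key=lambda r: (r["kind"], r["p_star"]))
        prev, next_id = _match_branches(prev, recs, next_id)
        records.append(recs)
        signatures.append(_signature(pv))

    folds: list[FoldPoint] = []
    for a, b, sa, sb in zip(values[:-1], values[1:], signatures[:-1], signatures[1:]):
        if sa == sb:
            continue
        lo, hi = a, b
        while hi - lo > FOLD_XTOL:
            mid = 0.5 * (lo + hi)
            if _signature(_apply(params, parameter, mid)) == sa:
                lo = mid
            else:
                hi = mid
        folds.append(
            FoldPoint(
                parameter=parameter,
                value=0.5 * (lo + hi),
                left_signature=sa,
                right_signature=sb,
            )
        )
    return ScanBranch(parameter=parameter, values=values, records=records, folds=folds)


def _root_count(ns: NormSensitivity, p_tilde: float, ratio: float, grid_size: int = 2001) -> int:
    y = 1.0 / (1.0 + ratio)
    c = ns.cdf_clipped(p_tilde)
    grid = np.linspace(0.0, p_tilde, grid_size)
    g = ns.cdf_clipped(y * grid + (1.0 - y) * c) - grid
    sign = np.sign(g)
    n = int(np.sum((sign[:-1] * sign[1:]) < 0))
    if abs(g[-1]) < 1e-12:
        n += 1
    if abs(g[0]) < 1e-12:
        n += 1
    return n


def _tangency_polish(
    ns: NormSensitivity, p_tilde: float, p0: float, y0: float
) -> tuple[float, float]:
    """Damped Newton on {F(p_bar) - p = 0, y f(p_bar) - 1 = 0} in (p, y)."""
    c = ns.cdf_clipped(p_tilde)

    def system(x):
        p, y = x
        p_bar = y * p + (1.0 - y) * c
        fp = ns.pdf_unchecked(p_bar)
        dfp = -((p_bar - ns.mean) / ns.variance) * fp
        g = np.array([ns.cdf_clipped(p_bar) - p, y * fp - 1.0])
        jac = np.array(
            [
                [fp * y - 1.0, fp * (p - c)],
                [y * y * dfp, fp + y * dfp * (p - c)],
            ]
        )
        return g, jac

    x = np.array([p0, y0])
    g, jac = system(x)
    for _ in range(100):
        if np.max(np.abs(g)) < 1e-13:
            break
        step = np.linalg.solve(jac, -g)
        norm0 = np.linalg.norm(g)
        scale = 1.0
        for _ in range(40):
            trial = x + scale * step
            if 0.0 < trial[1] <= 1.0:
                g_new, jac_new = system(trial)
                if np.linalg.norm(g_new) < norm0:
                    x, g, jac = trial, g_new, jac_new
                    break
            scale *= 0.5
        else:
            raise RuntimeError("fold polish failed to reduce the residual")
    if np.max(np.abs(g)) > 1e-10:
        raise RuntimeError(f"fold polish did not converge, residual {g}")
    return float(x[0]), float(x[1])


def fold_ratios(
    ns: NormSensitivity,
    p_tilde: float,
    ratio_grid=None,
) -> list[float]:
    """All outflow/learning ratios at which the savvy-root count changes.

    Zero folds: a single branch throughout (high-variance regime); one:
    the bistable coordination case; two: the window of three equilibria
    in the cooperation dilemma.
    """
    if ratio_grid is None:
        ratio_grid = np.geomspace(1e-3, 20.0, 120)
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    counts = [_root_count(ns, p_tilde, r) for r in ratio_grid]
    out: list[float] = []
    for a, b, ca, cb in zip(ratio_grid[:-1], ratio_grid[1:], counts[:-1], counts[1:]):
        if ca == cb:
            continue
        lo, hi = a, b
        while hi - lo > 1e-12 * max(1.0, hi):
            mid = 0.5 * (lo + hi)
            if _root_count(ns, p_tilde, mid) == ca:
                lo = mid
            else:
                hi = mid
        coarse = 0.5 * (lo + hi)
        # Polish on the tangency system, seeded at the near-double root.
        side = lo if _root_count(ns, p_tilde, lo) > _root_count(ns, p_tilde, hi) else hi
        y_side = 1.0 / (1.0 + side)
        c = ns.cdf_clipped(p_tilde)
        grid = np.linspace(0.0, p_tilde, 4001)
        g = ns.cdf_clipped(y_side * grid + (1.0 - y_side) * c) - grid
        sign = np.sign(g)
        brackets = np.nonzero((sign[:-1] * sign[1:]) < 0)[0]
        # The colliding pair is the adjacent pair of interior roots closest
        # together; seed p0 between them.
        if len(brackets) >= 2:
            roots = 0.5 * (grid[brackets] + grid[brackets + 1])
            gaps = np.diff(roots)
            k = int(np.argmin(gaps))
            p0 = 0.5 * (roots[k] + roots[k + 1])
        elif len(brackets) == 1:
            p0 = 0.5 * (grid[brackets[0]] + grid[brackets[0] + 1])
        else:
            p0 = 0.5 * p_tilde
        try:
            _, y_fold = _tangency_polish(ns, p_tilde, p0, 1.0 / (1.0 + coarse))
            out.append((1.0 - y_fold) / y_fold)
        except RuntimeError:
            out.append(coarse)
    return sorted(out)


def critical_ratio(ns: NormSensitivity, p_tilde: float, ratio_grid=None) -> float | None:
    """Outflow/learning ratio at which the low and middle savvy roots annihilate.

    This is the largest fold along the ratio axis; ``None`` when the
    branch is monotone (no fold, the high-variance regime).
    """
    folds = fold_ratios(ns, p_tilde, ratio_grid)
    return folds[-1] if folds else None


@dataclass(frozen=True)
class RegimeRecord:
    variance: float
    regime: Dilemma
    fold_ratios: tuple[float, ...]


def regime_diagram(mu: float, sigma2_values, p_tilde: float, ratio_grid=None) -> list[RegimeRecord]:
    """Classify the threshold regime and fold structure per variance value."""
    out = []
    for s2 in np.asarray(sigma2_values, dtype=float):
        ns = NormSensitivity(mu, float(s2))
        out.append(
            RegimeRecord(
                variance=float(s2),
                regime=classify_dilemma(ns),
                fold_ratios=tuple(fold_ratios(ns, p_tilde, ratio_grid)),
            )
        )
    return out


class AttractorClass(enum.Enum):
    FIXED_POINT = "fixed_point"
    LIMIT_CYCLE = "limit_cycle"
    BURSTING = "bursting"


@dataclass(frozen=True)
class CycleSummary:
    classification: AttractorClass
    period: float | None
    #: Per-variable (min, max) over the post-transient attractor.
    extrema: dict

    @property
    def amplitude(self) -> float:
        lo, hi = self.extrema["I"]
        return hi - lo


#: Oscillations smaller than this (times K) count as a fixed point.
FLAT_AMPLITUDE = 1e-6
#: Attractor minima below this (times K) flag a bursting regime.
BURST_FLOOR = 1e-4
#: Relative peak-amplitude drift per period allowed for a limit cycle.
DRIFT_TOL = 1e-3


def classify_attractor(traj: Trajectory, transient_fraction: float = 0.5) -> CycleSummary:
    """Classify the long-run behaviour of a trajectory from its I(t) signal.

    Peak detection on the insider count after discarding the transient:
    no material oscillation means a fixed point; regular sustained peaks a
    limit cycle; rare large excursions separated by a near-empty community
    a bursting regime.  Still-drifting oscillations raise, demanding a
    longer integration.
    """
    if not 0.0 <= transient_fraction < 1.0:
        raise ValueError("transient_fraction must lie in [0, 1)")
    start = int(len(traj.times) * transient_fraction)
    t = traj.times[start:]
    I = traj.I[start:]
    K = traj.params.K
    extrema = {
        name: (float(arr[start:].min()), float(arr[start:].max()))
        for name, arr in (("S", traj.S), ("I", traj.I), ("y", traj.y), ("p", traj.p))
    }

    span = I.max() - I.min()
    if span < FLAT_AMPLITUDE * K:
        return CycleSummary(AttractorClass.FIXED_POINT, None, extrema)

    peaks, props = find_peaks(I, prominence=FLAT_AMPLITUDE * K)
    if len(peaks) < 2:
        raise ValueError(
            "trajectory oscillates but shows fewer than 2 post-transient peaks; "
            "integrate longer"
        )
    heights = I[peaks]
    # Sustained vs decaying: compare amplitude about the mean in the last
    # quarter of the window against the drift-per-period bound.
    mean_I = I.mean()
    amp = np.abs(heights - mean_I)
    if amp[-1] < FLAT_AMPLITUDE * K:
        return CycleSummary(AttractorClass.FIXED_POINT, None, extrema)
    if len(peaks) < 5:
        raise ValueError(
            "fewer than 5 post-transient peaks; integrate longer to classify a cycle"
        )
    drift = np.abs(np.diff(amp)) / np.maximum(amp[:-1], 1e-300)
    # Ignore the first peaks (residual transient); require the tail regular.
    tail = drift[len(drift) // 2:]
    if np.median(tail) > DRIFT_TOL:
        raise ValueError(
            "peak amplitudes still drifting (median relative drift "
            f"{np.median(tail):.3g}); integrate longer"
        )
    period = float(np.median(np.diff(t[peaks])))

    if I.min() < BURST_FLOOR * K:
        widths = peak_widths(I, peaks, rel_height=0.5)[0]
        dt = t[1] - t[0]
        burst_width = float(np.median(widths) * dt)
        if period > 5.0 * burst_width:
            return CycleSummary(AttractorClass.BURSTING, period, extrema)
    return CycleSummary(AttractorClass.LIMIT_CYCLE, period, extrema)
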