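"""Trial sequential analysis: required information size, alpha/beta spending,
group-sequential boundaries and the cumulative Z-curve.

A cumulative meta-analysis is treated as a sequence of interim looks at a
canonical Gaussian process: at information fractions ``t_1 < ... < t_K`` the
pooled z-statistics ``Z_k`` behave (asymptotically) like a process with
``cov(Z_j, Z_k) = sqrt(t_j / t_k)`` and mean ``delta * sqrt(t_k)`` under a
drift ``delta``.  Two-sided monitoring boundaries are obtained from a
Lan-DeMets O'Brien-Fleming-type alpha-spending function by recursive
numerical integration of the process density over a fixed grid, and futility
(inner-wedge) boundaries from an analogous beta-spending function under the
design drift.  Information is counted in alleles (two per person), matching
the allele-model 2x2 tables the z-statistics are computed from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .meta import CumulativeResult, Z_975
from .simulate import derive_case_allele_freq

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _z(p: float) -> float:
    """Upper-tail-free normal quantile; 0.975 pinned to 1.959964."""
    if abs(p - 0.975) < 1e-12:
        return Z_975
    return float(norm.ppf(p))


# ---------------------------------------------------------------------------
# design: required information size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RISSpec:
    """Design parameters for the required information size.

    ``control_maf`` is the reference minor-allele frequency in controls;
    ``assumed_or`` the allele-model odds ratio the design should detect;
    ``heterogeneity_adjustment`` the anticipated fraction of total variance
    due to between-study heterogeneity, by which the information size is
    inflated (0.80 inflates five-fold).
    """

    control_maf: float
    alpha: float = 0.05
    power: float = 0.8
    assumed_or: float = 1.5
    heterogeneity_adjustment: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.control_maf < 1:
            raise ValueError("control_maf must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.assumed_or <= 0 or self.assumed_or == 1:
            raise ValueError("assumed_or must be positive and different from 1")
        if not 0 <= self.heterogeneity_adjustment < 1:
            raise ValueError("heterogeneity_adjustment must lie in [0, 1)")

    @property
    def drift(self) -> float:
        """Mean of the canonical Z-process at full information under H1."""
        return _z(1 - self.alpha / 2) + _z(self.power)


@dataclass(frozen=True)
class RISResult:
    """Required information size, in alleles summed over both arms."""

    unadjusted_alleles: float
    adjusted_alleles: float
    p1: float
    p2: float


def required_information_size(spec: RISSpec) -> RISResult:
    """Heterogeneity-adjusted required information size in alleles.

    The two-proportion (unpooled-variance) formula at allele level: with
    ``p2`` the control minor-allele frequency and ``p1`` the case frequency
    implied by the assumed odds ratio, the per-group allele count is
    ``(z_{1-a/2} + z_{pow})^2 (p1(1-p1) + p2(1-p2)) / (p1-p2)^2``; the total
    over both groups is then divided by ``1 - heterogeneity_adjustment``.
    """
    p2 = spec.control_maf
    p1 = derive_case_allele_freq(p2, spec.assumed_or)
    za = _z(1 - spec.alpha / 2)
    zb = _z(spec.power)
    n_per_group = (za + zb) ** 2 * (p1 * (1 - p1) + p2 * (1 - p2)) / (p1 - p2) ** 2
    unadjusted = 2.0 * n_per_group
    adjusted = unadjusted / (1.0 - spec.heterogeneity_adjustment)
    return RISResult(unadjusted_alleles=unadjusted, adjusted_alleles=adjusted, p1=p1, p2=p2)


# ---------------------------------------------------------------------------
# spending functions
# ---------------------------------------------------------------------------


def alpha_spent(t: float, alpha: float = 0.05) -> float:
    """O'Brien-Fleming-type cumulative alpha spent at information fraction t.

    ``2 (1 - Phi(z_{1-alpha/2} / sqrt(t)))`` — essentially nothing is spent
    early, and the full ``alpha`` is spent at ``t = 1``.
    """
    if not 0 < t <= 1:
        raise ValueError("information fraction must lie in (0, 1]")
    return 2.0 * float(norm.sf(_z(1 - alpha / 2) / math.sqrt(t)))


def beta_spent(t: float, beta: float = 0.2) -> float:
    """O'Brien-Fleming-shaped cumulative beta spent at fraction t.

    The shape ``2 (1 - Phi(z_{1-beta} / sqrt(t)))`` normalised so that the
    full ``beta`` is spent at ``t = 1``.
    """
    if not 0 < t <= 1:
        raise ValueError("information fraction must lie in (0, 1]")
    zb = _z(1 - beta)
    shape = 2.0 * float(norm.sf(zb / math.sqrt(t)))
    return shape * beta / (2.0 * float(norm.sf(zb)))


# ---------------------------------------------------------------------------
# boundary recursion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridConfig:
    """Numerical settings for the boundary recursion.

    The surviving density of the Z-process is tabulated on a symmetric grid
    of ``nodes`` points spanning ``[-zmax, zmax]``; each boundary is solved
    by bisection until the look's crossing probability matches its spending
    target within ``prob_tol``.
    """

    nodes: int = 4001
    zmax: float = 8.0
    prob_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.nodes < 101:
            raise ValueError("grid needs at least 101 nodes")
        if self.zmax <= 3:
            raise ValueError("zmax must exceed 3")
        if not 0 < self.prob_tol < 1e-2:
            raise ValueError("prob_tol must lie in (0, 0.01)")


DEFAULT_GRID = GridConfig()


def _norm_pdf(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / _SQRT_2PI


def _mass_between(z: np.ndarray, f: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of f over [lo, hi] with interpolated endpoints."""
    lo = max(lo, float(z[0]))
    hi = min(hi, float(z[-1]))
    if hi <= lo:
        return 0.0
    inside = (z > lo) & (z < hi)
    xs = np.concatenate(([lo], z[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, z, f)], f[inside], [np.interp(hi, z, f)]))
    return float(np.trapezoid(ys, xs))


def _propagate(
    z: np.ndarray,
    f: np.ndarray,
    lo: float,
    hi: float,
    t_prev: float,
    t_next: float,
    delta: float,
) -> np.ndarray:
    """Advance the surviving density from look at t_prev to look at t_next.

    The previous look's density ``f`` (on grid ``z``) is truncated to the
    continuation region ``(lo, hi)`` with linearly interpolated endpoint
    values, then convolved with the Gaussian increment kernel of the
    underlying Brownian motion (variance ``t_next - t_prev``, mean
    ``delta * (t_next - t_prev)``) and rescaled back to the z-scale.
    """
    lo = max(lo, float(z[0]))
    hi = min(hi, float(z[-1]))
    inside = (z > lo) & (z < hi)
    xs = np.concatenate(([lo], z[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, z, f)], f[inside], [np.interp(hi, z, f)]))
    # trapezoid weights on the (non-uniform at the ends) partition
    w = np.empty_like(xs)
    w[0] = 0.5 * (xs[1] - xs[0])
    w[-1] = 0.5 * (xs[-1] - xs[-2])
    if len(xs) > 2:
        w[1:-1] = 0.5 * (xs[2:] - xs[:-2])
    dt = t_next - t_prev
    sd = math.sqrt(dt)
    arg = (z[:, None] * math.sqrt(t_next) - xs[None, :] * math.sqrt(t_prev) - delta * dt) / sd
    kernel = _norm_pdf(arg)
    return (math.sqrt(t_next) / sd) * (kernel @ (ys * w))


def _solve_look(
    z: np.ndarray,
    f: np.ndarray,
    increment: float,
    side: str,
    prob_tol: float,
) -> float:
    """Boundary for one look by bisection on the crossing probability.

    ``side='outer'`` stops when |Z| >= c (two-sided monitoring): the
    crossing mass is the density outside (-c, c), decreasing in c.
    ``side='lower'`` stops when Z <= c (futility under drift): the crossing
    mass below c is increasing in c.
    """
    zmax = float(z[-1])
    total = _mass_between(z, f, -zmax, zmax)

    if side == "outer":
        def crossing(c: float) -> float:
            return total - _mass_between(z, f, -c, c)
        lo_c, hi_c = 0.0, zmax          # crossing: decreasing from total to 0
        if increment <= prob_tol:
            return zmax
        lo_v = crossing(lo_c)
        if increment >= lo_v:
            return lo_c
        for _ in range(200):
            mid = 0.5 * (lo_c + hi_c)
            v = crossing(mid)
            if abs(v - increment) <= prob_tol or hi_c - lo_c < 1e-12:
                return mid
            if v > increment:
                lo_c = mid
            else:
                hi_c = mid
        return 0.5 * (lo_c + hi_c)

    if side == "lower":
        def crossing(c: float) -> float:
            return _mass_between(z, f, -zmax, c)
        lo_c, hi_c = -zmax, zmax        # crossing: increasing from 0 to total
        if increment <= prob_tol:
            return -zmax
        if increment >= total:
            return zmax
        for _ in range(200):
            mid = 0.5 * (lo_c + hi_c)
            v = crossing(mid)
            if abs(v - increment) <= prob_tol or hi_c - lo_c < 1e-12:
                return mid
            if v < increment:
                lo_c = mid
            else:
                hi_c = mid
        return 0.5 * (lo_c + hi_c)

    raise ValueError(f"unknown side {side!r}")


def _validate_fractions(info_fractions: Sequence[float]) -> np.ndarray:
    ts = np.asarray(info_fractions, dtype=float)
    if ts.ndim != 1 or len(ts) == 0:
        raise ValueError("info_fractions must be a non-empty 1-d sequence")
    if np.any(ts <= 0) or np.any(ts > 1):
        raise ValueError("information fractions must lie in (0, 1]")
    if np.any(np.diff(ts) <= 0):
        raise ValueError("information fractions must be strictly increasing")
    return ts


def _spending_recursion(
    ts: np.ndarray,
    cum_targets: np.ndarray,
    side: str,
    delta: float,
    grid: GridConfig,
) -> np.ndarray:
    """Solve the whole boundary sequence for one spending schedule."""
    z = np.linspace(-grid.zmax, grid.zmax, grid.nodes)
    bounds = np.empty(len(ts))
    f: Optional[np.ndarray] = None
    spent = 0.0
    lo = hi = 0.0
    t_prev = 0.0
    for k, (t, tgt) in enumerate(zip(ts, cum_targets)):
        if f is None:
            f = _norm_pdf(z - delta * math.sqrt(t))
        else:
            f = _propagate(z, f, lo, hi, t_prev, t, delta)
        inc = max(0.0, float(tgt) - spent)
        c = _solve_look(z, f, inc, side, grid.prob_tol)
        bounds[k] = c
        if side == "outer":
            achieved = _mass_between(z, f, -grid.zmax, grid.zmax) - _mass_between(z, f, -c, c)
            lo, hi = -c, c
        else:
            achieved = _mass_between(z, f, -grid.zmax, c)
            lo, hi = c, grid.zmax
        spent += achieved
        t_prev = t
    return bounds


def monitoring_boundaries(
    info_fractions: Sequence[float],
    alpha: float = 0.05,
    grid: GridConfig = DEFAULT_GRID,
) -> np.ndarray:
    """Two-sided O'Brien-Fleming-type monitoring boundary magnitudes.

    At each look ``k`` the boundary ``u_k`` makes the cumulative probability
    under H0 of ``|Z_j| >= u_j`` for some ``j <= k`` equal to the alpha spent
    at ``t_k``.  Looks enter only through ``t_1..t_k``, so appending future
    looks never changes earlier boundaries.  A look whose spending increment
    is below the solver tolerance gets the grid edge (effectively an
    uncrossable boundary); its unspent alpha rolls forward.
    """
    ts = _validate_fractions(info_fractions)
    targets = np.array([alpha_spent(t, alpha) for t in ts])
    return _spending_recursion(ts, targets, "outer", 0.0, grid)


def futility_boundaries(
    info_fractions: Sequence[float],
    alpha: float = 0.05,
    beta: float = 0.2,
    drift: Optional[float] = None,
    grid: GridConfig = DEFAULT_GRID,
) -> np.ndarray:
    """Inner-wedge (futility) boundary magnitudes under the design drift.

    Beta-spending: at each look the boundary ``f_k`` makes the cumulative
    probability, under the alternative with mean ``drift * sqrt(t_k)``, of
    the Z-process falling to ``f_j`` or below at some ``j <= k`` equal to the
    beta spent at ``t_k``.  Looks where the solved boundary is negative are
    reported as NaN (wedge closed: too little information to conclude
    futility).  The futility computation is non-binding: monitoring
    boundaries are computed ignoring it.
    """
    ts = _validate_fractions(info_fractions)
    if drift is None:
        drift = _z(1 - alpha / 2) + _z(1 - beta)
    if drift <= 0:
        raise ValueError("drift must be positive")
    targets = np.array([beta_spent(t, beta) for t in ts])
    raw = _spending_recursion(ts, targets, "lower", drift, grid)
    out = raw.copy()
    out[out < 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# boundary set, Z-curve, crossings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundarySet:
    """Monitoring and futility boundaries at a sequence of interim looks.

    ``futility`` entries are NaN where the inner wedge is closed.  Looks at
    information fraction >= 1 (information beyond the required size) reuse
    the full-information boundary and carry no futility wedge, since the
    required-size route already applies there.
    """

    info_fractions: tuple
    monitoring: tuple
    futility: tuple
    alpha: float
    beta: float
    drift: float

    def __len__(self) -> int:
        return len(self.info_fractions)


def compute_boundaries(
    info_fractions: Sequence[float],
    alpha: float = 0.05,
    beta: float = 0.2,
    drift: Optional[float] = None,
    grid: GridConfig = DEFAULT_GRID,
) -> BoundarySet:
    """Boundary set for an arbitrary (possibly >1) fraction schedule.

    Fractions are capped at 1; looks after the first capped look reuse the
    full-information monitoring value and have no futility wedge.
    """
    raw = np.asarray(info_fractions, dtype=float)
    if raw.ndim != 1 or len(raw) == 0:
        raise ValueError("info_fractions must be a non-empty 1-d sequence")
    if np.any(raw <= 0) or np.any(np.diff(raw) <= 0):
        raise ValueError("information fractions must be positive and strictly increasing")
    if drift is None:
        drift = _z(1 - alpha / 2) + _z(1 - beta)
    capped = np.minimum(raw, 1.0)
    # strictly increasing prefix after capping: everything up to the first 1.0
    if np.any(capped >= 1.0):
        m = int(np.argmax(capped >= 1.0)) + 1
    else:
        m = len(capped)
    head = capped[:m]
    mon_head = monitoring_boundaries(head, alpha, grid)
    fut_head = futility_boundaries(head, alpha, beta, drift, grid)
    n_tail = len(capped) - m
    monitoring = np.concatenate([mon_head, np.full(n_tail, mon_head[-1])])
    futility = np.concatenate([fut_head, np.full(n_tail, np.nan)])
    return BoundarySet(
        info_fractions=tuple(capped.tolist()),
        monitoring=tuple(monitoring.tolist()),
        futility=tuple(futility.tolist()),
        alpha=alpha,
        beta=beta,
        drift=drift,
    )


class ZPoint(NamedTuple):
    info_fraction: float
    z: float
    cum_alleles: int
    k: int


@dataclass(frozen=True)
class ZCurve:
    """The cumulative z-statistics against (uncapped) information fraction."""

    points: tuple
    ris: RISResult


def build_z_curve(series: Sequence[CumulativeResult], ris: RISResult) -> ZCurve:
    """Map a cumulative meta-analysis series onto the information scale.

    Each look contributes its pooled z and its cumulative allele count
    divided by the adjusted required information size.  Fractions beyond 1
    are stored as-is (boundary evaluation caps them later).
    """
    series = list(series)
    if not series:
        raise ValueError("series must be non-empty")
    pts = [
        ZPoint(
            info_fraction=r.cum_alleles / ris.adjusted_alleles,
            z=r.z,
            cum_alleles=r.cum_alleles,
            k=i + 1,
        )
        for i, r in enumerate(series)
    ]
    return ZCurve(points=tuple(pts), ris=ris)


@dataclass(frozen=True)
class CrossingReport:
    """Where (if anywhere) the Z-curve left the continuation region.

    Looks are 1-based.  ``first_monitoring_look`` is the first look with
    ``|z|`` at or above the monitoring boundary (``monitoring_sign`` holds
    the sign of z there); ``first_futility_look`` the first look strictly
    inside the futility wedge; ``first_ris_look`` the first look whose
    cumulative information reached the adjusted required size.
    """

    first_monitoring_look: Optional[int]
    monitoring_sign: Optional[int]
    first_futility_look: Optional[int]
    ris_reached: bool
    first_ris_look: Optional[int]


def assess_crossings(curve: ZCurve, bounds: BoundarySet) -> CrossingReport:
    """Compare the Z-curve against a boundary set computed at its looks."""
    if len(curve.points) != len(bounds):
        raise ValueError(
            f"curve has {len(curve.points)} looks but bounds has {len(bounds)}"
        )
    capped = [min(p.info_fraction, 1.0) for p in curve.points]
    if not np.allclose(capped, bounds.info_fractions, atol=1e-9):
        raise ValueError("bounds were not computed at the curve's information fractions")
    first_mon: Optional[int] = None
    sign: Optional[int] = None
    first_fut: Optional[int] = None
    first_ris: Optional[int] = None
    for p, mon, fut in zip(curve.points, bounds.monitoring, bounds.futility):
        if first_mon is None and abs(p.z) >= mon:
            first_mon = p.k
            sign = 1 if p.z > 0 else -1
        if first_fut is None and not math.isnan(fut) and abs(p.z) < fut:
            first_fut = p.k
        if first_ris is None and p.info_fraction >= 1.0:
            first_ris = p.k
    return CrossingReport(
        first_monitoring_look=first_mon,
        monitoring_sign=sign,
        first_futility_look=first_fut,
        ris_reached=first_ris is not None,
        first_ris_look=first_ris,
    )
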