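"""Gaussian kernel density estimation and mode finding on one terminal node.

The density over a node's peak centers x_1..x_N is the equal-weight Gaussian
mixture

    f(x) = (1/(N h)) * sum_i K((x - x_i)/h),    K(u) = (2*pi)^(-1/2) exp(-u^2/2),

with bandwidth h the kernel standard deviation in bp. Such a mixture has at
most as many local maxima as components, so hill-climbing from every sample
point visits every mode whose basin holds data. The climb is a mean-shift
fixed-point iteration (globally convergent to a stationary point for Gaussian
kernels), polished by Newton steps on the gradient; a second-derivative test
classifies each stationary point. Local minima (antimodes) between adjacent
maxima are then bracketed and solved by root finding on the gradient, and the
antimodes partition the axis into basins that assign every sample point to
exactly one modal region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError

logger = logging.getLogger("tkde")

_SQRT_2PI = math.sqrt(2.0 * math.pi)

# iteration controls; all length tolerances scale with the bandwidth
MAX_ITER = 500
TOL_FIX_FRAC = 1e-3  # mean-shift stops when the step falls below this * h
MERGE_TOL_FRAC = 1e-2  # converged maxima closer than this * h are one mode
NEWTON_ITER = 60
_CHUNK = 512


@dataclass(frozen=True)
class DensityModel:
    """Sample points plus bandwidth; everything else is derived."""

    positions: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1 or pos.size == 0:
            raise ParameterError("positions must be a non-empty 1-D array")
        if not (self.bandwidth > 0):
            raise ParameterError(f"bandwidth must be positive: {self.bandwidth}")
        object.__setattr__(self, "positions", np.sort(pos))

    @property
    def n(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class ModeSet:
    """Alternating local maxima and minima of the estimated density."""

    maxima: np.ndarray
    minima: np.ndarray

    def __post_init__(self) -> None:
        if len(self.minima) != len(self.maxima) - 1:
            raise ValueError("maxima and minima must strictly alternate")
        merged = np.empty(len(self.maxima) + len(self.minima))
        merged[0::2] = self.maxima
        merged[1::2] = self.minima
        if np.any(np.diff(merged) <= 0):
            raise ValueError("modes do not alternate in increasing order")


@dataclass
class ModalRegion:
    """One mode with its basin's member sample points.

    Bounds are the min/max member positions, so a single-member region has
    width zero. The summit is the converged maximum location, clamped to the
    member span in the rare case numerical polish leaves it just outside.
    """

    summit: float
    left: float
    right: float
    member_indices: np.ndarray = field(repr=False)


def density(model: DensityModel, x) -> float | np.ndarray:
    """Evaluate the KDE at point(s) x (per-bp probability density)."""
    f, _, _ = _derivatives(model, x)
    return f


def _derivatives(model: DensityModel, x):
    """Density, gradient and second derivative at x, chunked over queries."""
    xq = np.atleast_1d(np.asarray(x, dtype=float))
    scalar = np.ndim(x) == 0
    pos, h, n = model.positions, model.bandwidth, model.n
    f = np.empty_like(xq)
    g = np.empty_like(xq)
    fpp = np.empty_like(xq)
    for i0 in range(0, xq.size, _CHUNK):
        blk = xq[i0 : i0 + _CHUNK]
        u = (blk[:, None] - pos[None, :]) / h
        k = np.exp(-0.5 * u * u)
        f[i0 : i0 + _CHUNK] = k.sum(axis=1) / (n * h * _SQRT_2PI)
        g[i0 : i0 + _CHUNK] = -(u * k).sum(axis=1) / (n * h * h * _SQRT_2PI)
        fpp[i0 : i0 + _CHUNK] = ((u * u - 1.0) * k).sum(axis=1) / (n * h**3 * _SQRT_2PI)
    if scalar:
        return float(f[0]), float(g[0]), float(fpp[0])
    return f, g, fpp


def _mean_shift(model: DensityModel, starts: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    """Run the fixed-point update x <- sum(x_i w_i)/sum(w_i) from each start."""
    pos, h = model.positions, model.bandwidth
    x = starts.astype(float).copy()
    active = np.ones(x.size, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        for j0 in range(0, idx.size, _CHUNK):
            sel = idx[j0 : j0 + _CHUNK]
            u = (x[sel, None] - pos[None, :]) / h
            w = np.exp(-0.5 * u * u)
            sw = w.sum(axis=1)
            ok = sw > 0.0  # a start sitting on a sample always has weight >= 1
            new = np.where(ok, (w @ pos) / np.where(sw > 0, sw, 1.0), x[sel])
            moved = np.abs(new - x[sel])
            x[sel] = new
            done = moved < tol
            active[sel[done]] = False
    n_left = int(active.sum())
    if n_left:
        logger.warning("mean-shift: %d start(s) not converged after %d iterations", n_left, max_iter)
    return x


def _newton_polish(model: DensityModel, x: float) -> float:
    """Drive the gradient to zero from an already-near-stationary point."""
    h = model.bandwidth
    tol_grad = 1e-10 / (model.n * h * h)  # scaled to the gradient's natural units
    for _ in range(NEWTON_ITER):
        _, g, fpp = _derivatives(model, x)
        if abs(g) < tol_grad or fpp == 0.0:
            break
        step = -g / fpp
        step = max(-h, min(h, step))
        x_new = x + step
        if abs(step) < 1e-12 * h:
            x = x_new
            break
        x = x_new
    return x


def find_modes(model: DensityModel, max_iter: int = MAX_ITER) -> ModeSet:
    """Locate all local maxima and minima of the node's density.

    Hill-climb from every distinct sample point, polish with Newton, classify
    by the second derivative, deduplicate maxima closer than MERGE_TOL_FRAC*h,
    and bracket one antimode between each adjacent pair of retained maxima.
    """
    pos, h = model.positions, model.bandwidth
    starts = np.unique(pos)
    if starts.size == 1:
        return ModeSet(maxima=starts.copy(), minima=np.empty(0))

    tol_fix = TOL_FIX_FRAC * h
    merge_tol = MERGE_TOL_FRAC * h
    converged = _mean_shift(model, starts, max_iter, tol_fix)

    fpp_tol = 1e-9 / (model.n * h**3)  # below this curvature the point is degenerate
    maxima: list[float] = []
    for x0 in converged:
        x1 = _newton_polish(model, float(x0))
        _, _, fpp = _derivatives(model, x1)
        if fpp > fpp_tol:
            continue  # Newton slid to an antimode; bracketing will recover it
        maxima.append(x1)  # negative or degenerate curvature: a (flat-topped) mode

    maxima = _dedup(model, np.sort(np.asarray(maxima)), merge_tol)
    maxima, minima = _antimodes(model, maxima)
    return ModeSet(maxima=np.asarray(maxima), minima=np.asarray(minima))


def _dedup(model: DensityModel, xs: np.ndarray, merge_tol: float) -> list[float]:
    """Collapse converged maxima closer than merge_tol; keep the densest."""
    if xs.size == 0:
        # pathological: all starts classified degenerate-minimum; fall back to
        # the densest sample point so every node yields at least one mode
        f = density(model, model.positions)
        return [float(model.positions[int(np.argmax(f))])]
    groups: list[list[float]] = [[float(xs[0])]]
    for x in xs[1:]:
        if x - groups[-1][-1] < merge_tol:
            groups[-1].append(float(x))
        else:
            groups.append([float(x)])
    out = []
    for grp in groups:
        dens = density(model, np.asarray(grp))
        out.append(grp[int(np.argmax(dens))])
    return out


def _antimodes(model: DensityModel, maxima: list[float]) -> tuple[list[float], list[float]]:
    """Find one local minimum between each adjacent pair of maxima.

    If no interior dip exists between a pair (numerical duplicates that
    survived dedup), the lower-density maximum is dropped and the scan
    restarts from the merged list.
    """
    maxima = sorted(maxima)
    while True:
        minima: list[float] = []
        merged = False
        for a, b in zip(maxima[:-1], maxima[1:]):
            m = _minimum_between(model, a, b)
            if m is None:
                fa, fb = density(model, a), density(model, b)
                maxima.remove(a if fa <= fb else b)
                merged = True
                break
            minima.append(m)
        if not merged:
            return maxima, minima


def _minimum_between(model: DensityModel, a: float, b: float) -> float | None:
    """One antimode in the open interval (a, b), or None if density never dips."""
    delta = max(1e-9 * model.bandwidth, 1e-9 * (b - a))
    lo, hi = a + delta, b - delta
    if lo >= hi:
        return None
    _, g_lo, _ = _derivatives(model, lo)
    _, g_hi, _ = _derivatives(model, hi)
    if g_lo < 0.0 < g_hi:
        return float(brentq(lambda x: _derivatives(model, x)[1], lo, hi, xtol=1e-9 * model.bandwidth))
    # gradient signs inconclusive at the bracket ends (flat or noisy); sample
    grid = np.linspace(lo, hi, 257)
    d = density(model, grid)
    k = int(np.argmin(d))
    f_ends = min(density(model, a), density(model, b))
    if d[k] >= f_ends * (1.0 - 1e-12):
        return None  # no genuine dip: a and b are one mode
    return float(grid[k])


def delineate_regions(model: DensityModel, modes: ModeSet) -> list[ModalRegion]:
    """Assign every sample point to the basin it falls in and bound regions.

    The antimodes split the axis into len(maxima) intervals; a point exactly
    on an antimode goes to the left region (deterministic tie-break). Region
    bounds are the min/max member positions, so singleton regions have width
    zero. Modes whose basin holds no sample point are dropped with a warning.
    """
    pos = model.positions
    which = np.searchsorted(modes.minima, pos, side="left")
    regions: list[ModalRegion] = []
    for k, summit in enumerate(modes.maxima):
        members = np.flatnonzero(which == k)
        if members.size == 0:
            logger.warning("mode at %.3f has no member peak centers; dropped", summit)
            continue
        left = float(pos[members[0]])
        right = float(pos[members[-1]])
        regions.append(
            ModalRegion(
                summit=float(min(max(summit, left), right)),
                left=left,
                right=right,
                member_indices=members,
            )
        )
    return regions
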