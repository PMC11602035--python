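"""Continuous piecewise-linear regression with free breakpoints.

Used to automate what an analyst otherwise does by eye: partitioning a
local-scaling-exponent (or divergence) curve into regimes and picking
the flat or growing segment.  The model is a linear spline

    y(x) = b0 + b1*x + sum_k g_k * max(x - t_k, 0)

with ``n_segments - 1`` interior breakpoints ``t_k``.  Given breakpoints
the coefficients are a linear least-squares problem; the breakpoints are
optimised by deterministic multi-start Nelder-Mead over quantile-spread
initialisations plus seeded random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["PiecewiseFit", "fit_piecewise_linear"]


@dataclass(frozen=True)
class PiecewiseFit:
    breakpoints: np.ndarray  # interior breakpoints, sorted
    slopes: np.ndarray       # one slope per segment
    intercept: float
    sse: float
    x_lo: float
    x_hi: float

    @property
    def n_segments(self) -> int:
        return self.slopes.size

    def segment_bounds(self, j: int) -> tuple[float, float]:
        """The x-interval covered by segment ``j``."""
        edges = np.concatenate([[self.x_lo], self.breakpoints, [self.x_hi]])
        return float(edges[j]), float(edges[j + 1])

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        design = _design(x, self.breakpoints)
        beta = np.concatenate([[self.intercept, self.slopes[0]], np.diff(self.slopes)])
        return design @ beta


def _design(x: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for t in breakpoints:
        cols.append(np.maximum(x - t, 0.0))
    return np.column_stack(cols)


def _solve(x: np.ndarray, y: np.ndarray, breakpoints: np.ndarray):
    design = _design(x, breakpoints)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def fit_piecewise_linear(
    x: np.ndarray,
    y: np.ndarray,
    n_segments: int,
    seed: int = 0,
    n_random_starts: int = 8,
) -> PiecewiseFit:
    """Fit a continuous piecewise-linear model with free interior breakpoints.

    Raises ``ValueError`` if fewer than ``2 * n_segments`` points are given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n_break = n_segments - 1
    if x.size < 2 * n_segments:
        raise ValueError("too few points for the requested segment count")
    x_lo, x_hi = float(x[0]), float(x[-1])
    span = x_hi - x_lo
    if span <= 0:
        raise ValueError("degenerate x range")

    rng = np.random.default_rng(seed)
    starts = [np.quantile(x, (np.arange(n_break) + 1) / n_segments)]
    # deterministic alternate starts: evenly spaced in x
    starts.append(x_lo + span * (np.arange(n_break) + 1) / n_segments)
    for _ in range(n_random_starts):
        starts.append(np.sort(rng.uniform(x_lo + 0.02 * span, x_hi - 0.02 * span, n_break)))

    def objective(t: np.ndarray) -> float:
        t = np.sort(t)
        # keep breakpoints interior and separated by at least 2% of span
        if t[0] <= x_lo + 0.01 * span or t[-1] >= x_hi - 0.01 * span:
            return np.inf
        if n_break > 1 and np.min(np.diff(t)) < 0.02 * span:
            return np.inf
        _, sse = _solve(x, y, t)
        return sse

    best_t, best_sse = None, np.inf
    for t0 in starts:
        res = minimize(objective, t0, method="Nelder-Mead",
                       options={"xatol": 1e-4 * span, "fatol": 1e-12, "maxiter": 2000})
        if res.fun < best_sse and np.isfinite(res.fun):
            best_sse, best_t = float(res.fun), np.sort(res.x)
    if best_t is None:
        raise RuntimeError("piecewise fit failed to converge from every start")

    beta, sse = _solve(x, y, best_t)
    slopes = np.cumsum(np.concatenate([[beta[1]], beta[2:]]))
    return PiecewiseFit(
        breakpoints=best_t, slopes=slopes, intercept=float(beta[0]),
        sse=sse, x_lo=x_lo, x_hi=x_hi,
    )
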