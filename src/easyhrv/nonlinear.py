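"""Non-linear HRV indices with fully automated parameter selection.

The chain of operations mirrors standard non-linear time-series practice:

1. Poincaré plot geometry (SD1/SD2) directly from the RR sequence.
2. Time-lag selection by a five-strategy cascade (autocorrelation first
   minimum, autocorrelation 1/e decay, mutual-information first minimum,
   mutual-information 1/e decay, fixed fallback of 30 beats).
3. Embedding dimension by Cao's nearest-neighbour method.
4. Correlation sums C(m, r) on a log-spaced radius grid for
   m in {m0, m0+1, m0+2}; local scaling exponents d log C / d log r.
5. Scaling-region detection by a 4-segment continuous piecewise-linear
   fit to the exponent curve; the flattest segment is the scaling
   region and its mean exponent the per-m correlation-dimension
   estimate.  Final estimates average the available per-m values.
6. Sample entropy as ln C(m, r) - ln C(m+1, r) averaged over the
   scaling region and over consecutive embedding dimensions.
7. A recording-specific small radius r_small solving
   mean_m C(m, r_small) = 1e-3 (the average probability of finding a
   phase-space neighbour), shared by the Lyapunov and RQA stages.
8. Maximal Lyapunov exponent from the Kantz divergence curve with a
   2-segment piecewise fit (growth phase then saturation).
9. Recurrence quantification analysis at radius r_small.

Every failure path yields NaN plus a log entry rather than an exception,
so one problematic recording can never abort a cohort run.  All
phase-space distances use the maximum norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .piecewise import PiecewiseFit, fit_piecewise_linear
from .series import BeatSeries

__all__ = [
    "EmbeddingParams",
    "CorrelationSumCurve",
    "ScalingRegion",
    "NonlinearIndices",
    "poincare_indices",
    "estimate_time_lag",
    "estimate_embedding_dim",
    "correlation_sum_curve",
    "detect_scaling_region",
    "correlation_dimension",
    "sample_entropy",
    "solve_small_radius",
    "max_lyapunov",
    "rqa_indices",
    "compute_nonlinear_indices",
    "NONLINEAR_INDEX_NAMES",
    "RQA_INDEX_NAMES",
]

RQA_INDEX_NAMES = (
    "REC", "DET", "RATIO", "Lmax", "Lmean", "LmeanWithoutMain",
    "DIV", "ENTR", "TREND", "LAM", "Vmax", "Vmean",
)
NONLINEAR_INDEX_NAMES = (
    "SD1", "SD2", "CorrelationDim", "SampleEntropy", "MaxLyapunov",
) + RQA_INDEX_NAMES


@dataclass(frozen=True)
class EmbeddingParams:
    """Phase-space reconstruction and estimator settings."""

    lag: int | None = None          # beats; estimated when None
    m0: int | None = None           # Cao embedding dimension; estimated when None
    theiler: int = 100              # temporal exclusion window, beats
    max_lag_search: int = 100
    fallback_lag: int = 30
    cao_threshold: float = 0.95
    cao_max_dim: int = 15
    n_radii: int = 100
    cao_max_points: int = 2500      # reference subsample for Cao's method
    lyap_max_horizon: int = 40      # beats
    lyap_max_refs: int = 1000
    seed: int = 0

    @property
    def m_range(self) -> tuple[int, int, int]:
        if self.m0 is None:
            raise ValueError("embedding dimension not yet estimated")
        return (self.m0, self.m0 + 1, self.m0 + 2)


@dataclass(frozen=True)
class ScalingRegion:
    log_r_lo: float
    log_r_hi: float
    plateau_value: float
    fit_residual: float

    def __post_init__(self) -> None:
        if not self.log_r_lo < self.log_r_hi:
            raise ValueError("empty scaling region")


@dataclass(frozen=True)
class CorrelationSumCurve:
    radii: np.ndarray                       # shared log-spaced grid
    C: dict[int, np.ndarray]                # per embedding dimension
    local_exponent: dict[int, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        exps = {}
        log_r = np.log(self.radii)
        for m, c in self.C.items():
            with np.errstate(divide="ignore"):
                log_c = np.log(c)
            exp = np.full_like(log_c, np.nan)
            # central differences where C > 0 on both sides
            exp[1:-1] = (log_c[2:] - log_c[:-2]) / (log_r[2:] - log_r[:-2])
            exps[m] = exp
        object.__setattr__(self, "local_exponent", exps)

    @property
    def m_values(self) -> tuple[int, ...]:
        return tuple(sorted(self.C))

    def mean_C(self) -> np.ndarray:
        """Correlation sum averaged over embedding dimensions."""
        return np.mean([self.C[m] for m in self.m_values], axis=0)


@dataclass(frozen=True)
class NonlinearIndices:
    SD1: float
    SD2: float
    CorrelationDim: float
    SampleEntropy: float
    MaxLyapunov: float
    REC: float
    DET: float
    RATIO: float
    Lmax: float
    Lmean: float
    LmeanWithoutMain: float
    DIV: float
    ENTR: float
    TREND: float
    LAM: float
    Vmax: float
    Vmean: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in NONLINEAR_INDEX_NAMES}


# ---------------------------------------------------------------- Poincaré

def poincare_indices(series: BeatSeries) -> tuple[float, float]:
    """Minor (SD1) and major (SD2) semi-axes of the Poincaré ellipse.

    SD1 captures beat-to-beat (short-term) variability, SD2 the
    longer-term spread along the line of identity.
    """
    rr = series.rr
    if rr.size < 3:
        raise ValueError("need at least three RR intervals")
    d = np.diff(rr)
    var_rr = np.var(rr)
    var_d = np.var(d)
    sd1 = float(np.sqrt(max(var_d / 2.0, 0.0)))
    sd2 = float(np.sqrt(max(2.0 * var_rr - var_d / 2.0, 0.0)))
    return sd1, sd2


# ---------------------------------------------------------------- embedding

def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.ones(max_lag + 1)
    return np.array([
        (x[: x.size - k] @ x[k:]) / denom for k in range(max_lag + 1)
    ])


def _ami(x: np.ndarray, max_lag: int, n_bins: int = 16) -> np.ndarray:
    """Average mutual information (nats) via equal-width histograms."""
    edges = np.linspace(x.min(), x.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        a = idx[: idx.size - k] if k else idx
        b = idx[k:] if k else idx
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        pa = joint.sum(axis=1, keepdims=True)
        pb = joint.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = joint * np.log(joint / (pa * pb))
        out[k] = np.nansum(term)
    return out


def _first_local_minimum(y: np.ndarray) -> int | None:
    for k in range(1, y.size - 1):
        if y[k] < y[k - 1] and y[k] <= y[k + 1]:
            return k
    return None


def _first_below(y: np.ndarray, level: float) -> int | None:
    below = np.nonzero(y <= level)[0]
    below = below[below > 0]
    return int(below[0]) if below.size else None


def estimate_time_lag(
    series: BeatSeries, params: EmbeddingParams | None = None
) -> tuple[int, str]:
    """Select the embedding time lag by a five-strategy cascade.

    Returns ``(lag, strategy)`` where strategy names which rule fired:
    ``acf_min``, ``acf_1e``, ``ami_min``, ``ami_1e`` or ``fallback``.
    """
    params = params or EmbeddingParams()
    rr = series.rr
    max_lag = min(params.max_lag_search, rr.size // 2 - 1)
    if rr.size < 10 * params.max_lag_search:
        warnings.warn("series is short for lag estimation; result may be noisy")
    if max_lag < 2:
        return params.fallback_lag, "fallback"

    acf = _acf(rr, max_lag)
    k = _first_local_minimum(acf)
    if k is not None:
        return max(k, 1), "acf_min"
    k = _first_below(acf, acf[0] / np.e)
    if k is not None:
        return max(k, 1), "acf_1e"
    ami = _ami(rr, max_lag)
    k = _first_local_minimum(ami)
    if k is not None:
        return max(k, 1), "ami_min"
    k = _first_below(ami, ami[0] / np.e)
    if k is not None:
        return max(k, 1), "ami_1e"
    return params.fallback_lag, "fallback"


def _maxnorm_dist(block: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Pairwise max-norm distances, built dimension by dimension to
    avoid a (chunk, n, m) intermediate."""
    d = np.abs(block[:, None, 0] - points[None, :, 0])
    for k in range(1, points.shape[1]):
        np.maximum(d, np.abs(block[:, None, k] - points[None, :, k]), out=d)
    return d


def _embed(x: np.ndarray, m: int, lag: int) -> np.ndarray:
    n = x.size - (m - 1) * lag
    if n < 2:
        raise ValueError("series too short for this embedding")
    return np.column_stack([x[k * lag: k * lag + n] for k in range(m)])


def _chunked_nn(points: np.ndarray, refs: np.ndarray, ref_idx: np.ndarray,
                theiler: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Max-norm nearest neighbour of each reference among all points.

    Self-matches (and, if ``theiler`` > 0, temporal neighbours) are
    excluded.  Returns (neighbour indices, distances).
    """
    n = points.shape[0]
    nn_idx = np.empty(ref_idx.size, dtype=int)
    nn_dist = np.empty(ref_idx.size)
    chunk = max(1, int(2e6 // max(n, 1)))
    all_idx = np.arange(n)
    for s in range(0, ref_idx.size, chunk):
        r = refs[s: s + chunk]
        d = _maxnorm_dist(r, points)
        ii = ref_idx[s: s + chunk]
        mask = np.abs(all_idx[None, :] - ii[:, None]) <= theiler
        d[mask] = np.inf
        nn_idx[s: s + chunk] = np.argmin(d, axis=1)
        nn_dist[s: s + chunk] = d[np.arange(d.shape[0]), nn_idx[s: s + chunk]]
    return nn_idx, nn_dist


def estimate_embedding_dim(
    series: BeatSeries, lag: int, params: EmbeddingParams | None = None
) -> int:
    """Cao's method: smallest d whose E1(d) = E(d+1)/E(d) stays above
    ``cao_threshold`` for all larger tested d; at least 2.

    If no dimension qualifies up to ``cao_max_dim`` the maximum is
    returned with a warning (the signature of a stochastic series).
    """
    params = params or EmbeddingParams()
    rr = series.rr.astype(float)
    max_dim = params.cao_max_dim
    need = (max_dim + 1) * lag + 2
    if rr.size < need:
        max_dim = max(3, (rr.size - 2) // lag)

    rng = np.random.default_rng(params.seed)
    E = np.full(max_dim + 1, np.nan)
    for d in range(1, max_dim + 1):
        emb_d = _embed(rr, d, lag)
        emb_d1 = _embed(rr, d + 1, lag)
        n = emb_d1.shape[0]  # points valid in both embeddings
        pts = emb_d[:n]
        if n > params.cao_max_points:
            ref_idx = np.sort(rng.choice(n, params.cao_max_points, replace=False))
        else:
            ref_idx = np.arange(n)
        nn_idx, nn_dist = _chunked_nn(pts, pts[ref_idx], ref_idx)
        valid = nn_dist > 0
        if not valid.any():
            break
        num = np.abs(emb_d1[ref_idx[valid]] - emb_d1[nn_idx[valid]]).max(axis=1)
        E[d] = float(np.mean(num / nn_dist[valid]))

    with np.errstate(invalid="ignore", divide="ignore"):
        E1 = E[2:] / E[1:-1]  # E1[d-1] = E(d+1)/E(d), d = 1..max_dim-1
    qualified = None
    for d in range(1, max_dim):
        tail = E1[d - 1:]
        tail = tail[np.isfinite(tail)]
        if tail.size and np.all(tail >= params.cao_threshold):
            qualified = d
            break
    if qualified is None:
        warnings.warn(
            "Cao's E1 never saturates; returning cao_max_dim "
            "(series behaves stochastically)"
        )
        return max_dim
    return max(qualified, 2)


# ------------------------------------------------------- correlation sums

def _pairwise_sample_distances(
    emb: np.ndarray, rng: np.random.Generator, n_pairs: int = 20000
) -> np.ndarray:
    n = emb.shape[0]
    i = rng.integers(0, n, n_pairs)
    j = rng.integers(0, n, n_pairs)
    keep = i != j
    d = np.abs(emb[i[keep]] - emb[j[keep]]).max(axis=1)
    return d[d > 0]


def _count_pairs_below(
    x: np.ndarray, m: int, lag: int, theiler: int, radii: np.ndarray
) -> tuple[np.ndarray, int]:
    """For each radius, count embedded pairs (j - i > theiler) with
    max-norm distance strictly below it.  Chunked O(N^2) scan."""
    emb = _embed(x, m, lag)
    n = emb.shape[0]
    counts = np.zeros(radii.size, dtype=np.int64)
    hist_edges = np.concatenate([[0.0], radii])
    n_pairs = 0
    chunk = max(1, int(8e6 // max(n, 1)))
    for s in range(0, n, chunk):
        block = emb[s: s + chunk]
        d = _maxnorm_dist(block, emb)
        ii = np.arange(s, s + block.shape[0])
        jj = np.arange(n)
        vals = d[(jj[None, :] - ii[:, None]) > theiler]
        n_pairs += vals.size
        # vals in [0, r_k) are strictly below radius k
        h, _ = np.histogram(vals, bins=hist_edges)
        counts += np.cumsum(h)
    return counts, n_pairs


def correlation_sum_curve(
    series: BeatSeries, params: EmbeddingParams
) -> CorrelationSumCurve:
    """Correlation sums over a shared log-spaced radius grid.

    C(m, r) is the Theiler-corrected fraction of embedded point pairs
    closer than r in the max norm, for m in {m0, m0+1, m0+2}.  The grid
    spans the 1st percentile to the maximum of a subsampled pairwise
    distance set at the largest embedding dimension.
    """
    if params.lag is None or params.m0 is None:
        raise ValueError("lag and m0 must be set before computing correlation sums")
    x = series.rr.astype(float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate series: all points identical")
    rng = np.random.default_rng(params.seed + 1)
    m_hi = params.m_range[-1]
    emb_hi = _embed(x, m_hi, params.lag)
    if emb_hi.shape[0] < 500:
        warnings.warn("fewer than 500 embedded points; correlation sums are noisy")
    samp = _pairwise_sample_distances(emb_hi, rng)
    if samp.size == 0:
        raise ValueError("degenerate series: all sampled distances zero")
    r_hi = samp.max() * 1.05
    # floor the grid at a small fraction of the attractor diameter so a
    # near-repeating series (clusters of numerically identical points)
    # cannot drive the radii below measurement resolution
    r_lo = max(np.percentile(samp, 1.0), 1e-4 * r_hi, 1e-12)
    radii = np.geomspace(r_lo, r_hi, params.n_radii)

    C: dict[int, np.ndarray] = {}
    for m in params.m_range:
        counts, n_pairs = _count_pairs_below(x, m, params.lag, params.theiler, radii)
        if n_pairs == 0:
            raise ValueError("no valid pairs beyond the Theiler window")
        C[m] = counts / n_pairs
    return CorrelationSumCurve(radii=radii, C=C)


def extend_curve_down(
    series: BeatSeries, params: EmbeddingParams, curve: CorrelationSumCurve,
    factor: float = 10.0,
) -> CorrelationSumCurve:
    """Extend the radius grid one decade downward (for r_small searches)."""
    radii = np.geomspace(curve.radii[0] / factor, curve.radii[0], 20, endpoint=False)
    x = series.rr.astype(float)
    C: dict[int, np.ndarray] = {}
    for m in curve.m_values:
        counts, n_pairs = _count_pairs_below(x, m, params.lag, params.theiler, radii)
        C[m] = np.concatenate([counts / n_pairs, curve.C[m]])
    return CorrelationSumCurve(radii=np.concatenate([radii, curve.radii]), C=C)


# ------------------------------------------------------- scaling region

def detect_scaling_region(
    curve: CorrelationSumCurve,
    m: int | None = None,
    n_segments: int = 4,
    seed: int = 0,
) -> ScalingRegion:
    """Find the scaling region of one exponent curve.

    Fits a continuous piecewise-linear model with ``n_segments`` segments
    to local exponent vs log radius and returns the segment with the
    flattest fitted slope, whose mean observed exponent estimates the
    correlation dimension.
    """
    if m is None:
        m = curve.m_values[0]
    exp = curve.local_exponent[m]
    log_r = np.log(curve.radii)
    valid = np.isfinite(exp)
    if valid.sum() < 8 * n_segments:
        raise ValueError("too few finite exponent points for region detection")
    xv, yv = log_r[valid], exp[valid]
    fit = fit_piecewise_linear(xv, yv, n_segments=n_segments, seed=seed)
    j = int(np.argmin(np.abs(fit.slopes)))
    lo, hi = fit.segment_bounds(j)
    inside = (xv >= lo) & (xv <= hi)
    if inside.sum() == 0:
        raise ValueError("empty scaling segment")
    plateau = float(np.mean(yv[inside]))
    resid = float(np.mean((yv[inside] - fit.predict(xv[inside])) ** 2))
    return ScalingRegion(log_r_lo=lo, log_r_hi=hi, plateau_value=plateau,
                         fit_residual=resid)


def correlation_dimension(
    curve: CorrelationSumCurve,
    regions: dict[int, ScalingRegion],
) -> float:
    """Average the per-dimension plateau estimates; NaN when none exist."""
    vals = [regions[m].plateau_value for m in curve.m_values if m in regions]
    if not vals:
        warnings.warn("no scaling-region estimate available; correlation dimension NA")
        return np.nan
    return float(np.mean(vals))


def sample_entropy(
    curve: CorrelationSumCurve,
    regions: dict[int, ScalingRegion],
) -> float:
    """Sample entropy from correlation-sum ratios inside the scaling region.

    sampEn(m, r) = ln C(m, r) - ln C(m+1, r), averaged over the radii of
    the lower dimension's scaling region and over consecutive embedding
    dimension pairs.  NaN when every ratio is degenerate.
    """
    log_r = np.log(curve.radii)
    ms = curve.m_values
    estimates = []
    for m_lo, m_hi in zip(ms[:-1], ms[1:]):
        if m_lo not in regions:
            continue
        reg = regions[m_lo]
        mask = (log_r >= reg.log_r_lo) & (log_r <= reg.log_r_hi)
        c_lo, c_hi = curve.C[m_lo][mask], curve.C[m_hi][mask]
        ok = (c_lo > 0) & (c_hi > 0)
        if not ok.any():
            continue
        estimates.append(float(np.mean(np.log(c_lo[ok]) - np.log(c_hi[ok]))))
    if not estimates:
        warnings.warn("sample entropy degenerate in the scaling region; NA")
        return np.nan
    return float(np.mean(estimates))


def solve_small_radius(curve: CorrelationSumCurve, target: float = 1e-3) -> float:
    """Radius where the dimension-averaged correlation sum equals ``target``.

    Interpolated log-log between bracketing grid points; if the curve
    floor sits above the target the smallest radius is returned with a
    warning (callers may first extend the grid downward once).
    """
    cbar = curve.mean_C()
    r = curve.radii
    pos = cbar > 0
    if not pos.any() or cbar[pos].min() > target:
        warnings.warn("correlation-sum floor above target; using smallest radius")
        return float(r[0])
    above = np.nonzero(pos & (cbar >= target))[0]
    k_hi = int(above[0])
    if cbar[k_hi] == target or k_hi == 0:
        return float(r[k_hi])
    k_lo = k_hi - 1
    while k_lo >= 0 and cbar[k_lo] <= 0:
        k_lo -= 1
    if k_lo < 0:
        return float(r[k_hi])
    lr = np.log(r)
    lc = np.log(cbar)
    t = (np.log(target) - lc[k_lo]) / (lc[k_hi] - lc[k_lo])
    return float(np.exp(lr[k_lo] + t * (lr[k_hi] - lr[k_lo])))


# ------------------------------------------------------------- Lyapunov

def kantz_divergence(
    series: BeatSeries, params: EmbeddingParams, r_small: float
) -> np.ndarray:
    """Kantz divergence curve S(k), k = 0..lyap_max_horizon.

    S(k) = mean over reference points of the log mean max-norm distance
    at horizon k between the reference trajectory and its r_small
    neighbours (Theiler-excluded).  Raises if fewer than 10% of the
    reference points have neighbours.
    """
    x = series.rr.astype(float)
    m, lag = params.m0, params.lag
    emb = _embed(x, m, lag)
    n = emb.shape[0]
    horizon = params.lyap_max_horizon
    n_use = n - horizon
    if n_use < 50:
        raise ValueError("series too short for the divergence horizon")
    rng = np.random.default_rng(params.seed + 2)
    if n_use > params.lyap_max_refs:
        refs = np.sort(rng.choice(n_use, params.lyap_max_refs, replace=False))
    else:
        refs = np.arange(n_use)

    idx_all = np.arange(n_use)
    sums = np.zeros(horizon + 1)
    counts = np.zeros(horizon + 1)
    n_with_neighbors = 0
    chunk = max(1, int(2e6 // max(n_use, 1)))
    for s in range(0, refs.size, chunk):
        block = refs[s: s + chunk]
        d0 = _maxnorm_dist(emb[block], emb[idx_all])
        excl = np.abs(idx_all[None, :] - block[:, None]) <= params.theiler
        d0[excl] = np.inf
        for bi, i in enumerate(block):
            nbrs = idx_all[d0[bi] < r_small]
            if nbrs.size == 0:
                continue
            n_with_neighbors += 1
            for k in range(horizon + 1):
                dk = np.abs(emb[i + k] - emb[nbrs + k]).max(axis=1)
                # floor exact recurrences so perfectly periodic
                # trajectories give a flat (slope ~0) curve, not -inf
                mean_d = max(dk.mean(), 1e-6 * r_small)
                sums[k] += np.log(mean_d)
                counts[k] += 1
    if n_with_neighbors < 0.1 * refs.size:
        raise ValueError(
            f"only {n_with_neighbors}/{refs.size} reference points have "
            f"neighbours within r_small={r_small:.4g}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def max_lyapunov(
    series: BeatSeries, params: EmbeddingParams, r_small: float
) -> float:
    """Maximal Lyapunov exponent per beat from the Kantz curve.

    A 2-segment piecewise line (growth then saturation) is fitted to
    S(k); the exponent is the slope of the first segment.  NaN on any
    failure (too few neighbours, non-convergence).
    """
    try:
        s_curve = kantz_divergence(series, params, r_small)
        k = np.arange(s_curve.size, dtype=float)
        ok = np.isfinite(s_curve)
        if ok.sum() < 8:
            raise ValueError("divergence curve mostly undefined")
        fit = fit_piecewise_linear(k[ok], s_curve[ok], n_segments=2,
                                   seed=params.seed)
        return float(fit.slopes[0])
    except (ValueError, RuntimeError) as err:
        warnings.warn(f"Lyapunov estimation failed: {err}; NA")
        return np.nan


# ------------------------------------------------------------------ RQA

def _line_histogram(lengths: list[int]) -> np.ndarray:
    if not lengths:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(max(lengths) + 1, dtype=np.int64)
    for l in lengths:
        out[l] += 1
    return out


def _runs(mask: np.ndarray) -> list[int]:
    """Lengths of runs of True in a boolean vector."""
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    flips = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(flips[1::2] - flips[0::2])


def rqa_indices(
    series: BeatSeries,
    params: EmbeddingParams,
    r_small: float,
    lmin: int = 2,
    vmin: int = 2,
) -> dict[str, float]:
    """Recurrence quantification at radius ``r_small``.

    The recurrence matrix is R_ij = [max-norm distance < r_small] on the
    (lag, m0) embedding.  Diagonal structures quantify determinism,
    vertical structures laminarity; divisions by zero (e.g. a plot with
    no recurrences) yield NaN for the affected fields.
    """
    x = series.rr.astype(float)
    emb = _embed(x, params.m0, params.lag)
    n = emb.shape[0]
    if n < 100:
        raise ValueError("need at least 100 embedded points for RQA")

    # ---- diagonal scan (offset k > 0; symmetric matrix)
    diag_lengths: list[int] = []
    rec_pairs = 0
    offsets = np.arange(1, n)
    diag_rate = np.full(n - 1, np.nan)
    for k in offsets:
        d = np.abs(emb[: n - k] - emb[k:]).max(axis=1)
        hits = d < r_small
        nh = int(hits.sum())
        rec_pairs += nh
        diag_rate[k - 1] = nh / (n - k)
        diag_lengths.extend(_runs(hits))

    total_offdiag = n * (n - 1)  # ordered pairs
    rec = 100.0 * (2 * rec_pairs) / total_offdiag

    na = float("nan")
    out: dict[str, float] = dict.fromkeys(RQA_INDEX_NAMES, na)
    out["REC"] = float(rec)

    hist = _line_histogram(diag_lengths)
    lengths = np.arange(hist.size)
    denom_all = float((lengths * hist).sum())
    num_det = float((lengths[lmin:] * hist[lmin:]).sum()) if hist.size > lmin else 0.0
    if denom_all > 0:
        out["DET"] = 100.0 * num_det / denom_all
    n_lines = int(hist[lmin:].sum()) if hist.size > lmin else 0
    if n_lines > 0:
        out["Lmean"] = (num_det + n) / (n_lines + 1)      # with line of identity
        out["LmeanWithoutMain"] = num_det / n_lines
        lmax = int(np.max(np.nonzero(hist)[0]))
        out["Lmax"] = float(lmax)
        out["DIV"] = 1.0 / lmax
        p = hist[lmin:][hist[lmin:] > 0].astype(float)
        p /= p.sum()
        out["ENTR"] = float(-(p * np.log(p)).sum())
    if out["REC"] > 0 and np.isfinite(out["DET"]):
        out["RATIO"] = out["DET"] / out["REC"]

    # TREND: slope of diagonal-wise recurrence rate (%) vs offset,
    # over offsets up to 90% of N
    k_max = int(0.9 * n)
    kk = offsets[:k_max].astype(float)
    rr_rate = 100.0 * diag_rate[:k_max]
    if kk.size >= 2 and np.isfinite(rr_rate).all():
        out["TREND"] = float(np.polyfit(kk, rr_rate, 1)[0])

    # ---- vertical scan (columns, main diagonal excluded)
    vert_lengths: list[int] = []
    chunk = max(1, int(4e6 // max(n, 1)))
    for s in range(0, n, chunk):
        block = emb[s: s + chunk]
        hits = _maxnorm_dist(block, emb) < r_small
        cols = np.arange(s, s + block.shape[0])
        hits[np.arange(block.shape[0]), cols] = False
        for row in hits:
            vert_lengths.extend(_runs(row))
    vhist = _line_histogram(vert_lengths)
    vlen = np.arange(vhist.size)
    vdenom = float((vlen * vhist).sum())
    vnum = float((vlen[vmin:] * vhist[vmin:]).sum()) if vhist.size > vmin else 0.0
    if vdenom > 0:
        out["LAM"] = 100.0 * vnum / vdenom
    nv = int(vhist[vmin:].sum()) if vhist.size > vmin else 0
    if nv > 0:
        out["Vmean"] = vnum / nv
        out["Vmax"] = float(np.max(np.nonzero(vhist)[0]))
    return out


# ------------------------------------------------------------ full suite

def compute_nonlinear_indices(
    series: BeatSeries,
    params: EmbeddingParams | None = None,
    do_rqa: bool = True,
    log: list | None = None,
) -> NonlinearIndices:
    """Run the full non-linear chain; failures produce NaN, never raise.

    ``log`` (a list, appended in place) collects warning strings so the
    orchestrator can attach them to the run log.
    """
    params = params or EmbeddingParams()
    notes = log if log is not None else []
    na = float("nan")
    values: dict[str, float] = dict.fromkeys(NONLINEAR_INDEX_NAMES, na)

    def record(stage: str, err: Exception) -> None:
        notes.append(f"{stage}: {err}")

    try:
        values["SD1"], values["SD2"] = poincare_indices(series)
    except ValueError as err:
        record("poincare", err)

    curve = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if params.lag is None:
                lag, _strategy = estimate_time_lag(series, params)
                params = replace(params, lag=lag)
            if params.theiler < params.lag:
                params = replace(params, theiler=params.lag)
            if params.m0 is None:
                m0 = estimate_embedding_dim(series, params.lag, params)
                params = replace(params, m0=m0)
            curve = correlation_sum_curve(series, params)
        except (ValueError, RuntimeError) as err:
            record("embedding", err)

    if curve is not None:
        regions: dict[int, ScalingRegion] = {}
        for m in curve.m_values:
            try:
                regions[m] = detect_scaling_region(curve, m=m, seed=params.seed)
            except (ValueError, RuntimeError) as err:
                record(f"scaling_region[m={m}]", err)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values["CorrelationDim"] = correlation_dimension(curve, regions)
            values["SampleEntropy"] = sample_entropy(curve, regions)

        try:
            cbar = curve.mean_C()
            floor = cbar[cbar > 0].min() if (cbar > 0).any() else np.inf
            if floor > 1e-3:
                curve_ext = extend_curve_down(series, params, curve)
                cbar_ext = curve_ext.mean_C()
                pos = cbar_ext > 0
                if pos.any() and cbar_ext[pos].min() <= 1e-3:
                    r_small = solve_small_radius(curve_ext)
                else:
                    # the jump at r -> 0 sits above the target (clustered
                    # attractor); keep the original grid's smallest radius
                    notes.append("r_small: correlation-sum floor above 1e-3 "
                                 "after extension; using smallest radius")
                    r_small = float(curve.radii[0])
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r_small = solve_small_radius(curve)
        except (ValueError, RuntimeError) as err:
            record("r_small", err)
            r_small = None

        if r_small is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values["MaxLyapunov"] = max_lyapunov(series, params, r_small)
            if do_rqa:
                try:
                    values.update(rqa_indices(series, params, r_small))
                except (ValueError, RuntimeError) as err:
                    record("rqa", err)

    return NonlinearIndices(**values)
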