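"""Non-linear indices: Poincaré, embedding, correlation sums, scaling
regions, entropy, Lyapunov and RQA, with brute-force oracles."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from easyhrv import BeatSeries, EmbeddingParams, poincare_indices
from easyhrv.nonlinear import (
    CorrelationSumCurve,
    _embed,
    compute_nonlinear_indices,
    correlation_sum_curve,
    detect_scaling_region,
    estimate_embedding_dim,
    estimate_time_lag,
    max_lyapunov,
    rqa_indices,
    sample_entropy,
    solve_small_radius,
)
from easyhrv.synthetic import SyntheticSpec, gen_rr


def series_from_rr(rr):
    return BeatSeries.from_rr(np.asarray(rr, dtype=float))


# ------------------------------------------------------------- oracles

def brute_correlation_sum(x, m, lag, theiler, radii):
    """O(N^2) double loop over embedded pairs."""
    emb = _embed(np.asarray(x, float), m, lag)
    n = emb.shape[0]
    counts = np.zeros(radii.size)
    n_pairs = 0
    for i in range(n):
        for j in range(i + theiler + 1, n):
            d = np.max(np.abs(emb[i] - emb[j]))
            n_pairs += 1
            counts += d < radii
    return counts / n_pairs


def brute_recurrence(x, m, lag, radius):
    emb = _embed(np.asarray(x, float), m, lag)
    n = emb.shape[0]
    R = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j:
                R[i, j] = np.max(np.abs(emb[i] - emb[j])) < radius
    return R


def brute_det(R, lmin=2):
    n = R.shape[0]
    num = den = 0
    for k in range(1, n):
        diag = np.diagonal(R, offset=k)
        run = 0
        for v in np.append(diag, False):
            if v:
                run += 1
            else:
                if run:
                    den += run
                    if run >= lmin:
                        num += run
                run = 0
    return 100.0 * num / den if den else np.nan


# ------------------------------------------------------------ Poincaré

class TestPoincare:
    def test_constant_series(self):
        sd1, sd2 = poincare_indices(series_from_rr(np.full(100, 800.0)))
        assert sd1 == 0.0 and sd2 == 0.0

    def test_sd1_equals_sdsd_over_sqrt2(self, rng):
        for _ in range(20):
            rr = rng.uniform(600, 1100, 500)
            sd1, _ = poincare_indices(series_from_rr(rr))
            pop_sdsd = np.std(np.diff(rr))  # population variance
            assert sd1 == pytest.approx(pop_sdsd / np.sqrt(2), abs=1e-12)

    def test_white_noise_isotropy(self, rng):
        rr = rng.normal(800, 30, 10_000)
        sd1, sd2 = poincare_indices(series_from_rr(rr))
        assert sd1 == pytest.approx(sd2, rel=0.05)

    def test_too_short(self):
        with pytest.raises(ValueError):
            poincare_indices(series_from_rr([800.0, 810.0]))


# ------------------------------------------------------------- time lag

class TestTimeLag:
    def test_iid_noise_small_lag(self, rng):
        rr = rng.normal(800, 30, 2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lag, strategy = estimate_time_lag(series_from_rr(rr))
        assert lag <= 3
        assert strategy in ("acf_min", "acf_1e")

    def test_sinusoid_first_acf_minimum_at_half_period(self):
        rr = 800 + 50 * np.sin(2 * np.pi * np.arange(2000) / 40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lag, strategy = estimate_time_lag(series_from_rr(rr))
        assert strategy == "acf_min"
        assert abs(lag - 20) <= 2

    def test_drifting_series_falls_back_to_30(self):
        # strong monotone drift: ACF decays slowly, AMI has no minimum
        rr = 700.0 + np.linspace(0, 400, 3000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lag, strategy = estimate_time_lag(series_from_rr(rr))
        if strategy == "fallback":
            assert lag == 30
        else:
            # the cascade may legitimately stop at an AMI criterion
            assert strategy.startswith("ami")


# ---------------------------------------------------------- Cao method

class TestCao:
    def test_henon_low_dimension(self, henon_series):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lag, _ = estimate_time_lag(henon_series)
            m0 = estimate_embedding_dim(henon_series, lag)
        assert m0 in (2, 3)

    def test_noise_needs_high_dimension(self, rng):
        rr = rng.normal(800, 30, 3000)
        params = EmbeddingParams()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m0 = estimate_embedding_dim(series_from_rr(rr), lag=1, params=params)
        assert m0 >= params.cao_max_dim / 2

    def test_deterministic_structure_needs_fewer_dimensions_than_noise(
            self, henon_series, rng):
        """Cao's estimate separates low-dimensional dynamics from noise."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m_henon = estimate_embedding_dim(henon_series, lag=1)
            rr = rng.normal(800, 30, 3000)
            m_noise = estimate_embedding_dim(series_from_rr(rr), lag=1)
        assert m_henon <= 3 < m_noise


# ----------------------------------------------------- correlation sums

@pytest.fixture(scope="module")
def small_curve(henon_series):
    rr = henon_series.rr[:203]
    params = EmbeddingParams(lag=1, m0=2, theiler=5, n_radii=40)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return series_from_rr(rr), params, correlation_sum_curve(
            series_from_rr(rr), params)


class TestCorrelationSum:

    def test_matches_brute_force_exactly(self, small_curve):
        series, params, curve = small_curve
        for m in curve.m_values:
            oracle = brute_correlation_sum(series.rr, m, params.lag,
                                           params.theiler, curve.radii)
            np.testing.assert_array_equal(curve.C[m], oracle)

    def test_saturation_and_floor(self, small_curve):
        series, params, curve = small_curve
        assert curve.C[2][-1] == 1.0  # radius above max pairwise distance
        big = np.array([1e9])
        np.testing.assert_array_equal(
            brute_correlation_sum(series.rr, 2, 1, 5, big), [1.0])
        tiny = np.array([1e-15])
        np.testing.assert_array_equal(
            brute_correlation_sum(series.rr, 2, 1, 5, tiny), [0.0])

    def test_monotone_in_radius_and_dimension(self, small_curve):
        _, _, curve = small_curve
        for m in curve.m_values:
            assert np.all(np.diff(curve.C[m]) >= 0)
        m_lo, m_mid, m_hi = curve.m_values
        # higher embedding dimension cannot raise the correlation sum
        assert np.all(curve.C[m_hi] <= curve.C[m_lo] + 1e-12)

    def test_degenerate_series_errors(self):
        params = EmbeddingParams(lag=1, m0=2, theiler=2)
        with pytest.raises(ValueError, match="degenerate"):
            correlation_sum_curve(series_from_rr(np.full(300, 800.0)), params)


# ------------------------------------------------------- scaling region

class TestScalingRegion:
    @staticmethod
    def synthetic_curve(plateau=1.2):
        """Exponent curve made of 4 exact segments with one flat plateau."""
        radii = np.geomspace(0.1, 100.0, 100)
        lr = np.log(radii)
        knots = np.log([0.7, 2.0, 15.0])
        y = np.empty_like(lr)
        seg0 = lr < knots[0]
        seg1 = (lr >= knots[0]) & (lr < knots[1])
        seg2 = (lr >= knots[1]) & (lr < knots[2])
        seg3 = lr >= knots[2]
        y[seg1] = 3.0 - (3.0 - plateau) * (lr[seg1] - knots[0]) / (knots[1] - knots[0])
        y[seg0] = 3.0 + 1.5 * (lr[seg0] - knots[0])
        y[seg2] = plateau
        y[seg3] = plateau - 0.8 * (lr[seg3] - knots[2])
        # integrate the exponent curve into a consistent log C curve
        log_c = np.concatenate([[-12.0], -12.0 + np.cumsum(
            0.5 * (y[1:] + y[:-1]) * np.diff(lr))])
        curve = CorrelationSumCurve(radii=radii, C={2: np.exp(log_c)})
        return curve, plateau

    def test_recovers_constructed_plateau(self):
        curve, plateau = self.synthetic_curve(1.2)
        region = detect_scaling_region(curve, m=2, seed=0)
        assert region.plateau_value == pytest.approx(plateau, abs=0.05)
        # breakpoints near log 2 and log 15 (within a grid step ~0.07)
        assert region.log_r_lo == pytest.approx(np.log(2.0), abs=0.15)
        assert region.log_r_hi == pytest.approx(np.log(15.0), abs=0.15)

    def test_zero_plateau(self):
        radii = np.geomspace(0.1, 10.0, 100)
        curve = CorrelationSumCurve(radii=radii, C={2: np.full(100, 0.5)})
        region = detect_scaling_region(curve, m=2, seed=0)
        assert region.plateau_value == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points(self):
        radii = np.geomspace(0.1, 10.0, 10)
        curve = CorrelationSumCurve(radii=radii, C={2: np.linspace(0.01, 1, 10)})
        with pytest.raises(ValueError):
            detect_scaling_region(curve, m=2)


# ------------------------------------------------- r_small and entropy

class TestSmallRadius:
    def test_closed_form_cubic(self):
        radii = np.geomspace(0.01, 10.0, 200)
        curve = CorrelationSumCurve(radii=radii, C={3: (radii / 10.0) ** 3})
        # (r/10)^3 = 1e-3  =>  r = 1
        assert solve_small_radius(curve) == pytest.approx(1.0, rel=1e-3)

    def test_bracketing_interpolation(self):
        radii = np.array([0.5, 2.0])
        curve = CorrelationSumCurve(radii=radii, C={2: np.array([1e-4, 1e-2])})
        r = solve_small_radius(curve)
        assert 0.5 < r < 2.0

    def test_floor_above_target_warns(self):
        radii = np.geomspace(0.1, 10.0, 50)
        curve = CorrelationSumCurve(radii=radii, C={2: np.linspace(0.01, 1, 50)})
        with pytest.warns(UserWarning, match="floor"):
            assert solve_small_radius(curve) == pytest.approx(0.1)


class TestSampleEntropy:
    def test_periodic_near_zero(self, periodic_nonlinear):
        assert abs(periodic_nonlinear.SampleEntropy) <= 0.15

    def test_noise_exceeds_periodic(self, rng, periodic_nonlinear):
        rr = rng.normal(800, 30, 3000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nl = compute_nonlinear_indices(series_from_rr(rr), do_rqa=False)
        assert nl.SampleEntropy > abs(periodic_nonlinear.SampleEntropy)

    def test_scale_invariance(self, henon_series):
        """sampEn is a ratio of correlation sums: scaling RR and radii
        together leaves it unchanged."""
        params = EmbeddingParams(lag=1, m0=2, theiler=20)
        rr = henon_series.rr[:1500]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = correlation_sum_curve(series_from_rr(rr), params)
            c2 = correlation_sum_curve(series_from_rr(rr * 2.0), params)
            regions1 = {m: detect_scaling_region(c1, m=m, seed=0) for m in c1.m_values}
            # same regions shifted by log 2
            regions2 = {m: detect_scaling_region(c2, m=m, seed=0) for m in c2.m_values}
            s1 = sample_entropy(c1, regions1)
            s2 = sample_entropy(c2, regions2)
        assert s1 == pytest.approx(s2, abs=0.05)


# ------------------------------------------------------------ Lyapunov

class TestLyapunov:
    def test_henon_positive_exponent(self, henon_nonlinear):
        # literature value ~0.42/iteration
        assert henon_nonlinear.MaxLyapunov > 0.2

    def test_periodic_no_divergence(self, periodic_nonlinear):
        assert periodic_nonlinear.MaxLyapunov <= 0.05

    def test_no_neighbors_gives_na(self, rng):
        rr = rng.normal(800, 30, 500)
        params = EmbeddingParams(lag=1, m0=3, theiler=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = max_lyapunov(series_from_rr(rr), params, r_small=1e-9)
        assert np.isnan(val)


# ----------------------------------------------------------------- RQA

class TestRQA:
    def test_rec_matches_brute_force_density(self, henon_series):
        rr = henon_series.rr[:304]
        params = EmbeddingParams(lag=1, m0=2, theiler=5)
        radius = 20.0
        out = rqa_indices(series_from_rr(rr), params, radius)
        R = brute_recurrence(rr, 2, 1, radius)
        n = R.shape[0]
        assert out["REC"] == pytest.approx(100.0 * R.sum() / (n * (n - 1)),
                                           abs=1e-12)

    def test_det_matches_brute_force(self, henon_series):
        rr = henon_series.rr[:304]
        params = EmbeddingParams(lag=1, m0=2, theiler=5)
        radius = 20.0
        out = rqa_indices(series_from_rr(rr), params, radius)
        R = brute_recurrence(rr, 2, 1, radius)
        assert out["DET"] == pytest.approx(brute_det(R), abs=1e-9)

    def test_periodic_structure(self, periodic_nonlinear):
        nl = periodic_nonlinear
        assert nl.DET >= 99.0
        assert nl.Lmax >= 1000  # diagonals persist across the recording

    def test_noise_low_determinism(self, rng):
        # lag >= 2 keeps embedding windows of diagonal-adjacent pairs
        # disjoint, so recurrences of i.i.d. noise are independent
        rr = rng.normal(800, 30, 320)
        params = EmbeddingParams(lag=3, m0=3, theiler=5)
        series = series_from_rr(rr)
        # pick a radius giving REC ~ 5%
        for radius in np.linspace(10, 120, 40):
            out = rqa_indices(series, params, float(radius))
            if 3.0 <= out["REC"] <= 8.0:
                break
        assert 3.0 <= out["REC"] <= 8.0
        assert out["DET"] < 50.0

    def test_no_recurrences_gives_na(self, rng):
        rr = rng.normal(800, 30, 300)
        params = EmbeddingParams(lag=1, m0=2, theiler=5)
        out = rqa_indices(series_from_rr(rr), params, r_small=1e-9)
        assert out["REC"] == 0.0
        assert np.isnan(out["DET"]) and np.isnan(out["Lmax"])

    def test_div_is_inverse_lmax(self, henon_nonlinear):
        assert henon_nonlinear.DIV == pytest.approx(1.0 / henon_nonlinear.Lmax)

    def test_ratio_identity(self, henon_nonlinear):
        assert henon_nonlinear.RATIO == pytest.approx(
            henon_nonlinear.DET / henon_nonlinear.REC)


# ------------------------------------------------------------ full run

class TestFullSuite:
    def test_henon_ground_truth(self, henon_nonlinear):
        assert 1.0 <= henon_nonlinear.CorrelationDim <= 1.4
        assert henon_nonlinear.MaxLyapunov > 0.2

    def test_noise_fills_embedding_space(self, rng):
        """i.i.d. noise fills the m=3 embedding space.

        For uniform noise of range a under the max norm, the exact local
        exponent is 3 r p'(r)/p(r) with p(r) = r(2a - r)/a^2, which drops
        below 3 at finite radii (cube edge effect); the detected plateau
        must match that closed form and stay far above any attractor
        dimension."""
        rr = rng.uniform(700, 900, 6000)
        params = EmbeddingParams(lag=1, m0=3, theiler=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = correlation_sum_curve(series_from_rr(rr), params)
            region = detect_scaling_region(curve, m=3, seed=0)
        a = 200.0
        r_mid = np.exp(0.5 * (region.log_r_lo + region.log_r_hi))
        expected = 3.0 * (2 * a - 2 * r_mid) / (2 * a - r_mid)
        assert region.plateau_value == pytest.approx(expected, abs=0.3)
        assert region.plateau_value > 2.0

    def test_quasi_periodic_limit_cycle_dimension(self):
        """Incommensurate period densely fills a closed curve: dim ~1."""
        rr = 800 + 30 * np.sin(2 * np.pi * np.arange(5000) / (40 * np.sqrt(2)))
        params = EmbeddingParams(lag=14, m0=2, theiler=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = correlation_sum_curve(series_from_rr(rr), params)
            region = detect_scaling_region(curve, m=2, seed=0)
        assert region.plateau_value == pytest.approx(1.0, abs=0.3)

    def test_dimension_estimates_stable_across_m(self, henon_series):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lag, _ = estimate_time_lag(henon_series)
            params = EmbeddingParams(lag=lag, m0=2, theiler=max(100, lag))
            curve = correlation_sum_curve(
                series_from_rr(henon_series.rr[:4000]), params)
            plateaus = [detect_scaling_region(curve, m=m, seed=0).plateau_value
                        for m in curve.m_values]
        assert np.ptp(plateaus) < 0.3

    def test_failures_become_na_not_exceptions(self):
        # far too short for the non-linear chain
        short = series_from_rr(np.array([800.0, 820.0, 790.0, 805.0]))
        log: list = []
        nl = compute_nonlinear_indices(short, log=log)
        assert np.isnan(nl.CorrelationDim)
        assert log  # failure was recorded

    def test_deterministic_under_seed(self, rng):
        rr = rng.normal(800, 40, 1200)
        series = series_from_rr(rr)
        params = EmbeddingParams(seed=77)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = compute_nonlinear_indices(series, params)
            b = compute_nonlinear_indices(series, params)
        for k, v in a.as_dict().items():
            v2 = b.as_dict()[k]
            assert (np.isnan(v) and np.isnan(v2)) or v == v2, k
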