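"""Core distribution: density, CDF, reliability, hazard, mode, median,
quantile, and the reduction to the classical Birnbaum-Saunders law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neutrobs import (
    NBSParams,
    NeutroPair,
    ncdf,
    nhazard,
    nmedian,
    nmode,
    npdf,
    nquantile,
    nreliability,
)

SQRT2PI = math.sqrt(2.0 * math.pi)


def classical(alpha, beta):
    """Independent classical oracle: scipy's fatigue-life distribution."""
    return stats.fatiguelife(alpha, scale=1.0 / beta)


class TestNeutroPair:
    def test_degenerate_collapses_to_scalar(self):
        p = NeutroPair.of(2.5)
        assert p.is_degenerate and float(p) == 2.5

    def test_ordered_rejects_reversed(self):
        with pytest.raises(ValueError, match="lower <= upper"):
            NeutroPair.ordered(2.0, 1.0)

    def test_non_degenerate_refuses_scalar_collapse(self):
        with pytest.raises(ValueError):
            float(NeutroPair(1.0, 2.0))


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": -1.0, "beta": 1.0},
        {"alpha": 1.0, "beta": 0.0},
        {"alpha": 1.0, "beta": 1.0, "indeterminacy": -0.1},
        {"alpha": 1.0, "beta": 1.0, "indeterminacy": NeutroPair(0.5, 0.2)},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NBSParams(**kwargs)

    def test_nonpositive_x_rejected(self):
        p = NBSParams(1.0, 1.0)
        for fn in (npdf, ncdf, nreliability, nhazard):
            with pytest.raises(ValueError, match="positive"):
                fn(-1.0, p)


class TestDensity:
    def test_unit_point_values(self):
        # at x = 1/beta the exponent vanishes and f = (1+I)/sqrt(2 pi)
        assert npdf(1.0, NBSParams(1, 1)).lower == pytest.approx(1 / SQRT2PI, abs=1e-12)
        got = npdf(1.0, NBSParams(1, 1, 0.5))
        assert got.lower == pytest.approx(1.5 / SQRT2PI, abs=1e-12)

    def test_total_mass_is_one_plus_I(self, quad, param_grid, indeterminacies):
        for a, b in param_grid:
            for i in indeterminacies:
                p = NBSParams(a, b, i)
                mass = quad(lambda x: npdf(x, p).lower, beta=b)
                assert mass == pytest.approx(1.0 + i, abs=1e-8)

    def test_mass_example(self, quad):
        p = NBSParams(1.25, 3.0, 0.2)
        assert quad(lambda x: npdf(x, p).lower, beta=3.0) == pytest.approx(1.2, abs=1e-8)

    def test_endpointwise_pair_evaluation(self):
        p = NBSParams(1.0, 1.0, NeutroPair(0.2, 0.5))
        got = npdf(1.0, p)
        assert got.lower == pytest.approx(1.2 / SQRT2PI)
        assert got.upper == pytest.approx(1.5 / SQRT2PI)


class TestCdf:
    def test_half_mass_at_reciprocal_rate(self):
        for a, b, i in [(1.0, 1.0, 0.0), (0.7, 2.5, 0.3), (2.0, 0.5, 0.8)]:
            got = ncdf(1.0 / b, NBSParams(a, b, i))
            assert got.lower == pytest.approx((1 + i) / 2, abs=1e-12)

    def test_upper_mass_limit(self):
        got = ncdf(1e6, NBSParams(1.0, 1.0, 0.2))
        assert got.lower == pytest.approx(1.2, abs=1e-9)

    def test_cdf_equals_integrated_pdf(self, quad):
        p = NBSParams(1.5, 2.0, 0.0)
        want = quad(lambda x: npdf(x, p).lower if x <= 2.0 else 0.0, beta=2.0)
        assert ncdf(2.0, p).lower == pytest.approx(want, abs=1e-8)

    def test_monotone_in_x_and_ordered_in_I(self):
        p = NBSParams(1.0, 2.0, NeutroPair(0.2, 0.5))
        xs = np.linspace(0.01, 10.0, 300)
        got = ncdf(xs, p)
        assert np.all(np.diff(got.lower) >= 0)
        assert np.all(got.lower <= got.upper)


class TestReliabilityHazard:
    def test_reliability_complement(self):
        p = NBSParams(1.0, 1.0, 0.2)
        assert nreliability(1.0, p).lower == pytest.approx(1.0 - 0.6, abs=1e-12)
        p0 = NBSParams(0.8, 1.5, 0.0)
        xs = np.linspace(0.05, 8, 50)
        r = nreliability(xs, p0).lower
        assert np.all((r >= 0) & (r <= 1))
        assert np.allclose(r, 1.0 - ncdf(xs, p0).lower)

    def test_reliability_negative_tail_under_indeterminacy(self):
        # ncdf tends to 1 + I, so the complement goes negative; reported as-is
        assert nreliability(1e5, NBSParams(1, 1, 0.5)).lower < 0

    def test_hazard_identity_with_density_ratio(self):
        p = NBSParams(1.0, 1.0)
        assert nhazard(1.0, p).lower == pytest.approx(2 / SQRT2PI, rel=1e-10)
        for a, b in [(0.5, 1.0), (1.5, 2.0)]:
            pp = NBSParams(a, b)
            xs = np.linspace(0.1, 10.0, 40)
            want = npdf(xs, pp).lower / (1.0 - ncdf(xs, pp).lower)
            assert np.allclose(nhazard(xs, pp).lower, want, rtol=1e-10)

    def test_hazard_indeterminacy_scaling(self):
        xs = np.array([0.3, 1.0, 4.0])
        base = nhazard(xs, NBSParams(1.1, 0.9)).lower
        got = nhazard(xs, NBSParams(1.1, 0.9, 0.2)).lower
        assert np.allclose(got, 1.2 * base, rtol=1e-12)

    def test_hazard_overflow_safe_far_in_tail(self):
        got = nhazard(1e4, NBSParams(0.5, 2.0)).lower
        assert np.isfinite(got) and got > 0


class TestMode:
    def test_worked_example(self):
        assert nmode(NBSParams(1.5, 2.0)) == pytest.approx(0.0794, abs=1e-4)

    def test_independent_of_indeterminacy(self):
        assert nmode(NBSParams(1.5, 2.0, 0.5)) == nmode(NBSParams(1.5, 2.0))

    @pytest.mark.parametrize("a,b", [(0.3, 1.0), (1.0, 2.0), (2.0, 0.5)])
    def test_matches_numeric_argmax(self, a, b):
        p = NBSParams(a, b)
        mode = nmode(p)
        # dense grid + golden-section refinement around the best grid point
        xs = np.linspace(mode / 50, mode * 50, 20001)
        fs = npdf(xs, p).lower
        k = int(np.argmax(fs))
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda x: -npdf(x, p).lower,
            bracket=(xs[max(k - 1, 0)], xs[k], xs[min(k + 1, xs.size - 1)]),
            method="golden", options={"xtol": 1e-10},
        )
        assert mode == pytest.approx(res.x, abs=1e-6)
        assert np.all(npdf(mode, p).lower >= fs)


class TestMedian:
    def test_worked_example(self):
        got = nmedian(NBSParams(1.5, 2.0, 0.2))
        assert got.lower == pytest.approx(0.3651, abs=1e-3)
        assert got.upper == pytest.approx(0.6846, abs=1e-3)

    def test_classical_double_root_at_reciprocal_rate(self):
        got = nmedian(NBSParams(0.7, 4.0, 0.0))
        assert got.lower == pytest.approx(0.25, abs=1e-12)
        assert got.upper == pytest.approx(0.25, abs=1e-12)

    def test_smaller_root_attains_half_mass(self):
        p = NBSParams(1.5, 2.0, 0.2)
        m = nmedian(p, strict=True)
        assert ncdf(float(m.lower), p).lower == pytest.approx(0.5, abs=1e-6)

    def test_paired_parameters_require_strict(self):
        p = NBSParams(1.5, 2.0, NeutroPair(0.2, 0.5))
        with pytest.raises(ValueError, match="strict"):
            nmedian(p)
        m = nmedian(p, strict=True)
        assert ncdf(float(m.lower), NBSParams(1.5, 2.0, 0.2)).lower == pytest.approx(0.5, abs=1e-6)
        assert ncdf(float(m.upper), NBSParams(1.5, 2.0, 0.5)).lower == pytest.approx(0.5, abs=1e-6)


class TestQuantile:
    def test_half_mass_point_is_reciprocal_rate(self):
        for i in (0.0, 0.2, 0.8):
            p = NBSParams(1.3, 2.0, i)
            assert nquantile((1 + i) / 2, p) == pytest.approx(0.5, abs=1e-12)

    def test_round_trip_through_cdf(self):
        p = NBSParams(1.0, 1.0, 0.2)
        for x in (0.2, 1.0, 5.0):
            assert nquantile(ncdf(x, p).lower, p) == pytest.approx(x, abs=1e-6)

    def test_classical_quantile_against_normal_transform(self):
        # closed-form oracle: s [(a z / 2) + sqrt((a z / 2)^2 + 1)]^2, s = 1/b
        a, b, prob = 0.5, 1.0, 0.975
        z = stats.norm.ppf(prob)
        want = (a * z / 2 + math.sqrt((a * z / 2) ** 2 + 1)) ** 2 / b
        assert nquantile(prob, NBSParams(a, b)) == pytest.approx(want, rel=1e-10)

    def test_out_of_range_p_rejected(self):
        p = NBSParams(1.0, 1.0, 0.2)
        for bad in (0.0, 1.2000001, -0.5):
            with pytest.raises(ValueError, match="attainable"):
                nquantile(bad, p)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p1=st.floats(0.01, 1.19), p2=st.floats(0.01, 1.19),
        a=st.floats(0.2, 2.5), b=st.floats(0.2, 4.0),
    )
    def test_monotone_in_p(self, p1, p2, a, b):
        params = NBSParams(a, b, 0.2)
        lo, hi = sorted((p1, p2))
        assert nquantile(lo, params) <= nquantile(hi, params) + 1e-12


class TestClassicalReduction:
    """At I = 0 everything must match an independent classical oracle."""

    def test_pdf_cdf_hazard_match_fatiguelife(self, param_grid):
        xs = np.array([0.05, 0.2, 0.5, 1.0, 2.0, 5.0])
        for a, b in param_grid:
            p = NBSParams(a, b, 0.0)
            oracle = classical(a, b)
            assert np.allclose(npdf(xs, p).lower, oracle.pdf(xs), atol=1e-10, rtol=1e-10)
            assert np.allclose(ncdf(xs, p).lower, oracle.cdf(xs), atol=1e-10, rtol=1e-10)
            want_h = oracle.pdf(xs) / oracle.sf(xs)
            assert np.allclose(nhazard(xs, p).lower, want_h, rtol=1e-9)

    def test_quantile_matches_fatiguelife(self, param_grid):
        probs = np.array([0.05, 0.25, 0.5, 0.75, 0.99])
        for a, b in param_grid:
            p = NBSParams(a, b, 0.0)
            want = classical(a, b).ppf(probs)
            got = np.array([nquantile(q, p) for q in probs])
            assert np.allclose(got, want, rtol=1e-9)
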