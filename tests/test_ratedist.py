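import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratebound.ratedist import (
    ComputationError,
    DiscreteRateDistribution,
    GammaSpec,
    InvalidParameterError,
    UndefinedCVError,
    cv_upper_bound,
    discretize_gamma,
    gamma_plugin_cv,
    is_at_bound,
    max_variance_equiprobable,
    moment_upper_bound,
    moments,
    variance_upper_bound,
)
from oracles import quadrature_bin_means


class TestDiscreteRateDistribution:
    def test_basic_moments(self):
        d = DiscreteRateDistribution((0.5, 1.5), (0.5, 0.5))
        assert d.k == 2
        assert d.mean == pytest.approx(1.0)
        assert d.variance == pytest.approx(0.25)
        assert d.cv == pytest.approx(0.5)
        assert d.equiprobable

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            DiscreteRateDistribution((-0.1, 1.0), (0.5, 0.5))
        with pytest.raises(InvalidParameterError):
            DiscreteRateDistribution((2.0, 1.0), (0.5, 0.5))  # unsorted
        with pytest.raises(InvalidParameterError):
            DiscreteRateDistribution((1.0, 2.0), (0.5, 0.6))  # sum != 1
        with pytest.raises(InvalidParameterError):
            DiscreteRateDistribution((1.0, 2.0), (0.0, 1.0))  # zero weight
        with pytest.raises(InvalidParameterError):
            DiscreteRateDistribution((), ())

    def test_from_unsorted_sorts_jointly(self):
        d = DiscreteRateDistribution.from_unsorted((3.0, 1.0), (0.2, 0.8))
        assert d.rates == (1.0, 3.0)
        assert d.weights == (0.8, 0.2)

    def test_cv_undefined_for_zero_mean(self):
        d = DiscreteRateDistribution((0.0,), (1.0,))
        with pytest.raises(UndefinedCVError):
            d.cv

    def test_rescaled_to_mean(self):
        d = DiscreteRateDistribution((0.5, 2.5), (0.5, 0.5))
        r = d.rescaled_to_mean(1.0)
        assert r.mean == pytest.approx(1.0)
        # CV is scale-invariant
        assert r.cv == pytest.approx(d.cv)

    def test_json_round_trip(self):
        d = DiscreteRateDistribution((0.1, 1.0, 1.9), (0.2, 0.5, 0.3))
        blob = json.dumps(d.to_json_dict())
        back = DiscreteRateDistribution.from_json_dict(json.loads(blob))
        assert back == d


class TestDiscretizeGamma:
    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 3.0])
    @pytest.mark.parametrize("k", [2, 3, 4, 8])
    def test_interval_means_match_quadrature(self, alpha, k):
        d = discretize_gamma(GammaSpec(alpha), k)
        oracle = quadrature_bin_means(alpha, k)
        oracle /= oracle.mean()  # package renormalizes to exact unit mean
        assert np.allclose(d.rates, oracle, rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.2, 0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("k", range(2, 11))
    def test_grid_invariants(self, alpha, k):
        d = discretize_gamma(GammaSpec(alpha), k)
        assert d.k == k
        assert d.equiprobable
        assert d.mean == pytest.approx(1.0, abs=1e-12)
        assert all(r >= 0 for r in d.rates)
        assert list(d.rates) == sorted(d.rates)
        # the structural bound must hold for every discretization
        assert d.cv <= cv_upper_bound(k) + 1e-12
        assert d.variance <= variance_upper_bound(k, 1.0) + 1e-12

    @pytest.mark.parametrize("k", [3, 5, 10])
    def test_cv_decreases_with_alpha(self, k):
        alphas = [0.01, 0.1, 0.5, 1.0, 2.0, 10.0]
        cvs = [discretize_gamma(GammaSpec(a), k).cv for a in alphas]
        assert all(a > b for a, b in zip(cvs, cvs[1:]))

    @pytest.mark.parametrize("k", [2, 3, 5, 10])
    def test_tiny_alpha_saturates_bound(self, k):
        # at the bottom of a practical alpha search range the discretized CV
        # pins against sqrt(K-1)
        d = discretize_gamma(GammaSpec(1e-3), k)
        assert d.cv >= 0.99 * cv_upper_bound(k)
        assert is_at_bound(d, 1e-2)

    def test_k1_is_point_mass(self):
        d = discretize_gamma(GammaSpec(0.5), 1)
        assert d.rates == (1.0,) and d.weights == (1.0,)

    def test_median_method(self):
        d = discretize_gamma(GammaSpec(1.0), 4, method="interval_median")
        assert d.equiprobable
        assert d.mean == pytest.approx(1.0, abs=1e-12)
        # medians differ from means
        dm = discretize_gamma(GammaSpec(1.0), 4, method="interval_mean")
        assert not np.allclose(d.rates, dm.rates)

    def test_bad_inputs(self):
        with pytest.raises(InvalidParameterError):
            discretize_gamma(GammaSpec(1.0), 0)
        with pytest.raises(InvalidParameterError):
            discretize_gamma(GammaSpec(1.0), 4, method="nope")
        with pytest.raises(InvalidParameterError):
            GammaSpec(-1.0)


class TestBounds:
    def test_formulas(self):
        assert variance_upper_bound(4, 1.0) == pytest.approx(3.0)
        assert variance_upper_bound(4, 2.0) == pytest.approx(12.0)
        assert moment_upper_bound(4, 1.0, 2) == pytest.approx(4.0)
        assert moment_upper_bound(3, 2.0, 3) == pytest.approx(9 * 8)
        assert cv_upper_bound(3) == pytest.approx(np.sqrt(2))
        assert cv_upper_bound(1) == 0.0

    def test_extremal_distribution_attains_bound(self):
        # all mass concentrated on one support point: (0, ..., 0, K mu)
        for k in (2, 3, 5):
            d = DiscreteRateDistribution.equiprobable_from_rates(
                [0.0] * (k - 1) + [k * 1.0])
            assert d.variance == pytest.approx(variance_upper_bound(k, 1.0))
            assert d.cv == pytest.approx(cv_upper_bound(k))

    def test_moment_bound_holds_on_random_equiprobable(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            k = int(rng.integers(2, 7))
            rates = rng.exponential(1.0, size=k)
            d = DiscreteRateDistribution.equiprobable_from_rates(rates)
            mu = d.mean
            ms = moments(d, max_order=4)
            for n in (2, 3, 4):
                assert ms.raw_moments[n] <= moment_upper_bound(k, mu, n) * (1 + 1e-12)

    def test_bad_inputs(self):
        with pytest.raises(InvalidParameterError):
            variance_upper_bound(0, 1.0)
        with pytest.raises(InvalidParameterError):
            variance_upper_bound(3, -1.0)
        with pytest.raises(InvalidParameterError):
            moment_upper_bound(3, 1.0, 0)

    def test_is_at_bound(self):
        tight = DiscreteRateDistribution.equiprobable_from_rates([0.0, 0.0, 3.0])
        loose = discretize_gamma(GammaSpec(1.0), 3)
        assert is_at_bound(tight)
        assert not is_at_bound(loose)
        uneven = DiscreteRateDistribution((0.5, 1.5), (0.4, 0.6))
        with pytest.raises(InvalidParameterError):
            is_at_bound(uneven)
        with pytest.raises(InvalidParameterError):
            is_at_bound(tight, relative_tolerance=0.5)

    def test_gamma_plugin_cv_is_continuous_cv(self):
        assert gamma_plugin_cv(GammaSpec(0.25)) == pytest.approx(2.0)
        # plug-in CV exceeds sqrt(K-1) even though the discretized CV cannot
        assert gamma_plugin_cv(GammaSpec(0.05)) > cv_upper_bound(4)


class TestMaxVarianceOracle:
    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0])
    def test_matches_analytic_bound(self, k, mu):
        val, dist = max_variance_equiprobable(k, mu, seed=1)
        assert val == pytest.approx(variance_upper_bound(k, mu), rel=1e-6)
        # argmax is the one-point concentration (0, ..., 0, K mu)
        expected = [0.0] * (k - 1) + [k * mu]
        assert np.allclose(dist.rates, expected, atol=1e-3 * k * mu)

    def test_domain(self):
        with pytest.raises(InvalidParameterError):
            max_variance_equiprobable(7, 1.0)
        with pytest.raises(InvalidParameterError):
            max_variance_equiprobable(3, 0.0)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    k=st.integers(min_value=2, max_value=8),
    raw=st.lists(st.floats(min_value=0.0, max_value=50.0), min_size=8, max_size=8),
)
def test_property_equiprobable_bound(k, raw):
    rates = raw[:k]
    if sum(rates) <= 0:
        rates[0] = 1.0
    d = DiscreteRateDistribution.equiprobable_from_rates(rates)
    mu = d.mean
    assert d.variance <= variance_upper_bound(k, mu) * (1 + 1e-9) + 1e-12
    if mu > 0:
        assert d.cv <= cv_upper_bound(k) * (1 + 1e-9)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    alpha=st.floats(min_value=1e-3, max_value=50.0),
    k=st.integers(min_value=1, max_value=12),
)
def test_property_discretize_gamma_valid(alpha, k):
    d = discretize_gamma(GammaSpec(alpha), k)
    assert d.k == k
    assert d.equiprobable
    assert d.mean == pytest.approx(1.0, abs=1e-9)
    assert d.cv <= cv_upper_bound(k) + 1e-9
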