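"""Kendall's Tau (tau-a), lagged decay, null CIs, and the log-Pearson r."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobiscale.correlation import (CorrelationError, LagDecay, TauResult,
                                   fit_tau_decay, kendall_tau, lagged_tau,
                                   log_pearson, scatter_correlation_pattern,
                                   tau_ci, tau_decay)
from mobiscale.correlation import _cmd_exact, _cmd_fast


def brute_force_tau(x, y):
    """Independent O(n^2) oracle: literal double loop over all pairs."""
    n = len(x)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return 2.0 * total / (n * (n - 1))


class TestKendallTau:
    def test_monotone_agreement(self, rng):
        x = rng.standard_normal(50)
        assert kendall_tau(x, np.exp(x), ci=False).tau == 1.0
        assert kendall_tau(x, -x ** 3, ci=False).tau == -1.0

    def test_small_example(self):
        # pairs of (1,2,3,4) vs (1,3,2,4): 5 concordant, 1 discordant
        res = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4], ci=False)
        assert res.tau == pytest.approx(4.0 / 6.0)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 40))
            x = rng.integers(0, 5, n).astype(float)  # many ties
            y = rng.integers(0, 5, n).astype(float)
            assert kendall_tau(x, y, ci=False).tau == \
                pytest.approx(brute_force_tau(x, y), abs=1e-15)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        base = kendall_tau(x, y, ci=False).tau
        assert kendall_tau(np.exp(x), np.arctan(y), ci=False).tau == base
        assert kendall_tau(x ** 3, 5 * y + 2, ci=False).tau == base

    def test_fast_path_matches_exact_path(self, rng):
        n = 4500  # above the exact-path cutoff
        x = np.round(rng.standard_normal(n), 2)  # rounding creates ties
        y = np.round(0.5 * x + rng.standard_normal(n), 2)
        assert _cmd_fast(x, y) == _cmd_exact(x, y)

    def test_length_mismatch(self):
        with pytest.raises(CorrelationError):
            kendall_tau([1, 2], [1, 2, 3])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.integers(min_value=-9, max_value=9),
                    min_size=2, max_size=60).flatmap(
        lambda xs: st.tuples(
            st.just(xs),
            st.lists(st.integers(min_value=-9, max_value=9),
                     min_size=len(xs), max_size=len(xs)))))
    def test_property_oracle_bounds_and_symmetry(self, xy):
        """tau-a equals the all-pairs oracle, lies in [-1, 1], and is
        symmetric in its arguments — on arbitrary tied integer series."""
        x = np.asarray(xy[0], dtype=float)
        y = np.asarray(xy[1], dtype=float)
        tau = kendall_tau(x, y, ci=False).tau
        assert tau == pytest.approx(brute_force_tau(x, y), abs=1e-14)
        assert -1.0 <= tau <= 1.0
        assert kendall_tau(y, x, ci=False).tau == tau


class TestLaggedTau:
    def test_lag_beyond_all_files(self):
        with pytest.raises(CorrelationError):
            lagged_tau([np.arange(5.0), np.arange(4.0)], lag=10)

    def test_pairs_do_not_span_files(self):
        # two strictly increasing files; a spanning pair would see the reset
        f1 = np.array([1.0, 2.0, 3.0])
        f2 = np.array([0.1, 0.2, 0.3])
        res = lagged_tau([f1, f2], lag=1)
        assert res.tau == 1.0
        assert res.n_pairs == 4

    def test_iid_within_null_ci(self, rng):
        files = [rng.lognormal(0, 1, 500) for _ in range(4)]
        res = lagged_tau(files, lag=1)
        assert abs(res.tau) < res.ci_halfwidth

    def test_ar1_monotone_decay(self):
        from mobiscale.synthetic_data import SeriesPlan, generate_series
        d = generate_series(SeriesPlan(kind="log_ar1", phi=0.8, length=5000,
                                       seed=11)).displacements
        # copula taus: lag k has coefficient phi^k, so 1 > 3 > 8 and all
        # well above the ~0.015 sampling noise
        t1 = lagged_tau([d], 1).tau
        t3 = lagged_tau([d], 3).tau
        t8 = lagged_tau([d], 8).tau
        assert t1 > t3 > t8 > 0


class TestTauDecay:
    def test_exact_power_law_decay(self):
        lags = np.arange(1, 21)
        taus = [TauResult(tau=float(l) ** -0.4, n_pairs=100, lag=int(l))
                for l in lags]
        ld = LagDecay(lags=lags, taus=taus)
        assert fit_tau_decay(ld) == pytest.approx(-0.4, abs=1e-9)

    def test_too_few_positive_points(self):
        lags = np.arange(1, 5)
        taus = [TauResult(tau=-0.1, n_pairs=100, lag=int(l)) for l in lags]
        with pytest.raises(CorrelationError):
            fit_tau_decay(LagDecay(lags=lags, taus=taus))

    def test_decay_curve_on_persistent_series(self):
        from mobiscale.synthetic_data import SeriesPlan, generate_series
        d = generate_series(SeriesPlan(kind="log_ar1", phi=0.8, length=4000,
                                       seed=5)).displacements
        ld = tau_decay([d], max_lag=10)
        assert ld.lags.tolist() == list(range(1, 11))
        assert ld.tau_values[0] > ld.tau_values[-1]
        assert np.isfinite(ld.decay_exponent)


class TestTauCI:
    def test_closed_form_value(self):
        # z * sqrt(2(2n+5) / (9 n (n-1))) at n = 1000, z = 1.96
        assert tau_ci(1000) == pytest.approx(0.0414, abs=5e-4)

    def test_shrinks_with_n(self):
        assert tau_ci(100_000) < tau_ci(1000) < tau_ci(50)

    def test_permutation_ci_covers_null(self, rng):
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        hw = tau_ci(300, method="permutation", n_shuffles=500, seed=3,
                    x=x, y=y)
        observed = abs(kendall_tau(x, y, ci=False).tau)
        assert observed < hw
        assert hw == pytest.approx(tau_ci(300), rel=0.25)


class TestLogPearson:
    def test_zero_variance_error(self):
        with pytest.raises(CorrelationError):
            log_pearson(2.0 ** np.zeros(10) * 5.0)

    def test_geometric_series_zero_variance(self):
        # constant-ratio series has linear ln(d): nonzero variance, but a
        # truly constant series must fail
        with pytest.raises(CorrelationError):
            log_pearson(np.full(20, 7.0))

    def test_ar1_recovery(self):
        from mobiscale.synthetic_data import SeriesPlan, generate_series
        d = generate_series(SeriesPlan(kind="log_ar1", phi=0.8, length=5000,
                                       seed=2)).displacements
        assert log_pearson(d).r_delta == pytest.approx(0.8, abs=0.03)

    def test_independent_near_zero(self, rng):
        d = rng.lognormal(3, 1, 4000)
        assert abs(log_pearson(d).r_delta) < 2.0 / np.sqrt(4000) * 2

    def test_requires_positive(self):
        with pytest.raises(CorrelationError):
            log_pearson([1.0, 0.0, 2.0])


class TestScatterPattern:
    def test_persistent_series_on_diagonal(self):
        d = np.logspace(0, 4, 500)  # each step close to the previous
        out = scatter_correlation_pattern([d])
        assert out["diagonal_mass"] == 1.0

    def test_shuffle_control_reduces_diagonal_mass(self):
        from mobiscale.synthetic_data import SeriesPlan, generate_series
        d = generate_series(SeriesPlan(kind="cascade", length=4096,
                                       seed=8, sigma=1.5)).displacements
        rng = np.random.default_rng(0)
        shuffled = d[rng.permutation(d.size)]
        real = scatter_correlation_pattern([d])["diagonal_mass"]
        ctrl = scatter_correlation_pattern([shuffled])["diagonal_mass"]
        assert real > ctrl

    def test_relative_mode_requires_means(self):
        with pytest.raises(CorrelationError):
            scatter_correlation_pattern([np.ones(10)], relative=True)
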