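import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsconv.error_profile import (
    BetaErrorModel,
    WindowStats,
    fit_beta_mom,
    fit_error_model_from_windows,
    overall_rate,
    positional_profile,
    rank_correlation,
    read_categories,
    variance_inflation,
    variance_inflation_analytic,
    window_rates,
)
from bsconv.io_formats import CytosineSiteRecord, MethylationCall, ReadCalls


def _site(pos, meth, unmeth, chrom="c1", context="CHH"):
    return CytosineSiteRecord(chrom, pos, "+", meth, unmeth, context, "CAT")


def _read(flags, strand_class="OT", read_id="r"):
    calls = tuple(
        MethylationCall(read_offset=i, context="CHH", unconverted=f)
        for i, f in enumerate(flags)
    )
    return ReadCalls(read_id=read_id, strand_class=strand_class, calls=calls)


def _window(rate, n=1000, start=0):
    y = round(rate * n)
    return WindowStats("c1", start, start + 150, y, n, 10.0, math.nan, 3, 3, 4)


class TestWindowRates:
    def test_counts_pool_within_window(self):
        records = [_site(10, 1, 9), _site(20, 3, 7)]
        (w,) = window_rates(records, 150, ("c1", 0, 150))
        assert (w.y, w.n) == (4, 20)
        assert w.rate == pytest.approx(0.2)

    def test_boundary_site_lands_in_second_window(self):
        # 1-based pos 151 is the first base of the second 150 bp window
        records = [_site(150, 1, 9), _site(151, 5, 5)]
        windows = window_rates(records, 150, ("c1", 0, 300))
        assert len(windows) == 2
        assert (windows[0].y, windows[1].y) == (1, 5)

    def test_empty_window_kept_with_nan_rate(self):
        windows = window_rates([_site(10, 1, 9)], 150, ("c1", 0, 300))
        assert windows[1].n == 0
        assert math.isnan(windows[1].rate)

    def test_window_sums_conserve_overall_counts(self):
        rng = np.random.default_rng(0)
        records = [
            _site(int(pos), int(m), 10)
            for pos, m in zip(
                sorted(rng.choice(np.arange(1, 1000), 80, replace=False)),
                rng.integers(0, 5, 80),
            )
        ]
        windows = window_rates(records, 37, ("c1", 0, 1000))
        y, n, _ = overall_rate(records)
        assert sum(w.y for w in windows) == y
        assert sum(w.n for w in windows) == n

    def test_context_site_counts(self):
        records = [
            _site(1, 0, 5, context="CG"),
            _site(5, 0, 5, context="CHG"),
            _site(9, 0, 5, context="CHH"),
        ]
        (w,) = window_rates(records, 50, ("c1", 0, 50))
        assert (w.n_cg, w.n_chg, w.n_chh) == (1, 1, 1)

    def test_unsorted_records_raise(self):
        with pytest.raises(ValueError, match="sorted"):
            window_rates([_site(20, 1, 9), _site(10, 1, 9)], 150, ("c1", 0, 150))

    def test_out_of_region_record_raises(self):
        with pytest.raises(ValueError, match="outside region"):
            window_rates([_site(500, 1, 9)], 150, ("c1", 0, 300))

    def test_gc_from_genome(self):
        from bsconv.io_formats import GenomeSequence

        genome = GenomeSequence("c1", "ATGC" * 25)
        (w,) = window_rates([_site(10, 1, 9)], 100, ("c1", 0, 100), genome=genome)
        assert w.gc == pytest.approx(0.5)


class TestOverallRate:
    def test_pools_counts(self):
        y, n, rate = overall_rate([_site(1, 0, 10), _site(2, 5, 5)])
        assert (y, n, rate) == (5, 20, 0.25)

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            overall_rate([_site(1, 0, 0)])

    def test_recovers_constant_rate_within_binomial_error(self, rng):
        # 10^4 sites x coverage 10 at a constant 8% error rate
        eps, cov, n_sites = 0.08, 10, 10_000
        meth = rng.binomial(cov, eps, size=n_sites)
        records = [_site(i + 1, int(m), cov - int(m)) for i, m in enumerate(meth)]
        _, n, rate = overall_rate(records)
        se = math.sqrt(eps * (1 - eps) / n)
        assert abs(rate - eps) < 3 * se


class TestBetaMoM:
    def test_exact_moments_recover_shape_parameters(self):
        # the analytic mean and variance of Beta(17, 220)
        mu = 17 / 237
        var = 17 * 220 / (237**2 * 238)
        model = fit_beta_mom(mu, var)
        assert model.a == pytest.approx(17.0, rel=1e-12)
        assert model.b == pytest.approx(220.0, rel=1e-12)

    def test_uniform_limit(self):
        model = fit_beta_mom(0.5, 1 / 12)
        assert (model.a, model.b) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_impossible_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            fit_beta_mom(0.5, 0.3)

    @given(
        a=st.floats(min_value=0.1, max_value=100),
        b=st.floats(min_value=0.1, max_value=100),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_on_analytic_moments(self, a, b):
        model = BetaErrorModel(a, b)
        fitted = fit_beta_mom(model.mean, model.variance)
        assert fitted.a == pytest.approx(a, rel=1e-8)
        assert fitted.b == pytest.approx(b, rel=1e-8)

    def test_two_window_hand_computation(self):
        # rates {0.05, 0.10}: mu = 0.075, s^2 = 0.00125 (ddof=1),
        # scale = 0.075*0.925/0.00125 - 1 = 54.5
        windows = [_window(0.05, n=100), _window(0.10, n=100, start=150)]
        model = fit_error_model_from_windows(windows)
        assert model.a == pytest.approx(0.075 * 54.5)
        assert model.b == pytest.approx(0.925 * 54.5)

    def test_sampled_rates_recover_parameters(self, error_model, rng):
        rates = error_model.rvs(10_000, rng)
        windows = [
            _window(r, n=10**9, start=150 * i) for i, r in enumerate(rates)
        ]
        fitted = fit_error_model_from_windows(windows)
        assert fitted.a == pytest.approx(17.0, rel=0.15)
        assert fitted.b == pytest.approx(220.0, rel=0.15)

    def test_zero_variance_raises(self):
        windows = [_window(0.1), _window(0.1, start=150)]
        with pytest.raises(ValueError, match="identical"):
            fit_error_model_from_windows(windows)


class TestVarianceInflation:
    def _binomial_null_windows(self, rng, global_rate=0.07, m=150, n=800):
        ys = rng.binomial(n, global_rate, size=m)
        return [
            WindowStats("c1", i * 150, (i + 1) * 150, int(y), n, 8.0, math.nan, 3, 3, 4)
            for i, y in enumerate(ys)
        ]

    def test_null_windows_give_ratio_near_one(self, rng):
        windows = self._binomial_null_windows(rng)
        ratio = variance_inflation(windows, 0.07, n_sims=200, seed=1)
        assert 0.6 < ratio < 1.6

    def test_beta_distributed_windows_are_overdispersed(self, error_model, rng):
        rates = error_model.rvs(200, rng)
        windows = [
            WindowStats("c1", i * 150, (i + 1) * 150, int(rng.binomial(1000, r)),
                        1000, 10.0, math.nan, 3, 3, 4)
            for i, r in enumerate(rates)
        ]
        ratio = variance_inflation(windows, float(np.mean(rates)), n_sims=100, seed=2)
        assert ratio > 5.0

    def test_single_window_raises(self):
        with pytest.raises(ValueError):
            variance_inflation([_window(0.1)], 0.1, seed=0)

    def test_window_order_invariance(self, rng):
        windows = self._binomial_null_windows(rng)
        a = variance_inflation(windows, 0.07, n_sims=100, seed=3)
        b = variance_inflation(windows[::-1], 0.07, n_sims=100, seed=3)
        assert a == pytest.approx(b, rel=1e-12)

    def test_simulated_null_matches_analytic_null(self, rng):
        windows = self._binomial_null_windows(rng)
        sim = variance_inflation(windows, 0.07, n_sims=500, seed=4)
        ana = variance_inflation_analytic(windows, 0.07)
        assert sim == pytest.approx(ana, rel=0.1)


class TestReadCategories:
    def test_categories_and_fractions(self):
        reads = [
            _read([True, True, True]),
            _read([False] * 5),
            _read([True, True, False, False, False]),
        ]
        counts, fractions = read_categories(reads)
        assert (counts.fully_unconverted, counts.fully_converted, counts.partial) == (1, 1, 1)
        assert fractions == [1.0, 0.0, 0.4]
        assert counts.total == 3

    def test_reads_without_cytosines_are_skipped(self):
        counts, fractions = read_categories([_read([])])
        assert counts.total == 0 and fractions == []


class TestPositionalProfile:
    def test_fully_unconverted_reads_rate_one_everywhere(self):
        reads = [_read([True] * 10) for _ in range(5)]
        profiles = positional_profile(reads, max_offset=10)
        rates = profiles["OT"].rates()
        assert np.all(rates == 1.0)

    def test_missing_strand_class_has_zero_totals(self):
        profiles = positional_profile([_read([True], strand_class="OT")], 5)
        assert profiles["CTOT"].total.sum() == 0

    def test_pooled_counts_conserve_call_totals(self, rng):
        reads = [
            _read(list(rng.random(12) < 0.3), strand_class=sc)
            for sc in ("OT", "OB", "CTOT", "CTOB")
            for _ in range(20)
        ]
        profiles = positional_profile(reads, max_offset=12)
        total_unconv = sum(p.unconverted.sum() for p in profiles.values())
        total_calls = sum(p.total.sum() for p in profiles.values())
        assert total_unconv == sum(r.n_unconverted for r in reads)
        assert total_calls == sum(r.n_calls for r in reads)


class TestRankCorrelation:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert rank_correlation(x, x) == pytest.approx(1.0)
        assert rank_correlation(x, x[::-1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks (1,2,3) vs (2,1,3): rho = 1 - 6*2/(3*8) = 0.5
        assert rank_correlation([1, 2, 3], [2, 1, 3]) == pytest.approx(0.5)

    def test_nan_pairs_dropped(self):
        rho = rank_correlation([1, 2, 3, math.nan], [2, 1, 3, 5])
        assert rho == pytest.approx(0.5)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 2, math.nan], [1, 2, 3])
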