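"""Pareto MLE, xmin selection, bootstrap GOF and exponent summaries."""

import numpy as np
import pytest

import burstlab as bl
from burstlab.synthetic_data import _truncated_pareto


def brute_force_xmin(values, min_tail_size, xmax=None):
    """Independent oracle: exhaustive scan over every distinct value with a
    hand-rolled KS distance against the fitted tail CDF."""
    values = np.asarray(values, dtype=float)
    best = None
    for cand in np.unique(values):
        if xmax is not None and cand >= xmax:
            continue
        tail = np.sort(values[values >= cand])
        if tail.size < min_tail_size:
            continue
        logs = np.log(tail / cand)
        if logs.sum() == 0:
            continue
        if xmax is None:
            shape = 1.0 + tail.size / logs.sum()
            cdf = 1.0 - (tail / cand) ** (1.0 - shape)
        else:
            fit = bl.mle_shape(tail, xmin=float(cand), xmax=xmax, min_tail_size=min_tail_size)
            shape = fit.shape
            cdf = fit.cdf(tail)
        n = tail.size
        ks = 0.0
        for k in range(n):
            ks = max(ks, abs(cdf[k] - k / n), abs(cdf[k] - (k + 1) / n))
        if best is None or ks < best[0]:
            best = (ks, float(cand), shape)
    return best


class TestMLEShape:
    def test_closed_form_by_hand(self):
        # {1, e, e^2}: sum of logs = 3, n = 3 -> shape 2, alpha -2
        sample = np.array([1.0, np.e, np.e**2])
        fit = bl.mle_shape(sample, xmin=1.0, min_tail_size=3)
        assert fit.alpha == pytest.approx(-2.0, rel=1e-12)

    def test_matches_closed_form_everywhere(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = bl.sample_pareto(rng.uniform(1.3, 4.0), 1.0, 500, seed=int(rng.integers(2**31)))
            fit = bl.mle_shape(x, xmin=1.0)
            expected = 1.0 + x.size / np.log(x).sum()
            assert fit.shape == pytest.approx(expected, rel=1e-10)

    def test_recovery_within_3se(self):
        x = bl.sample_pareto(2.5, 1.0, 10_000, seed=8)
        fit = bl.mle_shape(x, xmin=1.0)
        assert abs(fit.shape - 2.5) < 3 * (fit.shape - 1) / np.sqrt(x.size)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(bl.DegenerateSampleError):
            bl.mle_shape(np.array([1.0, 1.0, 1.0]), xmin=1.0, min_tail_size=3)

    def test_small_tail_rejected(self):
        with pytest.raises(bl.InsufficientDataError):
            bl.mle_shape(np.arange(1.0, 11.0), xmin=1.0, min_tail_size=50)

    def test_order_invariance(self):
        x = bl.sample_pareto(2.0, 1.0, 300, seed=9)
        a = bl.mle_shape(x, xmin=1.0).alpha
        b = bl.mle_shape(x[::-1].copy(), xmin=1.0).alpha
        assert a == b

    @pytest.mark.parametrize("shape", [1.2, 1.59, 2.0, 3.0])
    def test_truncated_mle_unbiased_under_cutoff(self, shape):
        rng = np.random.default_rng(10)
        x = _truncated_pareto(rng, shape, 1.0, 1440.0, 20_000)
        fit = bl.mle_shape(x, xmin=1.0, xmax=1440.0)
        # generous 4-sigma-ish bound via observed information
        var_log = np.var(np.log(x))
        se = 1.0 / np.sqrt(x.size * var_log)
        assert abs(fit.shape - shape) < 4 * se

    def test_invalid_bounds(self):
        x = bl.sample_pareto(2.0, 1.0, 100, seed=0)
        with pytest.raises(bl.InvalidParameterError):
            bl.mle_shape(x, xmin=0.0)
        with pytest.raises(bl.InvalidParameterError):
            bl.mle_shape(x, xmin=2.0, xmax=1.0)


class TestSelectXmin:
    def test_equals_brute_force_scan(self):
        rng = np.random.default_rng(11)
        for rep in range(10):
            n = int(rng.integers(80, 400))
            x = np.round(bl.sample_pareto(2.0, 1.0, n, seed=200 + rep), 2)
            fit = bl.select_xmin(x, min_tail_size=20)
            ks, xmin, shape = brute_force_xmin(x, min_tail_size=20)
            assert fit.xmin == pytest.approx(xmin)
            assert fit.shape == pytest.approx(shape, rel=1e-10)
            assert fit.ks_stat == pytest.approx(ks, rel=1e-10)

    def test_recovers_true_xmin_on_pure_pareto(self):
        x = bl.sample_pareto(2.2, 3.0, 5000, seed=12)
        fit = bl.select_xmin(x)
        assert fit.xmin <= np.quantile(x, 0.05)
        assert abs(fit.shape - 2.2) < 3 * fit.se_shape

    def test_too_small_sample_rejected(self):
        with pytest.raises(bl.InsufficientDataError):
            bl.select_xmin(np.arange(1.0, 11.0), min_tail_size=50)


class TestGOFBootstrap:
    def test_deterministic_for_fixed_seed(self):
        x = bl.sample_pareto(2.0, 1.0, 500, seed=13)
        fit = bl.mle_shape(x, xmin=1.0)
        a = bl.gof_bootstrap(x, fit, n_boot=100, seed=99)
        b = bl.gof_bootstrap(x, fit, n_boot=100, seed=99)
        assert a.p_value == b.p_value

    def test_exponential_data_rejected(self):
        rng = np.random.default_rng(14)
        x = rng.exponential(scale=30.0, size=5000)
        xmin = float(np.quantile(x, 0.2))
        fit = bl.mle_shape(x, xmin=xmin)
        result = bl.gof_bootstrap(x, fit, n_boot=100, seed=15)
        assert result.p_value < 0.05 and not result.accepted_at_5pct

    def test_acceptance_flag_matches_p(self):
        x = bl.sample_pareto(2.0, 1.0, 1000, seed=16)
        fit = bl.mle_shape(x, xmin=1.0)
        res = bl.gof_bootstrap(x, fit, n_boot=200, seed=17)
        assert res.accepted_at_5pct == (res.p_value >= 0.05)

    def test_small_n_boot_warns_zero_errors(self):
        x = bl.sample_pareto(2.0, 1.0, 200, seed=18)
        fit = bl.mle_shape(x, xmin=1.0)
        with pytest.warns(UserWarning):
            bl.gof_bootstrap(x, fit, n_boot=50, seed=0)
        with pytest.raises(bl.InvalidParameterError):
            bl.gof_bootstrap(x, fit, n_boot=0, seed=0)

    def test_semiparametric_body_resampling(self):
        # body below xmin comes from the data, tail from the model
        x = np.concatenate([np.linspace(0.1, 0.9, 200),
                            bl.sample_pareto(2.0, 1.0, 800, seed=19)])
        fit = bl.mle_shape(x, xmin=1.0)
        res = bl.gof_bootstrap(x, fit, n_boot=200, seed=20)
        assert res.p_value >= 0.05  # model data should not be rejected


class TestExponentSummaries:
    def _windowed(self, per_hour_values):
        samples = tuple(
            bl.InterEventSample(values=np.asarray(per_hour_values.get(h, [])),
                                label=f"hour-{h:02d}")
            for h in range(24)
        )
        mask = np.array([len(s) > 0 for s in samples])
        return bl.WindowedInterEvents(samples=samples, retained_mask=mask)

    def test_rel_devs_mean_zero(self):
        rng = np.random.default_rng(21)
        data = {h: bl.sample_pareto(2.0, 1.0, 500, seed=300 + h) for h in range(8)}
        summary = bl.window_exponents(
            self._windowed(data), bl.FitPolicy(fixed_xmin=1.0), editor_id="e"
        )
        assert summary.rel_devs.mean() == pytest.approx(0.0, abs=1e-12)
        assert summary.n_windows == 8

    def test_single_window_rel_dev_zero(self):
        data = {9: bl.sample_pareto(2.0, 1.0, 500, seed=22)}
        summary = bl.window_exponents(
            self._windowed(data), bl.FitPolicy(fixed_xmin=1.0)
        )
        assert np.array_equal(summary.rel_devs, [0.0])

    def test_unfittable_windows_recorded_as_skipped(self):
        data = {9: bl.sample_pareto(2.0, 1.0, 500, seed=23), 10: [5.0, 6.0]}
        summary = bl.window_exponents(
            self._windowed(data), bl.FitPolicy(fixed_xmin=1.0)
        )
        assert summary.hours == [9] and summary.skipped_hours == [10]

    def test_no_fittable_windows_raises(self):
        with pytest.raises(bl.InsufficientDataError):
            bl.window_exponents(self._windowed({9: [5.0, 6.0]}),
                                bl.FitPolicy(fixed_xmin=1.0))

    def test_pooled_sd_definition(self):
        s1 = bl.ExponentSummary(editor_id="a", hours=[0, 1],
                                window_alphas=np.array([-1.8, -2.2]),
                                window_ses=np.array([0.1, 0.1]))
        s2 = bl.ExponentSummary(editor_id="b", hours=[0, 1],
                                window_alphas=np.array([-2.0, -2.0]),
                                window_ses=np.array([0.1, 0.1]))
        pop = bl.population_summary([s1, s2])
        expected = np.std(np.concatenate([s1.rel_devs, s2.rel_devs]), ddof=1)
        assert pop.normal_fit[1] == pytest.approx(expected)
        assert pop.mean_alphas == pytest.approx([-2.0, -2.0])

    def test_empty_summaries_rejected(self):
        with pytest.raises(bl.InsufficientDataError):
            bl.population_summary([])
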