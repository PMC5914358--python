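"""Bootstrap over experimental units: moments, profiles, bagging, error model."""

import numpy as np
import pytest
from scipy import stats

import mrcoex as mx
from mrcoex.bootstrap import _MomentAccumulator


class TestMomentAccumulator:
    @pytest.mark.parametrize("dist", ["normal", "lognormal"])
    def test_streaming_matches_two_pass(self, dist):
        rng = np.random.default_rng(0)
        draw = rng.standard_normal if dist == "normal" else rng.standard_normal
        stack = [np.exp(draw((40, 40))) if dist == "lognormal" else draw((40, 40))
                 for _ in range(20)]
        acc = _MomentAccumulator((40, 40))
        for x in stack:
            acc.add(x)
        arr = np.stack(stack)
        assert np.allclose(acc.mean, arr.mean(0), atol=1e-10)
        assert np.allclose(acc.sd(), arr.std(0, ddof=1), atol=1e-10)
        assert np.allclose(acc.skewness(), stats.skew(arr, axis=0), atol=1e-8)
        assert np.allclose(acc.excess_kurtosis(), stats.kurtosis(arr, axis=0),
                           atol=1e-8)

    def test_lognormal_skewness_detected_against_closed_form(self):
        """Sample skewness of lognormal draws approaches the closed form
        (exp(s^2)+2) sqrt(exp(s^2)-1); normal draws stay near 0."""
        rng = np.random.default_rng(1)
        s = 0.5
        acc = _MomentAccumulator((2000,))
        for _ in range(400):
            acc.add(np.exp(s * rng.standard_normal(2000)))
        closed = (np.exp(s**2) + 2) * np.sqrt(np.exp(s**2) - 1)
        got = float(np.median(acc.skewness()))
        assert got > 0.5 * closed  # positive and of the right magnitude
        acc_n = _MomentAccumulator((2000,))
        for _ in range(400):
            acc_n.add(rng.standard_normal(2000))
        assert abs(float(np.median(acc_n.skewness()))) < 0.1


class TestBootstrapMR:
    def test_seeded_determinism(self, small_logged):
        logged, design, _ = small_logged
        a = mx.bootstrap_mr(logged, design, n_replicates=5, seed=11)
        b = mx.bootstrap_mr(logged, design, n_replicates=5, seed=11)
        for field in ("mean_mr", "sd_mr", "mean_logit_mr", "sd_logit_mr"):
            assert np.array_equal(getattr(a, field), getattr(b, field),
                                  equal_nan=True)
        c = mx.bootstrap_mr(logged, design, n_replicates=5, seed=12)
        assert not np.array_equal(a.mean_mr, c.mean_mr, equal_nan=True)

    def test_identical_experiments_give_zero_sd(self):
        """If every experiment is a copy of the same samples, resampling
        experiments changes nothing and the per-pair SD is 0."""
        rng = np.random.default_rng(2)
        block = rng.standard_normal((20, 4))
        values = np.hstack([block] * 5)
        expr = mx.ExpressionMatrix(
            [f"g{i}" for i in range(20)],
            [f"s{j}" for j in range(20)],
            values, scale="log2",
        )
        design = mx.BatchDesign({f"s{j}": f"e{j // 4}" for j in range(20)})
        summ = mx.bootstrap_mr(expr, design, n_replicates=6, seed=3)
        assert np.nanmax(summ.sd_mr) == pytest.approx(0.0, abs=1e-9)
        assert np.nanmax(summ.sd_logit_mr) == pytest.approx(0.0, abs=1e-9)

    def test_more_samples_shrink_logit_error(self):
        """Quadrupling the compendium (same structure) strictly lowers the
        mean logit-MR error."""
        scores = {}
        for n_exp, key in ((6, "small"), (24, "large")):
            cfg = mx.SimulationConfig(
                n_genes=60, n_modules=6, genes_per_module=10,
                n_experiments=n_exp, samples_per_experiment=10,
                loading=0.8, seed=5,
            )
            expr, design, _ = mx.simulate_expression(cfg)
            summ = mx.bootstrap_mr(mx.log_transform(expr), design,
                                   n_replicates=15, seed=6)
            scores[key] = float(np.nanmean(summ.offdiag("sd_logit_mr")))
        assert scores["large"] < scores["small"]

    def test_single_experiment_rejected(self):
        rng = np.random.default_rng(7)
        expr = mx.ExpressionMatrix(
            ["g0", "g1"], [f"s{j}" for j in range(4)],
            rng.standard_normal((2, 4)), scale="log2",
        )
        design = mx.BatchDesign({f"s{j}": "only" for j in range(4)})
        with pytest.raises(ValueError, match="experiments"):
            mx.bootstrap_mr(expr, design, n_replicates=3, seed=0)

    def test_sample_resampling_mode_runs(self, small_logged):
        logged, design, _ = small_logged
        summ = mx.bootstrap_mr(logged, design, n_replicates=4, seed=8,
                               resample_unit="samples")
        assert summ.n_replicates == 4
        assert np.isfinite(summ.offdiag("sd_logit_mr")).all()


@pytest.fixture(scope="module")
def bootstrap_summary():
    cfg = mx.SimulationConfig(
        n_genes=120, n_modules=8, genes_per_module=10,
        n_experiments=15, samples_per_experiment=4, loading=0.8, seed=9,
    )
    expr, design, _ = mx.simulate_expression(cfg)
    return mx.bootstrap_mr(mx.log_transform(expr), design,
                           n_replicates=20, seed=10)


class TestErrorProfile:
    def test_bin_count_and_coverage(self, bootstrap_summary):
        prof = mx.error_profile(bootstrap_summary, bin_width=0.05)
        assert prof.median.size == 20
        assert prof.counts.sum() == bootstrap_summary.offdiag("sd_mr").size
        assert prof.bin_edges[0] == 0.0 and prof.bin_edges[-1] == 1.0

    def test_quartiles_ordered(self, bootstrap_summary):
        prof = mx.error_profile(bootstrap_summary, bin_width=0.05, scale="mr")
        ok = ~np.isnan(prof.median)
        assert np.all(prof.q1[ok] <= prof.median[ok] + 1e-12)
        assert np.all(prof.median[ok] <= prof.q3[ok] + 1e-12)

    def test_logit_profile_flat_mid_range(self, bootstrap_summary):
        """On the logit scale the error profile is nearly constant over the
        10th-90th percentile range (max/min <= 2)."""
        prof = mx.error_profile(bootstrap_summary, bin_width=0.05, scale="logit")
        centers = prof.bin_centers
        mid = prof.median[(centers > 0.1) & (centers < 0.9)]
        assert np.nanmax(mid) / np.nanmin(mid) <= 2.0

    def test_raw_profile_peaks_mid_range(self, bootstrap_summary):
        """Raw-MR SD is largest for mid-range (uncorrelated) pairs and
        smallest near the extremes, unlike the flat logit profile."""
        raw = mx.error_profile(bootstrap_summary, bin_width=0.05, scale="mr")
        lg = mx.error_profile(bootstrap_summary, bin_width=0.05, scale="logit")
        ratio = lambda p: np.nanmax(p.median) / np.nanmin(p.median)
        assert ratio(raw) > ratio(lg)
        centers = raw.bin_centers
        mid = np.nanmean(raw.median[(centers > 0.4) & (centers < 0.6)])
        edge = np.nanmean(raw.median[(centers < 0.1) | (centers > 0.9)])
        assert mid > edge

    def test_constant_sd_field_gives_constant_medians(self, bootstrap_summary):
        import copy
        summ = copy.copy(bootstrap_summary)
        const = np.full_like(summ.sd_logit_mr, 0.7)
        np.fill_diagonal(const, np.nan)
        summ.sd_logit_mr = const
        prof = mx.error_profile(summ, bin_width=0.1, scale="logit")
        assert np.allclose(prof.median[~np.isnan(prof.median)], 0.7)


class TestErrorMoments:
    def test_logit_deviations_closer_to_normal(self, bootstrap_summary):
        """Across the central percentile range the raw-scale deviations are
        more skewed than the logit-scale ones."""
        raw = mx.error_moments(bootstrap_summary, scale="mr", bin_width=0.1)
        lg = mx.error_moments(bootstrap_summary, scale="logit", bin_width=0.1)
        mid = slice(3, 7)  # percentile 0.3-0.7
        assert np.nanmax(np.abs(raw.skewness[mid])) > \
            np.nanmax(np.abs(lg.skewness[mid]))

    def test_requires_enough_replicates(self, small_logged):
        logged, design, _ = small_logged
        summ = mx.bootstrap_mr(logged, design, n_replicates=3, seed=1)
        with pytest.raises(ValueError, match="replicates"):
            mx.error_moments(summ)


class TestBaggedMR:
    def test_single_replicate_is_that_replicate(self, small_logged):
        logged, design, _ = small_logged
        bag = mx.bagged_mr(logged, design, n_replicates=1, seed=13)
        from mrcoex.bootstrap import _replicate_mr
        single = _replicate_mr(
            logged, design,
            np.random.default_rng(np.random.SeedSequence(13).spawn(1)[0]),
            "experiments", "center",
        )
        np.fill_diagonal(single, np.nan)
        assert np.allclose(bag.values, single, equal_nan=True, atol=1e-9)

    def test_identical_replicates_fixed_point(self):
        rng = np.random.default_rng(14)
        block = rng.standard_normal((15, 5))
        expr = mx.ExpressionMatrix(
            [f"g{i}" for i in range(15)],
            [f"s{j}" for j in range(15)],
            np.hstack([block] * 3), scale="log2",
        )
        design = mx.BatchDesign({f"s{j}": f"e{j // 5}" for j in range(15)})
        bag = mx.bagged_mr(expr, design, n_replicates=5, seed=15)
        single = mx.mr_from_expression(mx.batch_center(expr, design))
        assert np.allclose(bag.values, single.values, equal_nan=True, atol=1e-9)

    def test_values_stay_inside_open_range(self, small_logged):
        logged, design, _ = small_logged
        bag = mx.bagged_mr(logged, design, n_replicates=8, seed=16)
        off = bag.offdiag()
        assert np.all(off > 0) and np.all(off < bag.n_genes)

    def test_arithmetic_mode_differs_from_logit_mode(self, small_logged):
        logged, design, _ = small_logged
        a = mx.bagged_mr(logged, design, n_replicates=5, seed=17, aggregate="logit")
        b = mx.bagged_mr(logged, design, n_replicates=5, seed=17, aggregate="mean")
        assert not np.allclose(a.values, b.values, equal_nan=True)
        off = ~np.eye(len(a.gene_ids), dtype=bool)
        assert np.all(b.values[off] > 0) and np.all(b.values[off] < b.n_genes)


class TestErrorModel:
    def test_collinear_points_recovered_exactly(self):
        pts = [(10, 3.0), (100, 2.0), (1000, 1.0)]
        em = mx.fit_error_model(pts)
        assert em.pearson_r == pytest.approx(-1.0)
        assert em.predict(100) == pytest.approx(2.0)
        assert em.slope == pytest.approx(-1.0 / np.log(10))

    def test_platform_table_correlation_matches_published(self):
        """The 16 public platforms: logit-MR error vs log(samples) has
        r ~= -0.90."""
        pts = list(zip(mx.PLATFORM_SUMMARY["samples"],
                       mx.PLATFORM_SUMMARY["logit_mr_error"]))
        em = mx.fit_error_model(pts)
        assert em.pearson_r == pytest.approx(-0.90, abs=0.01)

    def test_predicts_error_near_one_at_500_samples(self):
        pts = list(zip(mx.PLATFORM_SUMMARY["samples"],
                       mx.PLATFORM_SUMMARY["logit_mr_error"]))
        em = mx.fit_error_model(pts)
        assert 0.8 <= em.predict(500) <= 1.2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            mx.fit_error_model([(10, 1.0), (10, 2.0), (10, 3.0)])
        with pytest.raises(ValueError):
            mx.fit_error_model([(10, 1.0), (20, 2.0)])
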