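import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetpop.distribution_fitting import Histogram, compute_sse
from hetpop.low_bin_search import (
    LowBinConfig,
    baseline_bin_rules,
    bootstrap_perturb,
    bootstrap_subsample,
    build_histogram,
    find_cutoff_bin,
    low_bin_search,
    optimal_bin_number,
    three_sd_outliers,
)
from hetpop.synthetic_populations import PopulationSpec, ReceptorSample, generate_population

from conftest import geometric_mean


def cutoff_oracle(counts: np.ndarray, fraction: float):
    """Exhaustive condition-checking scan, written independently."""
    largest = 0
    for i, c in enumerate(counts):
        if c > counts[largest]:
            largest = i
    limit = fraction * counts[largest]
    for j in range(len(counts)):
        if j <= largest:
            continue
        own = counts[j] < limit
        left = counts[j - 1] < limit
        right = (counts[j + 1] < limit) if j + 1 < len(counts) else True
        if own and left and right:
            return j
    return None


class TestBuildHistogram:
    def test_hand_counted_example(self):
        hist = build_histogram(np.array([1.0, 1.0, 1.0, 9.0, 9.0]), 2)
        np.testing.assert_allclose(hist.edges, [1.0, 5.0, 9.0])
        np.testing.assert_array_equal(hist.counts, [3, 2])

    def test_count_conservation(self, lognormal_sample):
        for k in (5, 37, 101):
            assert build_histogram(lognormal_sample, k).total == lognormal_sample.n

    def test_matches_per_value_scan_oracle(self):
        rng = np.random.default_rng(23)
        values = rng.lognormal(7.0, 0.8, size=3_000)
        k = 37
        hist = build_histogram(values, k)
        lo, hi = values.min(), values.max()
        width = (hi - lo) / k
        oracle = np.zeros(k, dtype=int)
        for v in values:  # right-open bins, last bin closed
            idx = min(int((v - lo) / width), k - 1)
            oracle[idx] += 1
        np.testing.assert_array_equal(hist.counts, oracle)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            build_histogram(np.full(10, 3.0), 5)

    def test_equal_widths_and_centers(self, lognormal_sample):
        hist = build_histogram(lognormal_sample, 11)
        widths = np.diff(hist.edges)
        np.testing.assert_allclose(widths, widths[0], rtol=1e-9)
        np.testing.assert_allclose(hist.centers, (hist.edges[:-1] + hist.edges[1:]) / 2)


class TestOptimalBinNumber:
    def test_matches_exhaustive_argmin_oracle(self):
        config = LowBinConfig(k_min=5, k_max=60)
        for seed in range(20):
            sample = generate_population(
                PopulationSpec("lognormal", 7.8, 0.6, 2_000, seed=seed)
            )
            from hetpop.distribution_fitting import fit_mle

            fit = fit_mle(sample, "lognormal")
            k_star, sse_by_k = optimal_bin_number(sample, "lognormal", config, fit=fit)
            # independent scan: recompute every SSE and take the first argmin
            oracle_best, oracle_sse = None, math.inf
            for k in range(config.k_min, config.k_max + 1):
                s = compute_sse(build_histogram(sample, k), fit)
                if s < oracle_sse:
                    oracle_best, oracle_sse = k, s
            assert k_star == oracle_best
            assert sse_by_k[k_star] == pytest.approx(oracle_sse, rel=1e-12)

    def test_k_star_within_range(self, lognormal_sample):
        config = LowBinConfig(k_min=5, k_max=80)
        k_star, _ = optimal_bin_number(lognormal_sample, "lognormal", config)
        assert 5 <= k_star <= 80

    def test_tie_breaks_to_smallest_k(self, monkeypatch):
        import importlib

        # the package re-exports a function named like the module, so fetch
        # the module object explicitly
        lbs = importlib.import_module("hetpop.low_bin_search")
        monkeypatch.setattr(lbs, "compute_sse", lambda hist, fit: 1.0)
        sample = generate_population(PopulationSpec("lognormal", 7.8, 0.6, 500, seed=0))
        from hetpop.distribution_fitting import fit_mle

        fit = fit_mle(sample, "lognormal")
        k_star, _ = lbs.optimal_bin_number(sample, "lognormal", LowBinConfig(k_min=5, k_max=30), fit=fit)
        assert k_star == 5


class TestFindCutoffBin:
    def test_paper_worked_example_threshold(self):
        # largest bin 500 cells at the 1% criterion -> must have < 5 cells
        counts = np.array([500, 100, 50, 4, 3, 2])
        hist = Histogram(edges=np.arange(7.0), counts=counts)
        j = find_cutoff_bin(hist, LowBinConfig())
        threshold = LowBinConfig().eligibility_fraction * 500
        assert threshold == 5.0
        # index 3 fails (left neighbor 50 >= 5); index 4 is the first whose
        # own count and both neighbors are all < 5
        assert j == 4

    def test_hand_checked_scan(self):
        counts = np.array([10, 500, 40, 3, 2, 1])
        hist = Histogram(edges=np.arange(7.0), counts=counts)
        # index 3 fails: left neighbor 40 >= 5; index 4 qualifies
        assert find_cutoff_bin(hist, LowBinConfig()) == 4

    def test_no_bin_qualifies(self):
        hist = Histogram(edges=np.arange(4.0), counts=np.array([100, 90, 80]))
        assert find_cutoff_bin(hist, LowBinConfig()) is None

    def test_last_bin_missing_neighbor_counts_as_zero(self):
        counts = np.array([500, 100, 4, 2])
        hist = Histogram(edges=np.arange(5.0), counts=counts)
        assert find_cutoff_bin(hist, LowBinConfig()) == 3

    def test_oracle_equivalence_1000_random_histograms(self):
        rng = np.random.default_rng(99)
        config = LowBinConfig()
        for _ in range(1_000):
            k = int(rng.integers(3, 60))
            counts = rng.integers(0, 500, size=k)
            counts[rng.integers(0, k)] += 500  # ensure a clear largest bin
            hist = Histogram(edges=np.arange(float(k + 1)), counts=counts)
            assert find_cutoff_bin(hist, config) == cutoff_oracle(
                counts, config.eligibility_fraction
            )

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=2000), min_size=3, max_size=50),
        fraction=st.floats(min_value=0.001, max_value=0.2),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_property(self, counts, fraction):
        counts = np.asarray(counts)
        hist = Histogram(edges=np.arange(float(counts.size + 1)), counts=counts)
        config = LowBinConfig(eligibility_fraction=fraction)
        assert find_cutoff_bin(hist, config) == cutoff_oracle(counts, fraction)


class TestLowBinSearch:
    def test_planted_outliers_removed(self, contaminated_sample):
        result = low_bin_search(contaminated_sample)
        removed = ~result.kept_mask
        planted = contaminated_sample.components == 1
        assert removed[planted].mean() >= 0.90
        assert removed[~planted].mean() <= 0.01

    def test_no_sparse_tail_means_no_cutoff(self):
        rng = np.random.default_rng(31)
        sample = ReceptorSample(rng.uniform(1_000.0, 2_000.0, size=5_000))
        result = low_bin_search(sample)
        assert result.cutoff_bin_index is None
        assert result.removed_count == 0
        assert result.kept_mask.all()

    def test_deterministic(self, contaminated_sample):
        r1 = low_bin_search(contaminated_sample)
        r2 = low_bin_search(contaminated_sample)
        assert r1.optimal_k == r2.optimal_k
        assert r1.cutoff_value == r2.cutoff_value
        np.testing.assert_array_equal(r1.kept_mask, r2.kept_mask)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 100"):
            low_bin_search(ReceptorSample(np.linspace(1.0, 10.0, 50)))

    def test_conservation(self, contaminated_sample):
        result = low_bin_search(contaminated_sample)
        assert result.removed_count + int(result.kept_mask.sum()) == contaminated_sample.n

    def test_never_removes_left_tail(self, contaminated_sample):
        result = low_bin_search(contaminated_sample)
        if result.cutoff_value is not None:
            removed_values = contaminated_sample.values[~result.kept_mask]
            assert removed_values.min() >= result.cutoff_value

    def test_cutoff_monotonic_in_fraction(self, contaminated_sample):
        removed = [
            low_bin_search(
                contaminated_sample, LowBinConfig(eligibility_fraction=f)
            ).removed_count
            for f in (0.002, 0.01, 0.05)
        ]
        assert removed[0] <= removed[1] <= removed[2]


class TestThreeSdOutliers:
    def test_far_value_removed(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0.0, 1.0, size=1_000)
        spike = values.mean() + 4.5 * values.std()
        values = np.append(values, spike)
        mask = three_sd_outliers(values)
        assert not mask[-1]

    def test_all_equal_removes_nothing(self):
        assert three_sd_outliers(np.full(10, 5.0)).all()

    def test_matches_threshold_oracle(self):
        rng = np.random.default_rng(41)
        values = rng.lognormal(7.0, 1.0, size=2_000)
        mask = three_sd_outliers(values)
        oracle = np.array([v <= values.mean() + 3 * values.std() for v in values])
        np.testing.assert_array_equal(mask, oracle)

    def test_conservation(self):
        values = np.random.default_rng(4).lognormal(7.0, 1.0, size=500)
        mask = three_sd_outliers(values)
        assert mask.sum() + (~mask).sum() == values.size


class TestBaselineBinRules:
    def test_matlab_rule_matches_discussion_figure(self):
        assert baseline_bin_rules(29_584, "matlab_sqrt") == 172

    def test_matlab_rule_n1(self):
        assert baseline_bin_rules(1, "matlab_sqrt") == 1

    def test_palisade_configurable_exponent(self):
        for n, exp in [(29_584, 1 / 3), (50_000, 0.25), (1_000, 0.5)]:
            assert baseline_bin_rules(n, "palisade", exp) == math.floor(n**exp)

    def test_unknown_rule(self):
        with pytest.raises(ValueError, match="unknown rule"):
            baseline_bin_rules(100, "sturges")


@pytest.fixture(scope="module")
def boot_sample():
    return generate_population(PopulationSpec("lognormal", 7.0, 0.7, 4_000, seed=55))


class TestBootstrap:
    def test_full_size_subsample_reproduces_full_data(self, boot_sample):
        result = bootstrap_subsample(boot_sample, [boot_sample.n], trials=1, seed=1)
        full = low_bin_search(boot_sample)
        gm_full = geometric_mean(full.kept_values(boot_sample))
        assert result.trials[0]["geometric_mean"] == pytest.approx(gm_full, rel=1e-12)

    def test_subsample_reproducible(self, boot_sample):
        a = bootstrap_subsample(boot_sample, [500], trials=3, seed=5)
        b = bootstrap_subsample(boot_sample, [500], trials=3, seed=5)
        assert a.trials == b.trials

    def test_oversize_rejected(self, boot_sample):
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_subsample(boot_sample, [boot_sample.n + 1], trials=1, seed=0)

    def test_trial_count(self, boot_sample):
        result = bootstrap_subsample(boot_sample, [500, 1_000], trials=4, seed=2)
        assert len(result.trials) == 8

    def test_perturb_size_zero_identical_to_plain(self, boot_sample):
        result = bootstrap_perturb(boot_sample, [0], trials=1, seed=3)
        full = low_bin_search(boot_sample)
        gm_full = geometric_mean(full.kept_values(boot_sample))
        assert result.trials[0]["geometric_mean"] == pytest.approx(gm_full, rel=1e-12)
        assert result.trials[0]["cutoff_value"] == full.cutoff_value

    def test_perturb_dataset_gm_bounded_by_factor(self, boot_sample):
        # GM of a set with a subset scaled by 1.2 is <= 1.2 * GM (algebraic)
        gm0 = geometric_mean(boot_sample.values)
        result = bootstrap_perturb(boot_sample, [500, 2_000], trials=3, seed=4)
        for trial in result.trials:
            assert trial["dataset_geometric_mean"] <= 1.2 * gm0 + 1e-9
            assert trial["dataset_geometric_mean"] >= gm0 - 1e-9

    def test_perturb_count_exact(self, boot_sample):
        # exactly `size` values differ from the original
        rng = np.random.default_rng(6)
        size = 250
        idx = rng.choice(boot_sample.n, size=size, replace=False)
        perturbed = boot_sample.values.copy()
        perturbed[idx] *= 1.2
        assert int((perturbed != boot_sample.values).sum()) == size
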