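import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from carescape.geodetector import (
    METHODS,
    StratifiedSample,
    _jenks_breaks,
    discretize,
    interaction_detect,
    interaction_type,
    optimize_discretization,
    q_significance,
    q_statistic,
    run_factor_detection,
)
from carescape.synthetic_data import SyntheticConfig, simulate_city_table


def sample(y, labels):
    return StratifiedSample.from_labels(np.asarray(y, float), np.asarray(labels))


class TestQStatistic:
    def test_hand_variance_decomposition(self):
        # y 1..6 in two strata: sigma^2 = 35/12, within SS = 4, q = 1 - 4/17.5
        s = sample([1, 2, 3, 4, 5, 6], list("AAABBB"))
        assert q_statistic(s) == pytest.approx(1 - 4 / 17.5, abs=1e-12)

    def test_perfect_stratification(self):
        s = sample([2, 2, 5, 5, 9], list("AABBC"))
        assert q_statistic(s) == 1.0

    def test_single_stratum_explains_nothing(self):
        s = sample([1, 4, 2, 8], ["A"] * 4)
        assert q_statistic(s) == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            q_statistic(sample([3, 3, 3, 3], list("AABB")))

    def test_equals_anova_oracle_on_random_instances(self, rng):
        """q == 1 - SSW/SST by an independent groupby decomposition, 500 draws."""
        for _ in range(500):
            n = int(rng.integers(5, 60))
            m = int(rng.integers(2, 6))
            y = rng.normal(size=n)
            labels = rng.integers(0, m, size=n)
            sst = float(np.sum((y - y.mean()) ** 2))
            ssw = sum(
                float(np.sum((y[labels == g] - y[labels == g].mean()) ** 2))
                for g in np.unique(labels)
            )
            assert q_statistic(sample(y, labels)) == pytest.approx(
                1 - ssw / sst, abs=1e-9
            )

    @given(
        y=st.lists(st.floats(-100, 100), min_size=4, max_size=30),
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance(self, y, a, b):
        y = np.asarray(y)
        labels = np.arange(len(y)) % 3
        if np.var(y) == 0 or np.var(a * y + b) == 0:
            return
        q0 = q_statistic(sample(y, labels))
        q1 = q_statistic(sample(a * y + b, labels))
        assert q1 == pytest.approx(q0, abs=1e-9)


class TestQSignificance:
    def test_f_transform_matches_one_way_anova(self, rng):
        # (N-m)/(m-1) * q/(1-q) is identically the ANOVA F statistic
        y = rng.normal(size=30)
        labels = rng.integers(0, 3, size=30)
        s = sample(y, labels)
        q = q_statistic(s)
        f_geo = (s.N - s.m) / (s.m - 1) * q / (1 - q)
        groups = [y[labels == g] for g in np.unique(labels)]
        assert f_geo == pytest.approx(stats.f_oneway(*groups).statistic, abs=1e-9)

    def test_zero_noncentrality_reduces_to_central_f(self):
        # equal stratum means with m=2, equal sizes: lambda = 0 and both the
        # noncentral test and plain ANOVA give the same p-value
        y = np.array([1.0, 2.0, 3.0, 0.0, 2.0, 4.0])
        labels = np.array(list("AAABBB"))
        p = q_significance(sample(y, labels))
        assert p == pytest.approx(stats.f_oneway(y[:3], y[3:]).pvalue, abs=1e-9)

    def test_monotone_in_q(self):
        # stronger separation of stratum means drives p down
        base = np.array([0.0, 0.1, -0.1, 0.0, 0.1, -0.1] * 5)
        labels = (np.arange(30) % 2).astype(str)
        shift = np.where(labels == "0", 1.0, -1.0)
        ps = [
            q_significance(sample(base + c * shift, labels)) for c in (0.2, 0.6, 1.5, 4.0)
        ]
        assert all(b <= a for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-6

    def test_no_residual_dof_rejected(self):
        with pytest.raises(ValueError):
            q_significance(sample([1.0, 2.0], ["A", "B"]))


class TestDiscretize:
    def test_jenks_two_clusters(self):
        x = [1, 2, 3, 10, 11, 12]
        scheme = discretize(x, "natural_breaks", 2)
        labels = scheme.assign(x)
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_jenks_equals_exhaustive_enumeration(self, rng):
        """DP solution matches brute-force over all partitions, 200 vectors."""

        def brute(x_sorted, k):
            n = len(x_sorted)
            best = np.inf
            for cuts in itertools.combinations(range(1, n), k - 1):
                bounds = [0, *cuts, n]
                ssd = sum(
                    float(np.var(x_sorted[a:b]) * (b - a))
                    for a, b in zip(bounds, bounds[1:])
                )
                best = min(best, ssd)
            return best

        for _ in range(200):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, min(5, n)))
            x = np.sort(rng.normal(size=n))
            breaks = _jenks_breaks(x, k)
            labels = np.searchsorted(breaks, x)
            ssd_dp = sum(
                float(np.var(x[labels == g]) * np.sum(labels == g))
                for g in np.unique(labels)
            )
            assert ssd_dp == pytest.approx(brute(x, k), abs=1e-9)

    def test_quantile_equal_counts(self):
        x = np.arange(14, dtype=float)
        scheme = discretize(x, "quantile", 7)
        counts = np.bincount(scheme.assign(x))
        assert counts.tolist() == [2] * 7

    def test_std_dev_symmetric_breaks(self):
        x = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        scheme = discretize(x, "std_dev", 3)
        assert np.allclose(scheme.breaks, [-scheme.breaks[1], scheme.breaks[1]])

    def test_geometric_interval_widths_in_geometric_progression(self):
        x = np.array([1.0, 2.0, 5.0, 20.0, 81.0])
        scheme = discretize(x, "geometric_interval", 4)
        widths = np.diff(np.concatenate([[x.min()], scheme.breaks, [x.max()]]))
        ratios = widths[1:] / widths[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            discretize([1.0, 2.0, 3.0], "quantile", 5)
        with pytest.raises(ValueError, match="constant"):
            discretize([2.0, 2.0, 2.0], "natural_breaks", 2)
        with pytest.raises(ValueError, match="unknown"):
            discretize([1.0, 2.0, 3.0], "fisher", 2)


class TestOptimizeDiscretization:
    def test_noiseless_step_function_reaches_q_of_one(self):
        x = np.repeat([1.0, 5.0, 9.0], 5) + np.tile([0.0, 0.1, -0.1, 0.05, -0.05], 3)
        y = np.repeat([10.0, 20.0, 40.0], 5)
        scheme, res = optimize_discretization(x, y, k_range=(3, 5))
        assert res.q == pytest.approx(1.0)

    def test_returned_q_dominates_every_candidate(self, rng):
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        _, res = optimize_discretization(x, y, k_range=(3, 6))
        for method in METHODS:
            for k in range(3, 7):
                try:
                    scheme = discretize(x, method, k)
                except ValueError:
                    continue
                labels = scheme.assign(x)
                if len(np.unique(labels)) < 2:
                    continue
                q = q_statistic(sample(y, labels))
                assert res.q >= q - 1e-12

    def test_k_clipped_to_distinct_values(self, rng):
        x = np.tile([1.0, 2.0, 3.0, 4.0], 10)
        y = x + rng.normal(0, 0.1, 40)
        scheme, _ = optimize_discretization(x, y, k_range=(3, 10))
        assert scheme.k <= 4


class TestInteraction:
    @pytest.mark.parametrize(
        "q1,q2,q12,expected",
        [
            (0.3, 0.4, 0.9, "nonlinear_enhancement"),
            (0.3, 0.4, 0.5, "dual_factor_enhancement"),
            (0.3, 0.4, 0.7, "independent"),
            (0.3, 0.4, 0.35, "single_factor_nonlinear_weakening"),
            (0.3, 0.4, 0.1, "nonlinear_weakening"),
        ],
    )
    def test_typology_rules(self, q1, q2, q12, expected):
        assert interaction_type(q1, q2, q12) == expected

    def test_self_overlay_q_unchanged(self, rng):
        y = rng.normal(size=30)
        labels = rng.integers(0, 4, 30)
        res = interaction_detect(y, labels, labels)
        assert res.q12 == pytest.approx(res.q1, abs=1e-12)

    def test_refinement_monotonicity(self, rng):
        """Overlaying stratifications never lowers q below either factor."""
        for _ in range(200):
            n = int(rng.integers(6, 50))
            y = rng.normal(size=n)
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 3, n)
            res = interaction_detect(y, a, b)
            assert res.q12 >= max(res.q1, res.q2) - 1e-12

    def test_exact_overlays_cannot_weaken(self, rng):
        # consequence of refinement monotonicity: the two weakening types
        # are unreachable when q12 comes from a true overlay
        for seed in range(50):
            r = np.random.default_rng(seed)
            y = r.normal(size=30)
            res = interaction_detect(y, r.integers(0, 3, 30), r.integers(0, 3, 30))
            assert res.type not in (
                "nonlinear_weakening",
                "single_factor_nonlinear_weakening",
            ) or res.q12 == pytest.approx(max(res.q1, res.q2), abs=1e-9)


class TestRunFactorDetection:
    def test_identical_covariates_get_identical_results(self):
        cities, _ = simulate_city_table(
            SyntheticConfig(seed=3, table_params={"m_strata": 4, "n_units": 60, "q_target": 0.7})
        )
        for c in cities:
            c.covariates["X1"] = c.covariates["X2"]
        factors, _ = run_factor_detection(cities, factors=["X1", "X2"])
        f = {r.factor: r for r in factors}
        assert f["X1"].q == f["X2"].q
        assert f["X1"].scheme.to_dict() == f["X2"].scheme.to_dict()

    def test_planted_factor_ranks_first_single_run(self):
        cities, truth = simulate_city_table(
            SyntheticConfig(seed=11, table_params={"m_strata": 5, "n_units": 140, "q_target": 0.9})
        )
        factors, interactions = run_factor_detection(cities)
        assert factors[0].factor == truth["dominant"]
        assert factors[0].q > 0.8
        assert factors[0].p < 0.01
        assert len(interactions) == 9 * 8 // 2

    def test_decoy_only_table_keeps_q_low(self):
        hits = 0
        for seed in range(10):
            cities, _ = simulate_city_table(
                SyntheticConfig(seed=seed, table_params={"m_strata": 5, "n_units": 140, "q_target": 0.0})
            )
            factors, _ = run_factor_detection(cities, k_range=(3, 10))
            hits += factors[0].q < 0.5
        assert hits >= 9

    def test_constant_response_rejected(self):
        cities, _ = simulate_city_table(
            SyntheticConfig(seed=5, table_params={"m_strata": 3, "n_units": 30, "q_target": 0.5})
        )
        for c in cities:
            c.facility_count = 7
        with pytest.raises(ValueError, match="variance"):
            run_factor_detection(cities)
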