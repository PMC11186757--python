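"""Effect-size machinery: pooled SD, t intervals, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pbudget import (
    DataError,
    DomainError,
    bootstrap_effect,
    ci_eff,
    effect_estimate,
    pooled_sd,
)

sds = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


class TestPooledSD:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.5, 0.5, 0.5), (0.03, 0.04, 0.035355339059327376), (0.0, 0.0, 0.0)],
    )
    def test_examples(self, a, b, expected):
        assert pooled_sd(a, b) == pytest.approx(expected)

    @given(a=sds, b=sds)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_degree_one_homogeneous(self, a, b):
        assert pooled_sd(a, b) == pytest.approx(pooled_sd(b, a))
        assert pooled_sd(3 * a, 3 * b) == pytest.approx(3 * pooled_sd(a, b), rel=1e-9)

    def test_rejects_negative(self):
        with pytest.raises(DomainError):
            pooled_sd(-1.0, 1.0)


class TestCIEff:
    def test_against_t_table(self):
        # t_{0.975, 4} = 2.7764 from standard tables; half-width = t * sqrt(2/3)
        assert ci_eff(1.0, 3, 3, 95) == pytest.approx(2.7764 * np.sqrt(2 / 3), abs=2e-4)

    def test_width_increases_with_level(self):
        widths = [ci_eff(1.0, 3, 3, level) for level in (75, 85, 95)]
        assert widths[0] < widths[1] < widths[2]

    def test_zero_sd_gives_zero_width(self):
        assert ci_eff(0.0, 3, 3, 95) == 0.0

    def test_normal_limit_at_large_df(self):
        n = 500_001  # df = 10^6
        expected = stats.norm.ppf(0.975) * np.sqrt(2.0 / n)
        assert ci_eff(1.0, n, n, 95) == pytest.approx(expected, rel=1e-5)

    def test_rejects_degenerate_df(self):
        with pytest.raises(DomainError):
            ci_eff(1.0, 1, 1, 95)


class TestEffectEstimate:
    def test_identical_arms_give_zero_centred_cis(self):
        arm = np.array([1.0, 2.0, 3.0])
        est = effect_estimate(arm, arm)
        assert est.delta == 0.0
        for lo, hi in est.ci.values():
            assert lo == pytest.approx(-hi)
        assert not est.significant(95)

    @pytest.mark.parametrize(
        "ambient_mean, delta, expected_rel",
        [(0.39, 0.033, 8.46), (0.71, 0.043, 6.06), (2.718, -0.3, -11.04)],
    )
    def test_relative_effect_matches_reported_arithmetic(
        self, ambient_mean, delta, expected_rel
    ):
        spread = np.array([-0.01, 0.0, 0.01])
        est = effect_estimate(ambient_mean + spread, ambient_mean + delta + spread)
        assert est.relative_pct == pytest.approx(expected_rel, abs=0.05)

    def test_relative_effect_invariant_under_common_rescaling(self):
        amb = np.array([1.0, 1.2, 0.9])
        ele = np.array([1.1, 1.25, 1.0])
        a = effect_estimate(amb, ele)
        b = effect_estimate(1e3 * amb, 1e3 * ele)
        assert a.relative_pct == pytest.approx(b.relative_pct)

    def test_sem_is_pooled_sd_times_sqrt_term(self):
        amb = np.array([1.0, 2.0, 3.0])
        ele = np.array([2.0, 2.5, 4.5])
        est = effect_estimate(amb, ele)
        assert est.sem == pytest.approx(est.sd_eff * np.sqrt(2.0 / 3.0))

    def test_requires_two_plots(self):
        with pytest.raises(DataError):
            effect_estimate(np.array([1.0]), np.array([1.0, 2.0]))


class TestBootstrap:
    def test_constant_arms_give_degenerate_interval(self):
        amb = np.full(3, 2.0)
        ele = np.full(3, 2.0)
        boot = bootstrap_effect(amb, ele, n_resamples=200, seed=0)
        assert np.all(boot.deltas == 0.0)
        assert boot.ci[95] == (0.0, 0.0)

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(1)
        amb, ele = rng.normal(1, 0.1, 5), rng.normal(1.2, 0.1, 5)
        a = bootstrap_effect(amb, ele, n_resamples=300, seed=7)
        b = bootstrap_effect(amb, ele, n_resamples=300, seed=7)
        assert np.array_equal(a.deltas, b.deltas)
        assert a.ci == b.ci

    def test_percentile_bounds_inside_resampled_range(self):
        rng = np.random.default_rng(2)
        amb, ele = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        boot = bootstrap_effect(amb, ele, n_resamples=500, seed=3)
        lo, hi = boot.ci[95]
        assert boot.deltas.min() <= lo < hi <= boot.deltas.max()
        w75 = boot.ci[75][1] - boot.ci[75][0]
        w95 = boot.ci[95][1] - boot.ci[95][0]
        assert w75 <= w95

    def test_midpoint_agrees_with_t_interval_for_large_balanced_samples(self):
        rng = np.random.default_rng(4)
        amb = rng.normal(10.0, 1.0, 200)
        ele = rng.normal(11.0, 1.0, 200)
        boot = bootstrap_effect(amb, ele, n_resamples=2000, seed=5)
        est = effect_estimate(amb, ele)
        lo, hi = boot.ci[95]
        midpoint = 0.5 * (lo + hi)
        # location (not width) agreement, within a fraction of the resampling SD
        assert midpoint == pytest.approx(est.delta, abs=0.3 * boot.delta_sd)

    def test_nominal_coverage_for_normal_arms_at_n50(self):
        """Simulation oracle: with true delta 1, sd 0.1, n = 50 per arm, the
        percentile 95% interval contains the truth in ~95% of repetitions
        (binomial Monte-Carlo tolerance)."""
        rng = np.random.default_rng(6)
        n_reps, hits = 400, 0
        for r in range(n_reps):
            amb = rng.normal(0.0, 0.1, 50)
            ele = rng.normal(1.0, 0.1, 50)
            boot = bootstrap_effect(amb, ele, n_resamples=400,
                                    seed=int(rng.integers(2**31)))
            lo, hi = boot.ci[95]
            hits += int(lo <= 1.0 <= hi)
        coverage = hits / n_reps
        se = np.sqrt(0.95 * 0.05 / n_reps)
        assert abs(coverage - 0.95) < 3 * se + 0.005
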