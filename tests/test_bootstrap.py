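"""Bias-corrected percentile bootstrap: resampling, intervals, significance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import gelquant as gq
from gelquant.bootstrap import (
    bc_percentile_ci,
    bonferroni_level,
    bootstrap_statistic,
    pairwise_significance,
)
from gelquant.errors import ConfigError, ValidationError


def exhaustive_resample_means(values) -> np.ndarray:
    """All n**n equally likely resample means of a small sample."""
    values = list(values)
    n = len(values)
    return np.array(
        [np.mean(c) for c in itertools.product(values, repeat=n)]
    )


class TestBootstrapStatistic:
    def test_constant_values_give_constant_means(self):
        res = bootstrap_statistic([], [3.0, 3.0, 3.0, 3.0], B=50, seed=0)
        assert np.all(res == 3.0)

    def test_difference_of_constants(self):
        res = bootstrap_statistic([1.0] * 4, [3.0] * 4, B=50, seed=0)
        assert np.all(res == 2.0)

    def test_empty_group_contributes_zero_mean(self):
        res = bootstrap_statistic([10.0, 11.0, 10.0, 11.0], [], B=200, seed=0)
        assert np.all(res < 0)
        assert res.min() >= -11.0 and res.max() <= -10.0

    def test_both_groups_empty_is_an_error(self):
        with pytest.raises(ValidationError):
            bootstrap_statistic([], [], B=10, seed=0)

    def test_deterministic_given_seed(self):
        a = bootstrap_statistic([1, 2, 3, 4], [2, 3, 4, 5], B=100, seed=42)
        b = bootstrap_statistic([1, 2, 3, 4], [2, 3, 4, 5], B=100, seed=42)
        assert np.array_equal(a, b)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """For n=4 the 256-resample distribution is enumerable; the MC
        sample at B=20000 must agree in Kolmogorov distance."""
        values = [1.0, 2.0, 3.0, 4.0]
        exact = exhaustive_resample_means(values)
        mc = bootstrap_statistic([], values, B=20_000, seed=1)
        ks = stats.ks_2samp(mc, exact).statistic
        assert ks < 0.03


class TestBCPercentileCI:
    def test_symmetric_distribution_reduces_to_plain_percentile(self):
        # exactly half the resamples strictly below the observed value -> z0 = 0
        res = np.concatenate([np.arange(1, 1001), -np.arange(1, 1001)]).astype(float)
        ci = bc_percentile_ci(res, observed=0.0, confidence=0.95)
        assert ci.z0 == 0.0
        assert ci.lower == np.quantile(res, 0.025)
        assert ci.upper == np.quantile(res, 0.975)

    def test_degenerate_distribution_collapses_to_point(self):
        ci = bc_percentile_ci(np.full(100, 7.0), observed=7.0, confidence=0.95)
        assert (ci.lower, ci.upper) == (7.0, 7.0)

    def test_extreme_proportion_is_clamped(self):
        # observed above every resample: proportion clamps to 1 - 1/(2B)
        res = np.arange(100, dtype=float)
        ci = bc_percentile_ci(res, observed=1e9, confidence=0.95)
        assert np.isfinite(ci.z0)
        assert ci.z0 == pytest.approx(stats.norm.ppf(1 - 1 / 200))
        assert ci.lower <= ci.upper

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        res=st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=200),
        q=st.floats(0.05, 0.95),
    )
    def test_interval_is_ordered_and_within_resample_range(self, res, q):
        res = np.asarray(res)
        observed = float(np.quantile(res, q))
        ci = bc_percentile_ci(res, observed, confidence=0.95)
        assert ci.lower <= ci.upper
        assert res.min() <= ci.lower and ci.upper <= res.max()

    def test_small_sample_coverage_is_below_nominal_but_usable(self):
        """Unadjusted 95% BC intervals for a mean at n=4 under-cover --
        the classic small-n percentile-bootstrap bias; measured ~0.80."""
        rng = np.random.default_rng(12345)
        cover = 0
        n_runs = 2000
        for _ in range(n_runs):
            v = rng.normal(10, 2, 4)
            res = bootstrap_statistic([], v, B=2000, seed=rng)
            ci = bc_percentile_ci(res, v.mean(), 0.95)
            cover += ci.lower <= 10 <= ci.upper
        assert 0.75 < cover / n_runs < 0.97


class TestBonferroni:
    @pytest.mark.parametrize(
        "confidence,m,expected",
        [
            (0.95, 1, 0.95),
            (0.95, 3, 0.95 + 0.05 * 2 / 3),
            (0.95, 78 * 3, 1 - 0.05 / 234),
        ],
    )
    def test_adjusted_level(self, confidence, m, expected):
        assert bonferroni_level(confidence, m) == pytest.approx(expected, abs=1e-12)

    def test_invalid_family_size(self):
        with pytest.raises(ConfigError):
            bonferroni_level(0.95, 0)


def _paired_table(x_values, y_values):
    """2-group, 4-replicate table holding a single spot."""
    gels = [f"X_{i}" for i in range(1, 5)] + [f"Y_{i}" for i in range(1, 5)]
    row = list(x_values) + list(y_values)
    table = gq.SpotVolumeTable(pd.DataFrame([row], index=["s"], columns=gels))
    design = gq.ExperimentDesign.from_mapping(
        {g: g.split("_")[0] for g in gels}
    )
    return table, design


@pytest.mark.parametrize("mode", ["group_ci_overlap", "difference_ci"])
class TestPairwiseSignificance:
    def test_identical_constant_groups_not_significant(self, mode):
        table, design = _paired_table([5.0] * 4, [5.0] * 4)
        presence = gq.call_presence(table, design)
        (r,) = pairwise_significance(
            table, design, presence, gq.BootstrapSettings(mode=mode, seed=0)
        )
        assert not r.significant
        assert r.dv == 0.0

    def test_absent_group_is_significant_with_negative_dv(self, mode):
        table, design = _paired_table([10.0, 11.0, 10.0, 11.0], [np.nan] * 4)
        presence = gq.call_presence(table, design)
        (r,) = pairwise_significance(
            table, design, presence, gq.BootstrapSettings(mode=mode, seed=0)
        )
        assert r.significant
        assert not r.shared
        assert r.mean_y == 0.0
        assert r.dv == pytest.approx(-10.5)

    def test_clear_shift_is_significant(self, mode):
        table, design = _paired_table([10, 11, 10, 11], [30, 31, 30, 31])
        presence = gq.call_presence(table, design)
        (r,) = pairwise_significance(
            table, design, presence, gq.BootstrapSettings(mode=mode, seed=0)
        )
        assert r.significant
        assert r.dv == pytest.approx(20.0)

    def test_deterministic_and_order_invariant(self, mode):
        rng = np.random.default_rng(3)
        gels = [f"X_{i}" for i in range(1, 5)] + [f"Y_{i}" for i in range(1, 5)]
        vols = pd.DataFrame(
            rng.lognormal(3, 0.5, size=(20, 8)),
            index=[f"s{i}" for i in range(20)],
            columns=gels,
        )
        table = gq.SpotVolumeTable(vols)
        design = gq.ExperimentDesign.from_mapping(
            {g: g.split("_")[0] for g in gels}
        )
        presence = gq.call_presence(table, design)
        settings_ = gq.BootstrapSettings(mode=mode, B=500, seed=9)
        first = pairwise_significance(table, design, presence, settings_)
        again = pairwise_significance(table, design, presence, settings_)
        shuffled_ids = list(vols.index[::-1])
        shuffled = pairwise_significance(
            table.subset_spots(shuffled_ids), design,
            presence.subset(shuffled_ids), settings_,
        )
        by_id = {r.spot_id: r for r in shuffled}
        for r1, r2 in zip(first, again):
            assert (r1.spot_id, r1.significant, r1.dv) == (r2.spot_id, r2.significant, r2.dv)
            r3 = by_id[r1.spot_id]
            assert r1.significant == r3.significant
            assert r1.dv == r3.dv


class TestPairwiseSemantics:
    def test_stray_detections_below_threshold_count_as_absent(self):
        table, design = _paired_table([10, 11, 10, 11], [9.0, 9.5, np.nan, np.nan])
        presence = gq.call_presence(table, design, min_present_replicates=3)
        (r,) = pairwise_significance(table, design, presence)
        assert not r.shared
        assert r.mean_y == 0.0  # stray values excluded from the absent group

    def test_spot_absent_in_both_groups_of_a_pair_is_not_applicable(self):
        gels = [f"{g}_{i}" for g in ("X", "Y", "Z") for i in range(1, 5)]
        nan = np.nan
        row = [nan] * 8 + [5.0, 5.5, 6.0, 5.2]  # only group Z
        table = gq.SpotVolumeTable(pd.DataFrame([row], index=["s"], columns=gels))
        design = gq.ExperimentDesign.from_mapping({g: g.split("_")[0] for g in gels})
        presence = gq.call_presence(table, design)
        results = {(r.group_x, r.group_y): r for r in
                   pairwise_significance(table, design, presence)}
        assert not results[("X", "Y")].applicable
        assert not results[("X", "Y")].significant
        assert results[("X", "Z")].applicable and results[("X", "Z")].significant

    def test_larger_true_shift_never_loses_significance(self):
        """Monotonicity in difference mode: growing the mean shift (same
        seed) keeps the interval on the same side of zero."""
        x = np.array([10.0, 12.0, 9.0, 11.0])
        base_y = np.array([13.0, 15.0, 12.0, 14.0])
        was_significant = False
        for delta in [0.0, 2.0, 5.0, 10.0, 50.0]:
            y = base_y + delta
            dv = y.mean() - x.mean()
            res = bootstrap_statistic(x, y, B=2000, seed=7)
            ci = bc_percentile_ci(res, dv, bonferroni_level(0.95, 3))
            significant = ci.lower > 0 or ci.upper < 0
            if was_significant:
                assert significant
            was_significant = was_significant or significant
        assert was_significant

    def test_family_spots_pairs_is_more_conservative(self):
        rng = np.random.default_rng(5)
        gels = [f"X_{i}" for i in range(1, 5)] + [f"Y_{i}" for i in range(1, 5)]
        vols = pd.DataFrame(
            rng.lognormal(3, 0.5, size=(40, 8)),
            index=[f"s{i}" for i in range(40)], columns=gels,
        )
        vols.iloc[:10, 4:] *= 3.0  # shift ten spots
        table = gq.SpotVolumeTable(vols)
        design = gq.ExperimentDesign.from_mapping({g: g.split("_")[0] for g in gels})
        presence = gq.call_presence(table, design)
        loose = pairwise_significance(
            table, design, presence, gq.BootstrapSettings(seed=1, family="pairs")
        )
        strict = pairwise_significance(
            table, design, presence,
            gq.BootstrapSettings(seed=1, family="spots_pairs"),
        )
        assert sum(r.significant for r in strict) <= sum(r.significant for r in loose)
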