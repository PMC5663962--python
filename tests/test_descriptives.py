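"""Interaction rates, per-focal statistics, Kruskal-Wallis, collinearity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from orphanbonds.descriptives import (
    age_differences,
    collinearity_screen,
    interaction_rate,
    kruskal_wallis,
    partner_rates_by_stratum,
    partners_per_time,
)
from orphanbonds.focal_data_io import (
    DyadObservation,
    build_dyad_table,
    focal_statuses,
)
from orphanbonds.population_model import PartnerCategoryFlags


def _dyad(y, gamma, stratum="orphan", activity="feeding", **flags):
    return DyadObservation("F1", "P1", activity, stratum, y, gamma,
                           np.zeros(8), PartnerCategoryFlags(**flags))


class TestInteractionRate:
    def test_rate_is_count_over_exposure(self):
        assert _dyad(0, 120.0).rate == 0.0
        assert _dyad(3, 10.0).rate == pytest.approx(0.3)

    def test_median_and_iqr_per_category_cell(self):
        dyads = [_dyad(y, 10.0, sister=True) for y in (1, 2, 3)]
        df = interaction_rate(dyads).set_index("category")
        assert df.loc["sister", "median"] == pytest.approx(0.2)
        assert df.loc["sister", "n_dyads"] == 3

    def test_multi_flag_dyad_contributes_to_every_matching_cell(self):
        dyads = [_dyad(1, 10.0, sister=True, age_mate=True)]
        df = interaction_rate(dyads)
        assert set(df["category"]) == {"sister", "age_mate"}

    def test_empty_category_is_absent_not_zero(self):
        df = interaction_rate([_dyad(1, 10.0, bull=True)])
        assert "mother" not in set(df["category"])

    def test_rescaling_exposure_divides_rates(self):
        dyads = [_dyad(y, g, calf=True) for y, g in ((1, 10.0), (4, 20.0), (2, 5.0))]
        scaled = [_dyad(d.y, 10 * d.gamma_minutes, calf=True) for d in dyads]
        a = interaction_rate(dyads).set_index("category")
        b = interaction_rate(scaled).set_index("category")
        assert b.loc["calf", "median"] == pytest.approx(a.loc["calf", "median"] / 10)


class TestPartnersPerTime:
    def test_unique_partners_over_minutes(self, registry, follows, interactions):
        # FOC: 60 feeding minutes, affiliative partners SIS and MOM
        assert partners_per_time(follows, interactions, "FOC", "feeding") == \
            pytest.approx(2 / 60.0)

    def test_no_interactions_gives_zero(self, registry, follows):
        assert partners_per_time(follows, [], "FOC", "feeding") == 0.0

    def test_repeat_events_with_one_partner_count_once(
            self, registry, follows, interactions):
        # SIS has two affiliative feeding events but counts as one partner
        rate = partners_per_time(follows, interactions, "FOC", "feeding")
        assert rate == pytest.approx(2 / 60.0)

    def test_zero_minute_focal_excluded(self, registry, follows, interactions):
        with pytest.raises(ValueError):
            partners_per_time(follows, interactions, "FOC2", "resting")
        statuses = focal_statuses(follows, registry)
        groups = partner_rates_by_stratum(follows, interactions, statuses, "resting")
        assert groups["orphan"] == []  # FOC2 has no resting follows


class TestAgeDifferences:
    def test_mean_difference_per_focal(self, registry, follows, interactions):
        statuses = focal_statuses(follows, registry)
        diffs = age_differences(follows, interactions, registry, statuses,
                                "feeding", "all_partners", window=(2013.0, 2015.0))
        # FOC (b. 2004): partners SIS (b. 2001) and MOM (b. 1988) -> mean of (3, 16)
        assert diffs["non_orphan"] == [pytest.approx(9.5)]
        # FOC2 (b. 2003): partner GM (b. 1970) -> 33
        assert diffs["orphan"] == [pytest.approx(33.0)]

    def test_restricted_filter_keeps_only_older_females(
            self, registry, follows, interactions):
        from orphanbonds.focal_data_io import InteractionEvent
        statuses = focal_statuses(follows, registry)
        evs = interactions + [InteractionEvent("f1", "BULL", "play")]
        all_p = age_differences(follows, evs, registry, statuses,
                                "feeding", "all_partners", window=(2013.0, 2015.0))
        older = age_differences(follows, evs, registry, statuses,
                                "feeding", "older_females_excluding_bulls",
                                window=(2013.0, 2015.0))
        # the bull lowers FOC's all-partner mean but is excluded from the other
        assert all_p["non_orphan"][0] < older["non_orphan"][0]
        assert older["non_orphan"] == [pytest.approx(9.5)]

    def test_focal_with_only_bull_partners_excluded_under_restriction(
            self, registry, follows):
        from orphanbonds.focal_data_io import InteractionEvent
        statuses = focal_statuses(follows, registry)
        evs = [InteractionEvent("f1", "BULL", "play")]
        older = age_differences(follows, evs, registry, statuses,
                                "feeding", "older_females_excluding_bulls",
                                window=(2013.0, 2015.0))
        assert older["non_orphan"] == [] and older["orphan"] == []


class TestKruskalWallis:
    def test_hand_computed_value_without_ties(self):
        # ranks {1,2,3} vs {4,5,6}: H = 12/42*(36/3+225/3) - 21 = 3.857...
        res = kruskal_wallis([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(3.857, abs=5e-4)
        assert res.df == 1

    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_guarded(self):
        res = kruskal_wallis([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_agrees_with_reference_implementation_on_random_data(self):
        """Tie-corrected H and chi-square p match scipy.stats.kruskal to 1e-10
        on 100 random datasets, with and without ties."""
        rng = np.random.default_rng(2024)
        for i in range(100):
            n1, n2 = rng.integers(2, 30, size=2)
            if i % 2:
                a = rng.integers(0, 8, size=n1).astype(float)  # heavy ties
                b = rng.integers(0, 8, size=n2).astype(float)
            else:
                a = rng.normal(size=n1)
                b = rng.normal(size=n2)
            if np.unique(np.concatenate([a, b])).size == 1:
                continue
            ours = kruskal_wallis(a, b)
            ref_h, ref_p = sps.kruskal(a, b)
            assert ours.statistic == pytest.approx(ref_h, abs=1e-10)
            if np.isnan(ref_p):  # scipy round-off: H = -eps -> p = nan
                assert ours.pvalue == 1.0
            else:
                assert ours.pvalue == pytest.approx(ref_p, abs=1e-10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.integers(-50, 50), min_size=2, max_size=15),
        b=st.lists(st.integers(-50, 50), min_size=2, max_size=15),
    )
    def test_invariant_under_strictly_monotone_transform(self, a, b):
        h1 = kruskal_wallis(a, b).statistic
        f = lambda xs: [np.exp(x / 10.0) for x in xs]  # strictly increasing, tie-preserving
        h2 = kruskal_wallis(f(a), f(b)).statistic
        assert h1 >= 0.0
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_exact_permutation_small_samples(self):
        # complete separation of {1,2} vs {3,4}: 1 extreme split out of C(4,2)=6
        res = kruskal_wallis([1.0, 2.0], [3.0, 4.0], method="permutation")
        assert res.pvalue == pytest.approx(2 / 6)  # both one-sided extremes

    def test_pvalue_in_unit_interval(self):
        res = kruskal_wallis([1.0, 5.0, 2.0], [4.0, 3.0, 6.0])
        assert 0.0 < res.pvalue <= 1.0


class TestCollinearityScreen:
    def test_identical_columns_flagged(self):
        x = np.random.default_rng(0).normal(size=(50, 1))
        X = np.hstack([x, x])
        rep = collinearity_screen(X, ["a", "b"])
        assert not rep.passed
        assert rep.flagged_pairs[0][:2] == ("a", "b")
        assert rep.max_abs_r == pytest.approx(1.0)

    def test_boundary_exactly_point_seven_not_flagged(self):
        rep = collinearity_screen(np.eye(2), ["a", "b"], threshold=1.0)
        assert rep.passed  # |r| = 1 is not > 1

    def test_zero_variance_column_reported_degenerate(self):
        X = np.array([[1.0, 0.0, 1.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        rep = collinearity_screen(X, ["const", "a", "b"])
        assert rep.degenerate == ("const",)
        assert "const" not in rep.corr.columns

    def test_balanced_orthogonal_indicators_not_flagged(self):
        X = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        rep = collinearity_screen(X, ["a", "b"])
        # perfectly anti-correlated two-level indicators ARE collinear
        assert rep.max_abs_r == pytest.approx(1.0)
        X2 = np.array([[1, 0], [0, 0], [0, 1], [0, 0]], dtype=float)
        rep2 = collinearity_screen(X2, ["a", "b"])
        assert rep2.passed


def test_rates_on_assembled_dyads(registry, follows, interactions):
    dyads = build_dyad_table(follows, interactions, registry, "feeding", "non_orphan")
    df = interaction_rate(dyads).set_index("category")
    # SIS: 2 events / 60 min -> 1/30 per minute, in the sister cell
    assert df.loc["sister", "median"] == pytest.approx(1 / 30)
    assert df.loc["mother", "median"] == pytest.approx(1 / 30)
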