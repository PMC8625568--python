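import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bedbench as bb
from bedbench.benchmark import (
    GapCategory,
    aggregate,
    classify_gap,
    estimates_from_published,
    gap_census,
    project_unit,
)
from bedbench.cmh_index import ScenarioValue, build_composite, optimal_scenario
from bedbench.exceptions import ValidationError
from bedbench.regression import build_design, fit_wls


class TestClassifyGap:
    @pytest.mark.parametrize(
        "actual, lo, hi, expected",
        [
            (18.15, 28.76, 42.07, GapCategory.UNDER_PROVIDED),  # low provision
            (28.45, 18.35, 28.86, GapCategory.WITHIN),  # inside the interval
            (114.3, 25.67, 37.2, GapCategory.OVER_PROVIDED),  # high provision
            (10.0, 10.0, 20.0, GapCategory.WITHIN),  # boundary tie: closed interval
            (20.0, 10.0, 20.0, GapCategory.WITHIN),
        ],
    )
    def test_examples(self, actual, lo, hi, expected):
        assert classify_gap(actual, lo, hi) is expected

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValidationError):
            classify_gap(5.0, 10.0, 10.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0.1, 200), st.floats(0.1, 200),
        st.floats(1, 100), st.floats(0.1, 100),
    )
    def test_monotone_in_actual(self, a1, a2, lo, width):
        """Raising the actual rate never moves the category downward."""
        hi = lo + width
        order = [GapCategory.UNDER_PROVIDED, GapCategory.WITHIN, GapCategory.OVER_PROVIDED]
        lo_a, hi_a = min(a1, a2), max(a1, a2)
        r1 = order.index(classify_gap(lo_a, lo, hi))
        r2 = order.index(classify_gap(hi_a, lo, hi))
        assert r2 >= r1


@pytest.fixture(scope="module")
def fitted():
    table = bb.generate(bb.GeneratorConfig(seed=9, sigma=0.003))
    comp = build_composite(table)
    X, y = build_design(table, comp)
    fm = fit_wls(X, y)
    return table, comp, fm


class TestProjectUnit:
    def test_own_composite_scenario_is_identity(self, fitted):
        """Substituting the unit's own composite reproduces the unadjusted estimate."""
        table, comp, fm = fitted
        rec = table.records[3]
        c = float(comp.index.loc[rec.name])
        est = project_unit(fm, rec, c, scenario=ScenarioValue(value=c, fraction=0.1, k=5))
        assert est.adjusted == pytest.approx(est.unadjusted, rel=1e-12)

    def test_zero_noise_prediction_matches_hand_oracle(self):
        """On a noiseless surface the adjusted rate equals 1/(x* B)."""
        table = bb.generate(bb.GeneratorConfig(seed=3, sigma=0.0))
        comp = build_composite(table)
        X, y = build_design(table, comp)
        fm = fit_wls(X, y)
        scenario = optimal_scenario(comp.index, 0.10)
        rec = table.records[0]
        est = project_unit(fm, rec, float(comp.index.iloc[0]), scenario=scenario)
        x_star = np.array(
            [
                1.0,
                rec.disability_pct,
                rec.disability_pct**2,
                scenario.value,
                scenario.value**2,
                scenario.value**3,
                rec.married_pct,
                rec.life_expectancy,
            ]
        )
        expected = 1.0 / float(x_star @ fm.params.to_numpy())
        assert est.adjusted == pytest.approx(expected, rel=1e-10)
        # zero residual variance: interval collapses onto the estimate
        assert est.ci_low == pytest.approx(est.adjusted, rel=1e-8)
        assert est.ci_high == pytest.approx(est.adjusted, rel=1e-8)

    def test_published_nevada_row_passthrough(self, table2):
        row = table2.row("Nevada")
        assert row["adjusted"] == 35.41
        assert (row["ci_low"], row["ci_high"]) == (28.76, 42.07)


class TestPublishedClassification:
    def test_all_50_printed_labels_reproduced(self, table2):
        """Categories recomputed from printed (actual, lo, hi) match every label."""
        ests = estimates_from_published(table2)
        for est, printed in zip(ests, table2.frame["printed_label"]):
            assert est.category.printed_label() == printed, est.name

    def test_gap_census_counts(self, table2):
        census = gap_census(estimates_from_published(table2))
        assert census["counts"] == {
            "UNDER_PROVIDED": 16,
            "OVER_PROVIDED": 14,
            "WITHIN": 20,
        }
        assert sum(census["counts"].values()) == census["n"] == 50
        assert sum(census["shares"].values()) == pytest.approx(1.0)


class TestGapCensusEdges:
    def test_single_estimate(self, table2):
        ests = estimates_from_published(table2)[:1]
        census = gap_census(ests)
        assert sorted(census["counts"].values()) == [0, 0, 1]

    def test_all_under_when_actual_below_lo(self, table2):
        ests = estimates_from_published(table2)
        for e in ests:
            e.actual = e.ci_low - 1.0
            e.category = classify_gap(e.actual, e.ci_low, e.ci_high)
        census = gap_census(ests)
        assert census["counts"]["UNDER_PROVIDED"] == 50


class TestAggregate:
    def test_equal_weights_means(self, table2):
        ests = estimates_from_published(table2)[:2]
        ests[0].actual, ests[1].actual = 10.0, 30.0
        rows = aggregate(ests, weights=[1.0, 1.0])
        assert rows[0].weighted["actual"] == pytest.approx(20.0)
        assert rows[0].unweighted["actual"] == pytest.approx(20.0)

    def test_unequal_weights(self, table2):
        ests = estimates_from_published(table2)[:2]
        ests[0].actual, ests[1].actual = 10.0, 30.0
        rows = aggregate(ests, weights=[1.0, 3.0])
        assert rows[0].weighted["actual"] == pytest.approx(25.0)
        assert rows[0].unweighted["actual"] == pytest.approx(20.0)

    def test_published_unweighted_adjusted_mean(self, table2):
        """The unweighted mean adjusted estimate over the 50 states."""
        rows = aggregate(estimates_from_published(table2))
        # printed mean is 2-dp rounded; the exact mean of the column is 32.895
        assert rows[0].unweighted["adjusted"] == pytest.approx(32.89, abs=0.0051)

    def test_total_equals_single_group(self, table2):
        ests = estimates_from_published(table2)
        total = aggregate(ests, group_by=None)[0]
        by_region = aggregate(ests, group_by="region")
        assert total.n == sum(r.n for r in by_region) == 50

    def test_division_groups_cover_all_states(self, table2):
        rows = aggregate(estimates_from_published(table2), group_by="division")
        assert len(rows) == 9
        assert sum(r.n for r in rows) == 50

    def test_zero_weight_group_omitted_with_warning(self, table2):
        ests = estimates_from_published(table2)
        w = [0.0 if e.region == "West" else 1.0 for e in ests]
        with pytest.warns(UserWarning, match="zero weight"):
            rows = aggregate(ests, weights=w, group_by="region")
        assert {r.group for r in rows} == {"Northeast", "Midwest", "South"}
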