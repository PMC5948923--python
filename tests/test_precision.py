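"""Cochran/Grubbs screening, variance components, precision limits and
stratified aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from canopylai import (
    EstimateMatrix,
    InterlabPrecision,
    LIMIT_FACTOR,
    Stratum,
    VarianceComponents,
    classify_laboratories,
    cochran_statistic,
    critical_values,
    grubbs_statistic,
    precision_limits,
    simulate_estimate_matrix,
    stratify_summaries,
    variance_components,
)
from canopylai.precision import OUTLIER, RETAINED, STRAGGLER


def anova_oracle(values, n):
    """Independent one-way ANOVA estimators, written from the sums of squares."""
    p = values.shape[0]
    grand = values.mean()
    lab_means = values.mean(axis=1)
    ss_within = ((values - lab_means[:, None]) ** 2).sum()
    ms_within = ss_within / (p * (n - 1))
    s_d2 = ((lab_means - grand) ** 2).sum() / (p - 1)
    s_l2 = max(0.0, s_d2 - ms_within / n)
    return math.sqrt(ms_within), math.sqrt(ms_within + s_l2), grand


class TestCochran:
    def test_equal_variances_symmetry(self):
        assert cochran_statistic([2.0, 2.0, 2.0, 2.0]) == pytest.approx(0.25)

    def test_hand_computed_ratio(self):
        assert cochran_statistic([4.0, 1.0, 1.0, 1.0]) == pytest.approx(4 / 7)

    def test_dominating_lab_is_an_outlier_at_4x4(self):
        c = cochran_statistic([100.0, 1.0, 1.0, 1.0])
        assert c == pytest.approx(0.9709, abs=1e-4)
        assert c > critical_values("cochran", 0.01, p=4, nu=3)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            cochran_statistic([0.0, 0.0, 0.0])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 100.0), min_size=3, max_size=8),
        st.floats(0.1, 10.0),
    )
    def test_invariant_to_relabeling_and_common_scaling(self, variances, scale):
        c = cochran_statistic(variances)
        assert cochran_statistic(variances[::-1]) == pytest.approx(c)
        assert cochran_statistic([scale * v for v in variances]) == pytest.approx(c)
        assert 0 < c <= 1


class TestGrubbs:
    def test_hand_computed_high_suspect(self):
        g, idx = grubbs_statistic([1.0, 2.0, 3.0, 10.0])
        assert idx == 3
        assert g == pytest.approx(6 / math.sqrt(50 / 3), abs=1e-4)

    def test_symmetric_means_tie_breaks_toward_maximum(self):
        g, idx = grubbs_statistic([1.0, 2.0, 3.0, 4.0])
        assert g == pytest.approx(1.1619, abs=1e-4)
        assert idx == 3

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError):
            grubbs_statistic([2.0, 2.0, 2.0, 2.0])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(-50, 50).filter(lambda x: abs(x) > 1e-6),
            min_size=3, max_size=8, unique=True,
        ),
        st.floats(0.1, 5.0),
        st.floats(-20, 20),
    )
    def test_invariant_to_affine_transforms(self, means, a, b):
        g, _ = grubbs_statistic(means)
        g2, _ = grubbs_statistic([a * m + b for m in means])
        assert g2 == pytest.approx(g, rel=1e-9)


class TestCriticalValues:
    def test_grubbs_matches_published_table_p4(self):
        assert critical_values("grubbs", 0.05, 4) == pytest.approx(1.481, abs=1e-3)
        assert critical_values("grubbs", 0.01, 4) == pytest.approx(1.496, abs=1e-3)

    @pytest.mark.parametrize("p,nu", [(3, 3), (4, 3), (5, 3), (4, 2), (6, 5)])
    @pytest.mark.parametrize("alpha", [0.05, 0.01])
    def test_cochran_table_and_formula_agree(self, p, nu, alpha, monkeypatch):
        from canopylai import precision as prec
        table_value = critical_values("cochran", alpha, p, nu)
        monkeypatch.setattr(prec, "_COCHRAN_TABLE", {})
        formula_value = critical_values("cochran", alpha, p, nu)
        assert abs(table_value - formula_value) <= 1e-3

    def test_cochran_decreasing_in_lab_count(self):
        vals = [critical_values("cochran", 0.05, p, nu=3) for p in range(2, 12)]
        assert all(0 < v < 1 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestClassification:
    def test_inflated_within_variance_excluded_by_cochran(self):
        base = simulate_estimate_matrix(3.0, VarianceComponents(0.2, 0.1), seed=0)
        v = base.values.copy()
        v[1] = 3.0 + (v[1] - v[1].mean()) * 30.0  # gross variance inflation
        report = classify_laboratories(EstimateMatrix(values=np.maximum(v, 0)))
        assert report.cochran_suspect == "B"
        assert report.classification["B"] == OUTLIER
        assert "B" in report.excluded_labs

    def test_shifted_mean_excluded_by_grubbs(self):
        base = simulate_estimate_matrix(3.0, VarianceComponents(0.2, 0.1), seed=1)
        v = base.values.copy()
        v[2] += 1000.0  # shift large enough that G approaches its (p-1)/sqrt(p) ceiling
        report = classify_laboratories(EstimateMatrix(values=v))
        assert report.grubbs_suspect == "C"
        assert report.classification["C"] == OUTLIER

    def test_degenerate_constant_matrix_all_retained(self):
        report = classify_laboratories(EstimateMatrix(values=np.full((4, 4), 2.0)))
        assert all(c == RETAINED for c in report.classification.values())
        assert math.isnan(report.cochran_statistic)
        assert math.isnan(report.grubbs_statistic)

    def test_straggler_flagged_but_retained(self):
        # lab means (1, 2, 3, 13) give G = 1.4838, between the 5% (1.481)
        # and 1% (1.496) critical values: straggler, not excluded
        wiggle = np.array([-0.01, -0.01, 0.01, 0.01])  # equal within-lab variance
        v = np.array([1.0, 2.0, 3.0, 13.0])[:, None] + wiggle
        report = classify_laboratories(EstimateMatrix(values=v))
        assert report.classification["D"] == STRAGGLER
        assert "D" not in report.excluded_labs
        assert report.grubbs_critical_5 < report.grubbs_statistic <= report.grubbs_critical_1


class TestVarianceComponents:
    def test_between_lab_spread_only(self):
        m = EstimateMatrix(values=np.array([[1.0, 1.0], [3.0, 3.0]]))
        s_r, s_R, mean = variance_components(m)
        assert s_r == 0.0
        assert s_R == pytest.approx(math.sqrt(2.0))
        assert mean == 2.0

    def test_constant_matrix_gives_zero_components(self):
        m = EstimateMatrix(values=np.full((4, 4), 2.5))
        s_r, s_R, mean = variance_components(m)
        assert s_r == 0.0 and s_R == 0.0 and mean == 2.5

    def test_matches_anova_oracle_to_ten_decimals(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            v = rng.gamma(4.0, 0.5, size=(4, 4))
            m = EstimateMatrix(values=v)
            s_r, s_R, mean = variance_components(m)
            o_r, o_R, o_mean = anova_oracle(v, 4)
            assert s_r == pytest.approx(o_r, abs=1e-10)
            assert s_R == pytest.approx(o_R, abs=1e-10)
            assert mean == pytest.approx(o_mean, abs=1e-10)

    def test_excluded_lab_is_dropped(self):
        v = np.array([[1.0, 1.1], [1.0, 0.9], [50.0, 60.0]])
        m = EstimateMatrix(values=v)
        report = classify_laboratories(m)
        assert "C" in report.excluded_labs
        _, _, mean = variance_components(m, report)
        assert mean == pytest.approx(1.0)


class TestPrecisionLimits:
    def test_limit_factor_and_trivial_zero(self):
        assert precision_limits(0.0, 0.0, 1.0).r == 0.0
        res = precision_limits(1.0, 1.0, 5.0)
        assert res.r == pytest.approx(2.7718, abs=1e-4)
        assert res.R == res.r

    def test_ratio_r_over_sr_is_constant(self):
        for s in (0.1, 0.5, 2.0):
            res = precision_limits(s, s * 1.5, 4.0)
            assert res.r / res.S_r == pytest.approx(LIMIT_FACTOR)
            assert res.R >= res.r

    def test_relative_forms_are_percent_of_mean(self):
        res = precision_limits(0.2964, 0.35, 5.52)
        assert res.RSD_r == pytest.approx(100 * 0.2964 / 5.52)
        assert res.r == pytest.approx(0.82, abs=0.01)

    def test_zero_mean_with_spread_rejected(self):
        with pytest.raises(ValueError):
            precision_limits(0.1, 0.2, 0.0)


class TestStratify:
    def make_results(self):
        rows = [
            ("a", "row", 2.0, 0.4, 0.5),
            ("b", "row", 4.0, 0.8, 0.9),
            ("c", "sparse", 6.0, 1.2, 1.3),
        ]
        out = []
        for entity, cls, mean, r, R in rows:
            out.append(
                precision_limits(r / LIMIT_FACTOR, R / LIMIT_FACTOR, mean,
                                 entity_id=entity, canopy_class=cls, labs_used=4)
            )
        return out

    def test_means_and_per_entity_relative_ratios(self):
        res = self.make_results()
        summ = stratify_summaries(res, [Stratum("row", canopy_class="row")])[0]
        assert summ.n_entities == 2
        assert summ.mean_r == pytest.approx(0.6)
        # mean of per-entity ratios, not ratio of means
        assert summ.mean_relative_r == pytest.approx((100 * 0.4 / 2 + 100 * 0.8 / 4) / 2)

    def test_lai_bounds_are_strict(self):
        res = self.make_results()
        summ = stratify_summaries(res, [Stratum("high", lai_gt=4.0)])[0]
        assert summ.n_entities == 1
        assert summ.mean_r == pytest.approx(1.2)

    def test_empty_stratum_raises(self):
        with pytest.raises(ValueError):
            stratify_summaries(self.make_results(), [Stratum("none", lai_gt=99.0)])


class TestModelInterface:
    def make_long_df(self):
        records = []
        for e, (mean, cls) in enumerate([(2.0, "row"), (5.0, "sparse")]):
            m = simulate_estimate_matrix(
                mean, VarianceComponents(0.2, 0.1), seed=e,
                entity_id=f"e{e}", canopy_class=cls,
            )
            for l, lab in enumerate(m.labs):
                for k in range(m.n_replicates):
                    records.append(
                        {"entity_id": f"e{e}", "canopy_class": cls,
                         "laboratory": lab, "replicate": k + 1,
                         "lai": m.values[l, k]}
                    )
        return pd.DataFrame(records)

    def test_from_dataframe_fit_and_table(self):
        res = InterlabPrecision.from_dataframe(self.make_long_df()).fit()
        assert len(res.results) == 2
        table = res.table
        assert list(table["entity_id"]) == ["e0", "e1"]
        assert (table["R"] >= table["r"]).all()
        assert (table["S_R"] >= table["S_r"]).all()

    def test_summary_reports_limit_factor_and_entities(self):
        res = InterlabPrecision.from_dataframe(self.make_long_df()).fit()
        text = res.summary()
        assert "2.7718" in text
        assert "e0" in text and "e1" in text

    def test_unbalanced_design_rejected(self):
        df = self.make_long_df().iloc[:-1]
        with pytest.raises(ValueError):
            InterlabPrecision.from_dataframe(df)

    def test_zero_variance_entities_give_zero_limits(self):
        m = simulate_estimate_matrix(3.0, VarianceComponents(0.0, 0.0), seed=0)
        res = InterlabPrecision(m).fit()
        assert res.results[0].r == 0.0 and res.results[0].R == 0.0
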