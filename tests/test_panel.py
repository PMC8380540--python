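import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from adiposize import panel
from adiposize.geometry import ValidationError
from adiposize.panel import (
    describe,
    interdecile_range,
    modal_size,
    normality,
    per_subject_panels,
    pooled_panel,
    qq_points,
)

samples = st.lists(
    st.floats(min_value=0.1, max_value=1e5, allow_nan=False, allow_infinity=False),
    min_size=3, max_size=50,
)


class TestDescribe:
    def test_symmetric_sample(self):
        p = describe([1, 2, 3], shapiro=False)
        assert p.mean == 2 and p.median == 2
        assert p.skewness == pytest.approx(0, abs=1e-12)

    def test_hand_computed_skewness(self):
        # m2 = 0.1875, m3 = 0.09375 -> g1 = 1.1547
        p = describe([0, 0, 0, 1], shapiro=False)
        assert p.skewness == pytest.approx(0.09375 / 0.1875**1.5)
        assert p.skewness == pytest.approx(1.1547005, abs=1e-6)

    def test_two_point_kurtosis(self):
        p = describe([-1, 1, -1, 1], shapiro=False)
        assert p.kurtosis == pytest.approx(1.0)

    def test_normal_sample_kurtosis_near_three(self):
        rng = np.random.default_rng(0)
        p = describe(rng.standard_normal(100_000), shapiro=False)
        assert p.kurtosis == pytest.approx(3.0, abs=0.05)

    def test_zero_variance_reports_undefined_shape(self):
        p = describe([5.0, 5.0, 5.0, 5.0], shapiro=False)
        assert np.isnan(p.skewness) and np.isnan(p.kurtosis)
        assert p.mode == 5.0

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            describe([1.0, 2.0])

    @given(samples)
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, xs):
        """Every descriptor agrees with an explicit-loop implementation of
        the defining formulas on small samples."""
        p = describe(xs, shapiro=False)
        assert p.mean == pytest.approx(oracles.mean(xs), rel=1e-10)
        assert p.median == pytest.approx(oracles.median(xs), rel=1e-10, abs=1e-10)
        assert p.first_decile == pytest.approx(oracles.quantile(xs, 0.1), rel=1e-10, abs=1e-10)
        assert p.ninth_decile == pytest.approx(oracles.quantile(xs, 0.9), rel=1e-10, abs=1e-10)
        assert p.idr == pytest.approx(oracles.interdecile_range(xs), rel=1e-9, abs=1e-9)
        if len(set(xs)) > 1:
            assert p.skewness == pytest.approx(oracles.skewness(xs), rel=1e-9, abs=1e-9)
            assert p.kurtosis == pytest.approx(oracles.kurtosis(xs), rel=1e-9, abs=1e-9)

    @given(samples, st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=60, deadline=None)
    def test_linear_map_invariance(self, xs, c):
        """Under x -> c*x location/scale descriptors scale by c while
        skewness and kurtosis are unchanged (why area and surface area share
        identical shape statistics)."""
        if len(set(xs)) < 2:
            return
        a = describe(xs, shapiro=False)
        b = describe([c * x for x in xs], shapiro=False)
        assert b.skewness == pytest.approx(a.skewness, rel=1e-12, abs=1e-12)
        assert b.kurtosis == pytest.approx(a.kurtosis, rel=1e-12, abs=1e-12)
        for attr in ("mean", "median", "first_decile", "ninth_decile", "idr"):
            assert getattr(b, attr) == pytest.approx(c * getattr(a, attr), rel=1e-9)
        span = max(xs) - min(xs)
        assert b.mode == pytest.approx(c * a.mode, abs=c * max(span, 1e-9) * 1e-2 + 1e-9)

    def test_decile_order_invariant(self):
        p = describe(np.random.default_rng(3).lognormal(8, 1, 500), shapiro=False)
        assert p.first_decile <= p.median <= p.ninth_decile
        assert p.idr >= 0


class TestInterdecileRange:
    def test_published_decile_pair(self):
        assert interdecile_range(443.2, 7726.3) == pytest.approx(7283.1)

    def test_constant_sample(self):
        assert interdecile_range(4.0, 4.0) == 0.0

    def test_one_to_ten_interpolated(self):
        xs = list(range(1, 11))
        d1, d9 = oracles.quantile(xs, 0.1), oracles.quantile(xs, 0.9)
        assert (d1, d9) == (pytest.approx(1.9), pytest.approx(9.1))
        assert interdecile_range(d1, d9) == pytest.approx(7.2)

    def test_reversed_deciles_raise(self):
        with pytest.raises(ValidationError):
            interdecile_range(9.0, 1.0)


class TestMode:
    def test_symmetric_unimodal(self):
        assert modal_size([1, 2, 2, 3]) == pytest.approx(2.0, abs=0.02)

    def test_right_skew_ordering(self):
        rng = np.random.default_rng(5)
        xs = rng.lognormal(8, 0.6, 5000)
        p = describe(xs, shapiro=False)
        assert p.mode < p.median < p.mean

    def test_constant_sample(self):
        assert modal_size([3.0] * 12) == 3.0


class TestNormality:
    def test_lognormal_rejected(self):
        rng = np.random.default_rng(2)
        w, p = normality(rng.lognormal(8, 0.35, 500))
        assert p < 0.001

    def test_out_of_range_sizes(self):
        with pytest.raises(ValidationError):
            normality([1.0, 2.0])
        with pytest.raises(ValidationError, match="subsample"):
            normality(np.ones(5001))

    def test_large_sample_subsampled_inside_describe(self, caplog):
        rng = np.random.default_rng(4)
        with caplog.at_level(logging.INFO, logger="adiposize.panel"):
            p = describe(rng.standard_normal(6000) + 10, seed=1)
        assert np.isfinite(p.shapiro_p)
        assert any("subsampled" in r.message for r in caplog.records)


class TestQQ:
    def test_normal_scores_on_identity(self):
        from scipy import stats
        n = 200
        scores = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        table = qq_points(scores)
        np.testing.assert_allclose(table["sample"], table["theoretical"], atol=1e-6)

    def test_lognormal_convex_departure(self):
        rng = np.random.default_rng(6)
        table = qq_points(rng.lognormal(0, 1, 1000))
        upper = table.tail(10)
        assert (upper["sample"] > upper["theoretical"]).all()

    def test_minimal_size(self):
        assert len(qq_points([1.0, 2.0, 3.0])) == 3
        with pytest.raises(ValidationError):
            qq_points([1.0, 2.0])


class TestPooled:
    def test_pooled_size_is_k_times_subjects(self, small_cells):
        res = pooled_panel(small_cells, "sc", "histology", "area", k=40, seed=0)
        assert res.panel.n == 2 * 40
        assert res.subject_count == 2

    def test_short_subject_excluded_and_named(self, small_cells):
        extra = small_cells.iloc[:5].assign(subject_id="C")
        cells = pd.concat([small_cells, extra], ignore_index=True)
        res = pooled_panel(cells, "sc", "histology", "area", k=40, seed=0)
        assert res.excluded_subjects == ["C"]
        assert "C" not in res.retained_subjects

    def test_no_qualifying_subject_errors(self, small_cells):
        with pytest.raises(ValidationError):
            pooled_panel(small_cells, "sc", "histology", "area", k=1000, seed=0)

    def test_identical_subjects_share_skewness(self):
        rng = np.random.default_rng(8)
        base = rng.lognormal(8, 0.5, 600)
        cells = pd.concat([
            pd.DataFrame({"subject_id": s, "depot": "sc", "method": "histology",
                          "size_parameter": "area", "value": base, "unit": "um2"})
            for s in ("A", "B", "C")
        ], ignore_index=True)
        pooled = pooled_panel(cells, "sc", "histology", "area", k=500, seed=1)
        single = describe(base, shapiro=False)
        assert pooled.panel.skewness == pytest.approx(single.skewness, abs=0.15)


class TestPerSubject:
    def test_idr_linearity_across_cohort(self, tiny_cohort):
        """Cohort mean of per-subject IDR equals mean(D9) - mean(D1)."""
        panels, summary = per_subject_panels(
            tiny_cohort.cells, "area", {"histology": 50, "collagenase": 25},
            seed=0, shapiro=False)
        for _, row in summary.iterrows():
            assert row["idr_mean"] == pytest.approx(
                row["ninth_decile_mean"] - row["first_decile_mean"], rel=1e-12)

    def test_identical_subjects_zero_sd(self):
        base = np.random.default_rng(9).lognormal(8, 0.5, 80)
        cells = pd.concat([
            pd.DataFrame({"subject_id": s, "depot": "vc", "method": "histology",
                          "size_parameter": "area", "value": base, "unit": "um2"})
            for s in ("A", "B")
        ], ignore_index=True)
        _, summary = per_subject_panels(cells, "area", 80, seed=0, shapiro=False)
        # with every cell used, both subjects have identical panels
        assert summary["mean_sd"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert summary["skewness_sd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_units_follow_parameter(self, small_cells):
        panels, _ = per_subject_panels(small_cells, "volume", 40, seed=0,
                                       shapiro=False)
        hist = panels[panels["method"] == "histology"]
        assert (hist["units"] == "pl").all()
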