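import numpy as np
import pandas as pd
import pytest

import oracles
from adiposize import association
from adiposize.association import (
    adjusted_regression,
    bonferroni,
    cell_count_sensitivity,
    correlation_matrix,
    nested_subsample_simulation,
    respirometry_associations,
    subject_mean_sizes,
)
from adiposize.geometry import ValidationError


def sizes_frame(rng, n=60, depot="vc"):
    d = rng.normal(60, 8, n)
    return pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "depot": depot, "diameter": d, "area": np.pi / 4 * d**2,
    })


class TestBonferroni:
    def test_exact_formula_and_cap(self):
        assert bonferroni(0.01, 5) == pytest.approx(0.05)
        assert bonferroni(0.3, 10) == 1.0

    def test_monotone_in_p(self):
        ps = np.linspace(0.001, 0.2, 25)
        adj = [bonferroni(p, 7) for p in ps]
        assert all(a <= b for a, b in zip(adj, adj[1:]))

    def test_invalid_family(self):
        with pytest.raises(ValidationError):
            bonferroni(0.05, 0)


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        sizes = sizes_frame(rng)
        pheno = sizes[["subject_id"]].assign(shadow=sizes["diameter"])
        out = correlation_matrix(sizes, pheno, variables=["shadow"],
                                 size_parameters=["diameter"])
        row = out.iloc[0]
        assert row["estimate"] == pytest.approx(1.0)
        assert row["p"] < 1e-20

    def test_all_missing_variable_untested(self):
        rng = np.random.default_rng(1)
        sizes = sizes_frame(rng)
        pheno = sizes[["subject_id"]].assign(ghost=np.nan)
        out = correlation_matrix(sizes, pheno.assign(real=rng.normal(size=len(pheno))),
                                 variables=["ghost", "real"],
                                 size_parameters=["diameter"])
        ghost = out[out["variable"] == "ghost"].iloc[0]
        assert ghost["n"] == 0 and np.isnan(ghost["estimate"])
        # the untested pair does not count toward the Bonferroni family
        assert out.attrs["bonferroni_m"] == 1

    def test_pairwise_n_matches_brute_force(self):
        rng = np.random.default_rng(2)
        sizes = sizes_frame(rng, n=30)
        pheno = pd.DataFrame({
            "subject_id": sizes["subject_id"],
            "bmi": rng.normal(43, 13, 30), "glucose": rng.normal(6, 3, 30),
        })
        pheno.loc[rng.choice(30, 8, replace=False), "bmi"] = np.nan
        pheno.loc[rng.choice(30, 12, replace=False), "glucose"] = np.nan
        out = correlation_matrix(sizes, pheno, size_parameters=["diameter"])
        merged = sizes.merge(pheno, on="subject_id")
        for var in ("bmi", "glucose"):
            manual_n = sum(
                1 for _, row in merged.iterrows()
                if np.isfinite(row["diameter"]) and np.isfinite(row[var])
            )
            assert out.loc[out["variable"] == var, "n"].iloc[0] == manual_n

    def test_adjusted_p_is_min_one_mp(self):
        rng = np.random.default_rng(3)
        sizes = sizes_frame(rng)
        pheno = pd.DataFrame({
            "subject_id": sizes["subject_id"],
            "a": rng.normal(size=60), "b": rng.normal(size=60),
        })
        out = correlation_matrix(sizes, pheno, size_parameters=["diameter", "area"])
        m = out.attrs["bonferroni_m"]
        assert m == 4
        for _, row in out.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, m * row["p"]))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        sizes = sizes_frame(rng)
        pheno = pd.DataFrame({"subject_id": sizes["subject_id"],
                              "bmi": rng.normal(43, 13, 60)})
        out1 = correlation_matrix(sizes, pheno, size_parameters=["diameter"])
        shuffled = sizes.sample(frac=1.0, random_state=9).reset_index(drop=True)
        out2 = correlation_matrix(shuffled, pheno, size_parameters=["diameter"])
        assert out1["estimate"].iloc[0] == pytest.approx(out2["estimate"].iloc[0],
                                                         rel=1e-12)


class TestRegression:
    def test_noise_free_exact_recovery(self):
        bmi = np.linspace(20, 60, 30)
        df = pd.DataFrame({"bmi": bmi, "y": 2 + 3 * bmi})
        out = adjusted_regression(df, "y", ["bmi"])
        assert out["estimate"].iloc[0] == pytest.approx(3.0, rel=1e-10)

    def test_orthogonal_design_recovery(self):
        rng = np.random.default_rng(5)
        n = 64
        x1 = np.tile([-1.0, 1.0], n // 2)
        x2 = np.repeat([-1.0, 1.0], n // 2)
        y = 1.5 + 0.7 * x1 - 1.2 * x2 + rng.normal(0, 1e-4, n)
        out = adjusted_regression(pd.DataFrame({"x1": x1, "x2": x2, "y": y}),
                                  "y", ["x1", "x2"])
        est = dict(zip(out["variable"], out["estimate"]))
        assert est["y~x1"] == pytest.approx(0.7, abs=1e-3)
        assert est["y~x2"] == pytest.approx(-1.2, abs=1e-3)

    def test_standardized_single_covariate_equals_r(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=80)
        y = 0.4 * x + rng.normal(size=80)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        out = adjusted_regression(pd.DataFrame({"x": xs, "y": ys}), "y", ["x"])
        assert out["estimate"].iloc[0] == pytest.approx(
            oracles.pearson_r(list(x), list(y)), rel=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(size=30)})
        with pytest.raises(ValidationError, match="collinear"):
            adjusted_regression(df, "y", ["x", "x2"])

    def test_categorical_coding(self):
        rng = np.random.default_rng(8)
        n = 40
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        male = (sex == "male").astype(float)
        y = 10 + 4 * male + rng.normal(0, 1e-6, n)
        out = adjusted_regression(pd.DataFrame({"sex": sex, "y": y}), "y", ["sex"])
        assert out["estimate"].iloc[0] == pytest.approx(4.0, abs=1e-4)


class TestRespirometry:
    def test_negated_diameter_gives_minus_one(self):
        rng = np.random.default_rng(9)
        d = rng.normal(60, 8, 24)
        md = pd.DataFrame({"subject_id": [f"S{i}" for i in range(24)],
                           "depot": "sc", "diameter": d})
        resp = md[["subject_id", "depot"]].assign(
            free_oxphos=-d, oxphos=-d, ets=-d, leak=-d)
        out = respirometry_associations(resp, md)
        assert np.allclose(out["estimate"], -1.0)

    def test_permuted_labels_break_association(self):
        rng = np.random.default_rng(10)
        n = 200
        d = rng.normal(60, 8, n)
        md = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)],
                           "depot": "sc", "diameter": d})
        resp = md[["subject_id", "depot"]].assign(
            free_oxphos=rng.permutation(-d), oxphos=rng.permutation(-d),
            ets=rng.permutation(-d), leak=rng.permutation(-d))
        out = respirometry_associations(resp, md)
        assert (out["estimate"].abs() < 0.2).all()

    def test_bmi_adjustment_rows_present(self):
        rng = np.random.default_rng(11)
        n = 24
        d = rng.normal(60, 8, n)
        ids = [f"S{i}" for i in range(n)]
        md = pd.DataFrame({"subject_id": ids, "depot": "sc", "diameter": d})
        resp = md[["subject_id", "depot"]].assign(
            free_oxphos=1 - 0.01 * d + rng.normal(0, 0.05, n),
            oxphos=2 - 0.01 * d, ets=3 - 0.01 * d, leak=0.5 - 0.001 * d)
        pheno = pd.DataFrame({"subject_id": ids, "bmi": rng.normal(43, 13, n)})
        out = respirometry_associations(resp, md, pheno)
        assert (out["method"] == "ols").sum() == 4
        assert "oxphos~diameter|bmi" in set(out["variable"])


class TestCellCountSensitivity:
    def _cells(self, rng, n_subj=10, n_cells=60):
        frames = []
        for i in range(n_subj):
            areas = rng.lognormal(7.9, 0.4, n_cells)
            frames.append(pd.DataFrame({
                "subject_id": f"S{i:02d}", "depot": "sc", "method": "histology",
                "size_parameter": "area", "value": areas, "unit": "um2"}))
        return pd.concat(frames, ignore_index=True)

    def test_equal_counts_give_r_one(self):
        cells = self._cells(np.random.default_rng(12))
        r, p, table = cell_count_sensitivity(cells, 50, 50, seed=0)
        assert r == 1.0
        assert len(table) == 10

    def test_zero_within_subject_variance_gives_r_one(self):
        frames = [pd.DataFrame({
            "subject_id": f"S{i}", "depot": "sc", "method": "histology",
            "size_parameter": "area", "value": np.full(50, 1000.0 + 100 * i),
            "unit": "um2"}) for i in range(5)]
        r, _, _ = cell_count_sensitivity(pd.concat(frames, ignore_index=True),
                                         40, 10, seed=1)
        assert r == pytest.approx(1.0)

    def test_reduced_is_nested_subset(self):
        cells = self._cells(np.random.default_rng(13), n_subj=4)
        _, _, table = cell_count_sensitivity(cells, 60, 20, seed=2)
        # nested design: reduced mean recomputable from the full permutation
        from adiposize import geometry
        grp = cells[cells["subject_id"] == "S00"]["value"].to_numpy()
        full = geometry.sample_cells(grp, 60, 2, "S00", "sc", "histology")
        assert table.loc[table.subject_id == "S00", "mean_diameter_reduced"].iloc[0] \
            == pytest.approx(geometry.area_to_diameter(full[:20]).mean())

    def test_too_few_subjects(self):
        cells = self._cells(np.random.default_rng(14), n_subj=2)
        with pytest.raises(ValidationError):
            cell_count_sensitivity(cells, 50, 20, seed=0)

    def test_simulation_matches_closed_form(self):
        """The nested-subsample simulation agrees with the analytic
        correlation sqrt((sb^2+sw^2/kf)/(sb^2+sw^2/kr))."""
        expected = oracles.nested_subsample_r(7.8, 29.0, 500, 200)
        mean_r, rs = nested_subsample_simulation(
            n_subjects=146, n_replicates=30, seed=3)
        assert mean_r == pytest.approx(expected, abs=0.005)
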