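"""Vectorisation, model enumeration, mixed-model fitting, LRTs, screening, VIF."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import semioprofile as sp
from semioprofile.lmm_screen import (
    FitResult,
    ModelSpec,
    VarComp,
    build_model_spec,
    fit_lmm,
    lrt,
    screen_substances,
    unvectorise,
    vectorise,
    vif,
)


def tiny_meta(n=2):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "female": ["F1", "F2"][:n],
            "room": "room1",
            "batch": [f"F{i + 1}-c1" for i in range(n)],
            "cycle_state": ["follicular", "luteal"][:n],
            "age": [2, 8][:n],
            "parity": ["nulliparous", "parous"][:n],
            "side": "left",
            "ultrasound": "after",
            "a1": "no",
            "a2": "no",
            "a3": "yes",
            "a4": "no",
        }
    )


class TestVectorise:
    def test_2x3_gives_6_rows_and_roundtrip(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            index=["s0", "s1"],
            columns=["x", "y", "z"],
        )
        long = vectorise(values, tiny_meta())
        assert len(long) == 6
        assert list(long["y"]) == [1, 2, 3, 4, 5, 6]  # sample-major
        pd.testing.assert_frame_equal(
            unvectorise(long).astype(float), values, check_names=False
        )

    def test_age_z_unit_variance_over_females(self, small_study, rel_table):
        design, _, _ = small_study
        long = vectorise(rel_table.rel, design.animal_samples)
        per_female = long.drop_duplicates("female")["age_z"]
        assert per_female.mean() == pytest.approx(0.0, abs=1e-9)
        assert per_female.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_missing_metadata_errors(self):
        values = pd.DataFrame([[1.0]], index=["sX"], columns=["a"])
        with pytest.raises(ValueError, match="missing sample"):
            vectorise(values, tiny_meta())


class TestModelSpec:
    def test_full_enumeration_has_33_predictors(self):
        assert build_model_spec().n_predictors == 33

    def test_null_spec_has_30(self):
        assert build_model_spec(include_test_predictors=False).n_predictors == 30

    def test_unknown_drop_errors(self):
        with pytest.raises(ValueError, match="unknown variance"):
            build_model_spec().drop(["substance:weather"])

    def test_fixed_only_spec(self):
        spec = ModelSpec(fixed=("age_z",), vc=())
        assert spec.n_predictors == 1


class TestFitLmm:
    def test_balanced_one_way_matches_closed_form(self):
        """ML variance estimates equal the balanced one-way profiled optimum."""
        rng = np.random.default_rng(7)
        k, m = 8, 6
        y = rng.normal(0, 1, k * m) + np.repeat(rng.normal(0, 1.5, k), m)
        long = pd.DataFrame({"y": y, "grp": np.repeat([f"g{i}" for i in range(k)], m)})
        fit = fit_lmm(long, ModelSpec(fixed=(), vc=(VarComp(("grp",)),)), "ML")

        gm = y.reshape(k, m).mean(axis=1)
        ssb = m * ((gm - y.mean()) ** 2).sum()
        ssw = ((y.reshape(k, m) - gm[:, None]) ** 2).sum()
        n = k * m

        def dev(lg):  # independent 1-D profiled deviance via eigenstructure
            gam = np.exp(lg)
            return n * np.log((ssw + ssb / (1 + m * gam)) / n) + k * np.log(1 + m * gam)

        opt = minimize_scalar(dev, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-12})
        gam = np.exp(opt.x)
        s2e = (ssw + ssb / (1 + m * gam)) / n
        assert fit.sigma2_resid == pytest.approx(s2e, abs=1e-6)
        assert fit.variance_components["grp"] == pytest.approx(gam * s2e, abs=1e-6)

    def test_zero_variance_limit_equals_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 90)
        y = 2.0 + 0.5 * x + rng.normal(0, 1, 90)
        long = pd.DataFrame({"y": y, "x": x, "grp": np.repeat(list("abc"), 30)})
        fit = fit_lmm(long, ModelSpec(fixed=("x",), vc=(VarComp(("grp",)),)), "ML")
        X = np.column_stack([np.ones(90), x])
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.variance_components["grp"] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(fit.beta.to_numpy(), b_ols, atol=1e-6)

    def test_statsmodels_cross_check_single_intercept(self):
        """ML log-likelihood and estimates agree with statsmodels MixedLM."""
        smf = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        rng = np.random.default_rng(5)
        k, m = 12, 7
        x = rng.normal(0, 1, k * m)
        y = 1.0 + 0.4 * x + np.repeat(rng.normal(0, 1.2, k), m) + rng.normal(0, 0.8, k * m)
        long = pd.DataFrame({"y": y, "x": x, "grp": np.repeat([f"g{i}" for i in range(k)], m)})
        fit = fit_lmm(long, ModelSpec(fixed=("x",), vc=(VarComp(("grp",)),)), "ML")
        sm_fit = smf.MixedLM(y, np.column_stack([np.ones(k * m), x]),
                             groups=long["grp"]).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert np.allclose(fit.beta.to_numpy(), sm_fit.fe_params, atol=1e-4)
        assert fit.variance_components["grp"] == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), abs=1e-3
        )

    def test_reml_loglik_differs_but_vc_close(self):
        rng = np.random.default_rng(2)
        k, m = 10, 5
        y = rng.normal(0, 1, k * m) + np.repeat(rng.normal(0, 2.0, k), m)
        long = pd.DataFrame({"y": y, "grp": np.repeat([f"g{i}" for i in range(k)], m)})
        spec = ModelSpec(fixed=(), vc=(VarComp(("grp",)),))
        ml = fit_lmm(long, spec, "ML")
        reml = fit_lmm(long, spec, "REML")
        assert reml.variance_components["grp"] >= ml.variance_components["grp"]
        assert ml.loglik != reml.loglik

    def test_fixed_effect_recovery_over_seeds(self, small_cfg):
        """Planted cycle fixed shifts recovered within 3 MC SEs over 10 seeds."""
        import semioprofile.synthdata as sd

        spec_fit = ModelSpec(
            fixed=("cycle_state", "age_z", "parity"),
            vc=(VarComp(("sample",)), VarComp(("substance",)), VarComp(("female",))),
        )
        est = []
        truth_shift = 0.8
        for seed in range(10):
            design = sp.generate_design(small_cfg, seed=seed)
            gspec = sp.EffectSpec.random(
                n_substances=12, n_contaminants=0, n_cycle=0, n_age=0, n_parity=0,
                sigma_id=0.3, sigma_batch=0.0, sigma_resid=0.5, seed=seed,
            )
            areas, _ = sp.simulate_intensities(design, gspec, seed=seed)
            y = np.log(areas.loc[design.animal_samples["sample_id"]])
            # plant a uniform luteal shift on the log scale across substances
            meta = design.animal_samples
            lut = meta.set_index("sample_id")["cycle_state"] == "luteal"
            y = y.add(truth_shift * lut.astype(float), axis=0)
            long = vectorise(y, meta)
            fit = fit_lmm(long, spec_fit, "ML")
            est.append(fit.beta["cycle_state[luteal]"])
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert np.mean(est) == pytest.approx(truth_shift, abs=3 * se + 0.02)

    def test_rank_deficient_design_errors(self):
        long = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [1.0, 1, 1, 1]})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lmm(long, ModelSpec(fixed=("x",), vc=()), "ML")


@pytest.fixture(scope="module")
def fits(small_study, rel_table):
    design, _, truth = small_study
    y = sp.transform_response(rel_table, "normalised").y
    long = vectorise(y, design.animal_samples)
    spec = ModelSpec(
        fixed=("cycle_state", "age_z", "parity"),
        vc=(
            VarComp(("sample",)), VarComp(("substance",)), VarComp(("female",)),
            VarComp(("substance", "cycle_state")),
            VarComp(("substance", "parity")),
            VarComp(("substance",), slope="age_z"),
        ),
    )
    full = fit_lmm(long, spec, "ML")
    return long, spec, full, truth


class TestLrt:

    def test_self_comparison_degenerate(self, fits):
        _, _, full, _ = fits
        r = lrt(full, full)
        assert r.chi2 == 0.0 and r.p == 1.0 and r.df == 0

    def test_per_predictor_df_is_1_and_planted_effects_detected(self, fits):
        long, spec, full, _ = fits
        for comp in ("substance:cycle_state", "substance:parity", "substance|age_z"):
            red = fit_lmm(long, spec.drop([comp]), "ML")
            r = lrt(full, red)
            assert r.df == 1
            assert r.chi2 >= 0
            assert r.p < 0.01  # effects are planted in the fixture

    def test_full_null_df_3(self, fits):
        long, spec, full, _ = fits
        null = fit_lmm(
            long,
            spec.drop(["substance:cycle_state", "substance:parity", "substance|age_z"]),
            "ML",
        )
        r = lrt(full, null)
        assert r.df == 3
        assert full.loglik >= null.loglik

    def test_non_nested_errors(self, fits):
        long, spec, full, _ = fits
        other = ModelSpec(fixed=("cycle_state",), vc=(VarComp(("room",)),))
        fother = fit_lmm(long, other, "ML")
        with pytest.raises(ValueError, match="not nested"):
            lrt(full, fother)

    def test_ml_required(self, fits):
        long, spec, full, _ = fits
        reml = fit_lmm(long, spec.drop(["substance:parity"]), "REML")
        with pytest.raises(ValueError, match="ML"):
            lrt(full, reml)


class TestScreen:
    def make_fit(self, modes_dict):
        spec = ModelSpec(fixed=(), vc=tuple(VarComp(tuple(k.split(":"))) for k in modes_dict))
        return FitResult(
            spec=spec, method="ML", beta=pd.Series(dtype=float), sigma2_resid=1.0,
            variance_components={}, modes={k: pd.Series(v) for k, v in modes_dict.items()},
            loglik=0.0, n_obs=1, n_params=1, converged=True, n_iter=0,
        )

    def test_degenerate_equal_scores_all_flagged(self):
        modes = pd.Series(
            {("s1",): 1.0, ("s2",): -1.0, ("s3",): 1.0, ("s4",): -1.0}
        )
        fit = self.make_fit({"substance|age_z": modes})
        fit.modes["substance|age_z"].index = [("s1",), ("s2",), ("s3",), ("s4",)]
        res = screen_substances(fit, "age")
        assert res.threshold == pytest.approx(1.0)
        assert set(res.flagged) == {"s1", "s2", "s3", "s4"}

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 12)
        idx = [(f"s{i}",) for i in range(12)]
        f1 = self.make_fit({"substance|age_z": pd.Series(vals, index=idx)})
        f2 = self.make_fit({"substance|age_z": pd.Series(3.5 * vals, index=idx)})
        r1 = screen_substances(f1, "age")
        r2 = screen_substances(f2, "age")
        assert np.allclose(r2.scores, 3.5 * r1.scores)
        assert r1.flagged == r2.flagged

    def test_missing_component_errors(self):
        fit = self.make_fit({"substance|age_z": pd.Series({("s1",): 1.0})})
        with pytest.raises(ValueError, match="lacks"):
            screen_substances(fit, "cycle")
        with pytest.raises(ValueError, match="predictor"):
            screen_substances(fit, "weather")

    def test_sparse_planted_substances_recovered_cleanly(self, small_cfg):
        """3 strongly affected of 40: all flagged, directions match the plant."""
        gspec = sp.EffectSpec.random(
            n_substances=40, n_contaminants=0, n_cycle=3, n_age=3, n_parity=0,
            effect_size=1.5, seed=21,
        )
        design = sp.generate_design(small_cfg, seed=21)
        areas, truth = sp.simulate_intensities(design, gspec, seed=21)
        rel = sp.relative_areas(
            sp.AlignedTable(areas=areas.loc[design.animal_samples["sample_id"]],
                            ranges=pd.DataFrame({"range_id": areas.columns}))
        )
        y = sp.transform_response(rel, "normalised").y
        long = vectorise(y, design.animal_samples)
        spec = ModelSpec(
            fixed=("cycle_state", "age_z", "parity"),
            vc=(
                VarComp(("sample",)), VarComp(("substance",)), VarComp(("female",)),
                VarComp(("substance", "cycle_state")),
                VarComp(("substance",), slope="age_z"),
            ),
        )
        fit = fit_lmm(long, spec, "ML")
        res = screen_substances(fit, "cycle")
        assert truth.cycle_affected <= set(res.flagged)
        assert len(set(res.flagged) - truth.cycle_affected) <= 2

        res_age = screen_substances(fit, "age")
        planted = gspec.substances.set_index("id")["age_slope"]
        for sub in truth.age_affected & set(res_age.flagged):
            want = "decreasing" if planted[sub] < 0 else "increasing"
            assert res_age.directions[sub] == want


class TestVif:
    def test_orthogonal_design_vif_1(self):
        rng = np.random.default_rng(0)
        n = 64
        long = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "x1": np.tile([0.0, 1.0], n // 2),
                "x2": np.repeat([0.0, 1.0], n // 2),
            }
        )
        v = vif(long, ("x1", "x2"))
        assert np.allclose(v, 1.0, atol=1e-9)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        long = pd.DataFrame({"y": rng.normal(size=30), "x1": x, "x2": x})
        v = vif(long, ("x1", "x2"))
        assert np.isinf(v["x1"]) and np.isinf(v["x2"])

    def test_matches_direct_regression_oracle(self):
        rng = np.random.default_rng(2)
        n = 200
        x1 = rng.normal(size=n)
        x2 = 0.5 * x1 + np.sqrt(1 - 0.25) * rng.normal(size=n)
        long = pd.DataFrame({"y": rng.normal(size=n), "x1": x1, "x2": x2})
        v = vif(long, ("x1", "x2"))
        X = np.column_stack([np.ones(n), x2])
        b, *_ = np.linalg.lstsq(X, x1, rcond=None)
        resid = x1 - X @ b
        r2 = 1 - (resid @ resid) / ((x1 - x1.mean()) ** 2).sum()
        assert v["x1"] == pytest.approx(1 / (1 - r2), abs=1e-6)


class TestPlotting:
    def test_effect_plots_render(self, small_study, rel_table, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from semioprofile.plotting import plot_substance_effect

        design, _, _ = small_study
        y = sp.transform_response(rel_table, "normalised").y
        sub = y.columns[0]
        ax = plot_substance_effect(y, design.animal_samples, sub, "cycle")
        assert ax.get_ylabel() == sub
        ax2 = plot_substance_effect(y, design.animal_samples, sub, "age", slope=-0.3)
        assert ax2.get_xlabel() == "age (years)"
        with pytest.raises(ValueError, match="unknown predictor"):
            plot_substance_effect(y, design.animal_samples, sub, "weather")
        with pytest.raises(ValueError, match="unknown substance"):
            plot_substance_effect(y, design.animal_samples, "nope", "age")
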