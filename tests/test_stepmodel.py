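"""Random-intercept additive model: recovery, reductions, prediction."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from stepscape import stepmodel, synthdata
from stepscape.exposure import TYPES
from stepscape.stepmodel import ModelConfig


@pytest.fixture(scope="module")
def recovery_fit():
    rec = synthdata.generate_model_records(n_users=200, n_days=20, seed=3)
    return rec, stepmodel.fit(rec)


@pytest.fixture(scope="module")
def null_fit():
    rec = synthdata.generate_model_records(n_users=200, n_days=20, seed=3, null=True)
    return rec, stepmodel.fit(rec)


def _centered(values):
    v = np.asarray(values, dtype=float)
    return v - v.mean()


class TestFit:
    def test_variance_components_recovered(self, recovery_fit):
        _, fit = recovery_fit
        cfg = synthdata.WorldConfig()
        assert fit.sigma2_l1 ** 0.5 == pytest.approx(cfg.sigma_l1, rel=0.15)
        assert fit.sigma2_l2 ** 0.5 == pytest.approx(cfg.sigma_l2, rel=0.30)

    def test_smooth_shapes_recovered(self, recovery_fit):
        _, fit = recovery_fit
        informative = ["high_rise", "dense_low_rise", "low_rise", "railways"]
        for name in informative:
            term = next(t for t in fit.terms if t.name == name)
            xs = np.linspace(term.x_min, term.x_max, 100)
            est = _centered(fit.smooth_curve(name, xs)["estimate"])
            true = _centered(synthdata.TRUE_SMOOTHS[name](xs))
            rng = float(true.max() - true.min())
            rmse = float(np.sqrt(np.mean((est - true) ** 2)))
            assert rmse < 0.15 * rng, name
            assert term.significant, name

    def test_null_data_gives_flat_fit(self, null_fit):
        _, fit = null_fit
        assert fit.deviance_explained < 0.05
        assert fit.sigma2_l2 ** 0.5 < 100.0
        coverage = []
        for term in fit.terms:
            xs = np.linspace(term.x_min, term.x_max, 50)
            est = fit.smooth_curve(term.name, xs)
            # smooths shrink to ~0 relative to the noise sd
            assert np.abs(est["estimate"]).max() < 0.15 * synthdata.WorldConfig().sigma_l1
            coverage.append(((est["lo"] <= 0) & (0 <= est["hi"])).mean())
        # pointwise 95% bands may miss zero on parts of a few of the 8 null
        # smooths (ordinary type-I behaviour), but must mostly cover it
        assert np.mean(coverage) >= 0.8

    def test_refit_deterministic(self):
        rec = synthdata.generate_model_records(n_users=30, n_days=6, seed=5)
        f1 = stepmodel.fit(rec)
        f2 = stepmodel.fit(rec)
        np.testing.assert_allclose(f1.beta, f2.beta, rtol=1e-10)

    def test_deviance_explained_bounds_and_monotone(self, recovery_fit):
        rec, fit = recovery_fit
        assert 0.0 <= fit.deviance_explained <= 1.0
        # dropping a truly informative smooth cannot increase fit
        smaller = ModelConfig(smooth_types=tuple(t for t in TYPES if t != "high_rise"))
        fit_small = stepmodel.fit(rec, smaller)
        assert fit.deviance_explained >= fit_small.deviance_explained

    def test_requires_two_users(self):
        rec = synthdata.generate_model_records(n_users=5, n_days=4, seed=1)
        with pytest.raises(ValueError, match="2 users"):
            stepmodel.fit(rec[rec["uuid"] == rec["uuid"].iloc[0]])

    def test_rank_deficiency_names_columns(self):
        rec = synthdata.generate_model_records(n_users=20, n_days=4, seed=1)
        rec["sex"] = "male"
        with pytest.raises(ValueError, match="sex"):
            stepmodel.fit(rec)


class TestOlsReduction:
    def test_single_linear_smooth_no_random_equals_ols(self):
        rec = synthdata.generate_model_records(n_users=40, n_days=6, seed=7)
        cfg = ModelConfig(
            smooth_types=("parks_public",),
            linear_terms=frozenset({"parks_public"}),
            include_sex_age=False,
            include_random_intercept=False,
        )
        fit = stepmodel.fit(rec, cfg)
        x = np.log1p(rec["parks_public"].to_numpy(float))
        y = rec["steps"].to_numpy(float)
        slope, intercept = np.polyfit(x, y, 1)
        xc = x - x.mean()
        pred_ols = intercept + slope * x
        pred_fit = fit.predict_fixed(rec) + fit.beta[fit.terms[0].sl][0] * 0  # alpha + s
        # fixed-effects prediction is alpha + s(x) = OLS line
        np.testing.assert_allclose(pred_fit, pred_ols, rtol=1e-6)
        assert fit.beta[fit.terms[0].sl][0] == pytest.approx(slope, rel=1e-6)


class TestPredictFixed:
    def test_identity_for_identical_counts_across_users(self, recovery_fit):
        _, fit = recovery_fit
        base = {t: 5 for t in TYPES}
        rec = pd.DataFrame(
            [dict(uuid="zz1", date="2019-10-01", **base),
             dict(uuid="another", date="2019-10-09", **base)]
        )
        out = fit.predict_fixed(rec)
        assert out[0] == pytest.approx(out[1], abs=1e-9)

    def test_all_zero_counts_is_alpha_plus_s_at_zero(self, recovery_fit):
        _, fit = recovery_fit
        rec = pd.DataFrame([dict(uuid="q", date="2019-10-01", **{t: 0 for t in TYPES})])
        expected = fit.alpha + sum(
            float(fit.smooth_curve(t.name, [0.0])["estimate"][0])
            for t in fit.terms if t.kind != "dropped"
        )
        assert fit.predict_fixed(rec)[0] == pytest.approx(expected, abs=1e-6)

    def test_manual_basis_dot_product(self, recovery_fit):
        from scipy.interpolate import BSpline

        _, fit = recovery_fit
        rec = pd.DataFrame([dict(uuid="q", date="2019-10-01", **{t: 3 for t in TYPES})])
        manual = fit.alpha
        for term in fit.terms:
            if term.kind != "spline":
                continue
            x = np.array([np.log1p(3.0)])
            B = BSpline.design_matrix(x, term.knots, term.degree, extrapolate=True).toarray()
            manual += float((B @ term.Z @ fit.beta[term.sl])[0])
        assert fit.predict_fixed(rec)[0] == pytest.approx(manual, abs=1e-9)

    def test_record_order_invariance(self, recovery_fit):
        rec, fit = recovery_fit
        sample = rec.iloc[:50]
        perm = sample.sample(frac=1.0, random_state=1)
        out = pd.Series(fit.predict_fixed(perm), index=perm.index).sort_index()
        ref = pd.Series(fit.predict_fixed(sample), index=sample.index).sort_index()
        np.testing.assert_allclose(out.to_numpy(), ref.to_numpy(), rtol=1e-12)

    def test_unfitted_input_rejected(self):
        with pytest.raises(ValueError, match="fitted"):
            stepmodel.predict_fixed(object(), pd.DataFrame())


class TestSmoothCurve:
    def test_bands_finite_and_widen_toward_edges(self, recovery_fit):
        _, fit = recovery_fit
        term = next(t for t in fit.terms if t.name == "high_rise")
        xs = np.linspace(term.x_min, term.x_max, 201)
        cv = fit.smooth_curve("high_rise", xs)
        assert np.isfinite(cv[["estimate", "se", "lo", "hi"]].to_numpy()).all()
        # exposure indices are zero-inflated, so the low end is data-dense;
        # the sparse upper end of the range must have the widest band
        mid = cv["se"].iloc[90:110].mean()
        assert cv["se"].iloc[-1] > mid

    def test_invalid_smooth_name(self, recovery_fit):
        _, fit = recovery_fit
        with pytest.raises(ValueError, match="swamp"):
            fit.smooth_curve("swamp", [0.0])


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, recovery_fit, tmp_path):
        rec, fit = recovery_fit
        path = tmp_path / "model.json"
        stepmodel.save_fit(fit, path)
        back = stepmodel.load_fit(path)
        np.testing.assert_allclose(
            back.predict_fixed(rec.iloc[:25]), fit.predict_fixed(rec.iloc[:25]), rtol=1e-12
        )
        assert back.sigma2_l2 == pytest.approx(fit.sigma2_l2)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_against_mgcv_reference(tmp_path):
    """Independent oracle: the same model fitted by mgcv agrees closely."""
    rec = synthdata.generate_model_records(n_users=60, n_days=10, seed=3)
    fit = stepmodel.fit(rec)
    dat = rec.copy()
    dat["sex01"] = (dat["sex"] == "female").astype(int)
    dat["age"] = dat["age_group"].str[:-1].astype(int)
    dat.to_csv(tmp_path / "dat.csv", index=False)
    smooths = "+".join(f's(x_{t},bs="ps",k=10)' for t in TYPES)
    script = f"""
    library(mgcv)
    dat <- read.csv("{tmp_path}/dat.csv")
    dat$uuid <- factor(dat$uuid)
    for (nm in c({", ".join(repr(t) for t in TYPES)})) dat[[paste0("x_", nm)]] <- log1p(dat[[nm]])
    m <- gam(steps ~ sex01 + age + {smooths} + s(uuid, bs="re"), data = dat, method = "REML")
    vc <- gam.vcomp(m)
    xs <- seq(min(dat$x_high_rise), max(dat$x_high_rise), length = 50)
    nd <- dat[rep(1, 50), ]; nd$x_high_rise <- xs
    pr <- predict(m, nd, type = "terms")
    write.csv(data.frame(x = xs, s = pr[, "s(x_high_rise)"]), "{tmp_path}/curve.csv", row.names = FALSE)
    cat(sqrt(m$sig2), vc["s(uuid)", "std.dev"], summary(m)$dev.expl, sep = "\\n")
    """
    (tmp_path / "run.R").write_text(script)
    res = subprocess.run(
        ["Rscript", str(tmp_path / "run.R")], capture_output=True, text=True, timeout=300
    )
    assert res.returncode == 0, res.stderr[-2000:]
    sl1_r, sl2_r, dev_r = (float(v) for v in res.stdout.strip().split("\n")[-3:])
    assert fit.sigma2_l1 ** 0.5 == pytest.approx(sl1_r, rel=0.05)
    assert fit.sigma2_l2 ** 0.5 == pytest.approx(sl2_r, rel=0.10)
    assert fit.deviance_explained == pytest.approx(dev_r, abs=0.03)
    curve = pd.read_csv(tmp_path / "curve.csv")
    mine = _centered(fit.smooth_curve("high_rise", curve["x"].to_numpy())["estimate"])
    ref = _centered(curve["s"])
    rng = float(ref.max() - ref.min())
    assert float(np.sqrt(np.mean((mine - ref) ** 2))) < 0.02 * rng
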