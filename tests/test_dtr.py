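"""dWOLS engine: weights, vertex logic, recovery, double robustness."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from shockdtr.dtr import (StageFit, attach_class_labels, bootstrap_dtr,
                          fit_dtr, fit_stage_models, optimal_dose,
                          recommend_doses)

PSI = {"psi0": -0.064, "psi1": 0.008, "psi2": 0.008}  # vertex 4 - 0.5 z


def single_stage_sim(n, seed, psi=PSI, treatment_free="linear"):
    """One-stage cohort on the linear-probability scale (working-model truth).

    Doses sit far from zero so the nonnegativity clip is negligible and the
    linear treatment model stays correctly specified (its residuals symmetric),
    which the double-robustness property requires.
    """
    rng = np.random.default_rng(seed)
    z = rng.uniform(-2.0, 2.0, n)
    # doses far from zero with normal residuals: the normal treatment-density
    # family of the default weights is correctly specified, truncation at zero
    # is negligible, and the linear-probability outcome (almost) never clips
    a = np.maximum(5.0 + z + rng.normal(0.0, 1.0, n), 0.0)
    f = 0.45 + 0.05 * z if treatment_free == "linear" else 0.42 + 0.08 * (z * z - 1.0)
    p = np.clip(f + a * (psi["psi0"] + psi["psi1"] * z) + psi["psi2"] * a * a, 0.01, 0.99)
    y = (rng.random(n) < p).astype(float)
    return pd.DataFrame({"patient_id": np.arange(n), "day": 0, "z": z,
                         "dose": a, "death_hosp": y})


def multi_stage_sim(n, seed, vertices=(5.0, 4.5, 4.0, 3.5, 2.5), psi2=0.03):
    """Five-stage cohort; every stage's blip vertex is 'vertices[j] - 0.5 z'."""
    rng = np.random.default_rng(seed)
    days = [0, 1, 2, 3, 7]
    rows, total_regret = [], np.zeros(n)
    for j, day in enumerate(days):
        z = rng.standard_normal(n)
        a = np.maximum(rng.normal(vertices[j] + 0.3 * z, 1.0), 0.0)
        a_star = vertices[j] - 0.5 * z
        total_regret += psi2 * (a - a_star) ** 2
        rows.append(pd.DataFrame({"patient_id": np.arange(n), "day": day,
                                  "z": z, "dose": a}))
    p = np.clip(0.10 + total_regret, 0.0, 1.0)
    y = (rng.random(n) < p).astype(float)
    df = pd.concat(rows, ignore_index=True)
    df["death_hosp"] = y[df["patient_id"].to_numpy()]
    return df


class TestStageModels:
    def test_weights_reduce_to_centered_dose_without_covariate_signal(self):
        rng = np.random.default_rng(0)
        n = 600
        df = pd.DataFrame({"patient_id": range(n), "day": 0,
                           "z": rng.standard_normal(n),
                           "dose": rng.gamma(4.0, 0.5, n)})
        y = rng.random(n)
        # no state covariates: the treatment model is intercept-only, so the
        # balancing weights reduce exactly to |a - mean(a)| (up to the floor)
        fit, w = fit_stage_models(df, "dose", y, [], [], weight_scheme="abs_residual")
        a = df["dose"].to_numpy()
        expected = np.maximum(np.abs(a - a.mean()), 1e-3 * fit.treatment_resid_sd)
        assert np.allclose(w, expected, atol=1e-10)

    def test_treatment_model_matches_ols_oracle(self):
        df = single_stage_sim(2000, seed=1)
        fit, _ = fit_stage_models(df, "dose", df["death_hosp"].to_numpy(), ["z"], ["z"])
        ols = sm.OLS(df["dose"], sm.add_constant(df["z"])).fit()
        assert np.allclose(fit.treatment_coef, ols.params.to_numpy(), atol=1e-8)
        # truncation at zero is mild here; recovery within 3 SE of the truth
        assert abs(ols.params.iloc[1] - 1.0) < 3 * ols.bse.iloc[1] + 0.05

    def test_zero_blip_coefficients_within_3se(self):
        rng = np.random.default_rng(2)
        n = 2000
        df = pd.DataFrame({"patient_id": range(n), "day": 0,
                           "z": rng.standard_normal(n),
                           "dose": np.maximum(rng.normal(2, 1, n), 0)})
        y = (rng.random(n) < 0.3).astype(float)  # outcome unrelated to dose
        fit, _ = fit_stage_models(df, "dose", y, ["z"], ["z"])
        psi = np.concatenate([[fit.psi0], fit.psix, [fit.psi2]])
        assert (np.abs(psi) < 3 * fit.psi_se).all()
        assert fit.non_informative

    def test_small_stage_rejected(self):
        df = single_stage_sim(30, seed=3)
        with pytest.raises(ValueError, match="at-risk"):
            fit_stage_models(df, "dose", df["death_hosp"].to_numpy(), ["z"], ["z"])

    def test_collinear_design_named(self):
        df = single_stage_sim(500, seed=4)
        df["z2"] = 2.0 * df["z"]
        with pytest.raises(np.linalg.LinAlgError, match="z2"):
            fit_stage_models(df, "dose", df["death_hosp"].to_numpy(), ["z", "z2"], ["z"])


class TestOptimalDose:
    def _fit(self, psi0, psix, psi2, bounds=(0.0, 4.0)):
        return StageFit(stage=0, psi0=psi0, psix=np.asarray(psix, float),
                        psi2=psi2, beta=np.zeros(1), xbeta_cols=[],
                        xpsi_cols=["z"] if len(np.atleast_1d(psix)) else [],
                        treatment_coef=np.zeros(1), treatment_resid_sd=1.0,
                        bounds=bounds, weight_scheme="abs_residual", n=100)

    def test_interior_vertex(self):
        fit = self._fit(-2.0, [0.0], 1.0)
        assert optimal_dose(fit, [[0.0]])[0] == pytest.approx(1.0)

    def test_vertex_clipped_at_bound(self):
        fit = self._fit(2.0, [0.0], 1.0)  # vertex -1
        assert optimal_dose(fit, [[0.0]])[0] == 0.0

    def test_concave_blip_picks_better_endpoint(self):
        fit = self._fit(-1.0, [0.0], -0.5)
        lo, hi = fit.bounds
        g = lambda a: a * -1.0 + -0.5 * a * a
        want = lo if g(lo) <= g(hi) else hi
        assert optimal_dose(fit, [[0.0]])[0] == want
        assert not fit.convex

    def test_grid_search_oracle_under_generating_model(self):
        """Vertex/clipping logic agrees with brute-force grid minimization."""
        rng = np.random.default_rng(5)
        fit = self._fit(PSI["psi0"], [PSI["psi1"]], PSI["psi2"], bounds=(0.0, 5.0))
        grid = np.linspace(0.0, 5.0, 101)  # step = 1% of range
        for z in rng.standard_normal(50):
            blip = grid * (PSI["psi0"] + PSI["psi1"] * z) + PSI["psi2"] * grid**2
            best = grid[np.argmin(blip)]
            got = optimal_dose(fit, [[z]])[0]
            assert abs(got - best) <= 0.05 + 1e-12


class TestFitDtr:
    def test_single_stage_psi_recovery_within_bootstrap_se(self):
        df = single_stage_sim(2000, seed=6)
        fit = fit_dtr(df, "dose", ["z"], ["z"], stages=[0])
        sf = fit.stage_fits[0]
        boots = bootstrap_dtr(df, "dose", ["z"], ["z"], stages=[0],
                              n_boot=60, seed=7)[0]
        est = np.array([sf.psi0, sf.psix[0], sf.psi2])
        truth = np.array([PSI["psi0"], PSI["psi1"], PSI["psi2"]])
        se = boots.std(ddof=1).to_numpy()
        assert (np.abs(est - truth) < 3 * se).all()

    def test_five_stage_vertex_rmse_below_ten_percent_of_range(self):
        df = multi_stage_sim(2000, seed=8)
        fit = fit_dtr(df, "dose", ["z"], ["z"])
        vertices = (5.0, 4.5, 4.0, 3.5, 2.5)
        for j, day in enumerate([0, 1, 2, 3, 7]):
            sf = fit.stage_fits[day]
            sub = df[df["day"] == day]
            est = optimal_dose(sf, sub[["z"]].to_numpy())
            true = np.clip(vertices[j] - 0.5 * sub["z"].to_numpy(), *sf.bounds)
            rng_width = sf.bounds[1] - sf.bounds[0]
            rmse = np.sqrt(((est - true) ** 2).mean())
            assert rmse < 0.10 * rng_width, (day, rmse, rng_width)

    def test_double_robustness_bias_shrinks(self):
        """Misspecified treatment-free model + correct treatment model:
        psi error still shrinks with n (dWOLS double robustness)."""
        mae = {}
        for n in (500, 2000, 8000):
            errs = []
            for rep in range(25):
                df = single_stage_sim(n, seed=1000 * n + rep,
                                      treatment_free="quadratic")
                sf = fit_dtr(df, "dose", ["z"], ["z"], stages=[0]).stage_fits[0]
                errs.append(abs(sf.psix[0] - PSI["psi1"]))
            mae[n] = np.mean(errs)
        assert mae[2000] < mae[500] and mae[8000] < mae[500], mae
        assert mae[8000] < 0.7 * mae[500], mae

    def test_nonconstant_outcome_rejected(self):
        df = single_stage_sim(300, seed=9)
        df2 = pd.concat([df, df.assign(day=1, death_hosp=1 - df["death_hosp"])])
        with pytest.raises(ValueError, match="constant within patient"):
            fit_dtr(df2, "dose", ["z"], ["z"], stages=[0, 1])

    def test_empty_stage_skipped_and_recorded(self):
        df = single_stage_sim(400, seed=10)
        fit = fit_dtr(df, "dose", ["z"], ["z"], stages=[0, 3])
        assert fit.skipped_stages == [3]
        assert list(fit.stage_fits) == [0]


class TestRecommendDoses:
    def test_recommendations_within_bounds_and_flags(self):
        df = multi_stage_sim(800, seed=11)
        fit = fit_dtr(df, "dose", ["z"], ["z"])
        rec = recommend_doses(fit, df)
        for day, sf in fit.stage_fits.items():
            sub = rec[rec["day"] == day]
            assert (sub["optimal"] >= sf.bounds[0] - 1e-9).all()
            assert (sub["optimal"] <= sf.bounds[1] + 1e-9).all()
        assert len(rec) == len(df)
        assert np.allclose(rec["delta"], rec["actual"] - rec["optimal"])

    def test_zero_blip_recommendations_flagged(self):
        rng = np.random.default_rng(12)
        n = 1500
        df = pd.DataFrame({"patient_id": range(n), "day": 0,
                           "z": rng.standard_normal(n),
                           "dose": np.maximum(rng.normal(2, 1, n), 0),
                           "death_hosp": (rng.random(n) < 0.3).astype(float)})
        fit = fit_dtr(df, "dose", ["z"], ["z"], stages=[0])
        rec = recommend_doses(fit, df)
        assert rec["non_informative"].all()

    def test_declining_optimum_recovered_per_day(self):
        df = multi_stage_sim(2000, seed=13)
        fit = fit_dtr(df, "dose", ["z"], ["z"])
        med = recommend_doses(fit, df).groupby("day")["optimal"].median()
        assert (np.diff(med[[0, 1, 2, 3, 7]].to_numpy()) < 0).all()

    def test_affine_recode_of_nonblip_covariate_is_invariant(self):
        df = single_stage_sim(1500, seed=14)
        fit_a = fit_dtr(df, "dose", ["z"], [], stages=[0])
        df_b = df.assign(z=3.0 * df["z"] + 7.0)
        fit_b = fit_dtr(df_b, "dose", ["z"], [], stages=[0])
        rec_a = recommend_doses(fit_a, df)
        rec_b = recommend_doses(fit_b, df_b)
        assert np.allclose(rec_a["optimal"], rec_b["optimal"], atol=1e-6)


def test_attach_class_labels_one_hot(small_cohort):
    _, cohort, truth = small_cohort
    labels = truth.rename(columns={"true_class": "label"})[["patient_id", "day", "label"]]
    labeled = attach_class_labels(cohort, labels)
    hot = labeled[[f"class_{k}" for k in range(2, 6)]].sum(axis=1)
    assert set(hot.unique()) <= {0.0, 1.0}
    assert ((hot == 0) == (labeled["label"] == 1)).all()
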