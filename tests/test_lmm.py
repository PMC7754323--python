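"""One-stage ANCOVA LMM: design, REML correctness, inference."""

import numpy as np
import pandas as pd
import pytest

from pseudoipd.lmm import AncovaLMM, ModelSpec, _objective, build_design, fit_one_stage
from pseudoipd.simulate import SimScenario, simulate_ipd
from pseudoipd.twostage import fit_study_ancova

LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# independent dense-matrix evaluation of the restricted likelihood


def _dense_design(df, spec):
    """Build X, Z-blocks and residual-cell labels directly from the records."""
    df = df.copy()
    studies = list(dict.fromkeys(df["study"]))
    centers = df.groupby("study")["y_base"].mean()
    df["bc"] = df["y_base"] - df["study"].map(centers)
    x = df["treat"].to_numpy(float)

    cols = {}
    if spec.level == "stratified_study":
        for s in studies:
            cols[f"intercept[{s}]"] = (df["study"] == s).astype(float)
        for s in studies:
            cols[f"baseline_c[{s}]"] = df["bc"] * (df["study"] == s)
    else:
        cols["intercept"] = np.ones(len(df))
        cols["baseline_c"] = df["bc"]
    cols["treat"] = x
    if spec.interaction:
        cols["treat:baseline_c"] = df["bc"] * x
        if spec.include_across_trial:
            cols["treat:baseline_mean"] = df["study"].map(centers) * x
    X = pd.DataFrame(cols).to_numpy(float)

    kappa = 0.5 if spec.center_re else 0.0
    re_cols = []
    if spec.level == "random_study":
        re_cols += [np.ones(len(df)), df["bc"].to_numpy(float)]
    if spec.treatment_random:
        re_cols.append(x - kappa)
    if spec.interaction and (spec.treatment_random or spec.level == "random_study"):
        re_cols.append(df["bc"].to_numpy(float) * (x - kappa))
    Z = np.column_stack(re_cols) if re_cols else np.zeros((len(df), 0))

    rs = spec.residual_structure
    if rs == "by_study_arm":
        cell_names = [f"{s}/{a}" for s in studies for a in ("control", "treated")]
        cells = [f"{s}/{'treated' if t else 'control'}" for s, t in zip(df["study"], df["treat"])]
    elif rs == "by_study":
        cell_names = studies
        cells = list(df["study"])
    elif rs == "by_arm":
        cell_names = ["control", "treated"]
        cells = ["treated" if t else "control" for t in df["treat"]]
    else:
        cell_names = ["pooled"]
        cells = ["pooled"] * len(df)
    cell_idx = np.array([cell_names.index(c) for c in cells])
    study_idx = np.array([studies.index(s) for s in df["study"]])
    return X, list(cols), Z, cell_idx, study_idx, df["y_final"].to_numpy(float)


def _dense_G(theta_g, q, cov):
    L = np.zeros((q, q))
    if cov == "unstructured":
        L[np.diag_indices(q)] = np.exp(theta_g[:q])
        k = q
        for j in range(q):
            for i in range(j + 1, q):
                L[i, j] = theta_g[k]
                k += 1
    else:
        L[np.diag_indices(q)] = np.exp(theta_g)
    return L @ L.T


def dense_neg2_reml(df, spec, theta, n_res, q):
    X, names, Z, cell_idx, study_idx, y = _dense_design(df, spec)
    n, p = X.shape
    sig2 = np.exp(2.0 * np.asarray(theta[:n_res]))
    V = np.diag(sig2[cell_idx])
    if q:
        G = _dense_G(np.asarray(theta[n_res:]), q, spec.re_cov)
        for s in np.unique(study_idx):
            m = study_idx == s
            V[np.ix_(m, m)] += Z[m] @ G @ Z[m].T
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    val = (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtVX)[1]
        + r @ Vi @ r
        + (n - p) * LOG2PI
    )
    return val, beta, names, np.linalg.inv(XtVX)


DENSE_SPECS = [
    ModelSpec(level="stratified_study", residual_structure="by_study", reml_constant="rank"),
    ModelSpec(level="stratified_study", residual_structure="by_study_arm",
              interaction=True, reml_constant="rank"),
    ModelSpec(level="random_study", residual_structure="pooled", reml_constant="rank"),
    ModelSpec(level="random_study", residual_structure="by_arm",
              interaction=True, reml_constant="rank"),
]


@pytest.fixture(scope="module")
def tiny_ipd():
    sc = SimScenario(
        n_studies=3, n_per_arm=[12, 15, 10],
        mu_baseline=[150, 160, 155], sigma_baseline=[12, 15, 10],
        beta0=[140, 150, 148], beta1=-8.0, beta2=[0.5, 0.6, 0.4],
        tau1_sq=4.0, residual_structure="by_study", residuals=[9, 11, 8], seed=11,
    )
    return simulate_ipd(sc)


class TestRemlAgainstDenseOracle:
    @pytest.mark.parametrize("spec", DENSE_SPECS, ids=lambda s: f"{s.level}-{s.residual_structure}")
    def test_objective_matches_dense_formula(self, tiny_ipd, spec):
        model = AncovaLMM(tiny_ipd, spec)
        d = model.design
        rng = np.random.default_rng(0)
        n_g = d.q * (d.q + 1) // 2 if d.spec.re_cov == "unstructured" else d.q
        for _ in range(3):
            theta = np.concatenate([
                rng.uniform(1.5, 2.5, d.n_res),   # residual log-SDs
                rng.uniform(-0.5, 1.0, n_g),      # random-effect parameters
            ])
            mine = _objective(theta, d)
            dense, _, _, _ = dense_neg2_reml(tiny_ipd, spec, theta, d.n_res, d.q)
            assert mine == pytest.approx(dense, abs=1e-8)

    def test_fitted_optimum_matches_dense_formula(self, tiny_ipd):
        spec = ModelSpec(level="stratified_study", residual_structure="by_study",
                         reml_constant="rank")
        res = AncovaLMM(tiny_ipd, spec).fit()
        dense, _, _, _ = dense_neg2_reml(tiny_ipd, spec, res.theta,
                                         res.model.design.n_res, res.model.design.q)
        assert res.minus2_reml == pytest.approx(dense, abs=1e-8)

    def test_gls_consistency_at_optimum(self, tiny_ipd):
        # refitting the fixed effects by explicit dense GLS at the returned
        # variance parameters must reproduce the estimates and SEs
        spec = ModelSpec(level="stratified_study", residual_structure="by_study",
                         interaction=True, reml_constant="rank")
        res = AncovaLMM(tiny_ipd, spec).fit()
        d = res.model.design
        _, beta, names, cov = dense_neg2_reml(tiny_ipd, spec, res.theta, d.n_res, d.q)
        dense_params = pd.Series(beta, index=names)
        for nm in res.params.index:
            assert res.params[nm] == pytest.approx(dense_params[nm], abs=1e-10)
            j = names.index(nm)
            assert float(res.bse[nm]) == pytest.approx(np.sqrt(cov[j, j]), abs=1e-10)


class TestDesign:
    def test_centering_uses_observed_study_means(self, tiny_ipd):
        d = build_design(tiny_ipd, ModelSpec())
        means = tiny_ipd.groupby("study")["y_base"].mean()
        for b in d.blocks:
            assert b.center == pytest.approx(means[b.study_id], rel=1e-12)

    def test_shifted_data_moves_centers_by_arm_share_of_shift(
        self, hyp_ipd, hyp_ipd_imbalanced
    ):
        # the treated-arm -5 shift in ATMH moves the study mean by
        # -5 * nT / (nT + nC)
        d_bal = build_design(hyp_ipd, ModelSpec())
        d_imb = build_design(hyp_ipd_imbalanced, ModelSpec())
        c_bal = {b.study_id: b.center for b in d_bal.blocks}
        c_imb = {b.study_id: b.center for b in d_imb.blocks}
        assert c_imb["ATMH"] - c_bal["ATMH"] == pytest.approx(-5 * 780 / 1530, abs=1e-6)
        assert c_imb["SHEP"] == pytest.approx(c_bal["SHEP"], abs=1e-9)

    def test_single_arm_study_rejected(self, tiny_ipd):
        broken = tiny_ipd[~((tiny_ipd["study"] == "S1") & (tiny_ipd["treat"] == 0))]
        with pytest.raises(ValueError, match="both"):
            build_design(broken, ModelSpec())

    def test_constant_baseline_rejected(self, tiny_ipd):
        broken = tiny_ipd.copy()
        broken.loc[broken["study"] == "S2", "y_base"] = 160.0
        with pytest.raises(ValueError, match="constant"):
            build_design(broken, ModelSpec())

    def test_unstructured_cov_needs_two_effects(self, tiny_ipd):
        with pytest.raises(ValueError, match="unstructured"):
            build_design(tiny_ipd, ModelSpec(random_effects_cov="unstructured"))

    def test_omitting_across_trial_changes_interaction_estimand(self):
        # when across-trial effect modification (here +0.5 per baseline unit)
        # disagrees with the within-trial interaction (-0.1), the merged
        # coefficient is pulled toward the ecological association
        sc = SimScenario(
            n_studies=5, n_per_arm=20,
            mu_baseline=[120, 140, 160, 180, 200], sigma_baseline=[8] * 5,
            beta0=[130, 140, 150, 160, 170], beta1=-5.0, beta2=[0.5] * 5,
            beta3=-0.1, beta4=0.5, interaction=True,
            residual_structure="pooled", residuals=6.0, seed=13,
        )
        ipd = simulate_ipd(sc)
        with_sep = AncovaLMM(ipd, interaction=True, include_across_trial=True).fit()
        merged = AncovaLMM(ipd, interaction=True, include_across_trial=False).fit()
        # pulled toward the (larger) across-trial slope, and by more than
        # numerical tolerance
        assert merged.beta3 - with_sep.beta3 > 1e-3
        assert merged.beta3 < with_sep.beta4


class TestSingleStudyOls:
    def test_equals_closed_form_ols(self, tiny_ipd):
        one = tiny_ipd[tiny_ipd["study"] == "S1"].reset_index(drop=True)
        res = AncovaLMM(one, level="stratified_study", residual_structure="pooled",
                        treatment_random=False).fit()
        Xc = np.column_stack([
            np.ones(len(one)),
            one["treat"],
            one["y_base"] - one["y_base"].mean(),
        ])
        beta = np.linalg.lstsq(Xc, one["y_final"].to_numpy(), rcond=None)[0]
        assert res.beta1 == pytest.approx(beta[1], abs=1e-10)

    def test_equals_two_stage_first_stage(self, tiny_ipd):
        one = tiny_ipd[tiny_ipd["study"] == "S2"].reset_index(drop=True)
        res = AncovaLMM(one, residual_structure="pooled", treatment_random=False).fit()
        eff = fit_study_ancova(one)[0]
        assert res.beta1 == pytest.approx(eff.estimate, abs=1e-10)


class TestInference:
    def test_between_within_df(self, small_pseudo_ipd):
        res = fit_one_stage(small_pseudo_ipd, residual_structure="by_study")
        assert res.df_for("treat") == 3  # 4 studies - 1
        d = res.model.design
        assert res.df_for("intercept[S1]") == d.n_obs - d.p

    def test_unknown_effect_rejected(self, small_pseudo_ipd):
        res = fit_one_stage(small_pseudo_ipd, residual_structure="by_study")
        with pytest.raises(KeyError):
            res.conf_int("nonexistent")

    def test_ci_is_t_interval(self, small_pseudo_ipd):
        from scipy import stats

        res = fit_one_stage(small_pseudo_ipd, residual_structure="by_study")
        lo, hi, df = res.conf_int("treat")
        t = stats.t.ppf(0.975, df)
        assert hi - lo == pytest.approx(2 * t * float(res.bse["treat"]), rel=1e-12)

    def test_aic_counts_covariance_parameters_only(self, small_pseudo_ipd):
        res = fit_one_stage(small_pseudo_ipd, residual_structure="by_study_arm")
        assert res.n_cov_params == 8 + 1  # 4 studies x 2 arms + tau1
        assert res.aic == pytest.approx(res.minus2_reml + 2 * res.n_cov_params)

    def test_nesting_inequality_in_reml_deviance(self, small_pseudo_ipd):
        m2 = {
            rs: fit_one_stage(small_pseudo_ipd, residual_structure=rs).minus2_reml
            for rs in ("pooled", "by_arm", "by_study", "by_study_arm")
        }
        assert m2["by_study_arm"] <= m2["by_study"] + 1e-6
        assert m2["by_study_arm"] <= m2["by_arm"] + 1e-6
        assert m2["by_study"] <= m2["pooled"] + 1e-6
        assert m2["by_arm"] <= m2["pooled"] + 1e-6

    def test_boundary_heterogeneity_detected(self):
        sc = SimScenario(
            n_studies=4, n_per_arm=80,
            mu_baseline=[150, 152, 151, 149], sigma_baseline=[10, 10, 10, 10],
            beta0=[140, 141, 140, 142], beta1=-5.0, beta2=[0.5, 0.5, 0.5, 0.5],
            tau1_sq=0.0, residual_structure="pooled", residuals=6.0, seed=21,
        )
        res = fit_one_stage(simulate_ipd(sc), residual_structure="pooled")
        assert res.tau1_sq < 0.5
        if res.tau1_sq < 1e-10:
            assert bool(res.boundary_flags["treat"])

    def test_summary_mentions_key_quantities(self, small_pseudo_ipd):
        res = fit_one_stage(small_pseudo_ipd, residual_structure="by_study")
        text = res.summary()
        assert "treat" in text and "AIC" in text and "REML" in text


class TestStatsmodelsCrossCheck:
    def test_pooled_residual_matches_mixedlm(self):
        # statsmodels MixedLM can fit the pooled-residual special case and
        # serves as an independent REML implementation
        from statsmodels.regression.mixed_linear_model import MixedLM

        sc = SimScenario(
            n_studies=5, n_per_arm=40,
            mu_baseline=[150, 160, 155, 170, 165], sigma_baseline=[12, 15, 10, 9, 11],
            beta0=[140, 150, 148, 158, 152], beta1=-8.0,
            beta2=[0.5, 0.6, 0.4, 0.55, 0.5],
            tau1_sq=4.0, residual_structure="pooled", residuals=8.0, seed=3,
        )
        ipd = simulate_ipd(sc)
        mine = AncovaLMM(ipd, level="stratified_study", residual_structure="pooled").fit()
        df = ipd.copy()
        df["bc"] = df.groupby("study")["y_base"].transform(lambda s: s - s.mean())
        sm_fit = MixedLM.from_formula(
            "y_final ~ 0 + C(study) + bc:C(study) + treat",
            groups="study", re_formula="0 + treat", data=df,
        ).fit(reml=True)
        assert mine.beta1 == pytest.approx(float(sm_fit.params["treat"]), abs=1e-5)
        assert float(mine.bse["treat"]) == pytest.approx(float(sm_fit.bse["treat"]), rel=1e-3)
        assert mine.tau1_sq == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2)
        assert float(mine.residual_variances.iloc[0]) == pytest.approx(
            float(sm_fit.scale), rel=1e-3
        )
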