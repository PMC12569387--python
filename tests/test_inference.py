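"""Mixed models, Wald tables, EMM contrasts, Bayes factors, circular ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somacross import inference as inf
from somacross import synthetic_data as sd


@pytest.fixture(scope="module")
def pse_fit():
    data = sd.simulate_pse_table(31, -7.4, seed=42)
    return inf.fit_lmm(data, inf.LmmSpec("pse"))


class TestFitLmm:
    def test_degenerate_lmm_matches_ols(self):
        # no participant-level variance: fixed effects reduce to OLS
        data = sd.simulate_pse_table(
            30, -5.0, seed=3, sd_participant=0.0, sd_slope=0.0, sd_resid=4.0
        )
        fit = inf.fit_lmm(data, inf.LmmSpec("pse", random=("intercept",)))
        import statsmodels.formula.api as smf

        ols = smf.ols(
            "pse ~ C(session, Treatment('pre')) * C(intervention, Treatment('sham'))",
            data,
        ).fit()
        assert np.allclose(fit.result.fe_params, ols.params, atol=1e-4)

    def test_reports_realized_random_structure(self, pse_fit):
        assert pse_fit.random_structure in (
            ("intercept", "session", "intervention"),
            ("intercept", "intervention"),
            ("intercept",),
        )
        assert pse_fit.ladder_record[-1]["converged"]

    def test_unbalanced_data_still_converges(self):
        data = sd.simulate_pse_table(12, 0.0, seed=5)
        data = data.drop(index=[0, 5, 9]).reset_index(drop=True)
        fit = inf.fit_lmm(data, inf.LmmSpec("pse"))
        assert fit.result.converged

    def test_constant_response_rejected(self):
        data = sd.simulate_pse_table(5, 0.0, seed=0)
        data["pse"] = 1.0
        with pytest.raises(ValueError):
            inf.fit_lmm(data, inf.LmmSpec("pse"))

    def test_interaction_coverage_at_95(self):
        # the injected interaction falls inside its Wald 95% CI ~95% of runs
        hits, runs = 0, 60
        z = stats.norm.ppf(0.975)
        for seed in range(runs):
            data = sd.simulate_pse_table(20, -7.4, seed=900 + seed)
            fit = inf.fit_lmm(data, inf.LmmSpec("pse"))
            names = list(fit.result.fe_params.index)
            ix = [i for i, nm in enumerate(names) if ":" in nm][0]
            est = fit.result.fe_params.iloc[ix]
            se = np.sqrt(fit.fixed_cov()[ix, ix])
            hits += abs(est - (-7.4)) <= z * se
        assert hits / runs >= 0.85


class TestWaldType2:
    def test_equivalent_to_classical_anova_on_balanced_data(self):
        # large balanced 2x2, negligible random effects: Wald chi2 ~ df * F
        rng = np.random.default_rng(8)
        n = 200
        rows = []
        for pid in range(n):
            for intervention in ("sham", "RSS"):
                for session in ("pre", "post"):
                    y = (
                        1.0 * (session == "post")
                        + 2.0 * (intervention == "RSS")
                        + 1.5 * (session == "post") * (intervention == "RSS")
                        + rng.normal(0, 1.0)
                    )
                    rows.append(
                        {"participant": f"P{pid}", "session": session,
                         "intervention": intervention, "y": y}
                    )
        data = pd.DataFrame(rows)
        fit = inf.fit_lmm(data, inf.LmmSpec("y", random=("intercept",)))
        wald = inf.wald_type2(fit).set_index("term")

        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        ols = smf.ols("y ~ session * intervention", data).fit()
        classical = anova_lm(ols, typ=2)
        for term, row in classical.iloc[:-1].iterrows():
            got = wald.loc[term.replace(" ", ""), "chi2"]
            assert got == pytest.approx(row["df"] * row["F"], rel=0.05)

    def test_reports_every_fixed_term(self, pse_fit):
        wald = inf.wald_type2(pse_fit)
        assert set(wald["term"]) == {"session", "intervention",
                                     "session:intervention"}
        assert (wald["df"] == 1).all()
        assert wald["p"].between(0, 1).all()

    def test_eta2_definition(self, pse_fit):
        wald = inf.wald_type2(pse_fit)
        expected = wald["chi2"] / (wald["chi2"] + wald["resid_df"])
        assert np.allclose(wald["eta2"], expected)


class TestEmmContrasts:
    def test_bonferroni_families_match_printed_alphas(self, pse_fit):
        emm = inf.emm_contrasts(pse_fit, inf.postpre_family(pse_fit))
        assert np.allclose(emm["alpha_bonf"], 0.025)
        assert round(0.05 / 3, 3) == 0.017
        assert round(0.05 / 9, 3) == 0.006
        assert round(0.05 / 36, 4) == 0.0014

    def test_balanced_contrast_equals_cell_mean_difference(self):
        data = sd.simulate_pse_table(25, -6.0, seed=11, sd_participant=0.0,
                                     sd_slope=0.0)
        fit = inf.fit_lmm(data, inf.LmmSpec("pse", random=("intercept",)))
        emm = inf.emm_contrasts(fit, inf.postpre_family(fit)).set_index("contrast")
        cells = data.groupby(["intervention", "session"])["pse"].mean()
        for intervention in ("RSS", "sham"):
            raw = cells[(intervention, "post")] - cells[(intervention, "pre")]
            assert emm.loc[f"post-pre|{intervention}", "estimate"] == pytest.approx(
                raw, abs=1e-6
            )

    def test_cohens_d_is_estimate_over_residual_sd(self, pse_fit):
        emm = inf.emm_contrasts(pse_fit, inf.postpre_family(pse_fit))
        assert np.allclose(emm["cohens_d"], emm["estimate"] / pse_fit.residual_sd)

    def test_empty_family_rejected(self, pse_fit):
        with pytest.raises(ValueError):
            inf.emm_contrasts(pse_fit, [])


class TestPostpreSlopes:
    def test_point_estimates_equal_emm_contrasts(self, pse_fit):
        slopes = inf.postpre_slopes(pse_fit).set_index("intervention")
        emm = inf.emm_contrasts(pse_fit, inf.postpre_family(pse_fit)).set_index(
            "contrast"
        )
        for intervention in ("RSS", "sham"):
            assert slopes.loc[intervention, "estimate"] == pytest.approx(
                emm.loc[f"post-pre|{intervention}", "estimate"], abs=1e-10
            )

    def test_ci_ordering_and_flag(self, pse_fit):
        slopes = inf.postpre_slopes(pse_fit)
        assert (slopes["ci_low"] <= slopes["ci_high"]).all()
        for _, row in slopes.iterrows():
            assert row["excludes_zero"] == (
                row["ci_low"] > 0 or row["ci_high"] < 0
            )

    def test_zero_effect_coverage(self):
        # with no true effect, ~95% of CIs contain zero
        contains = 0
        runs = 60
        for seed in range(runs):
            data = sd.simulate_pse_table(20, 0.0, seed=7000 + seed)
            fit = inf.fit_lmm(data, inf.LmmSpec("pse"))
            slopes = inf.postpre_slopes(fit).set_index("intervention")
            contains += not slopes.loc["RSS", "excludes_zero"]
        assert contains / runs >= 0.85


class TestJzsBayesFactor:
    def test_null_t_supports_null_at_n30(self):
        assert inf.jzs_bf10(0.0, 30) < 1 / 3

    def test_bf_below_one_at_t0_for_all_n(self):
        for n in (2, 5, 10, 50, 200):
            assert inf.jzs_bf10(0.0, n) < 1.0

    def test_monotone_in_t(self):
        bfs = [inf.jzs_bf10(t, 31) for t in np.linspace(0, 6, 13)]
        assert np.all(np.diff(bfs) > 0)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in [(0.5, 10), (2.0, 20), (2.89, 31), (4.0, 50)]:
            ref = float(pingouin.bayesfactor_ttest(t, n, paired=True, r=0.707))
            assert inf.jzs_bf10(t, n) == pytest.approx(ref, rel=1e-6)

    def test_monte_carlo_prior_sampling_oracle(self):
        # importance-sample delta ~ Cauchy(0, r) and average the noncentral-t
        # density of the observed t; agreement to ~3 significant digits
        rng = np.random.default_rng(321)
        for t, n in [(1.0, 15), (2.5, 31)]:
            delta = 0.707 * rng.standard_cauchy(4_000_000)
            # the prior is symmetric: averaging +/-delta halves the variance
            dens = 0.5 * (
                stats.nct.pdf(t, n - 1, delta * np.sqrt(n))
                + stats.nct.pdf(t, n - 1, -delta * np.sqrt(n))
            )
            mc = dens.mean() / stats.t.pdf(t, n - 1)
            assert inf.jzs_bf10(t, n) == pytest.approx(mc, rel=2e-3)

    def test_strong_paired_effect_gives_evidence(self, rng):
        wins = 0
        for _ in range(40):
            diffs = rng.normal(0.7, 1.0, 31)  # d ~ 0.7 at n=31
            wins += inf.jzs_bf_paired(diffs) > 3
        assert wins / 40 > 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            inf.jzs_bf_paired(np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            inf.jzs_bf10(1.0, 1)


class TestHarrisonKanji:
    @staticmethod
    def design(n_per_cell):
        a = np.repeat(["sham", "RSS"], 2 * n_per_cell)
        b = np.tile(np.repeat(["pre", "post"], n_per_cell), 2)
        return a, b

    def test_identical_angles_degenerate(self):
        a, b = self.design(5)
        table = inf.harrison_kanji(np.full(20, 45.0), a, b)
        assert (table["p"] == 1.0).all()
        assert (table["variant"] == "degenerate").all()

    def test_concentrated_shift_detected(self, rng):
        a, b = self.design(31)
        hits = 0
        for _ in range(100):
            ang = np.degrees(rng.vonmises(0.0, 5.0, 124))
            ang[a == "RSS"] += 90.0
            table = inf.harrison_kanji(ang, a, b).set_index("term")
            hits += table.loc["factor_a", "p"] < 0.05
        assert hits / 100 >= 0.80

    def test_high_concentration_uses_f_variant(self, rng):
        a, b = self.design(20)
        ang = np.degrees(rng.vonmises(0.0, 10.0, 80))
        table = inf.harrison_kanji(ang, a, b)
        assert (table["variant"] == "high_concentration_F").all()

    def test_uniform_sample_uses_chi2_variant(self, rng):
        a, b = self.design(20)
        ang = rng.uniform(-180, 180, 80)
        table = inf.harrison_kanji(ang, a, b)
        assert (table["variant"] == "low_concentration_chi2").all()

    def test_empty_cell_rejected(self):
        a, b = self.design(3)
        a[(a == "RSS") & (b == "pre")] = "sham"
        with pytest.raises(ValueError):
            inf.harrison_kanji(np.zeros(12), a, b)


class TestPlainTests:
    def test_one_sample_matches_closed_form(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rec = inf.one_sample_t(v)
        expected = v.mean() / (v.std(ddof=1) / np.sqrt(5))
        assert abs(rec["t"] - expected) < 1e-12
        assert rec["df"] == 4

    def test_symmetric_values_give_t_zero(self):
        rec = inf.one_sample_t(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert rec["t"] == pytest.approx(0.0, abs=1e-12)
        assert rec["p"] == pytest.approx(1.0)

    def test_paired_identical_vectors_rejected_as_zero_variance(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            inf.paired_t(x, x)

    def test_pearson_r_roundtrip(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        rec = inf.pearson_r(x, y)
        assert 0 < rec["r"] < 1 and rec["n"] == 50
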