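"""Twin variance-component inference: fits, correlations, tests, CIs."""

import numpy as np
import pytest

import vertebrotwin as vt
from vertebrotwin.ace import (
    ACEModel, TwinPairData, CollinearityError, NestingError, profile_ci,
)

from oracles import grid_max_loglike, anova_icc


def simulate(n_mz, n_dz, A, C, E, seed, mean=0.0, betas=None):
    spec = vt.CohortSpec(n_mz_pairs=n_mz, n_dz_pairs=n_dz, seed=seed)
    df = vt.simulate_cohort(spec)
    ph = vt.PhenotypeSpec("y", mean, A, C, E, covariate_betas=betas or {})
    df["y"] = vt.simulate_ace_phenotype(df, ph, seed=seed)
    return df


class TestIntrapairCorrelation:
    def test_identical_twins_give_r_one(self):
        df = simulate(30, 10, 0.0, 1.0, 1e-12, seed=1)
        yy = df["y"].to_numpy().reshape(-1, 2)
        yy[:, 1] = yy[:, 0]
        df["y"] = yy.reshape(-1)
        res = vt.intrapair_correlation(df, "y", "MZ", adjust=())
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_independent_members_near_zero(self):
        df = simulate(5000, 5000, 0.0, 0.0, 1.0, seed=2)
        for z in ("MZ", "DZ"):
            res = vt.intrapair_correlation(df, "y", z, adjust=())
            assert abs(res.r) < 0.04
            assert res.ci_low < res.r < res.ci_high

    def test_matches_textbook_anova_icc_on_hand_fixture(self):
        rng = np.random.default_rng(42)
        pairs = rng.normal(0, 1, (10, 2)) + rng.normal(0, 1, (10, 1))
        rows = []
        for i, (y1, y2) in enumerate(pairs):
            for y in (y1, y2):
                rows.append({"pair_id": f"P{i}", "zygosity": "MZ", "y": y})
        import pandas as pd
        df = pd.DataFrame(rows)
        res = vt.intrapair_correlation(df, "y", "MZ", adjust=())
        assert res.r == pytest.approx(anova_icc(pairs), abs=1e-9)

    def test_degenerate_variance_flagged(self):
        import pandas as pd
        rows = [{"pair_id": f"P{i}", "zygosity": "MZ", "y": 3.14} for i in range(4) for _ in range(2)]
        res = vt.intrapair_correlation(pd.DataFrame(rows), "y", "MZ", adjust=())
        assert not res.defined


class TestFit:
    def test_pure_shared_environment(self):
        """y1 = y2 with varying pair means implies C ~ 1."""
        df = simulate(40, 20, 0.0, 1.0, 1e-6, seed=3)
        yy = df["y"].to_numpy().reshape(-1, 2)
        yy[:, 1] = yy[:, 0]
        df["y"] = yy.reshape(-1)
        fit = vt.fit_variance_components(df, "y", "ACE", covariates=())
        st = fit.standardized
        assert st["C"] > 0.98
        assert st["A"] < 0.02 and st["E"] < 0.02

    def test_optimizer_matches_grid_search_oracle(self):
        """30-pair fixture: quasi-Newton optimum equals an exhaustive search
        over standardized shares at 0.001 resolution (scale and mean
        concentrated in closed form) to within 1e-4 log-likelihood."""
        df = simulate(20, 10, 0.4, 0.3, 0.3, seed=9, mean=1.0)
        model = ACEModel.from_dataframe(df, "y", (), "ACE")
        fit = model.fit()
        ll_grid, *_ = grid_max_loglike(model.data.y, model.data.is_mz, step=0.001)
        assert abs(fit.log_likelihood - ll_grid) < 1e-4
        assert fit.log_likelihood >= ll_grid - 1e-6

    def test_ae_recovery_at_scale(self):
        """Standardized A=0.63 recovered within 0.03 at 5000+2500 pairs;
        the AE model implies rMZ=0.63, rDZ=0.315."""
        df = simulate(5000, 2500, 0.63, 0.0, 0.37, seed=11)
        fit = vt.fit_variance_components(df, "y", "AE", n_starts=2)
        assert fit.standardized["A"] == pytest.approx(0.63, abs=0.03)
        assert fit.implied_r_mz == pytest.approx(fit.standardized["A"], abs=1e-9)
        assert fit.implied_r_dz == pytest.approx(fit.standardized["A"] / 2, abs=1e-9)

    def test_standardized_components_sum_to_one(self):
        df = simulate(60, 30, 0.5, 0.2, 0.3, seed=12)
        for label in ("ACE", "AE", "CE", "E"):
            st = vt.fit_variance_components(df, "y", label).standardized
            assert st["A"] + st["C"] + st["E"] == pytest.approx(1.0, abs=1e-8)

    def test_nesting_monotonicity_of_loglikelihoods(self):
        df = simulate(80, 40, 0.4, 0.2, 0.4, seed=13)
        fits = {m: vt.fit_variance_components(df, "y", m) for m in ("ACE", "AE", "CE", "E")}
        sat = vt.fit_saturated(df, "y")
        assert sat.log_likelihood >= fits["ACE"].log_likelihood - 1e-6
        assert fits["ACE"].log_likelihood >= max(fits["AE"].log_likelihood,
                                                 fits["CE"].log_likelihood) - 1e-6
        assert min(fits["AE"].log_likelihood, fits["CE"].log_likelihood) >= \
               fits["E"].log_likelihood - 1e-6

    def test_affine_equivariance(self):
        """Rescaling the phenotype by s multiplies raw components by s^2 and
        leaves shares and p-values unchanged."""
        df = simulate(80, 40, 0.4, 0.2, 0.4, seed=14)
        f1 = vt.fit_variance_components(df, "y", "ACE")
        sat1 = vt.fit_saturated(df, "y")
        s = 3.7
        df2 = df.copy()
        df2["y"] = df2["y"] * s
        f2 = vt.fit_variance_components(df2, "y", "ACE")
        sat2 = vt.fit_saturated(df2, "y")
        assert f2.var_a == pytest.approx(f1.var_a * s ** 2, rel=1e-4, abs=1e-6)
        assert f2.var_e == pytest.approx(f1.var_e * s ** 2, rel=1e-4)
        for k in ("A", "C", "E"):
            assert f2.standardized[k] == pytest.approx(f1.standardized[k], abs=1e-5)
        p1 = vt.lrt_vs_saturated(f1, sat1).p_value
        p2 = vt.lrt_vs_saturated(f2, sat2).p_value
        assert p2 == pytest.approx(p1, abs=1e-6)

    def test_implied_correlation_ordering(self):
        df = simulate(100, 50, 0.5, 0.2, 0.3, seed=15)
        fit = vt.fit_variance_components(df, "y", "ACE")
        assert fit.implied_r_mz >= fit.implied_r_dz
        fit_ce = vt.fit_variance_components(df, "y", "CE")
        assert fit_ce.implied_r_mz == pytest.approx(fit_ce.implied_r_dz, abs=1e-12)

    def test_collinear_covariates_flagged(self, small_cohort):
        df = small_cohort.copy()
        df["y"] = vt.simulate_ace_phenotype(df, vt.PhenotypeSpec("y", 0, 0.3, 0.3, 0.4), seed=1)
        df["smoking_again"] = df["smoking"]
        with pytest.raises(CollinearityError):
            ACEModel.from_dataframe(df, "y", ("age", "sex", "smoking", "smoking_again"))

    def test_incomplete_pairs_dropped_and_counted(self, small_cohort):
        df = small_cohort.copy()
        df["y"] = vt.simulate_ace_phenotype(df, vt.PhenotypeSpec("y", 0, 0.3, 0.3, 0.4), seed=2)
        df = df.iloc[1:]  # orphan the first pair
        df.loc[df.index[5], "y"] = np.nan  # break another pair
        data = TwinPairData.from_dataframe(df, "y")
        assert data.n_dropped_pairs == 2
        assert data.n_pairs == 58


class TestSaturatedAndLRT:
    def test_saturated_type_one_error_calibrated(self):
        """ACE-generated data: the saturated-vs-ACE LRT rejects at ~5%.
        Run at 334+166 pairs where the chi-square approximation holds."""
        spec = vt.CohortSpec(n_mz_pairs=334, n_dz_pairs=166, seed=30)
        df = vt.simulate_cohort(spec)
        ph = vt.PhenotypeSpec("y", 0.0, 0.4, 0.2, 0.4)
        rej = 0
        n_rep = 300
        for rep in range(n_rep):
            df["y"] = vt.simulate_ace_phenotype(df, ph, seed=30_000 + rep)
            fit = vt.fit_variance_components(df, "y", "ACE", n_starts=2)
            sat = vt.fit_saturated(df, "y")
            rej += vt.lrt_vs_saturated(fit, sat).p_value < 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_heteroskedastic_zygosity_detected(self):
        """MZ variance twice DZ: the saturated model wins often at n=100."""
        spec = vt.CohortSpec(n_mz_pairs=67, n_dz_pairs=33, seed=31)
        df = vt.simulate_cohort(spec)
        ph = vt.PhenotypeSpec("y", 0.0, 0.0, 0.3, 0.7)
        rej = 0
        n_rep = 100
        for rep in range(n_rep):
            df["y"] = vt.simulate_ace_phenotype(df, ph, seed=40_000 + rep)
            scale = np.where(df.zygosity == "MZ", np.sqrt(2.0), 1.0)
            df["y"] = df["y"] * scale
            fit = vt.fit_variance_components(df, "y", "ACE", n_starts=2)
            sat = vt.fit_saturated(df, "y")
            rej += vt.lrt_vs_saturated(fit, sat).p_value < 0.05
        assert rej / n_rep > 0.5

    def test_identical_deviances_give_p_one(self):
        res = vt.lrt_from_deviances(100.0, 100.0, 9)
        assert res.p_value == pytest.approx(1.0)
        assert res.chi_square == 0.0

    def test_nesting_violation_raises(self):
        with pytest.raises(NestingError):
            vt.lrt_from_deviances(100.0, 99.0, 3)


class TestSelection:
    def test_printed_aic_triples_reproduce_study_choices(self):
        """Min-AIC on the published triples: AE for BA length, CE for BA area."""
        from collections import namedtuple
        Score = namedtuple("Score", "model_label aic bic k_params")
        length = [Score("ACE", 1179.85, 1166.67, 7), Score("AE", 1177.11, 1165.19, 6),
                  Score("CE", 1182.74, 1170.82, 6)]
        area = [Score("ACE", 277.860, 264.687, 7), Score("AE", 275.811, 263.888, 6),
                Score("CE", 275.271, 263.347, 6)]
        assert vt.select_model(length).model_label == "AE"
        assert vt.select_model(area).model_label == "CE"

    def test_tie_broken_by_bic_then_parsimony(self):
        from collections import namedtuple
        Score = namedtuple("Score", "model_label aic bic k_params")
        fits = [Score("AE", 100.0, 95.0, 6), Score("CE", 100.0, 94.0, 6),
                Score("E", 100.0, 94.0, 5)]
        assert vt.select_model(fits).model_label == "E"

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            vt.select_model([])


class TestProfileCI:
    def test_boundary_component_lower_bound_zero(self):
        df = simulate(100, 50, 0.0, 0.4, 0.6, seed=16)
        m = ACEModel.from_dataframe(df, "y", ("age", "sex"), "ACE")
        fit = m.fit(n_starts=2)
        if fit.standardized["A"] < 1e-6:
            lo, hi = profile_ci(m, fit, "A")
            assert lo == 0.0
            assert hi > 0.0

    def test_e_model_share_is_degenerate_one(self):
        df = simulate(40, 20, 0.0, 0.0, 1.0, seed=17)
        m = ACEModel.from_dataframe(df, "y", ("age", "sex"), "E")
        fit = m.fit()
        assert profile_ci(m, fit, "E") == (1.0, 1.0)

    def test_interval_brackets_estimate(self):
        df = simulate(200, 100, 0.5, 0.1, 0.4, seed=18)
        m = ACEModel.from_dataframe(df, "y", ("age", "sex"), "AE")
        fit = m.fit(n_starts=2)
        lo, hi = profile_ci(m, fit, "A")
        assert lo <= fit.standardized["A"] <= hi
        assert 0.0 <= lo < hi <= 1.0

    def test_profile_matches_parametric_bootstrap_on_large_fixture(self):
        """Profile interval endpoints agree with a parametric-bootstrap
        percentile interval within 0.05 on a 1500-pair fixture."""
        df = simulate(1000, 500, 0.5, 0.1, 0.4, seed=21)
        m = ACEModel.from_dataframe(df, "y", ("age", "sex"), "ACE")
        fit = m.fit(n_starts=2)
        lo, hi = profile_ci(m, fit, "A")
        rng = np.random.default_rng(99)
        d = m.data
        mean = d.x @ fit.params_beta
        covm = np.where(d.is_mz, fit.var_a + fit.var_c, 0.5 * fit.var_a + fit.var_c)
        v = fit.total_variance
        L11 = np.sqrt(v)
        L21 = covm / L11
        L22 = np.sqrt(np.maximum(v - L21 ** 2, 1e-12))
        boots = []
        for _ in range(250):
            z = rng.normal(size=(d.n_pairs, 2))
            yb = mean + np.column_stack([L11 * z[:, 0], L21 * z[:, 0] + L22 * z[:, 1]])
            fb = ACEModel(TwinPairData(yb, d.x, d.is_mz, d.exog_names), "ACE").fit(n_starts=1)
            boots.append(fb.standardized["A"])
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        assert abs(lo - blo) < 0.05
        assert abs(hi - bhi) < 0.05


class TestCovariateEffects:
    def test_smoking_slope_recovered(self):
        """beta = 0.212 on a diameter-like phenotype, n = 2000 pairs."""
        df = simulate(1340, 660, 0.0, 0.354, 0.646, seed=22, mean=3.42,
                      betas={"smoking": 0.212})
        fit = vt.fit_variance_components(df, "y", "CE",
                                         covariates=("age", "sex", "smoking"), n_starts=2)
        eff = fit.covariate_effects(["smoking"]).iloc[0]
        assert eff.beta == pytest.approx(0.212, abs=0.05)
        assert eff.ci_low < 0.212 < eff.ci_high

    def test_null_covariate_ci_coverage(self):
        """A covariate unrelated to the phenotype: the Wald CI covers 0 at
        ~95% over replicates."""
        spec = vt.CohortSpec(n_mz_pairs=134, n_dz_pairs=66, seed=23)
        df = vt.simulate_cohort(spec)
        ph = vt.PhenotypeSpec("y", 0.0, 0.3, 0.2, 0.5)
        cover = 0
        n_rep = 300
        for rep in range(n_rep):
            df["y"] = vt.simulate_ace_phenotype(df, ph, seed=60_000 + rep)
            fit = vt.fit_variance_components(
                df, "y", "ACE", covariates=("age", "sex", "hypertension"), n_starts=1)
            eff = fit.covariate_effects(["hypertension"]).iloc[0]
            cover += eff.ci_low <= 0.0 <= eff.ci_high
        assert 0.91 <= cover / n_rep <= 0.985

    def test_covariate_lrt_nesting_enforced(self):
        df = simulate(60, 30, 0.3, 0.3, 0.4, seed=24)
        full = vt.fit_variance_components(df, "y", "ACE", ("age", "sex", "smoking"))
        red = vt.fit_variance_components(df, "y", "ACE", ("age", "sex"))
        res = vt.covariate_lrt(full, red)
        assert res.df == 1
        assert 0.0 <= res.p_value <= 1.0
        with pytest.raises(NestingError):
            vt.covariate_lrt(red, full)

    def test_absent_covariate_name_rejected(self):
        df = simulate(30, 15, 0.3, 0.3, 0.4, seed=25)
        fit = vt.fit_variance_components(df, "y", "ACE")
        with pytest.raises(KeyError):
            fit.covariate_effects(["bmi"])
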