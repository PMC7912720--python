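"""Twin-cohort simulator: structure, covariance contracts, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import vertebrotwin as vt
from vertebrotwin.cohort import CohortSpecError, MissingCovariateError


def _double_entry_r(df, col):
    yy = df[col].to_numpy().reshape(-1, 2)
    both = np.concatenate([yy, yy[:, ::-1]])
    return float(np.corrcoef(both[:, 0], both[:, 1])[0, 1])


class TestSimulateCohort:
    def test_study_scale_counts(self):
        df = vt.simulate_cohort(vt.CohortSpec(n_mz_pairs=67, n_dz_pairs=33, seed=0))
        assert len(df) == 200
        assert (df.zygosity == "MZ").sum() == 134
        assert (df.zygosity == "DZ").sum() == 66
        assert df.pair_id.value_counts().eq(2).all()

    def test_all_female_when_prop_female_one(self):
        df = vt.simulate_cohort(vt.CohortSpec(prop_female=1.0, seed=1))
        assert (df.sex == "F").all()

    def test_pair_level_age_and_sex_identical_within_pair(self, small_cohort):
        for col in ("age", "sex", "zygosity"):
            assert small_cohort.groupby("pair_id")[col].nunique().eq(1).all()

    def test_bmi_consistent_with_height_and_weight(self, small_cohort):
        bmi = small_cohort.weight_kg / (small_cohort.height_cm / 100) ** 2
        assert np.max(np.abs(bmi - small_cohort.bmi)) < 0.1

    def test_group_age_means_recover_generating_parameters(self):
        """Monte-Carlo check at 10,000 pairs per group."""
        spec = vt.CohortSpec(
            n_mz_pairs=10_000, n_dz_pairs=10_000,
            age_mean_by_zygosity={"MZ": 49.57, "DZ": 56.0},
            age_sd_by_zygosity={"MZ": 14.42, "DZ": 15.23}, seed=5,
        )
        df = vt.simulate_cohort(spec)
        pair_age = df.groupby("pair_id").first()
        mz = pair_age[pair_age.zygosity == "MZ"].age
        dz = pair_age[pair_age.zygosity == "DZ"].age
        assert mz.mean() == pytest.approx(49.57, abs=0.5)
        assert dz.mean() == pytest.approx(56.0, abs=0.5)

    def test_same_seed_bit_identical(self):
        a = vt.simulate_cohort(vt.CohortSpec(seed=7))
        b = vt.simulate_cohort(vt.CohortSpec(seed=7))
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("kw", [
        {"n_mz_pairs": 0}, {"prop_female": 1.2},
        {"age_sd_by_zygosity": {"MZ": -1.0, "DZ": 15.0}},
        {"risk_factor_prevalences": {"smoking": 1.5}},
        {"risk_factor_prevalences": {"vaping": 0.2}},
        {"age_mean_by_zygosity": {"MZ": np.nan, "DZ": 56.0}},
    ])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(CohortSpecError):
            vt.CohortSpec(**kw)


class TestAcePhenotype:
    def test_independent_when_only_e(self):
        spec = vt.CohortSpec(n_mz_pairs=2000, n_dz_pairs=2000, seed=2)
        df = vt.simulate_cohort(spec)
        df["y"] = vt.simulate_ace_phenotype(df, vt.PhenotypeSpec("y", 0, 0, 0, 1.0), seed=2)
        for z in ("MZ", "DZ"):
            assert abs(_double_entry_r(df[df.zygosity == z], "y")) < 0.05

    def test_implied_twin_correlations(self):
        """a2=0.6, c2=0.2, e2=0.2 implies rMZ=0.8 and rDZ=0.5."""
        spec = vt.CohortSpec(n_mz_pairs=5000, n_dz_pairs=5000, seed=3)
        df = vt.simulate_cohort(spec)
        df["y"] = vt.simulate_ace_phenotype(df, vt.PhenotypeSpec("y", 0, 0.6, 0.2, 0.2), seed=3)
        assert _double_entry_r(df[df.zygosity == "MZ"], "y") == pytest.approx(0.8, abs=0.02)
        assert _double_entry_r(df[df.zygosity == "DZ"], "y") == pytest.approx(0.5, abs=0.02)

    def test_covariance_structure_within_monte_carlo_error(self):
        """Empirical MZ covariance ~ a2+c2 and DZ ~ a2/2+c2 (3 MC SEs)."""
        spec = vt.CohortSpec(n_mz_pairs=6000, n_dz_pairs=6000, seed=4)
        df = vt.simulate_cohort(spec)
        a2, c2, e2 = 1.3, 0.7, 1.1
        df["y"] = vt.simulate_ace_phenotype(df, vt.PhenotypeSpec("y", 5.0, a2, c2, e2), seed=4)
        for z, expect in (("MZ", a2 + c2), ("DZ", 0.5 * a2 + c2)):
            yy = df[df.zygosity == z]["y"].to_numpy().reshape(-1, 2)
            cov = np.cov(yy[:, 0], yy[:, 1])[0, 1]
            n = len(yy)
            total = a2 + c2 + e2
            se = np.sqrt((total ** 2 + expect ** 2) / n)
            assert abs(cov - expect) < 3 * se, z

    def test_replicate_distribution_covers_study_mz_correlation(self):
        """With a2=0.63, e2=0.37 at 67+33 pairs the sampling distribution of
        the MZ intrapair correlation covers the reported 0.616."""
        spec = vt.CohortSpec(n_mz_pairs=67, n_dz_pairs=33, seed=6)
        df = vt.simulate_cohort(spec)
        ph = vt.PhenotypeSpec("y", 0.0, 0.63, 0.0, 0.37)
        rs = []
        for rep in range(1000):
            df["y"] = vt.simulate_ace_phenotype(df, ph, seed=50_000 + rep)
            rs.append(_double_entry_r(df[df.zygosity == "MZ"], "y"))
        rs = np.asarray(rs)
        assert rs.min() < 0.616 < rs.max()
        assert np.quantile(rs, 0.025) < 0.616 < np.quantile(rs, 0.975)

    def test_covariate_effects_enter_mean(self):
        spec = vt.CohortSpec(n_mz_pairs=3000, n_dz_pairs=1000, seed=8)
        df = vt.simulate_cohort(spec)
        ph = vt.PhenotypeSpec("y", 10.0, 0.0, 0.0, 0.25,
                              covariate_betas={"smoking": 2.0})
        df["y"] = vt.simulate_ace_phenotype(df, ph, seed=8)
        gap = df[df.smoking == 1]["y"].mean() - df[df.smoking == 0]["y"].mean()
        assert gap == pytest.approx(2.0, abs=0.1)

    def test_missing_covariate_is_named_error(self, small_cohort):
        ph = vt.PhenotypeSpec("y", 0, 0, 0, 1.0, covariate_betas={"shoe_size": 1.0})
        with pytest.raises(MissingCovariateError):
            vt.simulate_ace_phenotype(small_cohort, ph, seed=0)

    @pytest.mark.parametrize("kw", [
        {"var_a": -0.1, "var_c": 0, "var_e": 1},
        {"var_a": 0, "var_c": 0, "var_e": 0},
        {"var_a": np.inf, "var_c": 0, "var_e": 1},
    ])
    def test_invalid_phenotype_spec_rejected(self, kw):
        with pytest.raises(CohortSpecError):
            vt.PhenotypeSpec("y", 0.0, **kw)

    def test_default_phenotype_set_has_16_indices(self):
        specs = vt.default_phenotype_specs()
        assert len(specs) == 16
        assert len({s.name for s in specs}) == 16
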