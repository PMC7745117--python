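import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import uavpheno as u
from uavpheno.synthetic_field import GeneticParams, TraitSpec


def balanced_data(seed, n_geno=20, n_reps=3, sigma_g=1.2, sigma_e=1.0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, sigma_g, n_geno)
    r = rng.normal(0, 0.5, n_reps)
    rows = []
    for i in range(n_geno):
        for j in range(n_reps):
            rows.append({
                "variety": f"g{i:03d}", "rep": j + 1,
                "y": 10 + g[i] + r[j] + rng.normal(0, sigma_e),
            })
    return pd.DataFrame(rows)


def anova_components(df):
    """Expected-mean-squares oracle for balanced complete-block data."""
    G = df["variety"].nunique()
    R = df["rep"].nunique()
    ybar = df["y"].mean()
    gm = df.groupby("variety")["y"].mean()
    rm = df.groupby("rep")["y"].mean()
    ms_g = R * ((gm - ybar) ** 2).sum() / (G - 1)
    resid = (df["y"].to_numpy() - gm[df["variety"]].to_numpy()
             - rm[df["rep"]].to_numpy() + ybar)
    ms_e = (resid ** 2).sum() / ((G - 1) * (R - 1))
    return (ms_g - ms_e) / R, ms_e


class TestCanopyTraits:
    def _table(self, green, yellow, dry, area=6.0):
        return pd.DataFrame({
            "plot_id": [1], "trial": "T1", "variety": "V1", "rep": 1,
            "block": 1, "plot_area_m2": [area], "area_soil_m2": [0.0],
            "area_green_m2": [green], "area_yellow_m2": [yellow],
            "area_dry_m2": [dry]})

    def test_all_green_canopy(self):
        out = u.compute_canopy_traits(self._table(3.0, 0.0, 0.0))
        assert out["total_cover"].iloc[0] == pytest.approx(0.5)
        assert out["RGC"].iloc[0] == pytest.approx(0.5)
        assert out["SI"].iloc[0] == 0.0

    def test_bare_plot_has_undefined_si(self):
        out = u.compute_canopy_traits(self._table(0.0, 0.0, 0.0))
        assert out["total_cover"].iloc[0] == 0.0
        assert np.isnan(out["SI"].iloc[0])

    def test_arithmetic_oracle(self, rng):
        for _ in range(10):
            g, y, d = rng.uniform(0, 2, 3)
            out = u.compute_canopy_traits(self._table(g, y, d))
            assert out["total_cover"].iloc[0] == pytest.approx((g + y + d) / 6.0)
            assert out["RGC"].iloc[0] == pytest.approx(g / 6.0)

    def test_invalid_plot_area(self):
        with pytest.raises(ValueError, match="plot area"):
            u.compute_canopy_traits(self._table(1.0, 0.0, 0.0, area=0.0))


class TestSenescenceIndex:
    def test_trial_mean_canopy_areas(self):
        """SI over mean class areas G=2.379, Y=1.625, D=0.376 m^2."""
        assert u.senescence_index(2.379, 1.625, 0.376) == pytest.approx(
            0.457, abs=5e-4)

    def test_boundaries(self):
        assert u.senescence_index(2.0, 0.0, 0.0) == 0.0
        assert u.senescence_index(0.0, 1.0, 0.5) == 1.0

    def test_undefined_without_canopy(self):
        assert np.isnan(u.senescence_index(0.0, 0.0, 0.0))

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            u.senescence_index(-1.0, 1.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(g=st.floats(0, 10), y=st.floats(0, 10), d=st.floats(0, 10),
           c=st.floats(0.01, 100))
    def test_scale_invariance_and_range(self, g, y, d, c):
        si = u.senescence_index(g, y, d)
        if np.isnan(si):
            return
        assert 0.0 <= si <= 1.0
        assert u.senescence_index(c * g, c * y, c * d) == pytest.approx(
            si, abs=1e-9)


class TestFitReml:
    def test_matches_anova_on_balanced_data(self):
        for seed in (1, 2, 3):
            df = balanced_data(seed)
            vc = u.fit_reml(df, "y", include_blocks=False)
            sg, se = anova_components(df)
            assert vc.sigma2_g == pytest.approx(sg, rel=1e-6)
            assert vc.sigma2_e == pytest.approx(se, rel=1e-6)
            assert vc.converged

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = balanced_data(4)
        vc = u.fit_reml(df, "y", include_blocks=False)
        md = smf.mixedlm("y ~ C(rep)", df, groups=np.ones(len(df)),
                         vc_formula={"geno": "0 + C(variety)"})
        fit = md.fit(reml=True)
        assert vc.sigma2_g == pytest.approx(float(fit.vcomp[0]), rel=1e-3)
        assert vc.sigma2_e == pytest.approx(float(fit.scale), rel=1e-3)

    def test_null_genetic_variance(self):
        """With sigma2_g = 0 the estimate collapses to near zero in >= 90%
        of seeds on a well-replicated design (the chance of a spurious
        estimate above 0.05*sigma2_e is the F(G-1, df_e) tail above
        1 + 0.05*n_reps, so it needs enough replication to be small)."""
        hits = 0
        for seed in range(50):
            df = balanced_data(100 + seed, n_geno=50, n_reps=6,
                               sigma_g=0.0, sigma_e=1.0)
            vc = u.fit_reml(df, "y", include_blocks=False)
            if vc.sigma2_g < 0.05 * vc.sigma2_e:
                hits += 1
        assert hits >= 45

    def test_constant_trait_degenerates(self):
        df = balanced_data(5)
        df["y"] = 7.0
        vc = u.fit_reml(df, "y", include_blocks=False)
        assert vc.sigma2_g == 0.0 and vc.sigma2_e == 0.0
        assert vc.degenerate

    def test_blues_recover_genotype_means_ols_case(self):
        # no blocks, balanced: BLUE = genotype mean adjusted for rep,
        # which for balanced data is just the genotype mean
        df = balanced_data(6)
        vc = u.fit_reml(df, "y", include_blocks=False)
        means = df.groupby("variety")["y"].mean()
        blues = vc.blues.set_index("variety")["blue"]
        np.testing.assert_allclose(blues[means.index], means, rtol=1e-8)

    def test_blups_shrink_toward_zero(self):
        df = balanced_data(7)
        vc = u.fit_reml(df, "y", include_blocks=False)
        blues_c = (vc.blues["blue"] - vc.blues["blue"].mean()).abs().mean()
        blups = vc.blups["blup"].abs().mean()
        assert blups < blues_c

    def test_requires_replication(self):
        df = balanced_data(8).query("rep == 1")
        with pytest.raises(ValueError, match="replicates"):
            u.fit_reml(df, "y")

    def test_block_variance_estimated(self):
        rng = np.random.default_rng(11)
        rows = []
        for rep in (1, 2, 3):
            for blk in (1, 2, 3, 4):
                b = rng.normal(0, 1.5)
                for g in range(5):
                    rows.append({
                        "variety": f"g{blk}{g}", "rep": rep, "block": blk,
                        "y": 5 + b + rng.normal(0, 0.5)})
        df = pd.DataFrame(rows)
        vc = u.fit_reml(df, "y", include_blocks=True)
        assert vc.sigma2_block > 0.5


class TestHeritability:
    def test_direct_substitution(self):
        assert u.heritability(1.0, 1.0, 3) == pytest.approx(0.75)

    def test_boundaries(self):
        assert u.heritability(0.0, 2.0, 3) == 0.0
        assert u.heritability(1.5, 0.0, 3) == 1.0
        with pytest.warns(UserWarning):
            assert np.isnan(u.heritability(0.0, 0.0, 3))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(sg=st.floats(0.01, 10), se=st.floats(0.01, 10),
           n=st.integers(1, 10))
    def test_monotonicity(self, sg, se, n):
        h = u.heritability(sg, se, n)
        assert 0 <= h <= 1
        assert u.heritability(sg * 1.5, se, n) >= h
        assert u.heritability(sg, se * 1.5, n) <= h
        assert u.heritability(sg, se, n + 1) >= h


def simulated_pair(seed, rho, n_geno=50, n_reps=3):
    layout = u.generate_trial_layout(n_geno, n_reps, seed=seed)
    traits = [TraitSpec("a", 0.0, 1.0, 0.1, 2.0),
              TraitSpec("b", 0.0, 1.0, 0.1, 2.0)]
    params = GeneticParams(n_geno, n_reps, traits,
                           np.array([[1.0, rho], [rho, 1.0]]), seed=seed + 1)
    return u.simulate_ground_truth(layout, params)


class TestGeneticCorrelation:
    def test_self_covariance_is_genetic_variance(self):
        truth = simulated_pair(21, 0.5)
        v = u.fit_reml(truth.plots, "a").sigma2_g
        assert u.genotypic_covariance(truth.plots, "a", "a") == pytest.approx(v)

    def test_self_correlation_is_one(self):
        truth = simulated_pair(22, 0.5)
        assert u.genetic_correlation(truth.plots, "a", "a").rho_g == 1.0

    def test_symmetry(self):
        truth = simulated_pair(23, 0.4)
        ab = u.genetic_correlation(truth.plots, "a", "b").rho_g
        ba = u.genetic_correlation(truth.plots, "b", "a").rho_g
        assert ab == ba

    def test_null_correlation_recovery(self):
        """With no genetic correlation, |rho_g| stays below 0.2 in >= 80%
        of seeds on an adequately powered design (the estimator's standard
        error scales roughly as 1/(h^2 sqrt(n_genotypes)))."""
        hits = 0
        for seed in range(50):
            layout = u.generate_trial_layout(150, 2, seed=700 + seed)
            traits = [TraitSpec("a", 0.0, 1.0, 0.1, 0.2),
                      TraitSpec("b", 0.0, 1.0, 0.1, 0.2)]
            params = GeneticParams(150, 2, traits, np.eye(2), seed=800 + seed)
            truth = u.simulate_ground_truth(layout, params)
            rho = u.genetic_correlation(truth.plots, "a", "b",
                                        include_blocks=False).rho_g
            if abs(rho) < 0.2:
                hits += 1
        assert hits >= 40

    def test_large_trial_consistency(self):
        """On a large trial the estimate tracks the realized correlation of
        the true genotype effects."""
        truth = simulated_pair(31, 0.6, n_geno=200)
        est = u.genetic_correlation(truth.plots, "a", "b").rho_g
        eff = truth.genotype_effects
        realized = np.corrcoef(eff["a"], eff["b"])[0, 1]
        assert est == pytest.approx(realized, abs=0.12)

    def test_rho_clamped_to_unit_interval(self):
        """Near-unit genetic correlation on small trials can overshoot the
        identity estimator; reported rho_g is always within [-1, 1] (or
        NaN-flagged when a genotypic variance collapses to zero)."""
        import warnings as _warnings

        truth = simulated_pair(33, 0.97, n_geno=30)
        gc = u.genetic_correlation(truth.plots, "a", "b")
        assert -1.0 <= gc.rho_g <= 1.0
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            for seed in range(50, 58):
                truth = simulated_pair(seed, 0.97, n_geno=12)
                rho = u.genetic_correlation(truth.plots, "a", "b",
                                            include_blocks=False).rho_g
                assert np.isnan(rho) or -1.0 <= rho <= 1.0


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert u.pearson(x, x).r == pytest.approx(1.0)
        assert u.pearson(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # r = (n*Sxy - Sx*Sy)/sqrt((n*Sxx-Sx^2)(n*Syy-Sy^2)) = 15/sqrt(228)
        res = u.pearson([1, 2, 3], [2, 4, 7])
        assert res.r == pytest.approx(15 / np.sqrt(228), abs=1e-12)
        assert round(res.r, 4) == 0.9934

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        res = u.pearson(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            u.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
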