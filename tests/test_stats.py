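"""Mixed-model fitting, marginal-mean contrasts, and two-way ANOVA."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from abrkit import simulate as sim
from abrkit.stats import (
    anova_two_way,
    contrasts_frame,
    emmeans,
    fit_mixed_model,
    pairwise_emmeans,
    significance_stars,
)
from conftest import truth_measurement_table


def _cohort(effects=None, seed=0, n=8):
    return sim.synth_cohort(n_per_group=n, effects=effects, seed=seed, n_epochs=2)


@pytest.fixture(scope="module")
def null_table():
    cohort = _cohort(effects=sim.GroupEffects(), seed=10)
    return truth_measurement_table(cohort, np.random.default_rng(0))


@pytest.fixture(scope="module")
def deficit_cohort():
    effects = sim.GroupEffects(wave4_amp_multiplier={("female", "Fmr1"): 0.7})
    return _cohort(effects=effects, seed=11)


class TestFitMixedModel:
    def test_recovers_wave4_deficit_within_2_se(self, deficit_cohort):
        rng = np.random.default_rng(1)
        table = truth_measurement_table(deficit_cohort, rng)
        fit = fit_mixed_model(table, "amplitude_av")
        res = pairwise_emmeans(fit, "genotype", by=("sex",),
                               at={"condition": "IV"})
        frame = contrasts_frame(res)
        row = frame[(frame["contrast"] == "Fmr1 - B6 [genotype]") &
                    (frame["by_sex"] == "female")].iloc[0]
        truth = deficit_cohort.truth.animals
        t_b6 = np.mean([
            np.mean([truth[a.animal].wave_amplitude_av[e][3] for e in ("left", "right")])
            for a in deficit_cohort.animals
            if a.sex == "female" and a.genotype == "B6"])
        t_fm = np.mean([
            np.mean([truth[a.animal].wave_amplitude_av[e][3] for e in ("left", "right")])
            for a in deficit_cohort.animals
            if a.sex == "female" and a.genotype == "Fmr1"])
        assert abs(row["estimate"] - (t_fm - t_b6)) < 2 * row["se"]
        assert row["p_adjusted"] < 0.05

    def test_zero_intercept_generator_flags_singular(self):
        """With no animal-level variation, the REML variance component sits at
        the boundary and is flagged singular."""
        effects = sim.GroupEffects(animal_intercept_sd_av=0.0)
        kernels = sim.WaveKernelParams(latency_jitter_sd_ms=0.0)
        cohort = sim.synth_cohort(n_per_group=4, effects=effects,
                                  kernels=kernels, seed=12, n_epochs=2)
        table = truth_measurement_table(cohort, np.random.default_rng(2),
                                        meas_sd=0.05)
        # align every animal's mean with its group mean so the sample's
        # between-animal variance is exactly zero, not just in expectation
        animal_mean = table.groupby("animal")["amplitude_av"].transform("mean")
        group_mean = table.groupby(["sex", "genotype"])[
            "amplitude_av"].transform("mean")
        table["amplitude_av"] += group_mean - animal_mean
        fit = fit_mixed_model(table, "amplitude_av")
        assert fit.singular
        assert fit.random_intercept_var == pytest.approx(0.0, abs=1e-6)

    def test_real_intercepts_not_flagged_singular(self, null_table):
        fit = fit_mixed_model(null_table, "amplitude_av")
        assert not fit.singular
        assert fit.random_intercept_var > 1e-3

    def test_rank_deficient_design_names_aliased_terms(self, null_table):
        table = null_table.copy()
        table["dup"] = table["genotype"]
        with pytest.raises(ValueError, match="aliased.*dup"):
            fit_mixed_model(table, "amplitude_av",
                            fixed="sex + genotype + dup + condition")

    def test_missing_response_column(self, null_table):
        with pytest.raises(ValueError, match="response column"):
            fit_mixed_model(null_table, "nope")


class TestPairwiseEmmeans:
    def test_three_genotypes_give_three_contrasts_per_sex(self, null_table):
        fit = fit_mixed_model(null_table, "amplitude_av")
        res = pairwise_emmeans(fit, "genotype", by=("sex",),
                               at={"condition": "IV"})
        assert len(res) == 6  # C(3,2) per sex
        for r in res:
            assert 0.0 <= r.p_raw <= 1.0
            assert 0.0 <= r.p_adjusted <= 1.0
            assert r.p_adjusted >= r.p_raw - 1e-12  # Tukey never anti-conservative

    def test_identical_groups_contrast_near_zero(self):
        """Null generator: genotype contrasts sit within 2 SE of zero."""
        cohort = _cohort(effects=sim.GroupEffects(), seed=13)
        table = truth_measurement_table(cohort, np.random.default_rng(3))
        fit = fit_mixed_model(table, "amplitude_av")
        res = pairwise_emmeans(fit, "genotype", by=("sex",),
                               at={"condition": "II"})
        # 6 contrasts at ~2 SE each: allow one marginal excursion
        n_large = sum(abs(r.estimate) > 2 * r.se for r in res)
        assert n_large <= 1

    def test_invariant_to_reference_level_recoding(self, null_table):
        fit1 = fit_mixed_model(null_table, "amplitude_av")
        recoded = null_table.copy()
        # relevel genotype so another level is the patsy reference
        recoded["genotype"] = pd.Categorical(
            recoded["genotype"], categories=["Fmr1 het", "B6", "Fmr1"])
        fit2 = fit_mixed_model(recoded, "amplitude_av")
        r1 = contrasts_frame(pairwise_emmeans(fit1, "genotype", by=("sex",),
                                              at={"condition": "IV"}))
        r2 = contrasts_frame(pairwise_emmeans(fit2, "genotype", by=("sex",),
                                              at={"condition": "IV"}))
        m1 = r1.set_index(["contrast", "by_sex"])["estimate"].sort_index()
        m2 = r2.set_index(["contrast", "by_sex"])["estimate"].sort_index()
        pd.testing.assert_series_equal(m1, m2, atol=1e-6, rtol=0)

    def test_litter_term_barely_moves_genotype_contrasts(self):
        """Litter has no generative effect: with/without the litter term the
        genotype contrast moves by well under half its SE on average."""
        diffs = []
        for seed in range(8):
            cohort = _cohort(effects=sim.GroupEffects(), seed=40 + seed, n=4)
            table = truth_measurement_table(cohort,
                                            np.random.default_rng(seed))
            f_with = fit_mixed_model(table, "amplitude_av")
            f_without = fit_mixed_model(table, "amplitude_av",
                                        fixed="sex * genotype * condition")
            c_with = contrasts_frame(pairwise_emmeans(
                f_with, "genotype", by=("sex",), at={"condition": "IV"}))
            c_without = contrasts_frame(pairwise_emmeans(
                f_without, "genotype", by=("sex",), at={"condition": "IV"}))
            d = (c_with["estimate"] - c_without["estimate"]).abs() / c_with["se"]
            diffs.append(d.mean())
        assert float(np.mean(diffs)) < 0.5

    def test_emmeans_table_shape(self, null_table):
        fit = fit_mixed_model(null_table, "amplitude_av")
        em = emmeans(fit, ["genotype"], at={"condition": "I"})
        assert set(em["genotype"]) == {"B6", "Fmr1", "Fmr1 het"}
        assert (em["se"] > 0).all()


class TestAnovaTwoWay:
    def test_sex_weight_effect_detected_genotype_null(self):
        """Generator gives females lower weight and no genotype effect."""
        cohort = _cohort(seed=14)
        res = anova_two_way(cohort.metadata, "weight_g")
        p_sex = res.table.loc["C(sex)", "PR(>F)"]
        p_gen = res.table.loc["C(genotype)", "PR(>F)"]
        assert p_sex < 0.001
        assert p_gen > 0.05
        assert "sexxgenotype" in res.tukey

    def test_constant_response_zero_between_ss(self):
        df = pd.DataFrame({
            "sex": ["female"] * 4 + ["male"] * 4,
            "genotype": ["B6", "B6", "Fmr1", "Fmr1"] * 2,
            "y": [5.0] * 8,
        })
        res = anova_two_way(df, "y")
        assert res.table.loc["C(sex)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.loc["C(genotype)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_cell_rejected(self):
        df = pd.DataFrame({
            "sex": ["female"] * 4 + ["male"] * 2,
            "genotype": ["B6", "B6", "Fmr1", "Fmr1", "B6", "B6"],
            "y": np.arange(6.0),
        })
        with pytest.raises(ValueError, match="empty design cells"):
            anova_two_way(df, "y")

    def test_null_permutation_pvalues_roughly_uniform(self):
        """Permuting genotype labels yields a near-uniform p distribution
        (KS distance < 0.15 over 200 permutations)."""
        cohort = _cohort(seed=15)
        base = cohort.metadata.copy()
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(200):
            perm = base.copy()
            perm["genotype"] = rng.permutation(perm["genotype"].to_numpy())
            res = anova_two_way(perm, "weight_g", posthoc=False)
            pvals.append(res.table.loc["C(genotype)", "PR(>F)"])
        ks = spstats.kstest(pvals, "uniform").statistic
        assert ks < 0.15


def test_contrasts_match_r_lmer_emmeans(tmp_path):
    """Cross-check the hand-built marginal-mean contrasts against the
    reference implementation (lme4/lmerTest + emmeans via Rscript) on a
    small cohort: estimates and SEs agree to 1e-4, t to 1e-3, Tukey p within
    the df-method difference (between-within here vs Kenward-Roger in R)."""
    import shutil
    import subprocess

    rscript = shutil.which("Rscript")
    if rscript is None:
        pytest.skip("Rscript not on PATH")
    effects = sim.GroupEffects(wave4_amp_multiplier={("female", "Fmr1"): 0.7})
    cohort = sim.synth_cohort(n_per_group=4, effects=effects, seed=21,
                              n_epochs=2)
    table = truth_measurement_table(cohort, np.random.default_rng(5))
    csv = tmp_path / "fixture.csv"
    table.to_csv(csv, index=False)

    fit = fit_mixed_model(table, "amplitude_av")
    ours = contrasts_frame(pairwise_emmeans(fit, "genotype", by=("sex",),
                                            at={"condition": "IV"}))

    r_code = f"""
    suppressMessages({{library(lme4); library(lmerTest); library(emmeans)}})
    d <- read.csv("{csv}")
    m <- lmer(amplitude_av ~ sex * genotype * condition + litter + (1|animal),
              data=d, REML=TRUE)
    em <- emmeans(m, ~ genotype | sex, at=list(condition="IV"))
    s <- summary(pairs(em))
    write.csv(s, "{tmp_path / 'r_out.csv'}", row.names=FALSE)
    """
    subprocess.run([rscript, "-e", r_code], check=True, capture_output=True)
    r_out = pd.read_csv(tmp_path / "r_out.csv")

    for _, rrow in r_out.iterrows():
        a, b = [s.strip() for s in rrow["contrast"].split(" - ")]
        # R reports "B6 - Fmr1"; ours is "Fmr1 - B6" (later minus earlier)
        match = ours[(ours["contrast"] == f"{b} - {a} [genotype]") &
                     (ours["by_sex"] == rrow["sex"])]
        sign = -1.0
        if match.empty:
            match = ours[(ours["contrast"] == f"{a} - {b} [genotype]") &
                         (ours["by_sex"] == rrow["sex"])]
            sign = 1.0
        row = match.iloc[0]
        assert row["estimate"] == pytest.approx(sign * rrow["estimate"], abs=1e-4)
        assert row["se"] == pytest.approx(rrow["SE"], abs=1e-4)
        assert row["t"] == pytest.approx(sign * rrow["t.ratio"], abs=1e-3)
        assert row["p_adjusted"] == pytest.approx(rrow["p.value"], abs=5e-3)


def test_significance_tiers():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.005) == "**"
    assert significance_stars(5e-5) == "***"
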