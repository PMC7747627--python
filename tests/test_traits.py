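from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heattent.traits import (
    DEFAULT_TRAIT_EFFECTS,
    GENOTYPES,
    EmergenceRecord,
    SeedSample,
    TraitEffect,
    checkline_uniformity,
    emergence_metrics,
    extrapolate_noninfected,
    generate_trait_data,
    grain_filling_duration,
    harvest_index,
    pct_difference,
    per_degC,
    protein_from_nitrogen,
    recover_treatment_effect,
    round_half_up,
    splitplot_anova,
    summarize_treatments,
)


class TestPctDifference:
    def test_everest_starch(self):
        assert pct_difference(59.80, 46.87) == -21.62

    def test_tascosa_starch(self):
        assert pct_difference(67.77, 51.15) == -24.52

    def test_identity_zero(self):
        assert pct_difference(42.0, 42.0) == 0.00

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            pct_difference(0.0, 10.0)

    @settings(max_examples=50, deadline=None)
    @given(
        c=st.floats(min_value=1.0, max_value=1e4),
        h=st.floats(min_value=0.0, max_value=1e4),
    )
    def test_closed_form(self, c, h):
        assert pct_difference(c, h) == round_half_up(100.0 * (h - c) / c)


class TestPerDegC:
    def test_yield_reduction(self):
        assert per_degC(13.6, 3.8) == 3.58

    def test_zero(self):
        assert per_degC(0.0, 3.8) == 0.0

    def test_kernel_weight(self):
        assert per_degC(4.8, 3.8) == 1.26

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            per_degC(10.0, 0.0)


class TestProteinFromNitrogen:
    def test_factor(self):
        assert protein_from_nitrogen(2.0) == pytest.approx(11.4)

    def test_zero(self):
        assert protein_from_nitrogen(0.0) == 0.0

    def test_everest_control(self):
        assert protein_from_nitrogen(2.617) == pytest.approx(14.92, abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            protein_from_nitrogen(-1.0)


class TestExtrapolation:
    def test_identity_when_infection_free(self):
        s = SeedSample(0, 100, 0.0, 3.0)
        assert extrapolate_noninfected(s) == pytest.approx(3.0)

    def test_arithmetic(self):
        s = SeedSample(20, 100, 0.4, 3.0)
        assert extrapolate_noninfected(s) == pytest.approx(3.6)

    def test_no_noninfected_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_noninfected(SeedSample(10, 0, 0.5, 0.0))

    def test_extrapolated_tracks_whole_sample(self):
        # Monte-Carlo cohort: 10% infected seeds, infected 40% lighter; the
        # HNT-as-%-of-control differential of extrapolated weights must track
        # the infection-free ground truth with R^2 > 0.9.
        rng = np.random.default_rng(8)
        truth_ratio, extrap_ratio = [], []
        for _ in range(60):
            base = rng.uniform(0.028, 0.038)  # per-seed weight, g
            effect = rng.uniform(0.75, 1.0)  # HNT as fraction of control
            ratios = {}
            for treat, mult in (("control", 1.0), ("hnt", effect)):
                n = 400
                n_inf = rng.binomial(n, 0.1)
                w_ok = base * mult * (n - n_inf) * rng.normal(1, 0.02)
                w_inf = base * mult * 0.6 * n_inf * rng.normal(1, 0.02)
                s = SeedSample(n_inf, n - n_inf, w_inf, w_ok)
                ratios[treat] = extrapolate_noninfected(s)
            truth_ratio.append(effect)
            extrap_ratio.append(ratios["hnt"] / ratios["control"])
        r = np.corrcoef(truth_ratio, extrap_ratio)[0, 1]
        assert r**2 > 0.9


class TestDerivedTraits:
    def test_harvest_index(self):
        assert harvest_index(400.0, 1053.0) == pytest.approx(0.38, abs=0.005)

    def test_zero_yield(self):
        assert harvest_index(0.0, 500.0) == 0.0

    def test_zero_biomass_rejected(self):
        with pytest.raises(ValueError):
            harvest_index(100.0, 0.0)

    def test_grain_filling_duration(self):
        assert grain_filling_duration(date(2019, 5, 24), date(2019, 7, 5)) == 42


class TestEmergence:
    def test_all_day_one(self):
        rec = EmergenceRecord("g", "control", (24,), 24)
        assert emergence_metrics(rec) == (100.0, 24.0)

    def test_none_emerge(self):
        rec = EmergenceRecord("g", "control", (0, 0, 0), 24)
        assert emergence_metrics(rec) == (0.0, 0.0)

    def test_split_days(self):
        rec = EmergenceRecord("g", "control", (0, 12, 0, 12), 24)
        pct, idx = emergence_metrics(rec)
        assert pct == 100.0
        assert idx == pytest.approx(9.0)  # 12/2 + 12/4

    def test_overflow_rejected(self):
        with pytest.raises(ValueError):
            EmergenceRecord("g", "control", (30,), 24)


def zero_noise_effects(effect_pct=0.0, trait="grain_yield_g_m2", control_mean=500.0):
    return {trait: TraitEffect(trait, control_mean, effect_pct, 0.0, 0.0, 0.0)}


class TestGenerator:
    def test_zero_sds_hit_cell_means(self):
        obs = generate_trait_data(zero_noise_effects(effect_pct=-10.0), seed=1)
        cells = obs.groupby("treatment")["value"].unique()
        assert np.allclose(cells["control"], 500.0)
        assert np.allclose(cells["HNT"], 450.0)

    def test_deterministic_under_seed(self):
        a = generate_trait_data(seed=11)
        b = generate_trait_data(seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_layout(self):
        obs = generate_trait_data(seed=0)
        one = obs[obs["trait"] == "grain_yield_g_m2"]
        assert set(one["genotype"]) == set(GENOTYPES)
        everest = one[(one["genotype"] == "Everest") & (one["treatment"] == "control")]
        assert len(everest) == 3 * 8  # check line in all 8 blocks of each tent
        assert not one.duplicated(["genotype", "treatment", "tent", "block"]).any()

    def test_injected_yield_effect_means(self):
        cfg = {"grain_yield_g_m2": TraitEffect("grain_yield_g_m2", 512.8, -17.0, 0.0, 0.0, 5.0)}
        obs = generate_trait_data(cfg, seed=3)
        hnt = obs[obs["treatment"] == "HNT"]["value"].mean()
        se = 5.0 / np.sqrt((obs["treatment"] == "HNT").sum())
        assert abs(hnt - 512.8 * 0.83) < 4 * se

    def test_effect_recovery_within_2se(self):
        obs = generate_trait_data(seed=21)
        est, se = recover_treatment_effect(obs, "grain_yield_g_m2")
        injected = DEFAULT_TRAIT_EFFECTS["grain_yield_g_m2"].effect_pct
        assert abs(est - injected) < 2 * se


class TestSummaries:
    def test_overall_is_mean_of_means(self):
        obs = generate_trait_data(seed=5)
        summ = summarize_treatments(obs, traits=["starch_pct"])
        overall = summ[summ["genotype"] == "Overall average"].iloc[0]
        per_geno = summ[summ["genotype"] != "Overall average"]
        assert overall["mean_control"] == pytest.approx(per_geno["mean_control"].mean())
        assert overall["pct_diff"] == pct_difference(
            per_geno["mean_control"].mean(), per_geno["mean_hnt"].mean()
        )
        assert overall["pct_diff_mean_of_rows"] == round_half_up(per_geno["pct_diff"].mean())

    def test_per_degc_requires_explicit_delta(self):
        obs = generate_trait_data(seed=5)
        summ = summarize_treatments(obs, traits=["starch_pct"])
        assert "per_degC" not in summ.columns
        summ2 = summarize_treatments(obs, traits=["starch_pct"], delta_T_C=3.8)
        assert "per_degC" in summ2.columns


class TestSplitPlotAnova:
    def test_no_effect_limit_same_letters(self):
        # identical treatment groups (jitter sd -> 0 limit): one shared letter
        obs = generate_trait_data(zero_noise_effects(), seed=2)
        res = splitplot_anova(obs, "grain_yield_g_m2")
        assert set(res.treatment_means["letter"]) == {"a"}
        assert res.p_T == pytest.approx(1.0)

    def test_strong_effect_detected_and_separated(self):
        cfg = {"t": TraitEffect("t", 500.0, -30.0, 5.0, 1.0, 5.0)}
        obs = generate_trait_data(cfg, seed=3)
        res = splitplot_anova(obs, "t")
        assert res.p_T < 0.01
        tm = res.treatment_means.set_index("treatment")
        assert tm.loc["control", "letter"] != tm.loc["HNT", "letter"]

    def test_single_tent_rejected(self):
        obs = generate_trait_data(seed=1, n_tents=1)
        with pytest.raises(ValueError, match="single tent"):
            splitplot_anova(obs, "grain_yield_g_m2")

    def test_df_decomposition(self):
        obs = generate_trait_data(seed=4)
        res = splitplot_anova(obs, "grain_yield_g_m2")
        # 2x3x12 balanced layout: 1 + 4 + 11 + 11 + 44 = 71 = N - 1
        assert res.anova_table["df"].tolist() == [1, 4, 11, 11, 44]
        total_ss = res.anova_table["ss"].sum()
        cells = obs[obs["trait"] == "grain_yield_g_m2"].groupby(
            ["treatment", "tent", "genotype"]
        )["value"].mean()
        assert total_ss == pytest.approx(((cells - cells.mean()) ** 2).sum())

    def test_oracle_f_statistics(self):
        # independent oracle: same sums of squares out of naive nested loops
        obs = generate_trait_data(seed=13)
        trait = "grain_yield_g_m2"
        cells = (
            obs[obs["trait"] == trait]
            .groupby(["treatment", "tent", "genotype"], as_index=False)["value"]
            .mean()
        )
        y = {}
        for _, r in cells.iterrows():
            y[(r["treatment"], r["tent"], r["genotype"])] = r["value"]
        treatments = sorted({k[0] for k in y})
        tents = sorted({k[1] for k in y})
        genos = sorted({k[2] for k in y})
        grand = np.mean(list(y.values()))
        g_ = len(genos)
        t_ = len(tents)
        ss_T = sum(
            t_ * g_ * (np.mean([y[(tr, te, ge)] for te in tents for ge in genos]) - grand) ** 2
            for tr in treatments
        )
        ss_wp = sum(
            g_ * (np.mean([y[(tr, te, ge)] for ge in genos]) - grand) ** 2
            for tr in treatments
            for te in tents
        )
        res = splitplot_anova(obs, trait)
        tab = res.anova_table.set_index("source")
        assert tab.loc["temperature", "ss"] == pytest.approx(ss_T)
        assert tab.loc["tent(T)", "ss"] == pytest.approx(ss_wp - ss_T)

    def test_null_pvalues_roughly_uniform(self):
        # reduced-size calibration run; the full 1000-rep check is in acceptance
        cfg = {"t": TraitEffect("t", 500.0, 0.0, 20.0, 10.0, 30.0)}
        ps = [splitplot_anova(generate_trait_data(cfg, seed=s), "t").p_T for s in range(120)]
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= rate <= 0.13  # binomial(120, .05) 3-sigma-ish band


class TestChecklineUniformity:
    def test_identical_values_uniform(self):
        obs = generate_trait_data(zero_noise_effects(), seed=1)
        rep = checkline_uniformity(obs, traits=["grain_yield_g_m2"])
        assert (rep["p_value"] == 1.0).all()
        assert rep["uniform"].all()
        assert len(rep) == 6  # 2 treatments x 3 tents

    def test_separated_groups_detected(self):
        obs = generate_trait_data(zero_noise_effects(), seed=1)
        rng = np.random.default_rng(5)
        obs = obs.copy()
        jitter = rng.normal(0, 1.0, len(obs))
        shift = np.where(obs["block"] >= 5, 5.0, 0.0)  # 5 within-group SDs
        obs["value"] = obs["value"] + jitter + shift
        rep = checkline_uniformity(obs, traits=["grain_yield_g_m2"])
        assert (rep["p_value"] < 0.05).all()

    def test_missing_blocks_skipped_with_warning(self):
        obs = generate_trait_data(seed=1)
        obs = obs[~((obs["genotype"] == "Everest") & (obs["block"] == 8) & (obs["tent"] == 1))]
        with pytest.warns(UserWarning, match="missing blocks"):
            rep = checkline_uniformity(obs, traits=["grain_yield_g_m2"])
        assert len(rep) == 4  # both treatments' tent 1 skipped

    def test_false_alarm_rate_near_alpha(self):
        # null positional effect -> rejection rate ~ 0.05
        cfg = {"t": TraitEffect("t", 500.0, 0.0, 0.0, 0.0, 10.0)}
        hits = total = 0
        for s in range(120):
            rep = checkline_uniformity(generate_trait_data(cfg, seed=s), traits=["t"])
            hits += int((rep["p_value"] < 0.05).sum())
            total += len(rep)
        rate = hits / total
        assert 0.02 <= rate <= 0.09
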