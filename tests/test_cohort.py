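"""Subject and tract-profile generator behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tractclass import cohort
from tractclass.cohort import (BUNDLES, HEMISPHERES, NODE_COLUMNS,
                               TISSUE_PROPERTIES, EffectConfig)


class TestGenerateSubjects:
    def test_empty_cohort(self):
        df = cohort.generate_subjects(0, 0, seed=1)
        assert len(df) == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cohort.generate_subjects(-1, 5, seed=1)

    def test_same_seed_bitwise_identical(self):
        a = cohort.generate_subjects(50, 80, seed=7)
        b = cohort.generate_subjects(50, 80, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_age_confound_at_study_scale(self):
        """Cases ~N(68,7), controls ~N(62,7): group means within 2·SE."""
        df = cohort.generate_subjects(905, 5292, seed=11)
        cases = df[df.label == "case"]
        ctrls = df[df.label == "control"]
        assert abs(cases.age.mean() - 68) < 2 * 7 / np.sqrt(905)
        assert abs(ctrls.age.mean() - 62) < 2 * 7 / np.sqrt(5292)
        assert df.age.between(*cohort.AGE_RANGE).all()
        assert df.id.is_unique

    def test_ids_unique_across_groups(self):
        df = cohort.generate_subjects(10, 10, seed=3)
        assert df.id.nunique() == 20


class TestEligibility:
    def _frame(self, acuities):
        return pd.DataFrame({
            "id": [f"s{i}" for i in range(len(acuities))],
            "acuity_logmar": acuities,
        })

    def test_direct_predicate(self):
        df = self._frame([0.1, 0.3, 0.4, np.nan])
        assert len(cohort.apply_eligibility(df, 0.3)) == 3

    def test_unmeasured_always_retained(self):
        df = self._frame([np.nan] * 4)
        assert len(cohort.apply_eligibility(df, 0.3)) == 4

    def test_minus_infinity_keeps_only_unmeasured(self):
        df = self._frame([0.0, -0.1, np.nan])
        kept = cohort.apply_eligibility(df, -np.inf)
        assert list(kept.id) == ["s2"]


class TestEffectConfig:
    def test_unknown_bundle_key_rejected(self):
        with pytest.raises(ValueError):
            EffectConfig(offsets={("BOGUS", "FA"): np.zeros(100)})

    def test_bad_missing_rate_rejected(self):
        with pytest.raises(ValueError):
            EffectConfig(missing_rates={("OR", "L"): 1.5})

    def test_total_sd_combines_noise_components(self):
        cfg = EffectConfig()
        tp = "FA"
        expected = cfg.node_sd[tp] * np.sqrt(1 + cfg.intercept_sd_frac ** 2)
        assert cfg.total_sd(tp) == pytest.approx(expected)


class TestGenerateProfiles:
    def test_shape_and_determinism(self, subject_builder):
        subs = cohort.generate_subjects(5, 5, seed=2)
        a = cohort.generate_profiles(subs, EffectConfig(), seed=4)
        b = cohort.generate_profiles(subs, EffectConfig(), seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 10 * len(BUNDLES) * len(HEMISPHERES) * len(TISSUE_PROPERTIES)
        assert not a["missing"].any()

    def test_fa_range_and_positivity(self):
        subs = cohort.generate_subjects(30, 30, seed=5)
        prof = cohort.generate_profiles(subs, EffectConfig(), seed=6)
        fa = prof[prof.tissue_property == "FA"][NODE_COLUMNS].to_numpy()
        assert ((fa >= 0) & (fa <= 1)).all()
        rest = prof[prof.tissue_property != "FA"][NODE_COLUMNS].to_numpy()
        assert (rest > 0).all()

    def test_null_effects_give_null_node_differences(self):
        """With zero offsets, per-node case/control t statistics stay small."""
        subs = cohort.generate_subjects(300, 300, seed=8)
        prof = cohort.generate_profiles(subs, cohort.null_effects(), seed=9)
        sel = prof[(prof.bundle == "OR") & (prof.tissue_property == "MK")
                   & (prof.hemisphere == "L")]
        merged = sel.merge(subs[["id", "label"]], left_on="subject_id",
                           right_on="id")
        case = merged[merged.label == "case"][NODE_COLUMNS].to_numpy()
        ctrl = merged[merged.label == "control"][NODE_COLUMNS].to_numpy()
        t, _ = stats.ttest_ind(case, ctrl, axis=0)
        assert np.max(np.abs(t)) < 4.5

    def test_or_mk_reduced_bundle_wide(self):
        """Default effect: case MK below control MK at > 90 of 100 OR nodes."""
        subs = cohort.generate_subjects(500, 500, seed=10)
        prof = cohort.generate_profiles(subs, EffectConfig(), seed=11)
        sel = prof[(prof.bundle == "OR") & (prof.tissue_property == "MK")
                   & (prof.hemisphere == "L")]
        merged = sel.merge(subs[["id", "label"]], left_on="subject_id",
                           right_on="id")
        case = merged[merged.label == "case"][NODE_COLUMNS].to_numpy().mean(0)
        ctrl = merged[merged.label == "control"][NODE_COLUMNS].to_numpy().mean(0)
        assert np.sum(case < ctrl) > 90

    def test_control_bundles_null_under_default_effect(self):
        """CST/UNC case and control mean profiles agree within sampling error
        (per-node two-sample t, Bonferroni-corrected, over multiple seeds)."""
        n_tests = 0
        worst = 0.0
        for seed in (21, 22):
            subs = cohort.generate_subjects(250, 250, seed=seed)
            prof = cohort.generate_profiles(subs, EffectConfig(), seed=seed + 100)
            merged = prof.merge(subs[["id", "label"]], left_on="subject_id",
                                right_on="id")
            for bundle in ("CST", "UNC"):
                sel = merged[merged.bundle == bundle]
                case = sel[sel.label == "case"][NODE_COLUMNS].to_numpy()
                ctrl = sel[sel.label == "control"][NODE_COLUMNS].to_numpy()
                t, _ = stats.ttest_ind(case, ctrl, axis=0)
                worst = max(worst, float(np.max(np.abs(t))))
                n_tests += t.size
        # Bonferroni threshold at alpha=0.01 over all nodes tested
        thresh = stats.norm.ppf(1 - 0.01 / 2 / n_tests)
        assert worst < thresh

    def test_single_node_shift_calibrates_to_auc(self):
        """A d-SD shift at one node gives per-node AUC ≈ Φ(d/√2)."""
        d = 0.5
        offs = np.zeros(100)
        offs[50] = d
        cfg = EffectConfig(offsets={("OR", "FA"): offs},
                           missing_rates={})
        subs = cohort.generate_subjects(2500, 2500, seed=30)
        prof = cohort.generate_profiles(subs, cfg, seed=31)
        sel = prof[(prof.bundle == "OR") & (prof.tissue_property == "FA")
                   & (prof.hemisphere == "L")]
        merged = sel.merge(subs[["id", "label"]], left_on="subject_id",
                           right_on="id")
        case = merged[merged.label == "case"]["n50"].to_numpy()
        ctrl = merged[merged.label == "control"]["n50"].to_numpy()
        auc = np.mean(case[:, None] > ctrl[None, :])
        assert abs(auc - stats.norm.cdf(d / np.sqrt(2))) < 0.02

    def test_mixture_effect_leaves_means_equal(self):
        """Sign-flip mixture: distributions differ but group means do not."""
        curve = np.full(100, 0.8)
        cfg = EffectConfig(offsets={},
                           mixture_offsets={("OR", "MK"): curve})
        subs = cohort.generate_subjects(400, 400, seed=33)
        prof = cohort.generate_profiles(subs, cfg, seed=34)
        sel = prof[(prof.bundle == "OR") & (prof.tissue_property == "MK")
                   & (prof.hemisphere == "L")]
        merged = sel.merge(subs[["id", "label"]], left_on="subject_id",
                           right_on="id")
        case = merged[merged.label == "case"][NODE_COLUMNS].to_numpy()
        ctrl = merged[merged.label == "control"][NODE_COLUMNS].to_numpy()
        t, _ = stats.ttest_ind(case.mean(1), ctrl.mean(1))
        assert abs(t) < 4  # means equal
        assert case.mean(1).var() > 2 * ctrl.mean(1).var()  # distributions differ


class TestMissingness:
    def _profiles(self, n=200, seed=40):
        subs = cohort.generate_subjects(n // 2, n // 2, seed=seed)
        prof = cohort.generate_profiles(subs, cohort.null_effects(), seed=seed + 1)
        return subs, prof

    def test_zero_rate_no_missing(self):
        _, prof = self._profiles(40)
        cfg = EffectConfig(missing_rates={})
        out = cohort.inject_missingness(prof, cfg, seed=1)
        assert not out.missing.any()

    def test_rate_one_knocks_out_whole_bundle(self):
        _, prof = self._profiles(40)
        cfg = EffectConfig(missing_rates={("OR", "L"): 1.0, ("OR", "R"): 1.0})
        out = cohort.inject_missingness(prof, cfg, seed=2)
        assert out[out.bundle == "OR"].missing.all()
        assert not out[out.bundle != "OR"].missing.any()

    def test_empirical_rate_matches_configuration(self):
        """OR-left knockout at 4.2% lands within 3·SE on 2000 subjects."""
        subs, prof = self._profiles(2000, seed=44)
        out = cohort.inject_missingness(prof, EffectConfig(), seed=45)
        orl = out[(out.bundle == "OR") & (out.hemisphere == "L")]
        frac = orl.groupby("subject_id").missing.first().mean()
        se = np.sqrt(0.042 * 0.958 / 2000)
        assert abs(frac - 0.042) < 3 * se

    def test_missingness_joint_across_tissue_properties(self):
        _, prof = self._profiles(400, seed=46)
        out = cohort.inject_missingness(prof, EffectConfig(), seed=47)
        per_block = out.groupby(["subject_id", "bundle", "hemisphere"])["missing"]
        assert (per_block.nunique() == 1).all()

    def test_missingness_independent_of_label(self):
        """χ² of missing-indicator × label non-significant across seeds."""
        n_sig = 0
        for seed in range(20):
            subs = cohort.generate_subjects(300, 300, seed=seed)
            prof = cohort.generate_profiles(subs, cohort.null_effects(),
                                            seed=seed + 500)
            out = cohort.inject_missingness(prof, EffectConfig(), seed=seed + 900)
            orl = out[(out.bundle == "OR") & (out.hemisphere == "L")
                      & (out.tissue_property == "FA")]
            merged = orl.merge(subs[["id", "label"]], left_on="subject_id",
                               right_on="id")
            tab = pd.crosstab(merged.label, merged.missing)
            if tab.shape == (2, 2):
                _, p, _, _ = stats.chi2_contingency(tab)
                n_sig += p < 0.01
        assert n_sig <= 1


class TestProfileIO:
    def test_long_roundtrip_preserves_missing_blocks(self, tmp_path):
        subs = cohort.generate_subjects(20, 20, seed=50)
        prof = cohort.generate_profiles(subs, EffectConfig(), seed=51)
        prof = cohort.inject_missingness(
            prof, EffectConfig(missing_rates={("OR", "L"): 0.3}), seed=52)
        path = tmp_path / "profiles.csv"
        cohort.write_profiles(prof, path)
        back = cohort.read_profiles(path, subject_ids=subs["id"])
        key = ["subject_id", "bundle", "hemisphere", "tissue_property"]
        a = prof.sort_values(key).reset_index(drop=True)
        b = back.sort_values(key).reset_index(drop=True)
        assert (a["missing"].to_numpy() == b["missing"].to_numpy()).all()
        extant = ~a["missing"].to_numpy()
        np.testing.assert_allclose(
            a.loc[extant, NODE_COLUMNS].to_numpy(dtype=float),
            b.loc[extant, NODE_COLUMNS].to_numpy(dtype=float), rtol=1e-5)
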