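"""Mahalanobis matching, assignment optimality, and tandem splitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tractclass import cohort, matching
from tests.conftest import make_subjects


class TestConfounderMatrix:
    def test_covariance_uses_n_minus_one(self):
        subs = make_subjects(["a", "b"], ["case", "control"],
                             ages=[60.0, 70.0])
        X, cov, cols = matching.confounder_matrix(subs, ("age",))
        assert cols == ["age"]
        assert cov[0, 0] == pytest.approx(50.0, rel=1e-6)

    def test_unknown_confounder_rejected(self):
        subs = make_subjects(["a"], ["case"])
        with pytest.raises(KeyError):
            matching.confounder_matrix(subs, ("age", "shoe_size"))

    def test_categorical_one_hot(self):
        subs = make_subjects(["a", "b", "c"], ["case"] * 3)
        subs["ethnicity"] = [0, 1, 2]
        X, cov, cols = matching.confounder_matrix(subs, ("ethnicity",))
        assert X.shape == (3, 3)
        assert X.sum(axis=1).tolist() == [1, 1, 1]

    def test_constant_column_warns_and_regularizes(self):
        subs = make_subjects(["a", "b"], ["case", "control"])
        with pytest.warns(UserWarning):
            _, cov, _ = matching.confounder_matrix(subs, ("tdi",))
        np.linalg.cholesky(cov)  # invertible


class TestMahalanobis:
    def test_zero_for_identical_points(self):
        assert matching.mahalanobis([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_euclidean_special_case(self):
        assert matching.mahalanobis([3.0, 4.0], [0.0, 0.0],
                                    np.eye(2)) == pytest.approx(5.0)

    def test_hand_computed_anisotropic_case(self):
        cov = np.array([[4.0, 0.0], [0.0, 1.0]])
        d = matching.mahalanobis([2.0, 1.0], [0.0, 0.0], np.linalg.inv(cov))
        assert d == pytest.approx(np.sqrt(2.0))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            matching.mahalanobis([1.0], [1.0, 2.0], np.eye(2))


def _random_cohort(rng, n_case, n_control):
    n = n_case + n_control
    df = make_subjects([f"s{i}" for i in range(n)],
                       ["case"] * n_case + ["control"] * n_control,
                       ages=rng.normal(60, 8, n))
    df["tdi"] = rng.normal(0, 3, n)
    df["sex"] = rng.integers(0, 2, n)
    df["ethnicity"] = rng.integers(0, 3, n)
    return df[df.label == "case"], df[df.label == "control"]


def brute_force_min_total(D):
    """Exhaustive minimum total distance over all case→control injections."""
    n_case, n_control = D.shape
    best = np.inf
    for perm in itertools.permutations(range(n_control), n_case):
        best = min(best, sum(D[i, j] for i, j in enumerate(perm)))
    return best


class TestMatchCohorts:
    def test_identical_groups_all_matched_at_zero(self):
        rng = np.random.default_rng(0)
        cases, _ = _random_cohort(rng, 8, 0)
        controls = cases.copy()
        controls["id"] = [f"c{i}" for i in range(len(controls))]
        controls["label"] = "control"
        pairs = matching.match_cohorts(cases, controls)
        assert len(pairs) == 8
        assert np.allclose(pairs.distance, 0.0, atol=1e-6)

    def test_empty_inputs_empty_matched_set(self):
        rng = np.random.default_rng(1)
        cases, controls = _random_cohort(rng, 4, 10)
        assert len(matching.match_cohorts(cases.iloc[:0], controls)) == 0
        assert len(matching.match_cohorts(cases, controls.iloc[:0])) == 0

    def test_assignment_matches_brute_force_oracle(self):
        """Total assigned distance equals the exhaustive minimum (≤ 6×6)."""
        rng = np.random.default_rng(2)
        for trial in range(25):
            n_case = int(rng.integers(2, 7))
            n_control = int(rng.integers(n_case, 7))
            cases, controls = _random_cohort(rng, n_case, n_control)
            D = matching._distance_matrix(
                cases, controls, ("age", "tdi"), (), 0.0)
            pairs = matching.match_cohorts(cases, controls,
                                           confounders=("age", "tdi"),
                                           threshold=np.inf, categorical=())
            assert pairs.distance.sum() == pytest.approx(
                brute_force_min_total(D), rel=1e-9)

    def test_threshold_applied_after_assignment(self):
        rng = np.random.default_rng(3)
        cases, controls = _random_cohort(rng, 6, 20)
        loose = matching.match_cohorts(cases, controls, threshold=np.inf)
        tight = matching.match_cohorts(cases, controls, threshold=0.3)
        # pruning keeps a subset of the same optimal pairs
        loose_pairs = set(zip(loose.case_id, loose.control_id))
        assert set(zip(tight.case_id, tight.control_id)) <= loose_pairs
        assert (tight.distance <= 0.3).all()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        cases, controls = _random_cohort(rng, 30, 100)
        sizes = [len(matching.match_cohorts(cases, controls, threshold=t))
                 for t in (0.05, 0.15, 0.3, 1.0)]
        assert sizes == sorted(sizes)

    def test_confounded_cohort_balance_recovery(self):
        """Pre-match age gap ≈ 6 years collapses below 0.5 after matching."""
        subs = cohort.generate_subjects(300, 1800, seed=7)
        cases = subs[subs.label == "case"]
        controls = subs[subs.label == "control"]
        pre_gap = cases.age.mean() - controls.age.mean()
        assert pre_gap > 4.0
        pairs = matching.match_cohorts(cases, controls)
        age = subs.set_index("id").age
        gap = age.loc[pairs.case_id].mean() - age.loc[pairs.control_id].mean()
        assert abs(gap) < 0.5
        assert len(pairs) < len(cases)

    def test_each_id_used_at_most_once(self):
        rng = np.random.default_rng(5)
        cases, controls = _random_cohort(rng, 20, 50)
        pairs = matching.match_cohorts(cases, controls, threshold=np.inf)
        assert pairs.case_id.is_unique and pairs.control_id.is_unique


class TestSplitTandem:
    def _pairs(self, n):
        return pd.DataFrame({"case_id": [f"g{i}" for i in range(n)],
                             "control_id": [f"c{i}" for i in range(n)],
                             "distance": np.zeros(n)})

    def test_hundred_pairs_64_16_20(self):
        out = matching.split_tandem(self._pairs(100), seed=1)
        counts = out.split.value_counts()
        assert counts["train"] == 64
        assert counts["validation"] == 16
        assert counts["test"] == 20

    def test_single_pair_stays_together(self):
        out = matching.split_tandem(self._pairs(1), seed=2)
        assert len(out) == 1
        assert out.split.iloc[0] in {"train", "validation", "test"}
        subj = matching.subject_splits(out)
        assert subj.split.nunique() == 1

    def test_partition_property(self):
        pairs = self._pairs(37)
        out = matching.split_tandem(pairs, seed=3)
        assert len(out) == 37
        assert set(out.split) <= {"train", "validation", "test"}
        subj = matching.subject_splits(out)
        assert subj.subject_id.is_unique  # no subject in two splits

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            matching.split_tandem(self._pairs(10), fractions=(0.5, 0.2, 0.2))

    def test_rounding_rule_test_then_validation(self):
        out = matching.split_tandem(self._pairs(13), seed=4)
        counts = out.split.value_counts()
        assert counts.get("test", 0) == round(0.20 * 13)
        assert counts.get("validation", 0) == round(0.16 * 13)


class TestGeneralizationDataset:
    def test_second_disease_matching_bounded_by_pool(self):
        subs = pd.concat([
            cohort.generate_subjects(0, 1200, seed=9, id_prefix="C"),
            cohort.generate_subjects(
                81, 0, seed=10, cfg=cohort.CohortConfig(case_age_mean=70),
                case_label="amd", id_prefix="M"),
        ], ignore_index=True)
        pairs = matching.build_generalization_dataset(
            subs, used_ids=set(), selector=lambda df: df.label.eq("amd"))
        assert 0 < len(pairs) <= 81
        assert (pairs.distance <= 0.3).all()

    def test_used_controls_removed(self):
        subs = cohort.generate_subjects(10, 40, seed=11)
        used = set(subs.id)
        with pytest.warns(UserWarning):
            pairs = matching.build_generalization_dataset(
                subs, used_ids=used, selector=lambda df: df.label.eq("case"))
        assert len(pairs) == 0

    def test_age_shift_matches_younger_controls(self):
        """Shifted matching pairs 70-year-olds with ≈ 60-year-olds."""
        subs = cohort.generate_subjects(0, 4000, seed=12)
        pairs = matching.build_generalization_dataset(
            subs, used_ids=set(),
            selector=lambda df: (df.age >= 69.5) & (df.age < 70.5),
            age_shift=10.0)
        assert len(pairs) > 20
        age = subs.set_index("id").age
        assert age.loc[pairs.case_id].mean() == pytest.approx(70.0, abs=0.5)
        assert age.loc[pairs.control_id].mean() == pytest.approx(60.0, abs=1.0)
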