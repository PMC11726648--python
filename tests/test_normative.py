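"""Matched-reference z-scores, exact rank p-values, thin calls, and TPF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from mosaicmap import (MosaicNormativeScorer, PatchSet, call_thin,
                       match_reference, null_thin_probability,
                       patch_p_exhaustive, patch_z, score_patient, tpf)
from mosaicmap.normative import MatchingError, ValidationError


def demo_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "age", "sex"])


class TestMatchReference:
    def test_inclusive_two_year_same_sex_rule(self):
        cohort = demo_frame([("a", 58.0, "F"), ("b", 62.0, "F"),
                             ("c", 62.1, "F"), ("d", 60.0, "M")])
        subset = match_reference({"subject_id": "p", "age": 60.0, "sex": "F"},
                                 cohort, min_ref=1)
        assert subset.member_ids == ("a", "b")

    def test_no_same_sex_match_raises(self):
        cohort = demo_frame([("a", 40.0, "F"), ("b", 41.0, "F")])
        with pytest.raises(MatchingError, match="p"):
            match_reference({"subject_id": "p", "age": 40.0, "sex": "M"},
                            cohort, min_ref=1)

    def test_min_ref_enforced_with_achieved_count(self):
        cohort = demo_frame([("a", 60.0, "F"), ("b", 61.0, "F")])
        with pytest.raises(MatchingError, match="only 2"):
            match_reference({"subject_id": "p", "age": 60.0, "sex": "F"},
                            cohort, min_ref=10)

    def test_matches_brute_force_filter(self, small_study):
        demo = small_study.normative.demographics
        patient = {"subject_id": "p", "age": 63.5, "sex": "F"}
        subset = match_reference(patient, demo)
        brute = [row.subject_id for row in demo.itertuples()
                 if row.sex == "F" and abs(row.age - 63.5) <= 2.0]
        assert list(subset.member_ids) == brute


class TestPatchZ:
    def test_patient_at_reference_mean_gives_zero(self):
        ref = np.array([[2.0, 3.0], [2.2, 3.4]])
        z = patch_z(np.array([2.1, 3.2]), ref)
        assert np.allclose(z, 0.0)

    def test_hand_computed_sample_sd_case(self):
        # ref {2.0, 2.2}: mean 2.1, sample SD 0.2/sqrt(2); patient 1.9
        z = patch_z(np.array([1.9]), np.array([[2.0], [2.2]]))
        assert np.allclose(z, (1.9 - 2.1) / (0.2 / np.sqrt(2)))
        assert np.allclose(z, -np.sqrt(2))

    def test_thinner_patch_gives_strictly_smaller_z(self, rng):
        ref = rng.normal(2.5, 0.1, size=(20, 5))
        x = rng.normal(2.5, 0.1, size=5)
        thinner = x.copy()
        thinner[2] -= 0.05
        z0, z1 = patch_z(x, ref), patch_z(thinner, ref)
        assert z1[2] < z0[2]
        assert np.array_equal(np.delete(z0, 2), np.delete(z1, 2))

    def test_zero_reference_sd_yields_nan_and_is_excluded_from_thin_calls(self):
        ref = np.tile(np.array([[2.0, 2.5]]), (25, 1))
        ref[:, 1] += np.linspace(-0.1, 0.1, 25)
        stats = score_patient(np.array([1.0, 2.0]), ref, patient_id="p")
        assert np.isnan(stats.z[0]) and np.isfinite(stats.z[1])
        assert stats.degenerate_patches.tolist() == [0]
        assert not stats.thin[0]  # would be thin by rank, but sd=0 excludes it


class TestPatchPExhaustive:
    def test_below_all_references(self, rng):
        ref = rng.normal(2.5, 0.1, size=(20, 3))
        x = ref.min(axis=0) - 0.1
        assert np.allclose(patch_p_exhaustive(x, ref), 1 / 21)

    def test_above_all_references(self, rng):
        ref = rng.normal(2.5, 0.1, size=(20, 3))
        x = ref.max(axis=0) + 0.1
        assert np.allclose(patch_p_exhaustive(x, ref), 1.0)

    def test_ties_count_toward_le_set(self):
        ref = np.array([[2.0], [2.1], [2.2]])
        # patient equal to the smallest reference: k = 1, p = 2/4
        assert patch_p_exhaustive(np.array([2.0]), ref)[0] == pytest.approx(0.5)

    def test_null_rank_is_discrete_uniform(self, rng):
        n_ref = 30
        hits = 0
        n_sim = 4000
        for _ in range(n_sim):
            ref = rng.normal(size=(n_ref, 1))
            p = patch_p_exhaustive(rng.normal(size=1), ref)[0]
            hits += p <= 0.05
        expect = 1 / 31
        se = np.sqrt(expect * (1 - expect) / n_sim)
        assert abs(hits / n_sim - expect) < 3 * se

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValidationError):
            patch_p_exhaustive(np.array([np.nan]), np.ones((5, 1)))


class TestCallThinAndTPF:
    def test_threshold_is_strict(self):
        thin = call_thin(np.array([0.05, 1 / 31, 1.0]), alpha=0.05)
        assert thin.tolist() == [False, True, False]

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            call_thin(np.array([0.5]), alpha=1.5)

    def test_tpf_over_roi(self):
        thin = np.zeros(1000, dtype=bool)
        roi = PatchSet(name="roi", indices=tuple(range(79)))
        thin[[0, 5, 11, 78]] = True
        result = tpf(thin, roi)
        assert result.n_thin == 4
        assert result.tpf == pytest.approx(4 / 79)

    def test_no_thin_patches_gives_zero_everywhere(self):
        thin = np.zeros(50, dtype=bool)
        assert tpf(thin).tpf == 0.0
        assert tpf(thin, PatchSet(name="r", indices=(1, 2, 3))).tpf == 0.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_thin_count_decomposes_over_any_partition(self, seed):
        rng = np.random.default_rng(seed)
        thin = rng.random(200) < 0.1
        size = int(rng.integers(1, 199))
        left = np.sort(rng.choice(200, size=size, replace=False))
        right = np.setdiff1d(np.arange(200), left)
        n_left = tpf(thin, PatchSet(name="L", indices=tuple(left))).n_thin
        n_right = tpf(thin, PatchSet(name="R", indices=tuple(right))).n_thin
        assert n_left + n_right == tpf(thin).n_thin


def test_null_thin_probability_closed_form():
    # n_ref = 30: only rank 1 of 31 satisfies p < 0.05
    assert null_thin_probability(30) == pytest.approx(1 / 31)
    # alpha*(n+1) integer: strict inequality excludes the boundary rank
    assert null_thin_probability(19, alpha=0.05) == 0.0
    assert null_thin_probability(39, alpha=0.05) == pytest.approx(1 / 40)


class TestScorerEstimator:
    def test_transform_returns_z_matrix(self, fitted_scorer, small_study):
        z = fitted_scorer.transform(small_study.patient_thickness,
                                    small_study.patient_demographics)
        assert z.shape == (30, 121)
        assert z.columns[0] == "subject_id"

    def test_scoring_is_deterministic(self, fitted_scorer, small_study):
        a = fitted_scorer.score_patients(small_study.patient_thickness,
                                         small_study.patient_demographics)
        b = fitted_scorer.score_patients(small_study.patient_thickness,
                                         small_study.patient_demographics)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.z, sb.z, equal_nan=True)
            assert np.array_equal(sa.p, sb.p)
            assert np.array_equal(sa.thin, sb.thin)

    def test_z_and_p_rank_patients_identically(self, fitted_scorer, small_study):
        stats = fitted_scorer.score_patients(small_study.patient_thickness,
                                             small_study.patient_demographics)
        z = np.array([s.z[0] for s in stats])
        p = np.array([s.p[0] for s in stats])
        nref = np.array([s.n_ref for s in stats])
        # within a shared reference group, smaller z must mean smaller-or-equal p
        for group in np.unique(nref):
            members = np.flatnonzero(nref == group)
            order = members[np.argsort(z[members])]
            assert (np.diff(p[order]) >= 0).all()

    def test_sklearn_clone_and_params(self):
        scorer = MosaicNormativeScorer(age_window=3.0, alpha=0.01)
        cloned = clone(scorer)
        assert cloned.get_params() == scorer.get_params()

    def test_tpf_table_shape(self, fitted_scorer, patient_stats, small_config):
        table = fitted_scorer.tpf_table(
            patient_stats, {"restricted": small_config.resolved_roi(), "wholebrain": None})
        assert len(table) == 2 * len(patient_stats)
        assert set(table["patch_set"]) == {"restricted", "wholebrain"}
        assert table["tpf"].between(0, 1).all()
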