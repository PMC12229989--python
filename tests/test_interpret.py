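import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypermhc.errors import InvalidMap, PeptideTooShort, ShapeError
from hypermhc.interpret import (
    CorePrediction,
    attention_contribution,
    combine_importance,
    contact_profile,
    detect_core,
    perturbation_importance,
    residue_importance,
    score_core_overlap,
)
from hypermhc.seq_io import CoreAnnotation


def brute_force_core(values, window=9):
    sums = [values[s : s + window].sum() for s in range(len(values) - window + 1)]
    best = max(range(len(sums)), key=lambda s: (sums[s], -s))
    return best, sums[best]


class TestAttentionContribution:
    def test_uniform_attention_gives_uniform_contributions(self):
        A = np.full((6, 6), 1.0 / 6)
        assert np.allclose(attention_contribution(A), np.full(6, 1 / 6))

    def test_attended_residue_has_maximal_contribution(self):
        A = np.full((5, 5), 0.01)
        A[:, 2] = 0.96  # everyone attends residue 2
        contrib = attention_contribution(A)
        assert np.argmax(contrib) == 2
        assert contrib.sum() == pytest.approx(1.0, abs=1e-9)

    def test_validation(self):
        with pytest.raises(ShapeError):
            attention_contribution(np.ones((3, 4)))
        with pytest.raises(ShapeError):
            attention_contribution(-np.ones((3, 3)))


class TestCombineImportance:
    def test_zero_factor_annihilates(self):
        assert np.allclose(combine_importance(np.zeros(4), np.ones(4)), 0.0)

    def test_uniform_contextual_preserves_spatial_shape(self):
        spatial = np.array([1.0, 3.0, 2.0])
        combined = combine_importance(np.full(3, 0.5), spatial)
        assert np.allclose(combined / combined.sum(), spatial / spatial.sum())

    def test_permutation_commutes(self):
        rng = np.random.default_rng(0)
        c, s = rng.random(6), rng.random(6)
        perm = rng.permutation(6)
        assert np.allclose(
            combine_importance(c, s)[perm], combine_importance(c[perm], s[perm])
        )

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            combine_importance(np.ones(3), np.ones(4))


class TestDetectCore:
    def test_worked_example(self):
        imp = np.array([0, 0, 0] + [1] * 9, dtype=float)
        pred = detect_core(imp)
        assert (pred.start, pred.score) == (3, 9.0)

    def test_leftmost_tie_on_uniform(self):
        pred = detect_core(np.ones(12))
        assert pred.start == 0

    def test_single_window(self):
        assert detect_core(np.arange(9, dtype=float)).start == 0

    def test_too_short(self):
        with pytest.raises(PeptideTooShort):
            detect_core(np.ones(8))

    @given(st.integers(min_value=9, max_value=20), st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force(self, n, seed):
        values = np.random.default_rng(seed).random(n)
        pred = detect_core(values)
        start, score = brute_force_core(values)
        assert pred.start == start
        assert pred.score == pytest.approx(score)


class TestContactProfile:
    def test_worked_example(self):
        P = contact_profile(np.array([[0.0, 2.0], [4.0, 2.0]]))
        assert np.allclose(P, [[0.0, 0.5], [1.0, 0.5]])

    def test_constant_maps_to_zeros(self):
        assert np.allclose(contact_profile(np.full((3, 4), 2.2)), 0.0)

    def test_range_invariants(self):
        rng = np.random.default_rng(1)
        H = rng.standard_normal((5, 7))
        P = contact_profile(H)
        assert P.min() == pytest.approx(0.0)
        assert P.max() == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        H = rng.standard_normal((4, 6))
        assert np.allclose(contact_profile(H), contact_profile(3.7 * H + 11.0))

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidMap):
            contact_profile(np.array([[np.nan, 1.0]]))


class TestCoreOverlap:
    @pytest.mark.parametrize(
        "pred_start, truth_start, category",
        [(3, 3, "exact"), (4, 3, "shifted_1"), (1, 3, "shifted_2"), (8, 3, "miss")],
    )
    def test_categories(self, pred_start, truth_start, category):
        pred = CorePrediction(start=pred_start, score=1.0)
        truth = CoreAnnotation("X", "ACDEFGHIKLMNPQR", truth_start)
        assert score_core_overlap(pred, truth) == category

    def test_peptide_mismatch(self):
        pred = CorePrediction(start=0, score=1.0)
        truth = CoreAnnotation("X", "ACDEFGHIKLMNPQR", 0)
        with pytest.raises(ShapeError):
            score_core_overlap(pred, truth, peptide="WCDEFGHIKLMNPQR")


class TestPerturbationImportance:
    def test_nonnegative_and_deterministic(self, fitted_model, small_dataset):
        rec = small_dataset.records[0]
        al = small_dataset.allele_of(rec)
        backend = fitted_model.backend_
        imp1 = perturbation_importance(fitted_model, al, rec.peptide, backend)
        imp2 = perturbation_importance(fitted_model, al, rec.peptide, backend)
        assert np.array_equal(imp1, imp2)
        assert np.all(imp1 >= 0)
        assert imp1.shape == (len(rec.peptide),)

    def test_model_blind_to_peptide_gives_zero_importance(self, fitted_model, small_dataset):
        rec = small_dataset.records[1]
        al = small_dataset.allele_of(rec)
        # zero every classification-head parameter: the binding
        # probability is then constant, so occlusion changes nothing
        saved = {}
        for member in fitted_model.members_:
            for k, v in member["params"].items():
                if k.startswith("clf_"):
                    saved[id(v)] = v.copy()
                    v[...] = 0.0
        try:
            imp = perturbation_importance(
                fitted_model, al, rec.peptide, fitted_model.backend_
            )
            assert np.allclose(imp, 0.0)
        finally:
            for member in fitted_model.members_:
                for k, v in member["params"].items():
                    if k.startswith("clf_"):
                        v[...] = saved[id(v)]

    def test_residue_importance_pipeline(self, fitted_model, small_dataset):
        rec = small_dataset.records[2]
        al = small_dataset.allele_of(rec)
        imp = residue_importance(fitted_model, al, rec.peptide, fitted_model.backend_)
        assert imp.shape == (len(rec.peptide),)
        assert np.all(imp >= 0)
        pred = detect_core(imp)
        assert 0 <= pred.start <= len(rec.peptide) - 9
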