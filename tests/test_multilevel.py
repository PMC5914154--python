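"""Paired assembly, variation splitting, scaling/fusion, and NIPALS PLS-DA."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import breathpair as bp
from conftest import single_block_config


def toy_cohort(values: dict, subjects, visits, block="blk", features=("x0",)):
    """Small cohort from a {(subject, visit): row} dict; None marks missing."""
    index = pd.MultiIndex.from_product([subjects, visits], names=["subject", "visit"])
    data, mask = [], []
    for key in index:
        row = values[key]
        data.append([0.0 if v is None else float(v) for v in row])
        mask.append([v is not None for v in row])
    df = pd.DataFrame(data, index=index, columns=list(features))
    m = pd.DataFrame(mask, index=index, columns=list(features))
    return bp.Cohort(blocks={block: df}, masks={block: m})


class TestAssemblePaired:
    def test_enose_pair_shape(self, complete_cohort):
        pm = bp.assemble_paired(complete_cohort, ["carbon_polymer", "quartz"], "V1", "V4")
        assert pm.X.shape == (28, 40)  # 14 subjects x 2 visits, 32 + 8 sensors
        assert pm.n_subjects == 14
        assert pm.excluded_subjects == []
        assert np.array_equal(np.unique(pm.y), [-1.0, 1.0])
        # y alternates -1 (visit a) / +1 (visit b) within each subject
        assert np.array_equal(pm.y, np.tile([-1.0, 1.0], 14))

    def test_subject_with_missing_cell_excluded(self):
        values = {
            ("S1", "V1"): [1.0], ("S1", "V4"): [2.0],
            ("S2", "V1"): [3.0], ("S2", "V4"): [None],
            ("S3", "V1"): [5.0], ("S3", "V4"): [6.0],
        }
        cohort = toy_cohort(values, ["S1", "S2", "S3"], ["V1", "V4"])
        pm = bp.assemble_paired(cohort, ["blk"], "V1", "V4")
        assert pm.subjects == ["S1", "S3"]
        assert pm.excluded_subjects == ["S2"]
        assert pm.X.shape == (4, 1)

    def test_retained_set_matches_hand_enumeration(self):
        # S1 complete; S2 missing at V1; S3 missing only at V2 (irrelevant
        # visit) so it stays; missingness placed by hand
        values = {
            ("S1", "V1"): [1.0, 1.0], ("S1", "V2"): [1.0, 1.0], ("S1", "V3"): [1.0, 1.0],
            ("S2", "V1"): [None, 1.0], ("S2", "V2"): [1.0, 1.0], ("S2", "V3"): [1.0, 1.0],
            ("S3", "V1"): [2.0, 2.0], ("S3", "V2"): [None, None], ("S3", "V3"): [2.0, 2.0],
        }
        cohort = toy_cohort(values, ["S1", "S2", "S3"], ["V1", "V2", "V3"],
                            features=("x0", "x1"))
        pm = bp.assemble_paired(cohort, ["blk"], "V1", "V3")
        assert pm.subjects == ["S1", "S3"]
        pm2 = bp.assemble_paired(cohort, ["blk"], "V2", "V3")
        assert pm2.subjects == ["S1", "S2"]

    def test_fewer_than_two_complete_subjects_errors(self):
        values = {
            ("S1", "V1"): [1.0], ("S1", "V2"): [None],
            ("S2", "V1"): [None], ("S2", "V2"): [2.0],
            ("S3", "V1"): [3.0], ("S3", "V2"): [4.0],
        }
        cohort = toy_cohort(values, ["S1", "S2", "S3"], ["V1", "V2"])
        with pytest.raises(bp.InsufficientDataError):
            bp.assemble_paired(cohort, ["blk"], "V1", "V2")

    def test_unknown_visit_or_block_keyerror(self, complete_cohort):
        with pytest.raises(KeyError, match="V9"):
            bp.assemble_paired(complete_cohort, ["quartz"], "V1", "V9")
        with pytest.raises(KeyError, match="nope"):
            bp.assemble_paired(complete_cohort, ["nope"], "V1", "V4")


def paired_from_matrix(X, n_subjects, block_index=None):
    X = np.asarray(X, dtype=float)
    return bp.PairedMatrix(
        subjects=[f"S{i}" for i in range(n_subjects)],
        visit_pair=("a", "b"),
        X=X,
        y=np.tile([-1.0, 1.0], n_subjects),
        feature_names=[f"f{j}" for j in range(X.shape[1])],
        block_index=np.asarray(
            block_index if block_index is not None else ["blk"] * X.shape[1],
            dtype=object,
        ),
    )


class TestSplitVariation:
    def test_hand_computed_two_subject_example(self):
        # subjects with rows (1, 3) and (2, 6): grand mean 3, subject means 2
        # and 4, within parts -+1 and -+2
        pm = paired_from_matrix([[1.0], [3.0], [2.0], [6.0]], 2)
        dec = bp.split_variation(pm)
        assert dec.m == pytest.approx([3.0])
        assert dec.X_between.ravel() == pytest.approx([-1, -1, 1, 1])
        assert dec.X_within.ravel() == pytest.approx([-1, 1, -2, 2])

    def test_identical_rows_give_zero_within(self):
        pm = paired_from_matrix([[2.0, 5.0], [2.0, 5.0], [1.0, 0.0], [3.0, 4.0]], 2)
        dec = bp.split_variation(pm)
        assert np.allclose(dec.X_within[:2], 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(1, 6), st.integers(0, 2**31 - 1))
    def test_reconstruction_identity_and_antisymmetry(self, n, p, seed):
        X = np.random.default_rng(seed).normal(size=(2 * n, p)) * 10
        pm = paired_from_matrix(X, n)
        dec = bp.split_variation(pm)
        recon = dec.m[None, :] + dec.X_between + dec.X_within
        assert np.max(np.abs(recon - X)) < 1e-10 * max(1, np.max(np.abs(X)))
        # two-visit antisymmetry: each subject's within rows are negatives
        assert np.max(np.abs(dec.X_within[0::2] + dec.X_within[1::2])) < 1e-10
        # columns of the within part sum to zero
        assert np.max(np.abs(dec.X_within.sum(axis=0))) < 1e-8

    def test_within_parts_matches_split(self, rng):
        X = rng.normal(size=(10, 5))
        pm = paired_from_matrix(X, 5)
        assert np.allclose(bp.within_parts(X), bp.split_variation(pm).X_within)


class TestScaling:
    def test_training_columns_standardized(self, rng):
        X = rng.normal(loc=3.0, scale=2.5, size=(12, 4))
        sm = bp.fit_scaling(X, ["b"] * 4, block_weight=False)
        Z = bp.apply_scaling(sm, X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(Z.var(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_block_weight_is_inverse_sqrt_block_size(self, rng):
        X = rng.normal(size=(10, 6))
        sm = bp.fit_scaling(X, ["a"] * 4 + ["b"] * 2)
        assert np.allclose(sm.block_weight[:4], 1 / np.sqrt(4))
        assert np.allclose(sm.block_weight[4:], 1 / np.sqrt(2))

    def test_equal_size_blocks_get_equal_total_variance(self, rng):
        X = rng.normal(size=(40, 8))
        sm = bp.fit_scaling(X, ["a"] * 4 + ["b"] * 4)
        Z = bp.apply_scaling(sm, X)
        va = Z[:, :4].var(axis=0, ddof=1).sum()
        vb = Z[:, 4:].var(axis=0, ddof=1).sum()
        assert va == pytest.approx(vb, rel=1e-10)
        assert va == pytest.approx(1.0, rel=1e-10)  # 4 features x 1/4 each

    def test_heldout_row_matches_hand_formula(self, rng):
        X = rng.normal(size=(8, 3))
        x_new = rng.normal(size=(1, 3))
        sm = bp.fit_scaling(X, ["a", "a", "b"])
        expected = (x_new - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        expected = expected / np.sqrt([2, 2, 1])
        assert np.allclose(bp.apply_scaling(sm, x_new), expected)

    def test_constant_feature_dropped_and_recorded(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        sm = bp.fit_scaling(X, ["a"] * 3, feature_names=["u", "v", "w"])
        assert sm.dropped == ["v"]
        assert bp.apply_scaling(sm, X).shape == (10, 2)

    def test_all_constant_errors(self):
        with pytest.raises(bp.DegenerateDataError):
            bp.fit_scaling(np.ones((5, 3)), ["a"] * 3)


class TestPLS:
    def test_single_predictor_equal_to_y(self):
        y = np.tile([-1.0, 1.0], 10)
        X = y[:, None].copy()
        model = bp.fit_pls_da(X, y, n_components=1)
        assert model.W[:, 0] == pytest.approx([1.0])
        t = model.T[:, 0]
        assert np.allclose(t / np.abs(t).max(), y)

    def test_first_weight_matches_cross_covariance_svd(self, rng):
        X = rng.normal(size=(20, 6))
        X -= X.mean(axis=0)
        y = np.tile([-1.0, 1.0], 10)
        model = bp.fit_pls_da(X, y, n_components=2)
        u = np.linalg.svd((X.T @ y)[:, None], full_matrices=False)[0][:, 0]
        w = model.W[:, 0]
        assert min(np.abs(w - u).max(), np.abs(w + u).max()) < 1e-8

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(16, 7))
        X -= X.mean(axis=0)
        y = np.tile([-1.0, 1.0], 8)
        model = bp.fit_pls_da(X, y, n_components=3)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0)

    def test_sklearn_cross_check_first_component(self, rng):
        # independent implementation route: scikit-learn's NIPALS PLS
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(14, 5))
        X -= X.mean(axis=0)
        y = np.tile([-1.0, 1.0], 7)
        ours = bp.fit_pls_da(X, y, n_components=2)
        ref = PLSRegression(n_components=2, scale=False).fit(X, y)
        for a in range(2):
            w_ref = ref.x_weights_[:, a]
            w = ours.W[:, a]
            assert min(np.abs(w - w_ref).max(), np.abs(w + w_ref).max()) < 1e-8

    def test_rank_deficient_input_stops_early(self, rng):
        base = rng.normal(size=(12, 2))
        X = np.hstack([base, base @ rng.normal(size=(2, 3))])  # rank 2
        X -= X.mean(axis=0)
        y = np.tile([-1.0, 1.0], 6)
        model = bp.fit_pls_da(X, y, n_components=4)
        assert model.achieved <= 2
        assert model.W.shape[1] == model.achieved

    def test_project_training_rows_reproduces_scores(self, rng):
        X = rng.normal(size=(12, 5))
        X -= X.mean(axis=0)
        y = np.tile([-1.0, 1.0], 6)
        model = bp.fit_pls_da(X, y, n_components=2)
        assert np.max(np.abs(bp.project(model, X) - model.T)) < 1e-8

    def test_projection_is_linear(self, rng):
        X = rng.normal(size=(10, 4))
        X -= X.mean(axis=0)
        y = np.tile([-1.0, 1.0], 5)
        model = bp.fit_pls_da(X, y, n_components=2)
        q = rng.normal(size=(1, 4))
        assert np.allclose(bp.project(model, -q), -bp.project(model, q))

    def test_heldout_matches_closed_form_rotation(self, rng):
        X = rng.normal(size=(12, 5))
        X -= X.mean(axis=0)
        y = np.tile([-1.0, 1.0], 6)
        model = bp.fit_pls_da(X, y, n_components=2)
        x_new = rng.normal(size=(3, 5))
        A = model.achieved
        R = model.W[:, :A] @ np.linalg.inv(model.P[:, :A].T @ model.W[:, :A])
        assert np.max(np.abs(bp.project(model, x_new) - x_new @ R)) < 1e-8

    def test_feature_mismatch_errors(self, rng):
        X = rng.normal(size=(8, 4))
        y = np.tile([-1.0, 1.0], 4)
        model = bp.fit_pls_da(X - X.mean(axis=0), y, n_components=1)
        with pytest.raises(bp.FeatureMismatchError):
            bp.project(model, rng.normal(size=(2, 5)))


class TestPipelineProperties:
    def test_subject_permutation_equivariance(self, rng):
        X = rng.normal(size=(12, 5))
        pm = paired_from_matrix(X, 6)
        perm = rng.permutation(6)
        pm_perm = pm.take_subjects(perm)

        dec, dec_p = bp.split_variation(pm), bp.split_variation(pm_perm)
        rows = np.ravel([[2 * i, 2 * i + 1] for i in perm])
        assert np.allclose(dec_p.X_within, dec.X_within[rows])
        assert np.allclose(dec_p.m, dec.m)

        m1 = bp.fit_pls_da(dec.X_within, pm.y, 2)
        m2 = bp.fit_pls_da(dec_p.X_within, pm_perm.y, 2)
        assert np.allclose(m2.W, m1.W)          # loadings identical
        assert np.allclose(m2.T, m1.T[rows])    # scores permuted alongside rows

    def test_within_pls_equivalent_to_difference_matrix(self, rng):
        # subject-level decision scores from the +-d/2 within rows equal half
        # the projection of the scaled difference vectors d_i = x_b - x_a
        X = rng.normal(size=(16, 6))
        pm = paired_from_matrix(X, 8)
        dec = bp.split_variation(pm)
        sm = bp.fit_scaling(dec.X_within, pm.block_index)
        Z = bp.apply_scaling(sm, dec.X_within)
        model = bp.fit_pls_da(Z, pm.y, 2)

        d = X[1::2] - X[0::2]
        Zd = bp.apply_scaling(sm, d / 2.0) - bp.apply_scaling(sm, -d / 2.0)
        t_rows = bp.project(model, bp.apply_scaling(sm, bp.within_parts(X)))
        t_diff = bp.project(model, Zd)
        assert np.allclose(t_rows[1::2], t_diff / 2.0)
        assert np.allclose(t_rows[0::2], -t_diff / 2.0)
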