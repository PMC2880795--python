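"""Infomax fitting, projector algebra, recovery against independent
oracles, and split-half stability."""

import numpy as np
import pytest
from scipy import stats as sps

from erpica.ica import (
    MixingModel,
    component_timecourse,
    explained_power_fraction,
    fit_infomax,
    match_topographies,
    project_component,
    spatial_filter,
    split_half_stability,
)


def rotation_search_oracle(P: np.ndarray, n_grid: int = 3600) -> np.ndarray:
    """Brute-force 2-D ICA: whiten, then grid-search the rotation angle
    maximizing total |excess kurtosis| of the rotated coordinates.
    Independent of the gradient-based path under test."""
    Xc = P - P.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / Xc.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    white = vecs @ np.diag(vals**-0.5) @ vecs.T
    Z = white @ Xc
    best, best_theta = -np.inf, 0.0
    for theta in np.linspace(0, np.pi / 2, n_grid, endpoint=False):
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        Y = R @ Z
        score = np.sum(np.abs(sps.kurtosis(Y, axis=1)))
        if score > best:
            best, best_theta = score, theta
    c, s = np.cos(best_theta), np.sin(best_theta)
    return np.array([[c, -s], [s, c]]) @ Z


def source_correlations(S_true, S_est):
    """Best |corr| per true source after optimal assignment."""
    k = S_true.shape[0]
    C = np.abs(np.corrcoef(np.vstack([S_true, S_est]))[:k, k:])
    from scipy.optimize import linear_sum_assignment

    r, c = linear_sum_assignment(-C)
    return C[r, c]


class TestFitInfomax:
    def test_laplacian_mixture_recovered(self, toy_mixture, toy_model):
        _, S, P = toy_mixture
        corr = source_correlations(S, toy_model.U @ P)
        assert np.all(corr >= 0.95)

    def test_independent_input_gives_near_permutation(self):
        rng = np.random.default_rng(4)
        S = rng.laplace(size=(3, 6000))
        model = fit_infomax(S, seed=0)
        corr = source_correlations(S, model.U @ S)
        assert np.all(corr >= 0.95)

    def test_same_seed_identical(self, toy_mixture):
        _, _, P = toy_mixture
        a = fit_infomax(P, seed=12)
        b = fit_infomax(P, seed=12)
        assert np.array_equal(a.U, b.U)

    def test_different_seeds_agree_after_convention(self, toy_mixture):
        _, _, P = toy_mixture
        a = fit_infomax(P, seed=1)
        b = fit_infomax(P, seed=2)
        pairs = match_topographies(a.topographies, b.topographies)
        assert all(c > 0.999 for _, _, c in pairs)

    def test_rank_deficient_raises_with_advice(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 500))
        X[2] = X[0] + X[1]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_infomax(X)

    def test_rank_mode_reduces_dimension(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.laplace(size=(2, 3000))])
        A = rng.standard_normal((4, 2))
        model = fit_infomax(A @ X, n_components="rank", seed=0)
        assert model.n_components == 2

    def test_non_convergence_flag(self, toy_mixture):
        _, _, P = toy_mixture
        model = fit_infomax(P, max_iter=2, seed=0)
        assert model.converged is False

    def test_matches_rotation_search_oracle(self, toy_mixture):
        _, _, P = toy_mixture
        S_oracle = rotation_search_oracle(P)
        model = fit_infomax(P, seed=3)
        corr = source_correlations(S_oracle, model.U @ P)
        assert np.all(corr >= 0.95)


class TestProjectorAlgebra:
    def test_filters_idempotent(self, square_model):
        model, _ = square_model
        for i in range(model.n_components):
            F = spatial_filter(model, i)
            assert np.max(np.abs(F @ F - F)) < 1e-8

    def test_filters_annihilate_each_other(self, square_model):
        model, _ = square_model
        for i in range(model.n_components):
            for j in range(model.n_components):
                if i != j:
                    F = spatial_filter(model, i) @ spatial_filter(model, j)
                    assert np.max(np.abs(F)) < 1e-8

    def test_filters_sum_to_identity(self, square_model):
        model, _ = square_model
        total = sum(spatial_filter(model, i) for i in range(model.n_components))
        assert np.max(np.abs(total - np.eye(model.n_channels))) < 1e-8

    def test_random_invertible_unmixing_sums_to_identity(self):
        rng = np.random.default_rng(5)
        U = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        model = MixingModel(U=U, U_inv=np.linalg.inv(U), channel_order=("a", "b", "c"))
        total = sum(model.spatial_filter(i) for i in range(3))
        assert np.max(np.abs(total - np.eye(3))) < 1e-8

    def test_projections_sum_to_data(self, square_model):
        model, P = square_model
        recon = sum(project_component(model, i, P) for i in range(model.n_components))
        assert np.max(np.abs(recon - P)) < 1e-8

    def test_projection_idempotent_and_rank_one(self, square_model):
        model, P = square_model
        Pi = project_component(model, 0, P)
        again = project_component(model, 0, Pi)
        assert np.allclose(Pi, again, atol=1e-8)
        s = np.linalg.svd(Pi, compute_uv=False)
        assert s[1] / s[0] < 1e-10

    def test_invalid_component_index(self, square_model):
        model, _ = square_model
        with pytest.raises(IndexError):
            spatial_filter(model, model.n_components)


class TestTimecourse:
    def test_recovers_known_sources_exactly(self, square_model):
        model, _ = square_model
        S = np.random.default_rng(6).normal(size=(model.n_components, 50))
        P = model.U_inv @ S
        for i in range(model.n_components):
            assert np.allclose(component_timecourse(model, i, P), S[i], atol=1e-8)

    def test_zero_data_zero_timecourse(self, square_model):
        model, _ = square_model
        out = component_timecourse(model, 0, np.zeros((model.n_channels, 20)))
        assert np.all(out == 0.0)

    def test_channel_mismatch_raises(self, square_model):
        model, _ = square_model
        with pytest.raises(ValueError):
            component_timecourse(model, 0, np.zeros((model.n_channels + 1, 20)))


class TestExplainedPower:
    def test_all_components_explain_everything(self, square_model):
        model, P = square_model
        assert explained_power_fraction(model, range(model.n_components), P) == pytest.approx(1.0, abs=1e-9)

    def test_no_components_explain_nothing(self, square_model):
        model, P = square_model
        assert explained_power_fraction(model, [], P) == 0.0

    def test_zero_power_raises(self, square_model):
        model, _ = square_model
        with pytest.raises(ValueError):
            explained_power_fraction(model, [0], np.zeros((model.n_channels, 5)))

    def test_components_ordered_by_descending_power(self, square_model):
        model, P = square_model
        fractions = [explained_power_fraction(model, [i], P) for i in range(model.n_components)]
        assert fractions == sorted(fractions, reverse=True)


class TestSplitHalf:
    def test_duplicate_halves_perfectly_stable(self, recovery_dataset):
        _, _, ds = recovery_dataset
        ids = tuple(sorted(ds.subject_ids)[:10])
        report = split_half_stability(ds, seed=0, halves=(ids, ids))
        assert report.mean_abs_correlation == pytest.approx(1.0, abs=1e-6)

    def test_high_snr_halves_stable(self, recovery_dataset):
        _, _, ds = recovery_dataset
        report = split_half_stability(ds, seed=0)
        assert report.mean_abs_correlation >= 0.9

    def test_invariant_to_subject_order(self, recovery_dataset):
        _, _, ds = recovery_dataset
        shuffled = type(ds)(subjects=list(reversed(ds.subjects)), provenance=ds.provenance)
        a = split_half_stability(ds, seed=5)
        b = split_half_stability(shuffled, seed=5)
        assert a.halves == b.halves
        assert a.mean_abs_correlation == b.mean_abs_correlation

    def test_too_few_subjects(self, recovery_dataset):
        _, _, ds = recovery_dataset
        two = [s for s in ds.subjects if s.subject_id in ds.subject_ids[:2]]
        small = type(ds)(subjects=two)
        with pytest.raises(ValueError, match="4 subjects"):
            split_half_stability(small)
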