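import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ppmsdm import enfa
from ppmsdm.grid import GeoGrid, RasterStack
from ppmsdm.occurrences import OccurrenceSet


def _correlated(rng, n, chol):
    return rng.normal(size=(n, chol.shape[0])) @ chol.T


@pytest.fixture(scope="module")
def chol3():
    return np.linalg.cholesky(np.array([[1.0, 0.5, 0.2],
                                        [0.5, 1.0, 0.3],
                                        [0.2, 0.3, 1.0]]))


class TestMarginalitySpecialization:
    def test_background_identical_presences_are_null(self, chol3):
        rng = np.random.default_rng(0)
        bg = _correlated(rng, 100_000, chol3)
        occ = _correlated(rng, 100_000, chol3)
        res = enfa.enfa_fit_matrix(bg, occ)
        assert res.marginality <= 0.05
        assert abs(res.specialization - 1.0) <= 0.05

    def test_one_sd_shift_on_one_predictor(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(100_000, 2))
        occ = rng.normal(size=(100_000, 2))
        occ[:, 0] += 1.0
        res = enfa.enfa_fit_matrix(bg, occ)
        np.testing.assert_allclose(res.marginality_vector, [1.0, 0.0], atol=0.02)
        assert res.marginality == pytest.approx(1.0, abs=0.02)

    def test_narrow_niche_raises_specialization(self):
        rng = np.random.default_rng(2)
        bg = rng.normal(size=(50_000, 2))
        occ = rng.normal(size=(20_000, 2)) * [0.5, 1.0] + [0.5, 0.0]
        res = enfa.enfa_fit_matrix(bg, occ)
        assert res.specialization > 1.2


class TestFactorAlgebra:
    def test_factors_are_rs_orthogonal(self, chol3):
        rng = np.random.default_rng(3)
        bg = _correlated(rng, 20_000, chol3)
        occ = 0.7 * _correlated(rng, 5_000, chol3) + np.array([0.8, -0.2, 0.1])
        res = enfa.enfa_fit_matrix(bg, occ)
        mu, sd = bg.mean(0), bg.std(0)
        z_occ = (occ - mu) / sd
        zc = z_occ - z_occ.mean(0)
        r_s = zc.T @ zc / len(zc)
        gram = res.loadings.T @ r_s @ res.loadings
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    @pytest.mark.parametrize("p, seed", [(2, 10), (3, 11)])
    def test_lambda2_matches_numerical_rayleigh_maximization(self, p, seed):
        rng = np.random.default_rng(seed)
        mix = rng.normal(size=(p, p)) + np.eye(p)
        bg = rng.normal(size=(5000, p)) @ mix
        occ = 0.6 * rng.normal(size=(3000, p)) @ mix + rng.normal(size=p)
        res = enfa.enfa_fit_matrix(bg, occ)

        mu, sd = bg.mean(0), bg.std(0)
        z_bg, z_occ = (bg - mu) / sd, (occ - mu) / sd
        r_g = np.cov(z_bg.T, ddof=0)
        zc = z_occ - z_occ.mean(0)
        r_s = zc.T @ zc / len(zc)
        m = z_occ.mean(0)

        best = -np.inf
        for trial in range(10):
            u0 = np.random.default_rng(trial).normal(size=p)
            sol = optimize.minimize(
                lambda u: -(u @ r_g @ u) / (u @ r_s @ u), u0,
                constraints=[{"type": "eq", "fun": lambda u: u @ r_s @ m}],
                method="SLSQP", options={"maxiter": 2000, "ftol": 1e-16})
            if sol.success:
                best = max(best, -sol.fun)
        assert res.eigenvalues[1] == pytest.approx(best, abs=1e-6)

    def test_affine_predictor_transform_changes_nothing(self, chol3):
        rng = np.random.default_rng(4)
        bg = _correlated(rng, 10_000, chol3)
        occ = 0.8 * _correlated(rng, 4_000, chol3) + np.array([0.5, 0.0, -0.3])
        res1 = enfa.enfa_fit_matrix(bg, occ)
        scale = np.array([100.0, 0.01, 7.0])
        shift = np.array([-40.0, 3.0, 0.0])
        res2 = enfa.enfa_fit_matrix(bg * scale + shift, occ * scale + shift)
        assert res1.marginality == pytest.approx(res2.marginality, abs=1e-10)
        assert res1.specialization == pytest.approx(res2.specialization, abs=1e-10)
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-8)

    def test_duplicating_every_occurrence_changes_nothing(self, chol3):
        rng = np.random.default_rng(5)
        bg = _correlated(rng, 10_000, chol3)
        occ = 0.8 * _correlated(rng, 2_000, chol3) + 0.4
        res1 = enfa.enfa_fit_matrix(bg, occ)
        res2 = enfa.enfa_fit_matrix(bg, np.vstack([occ] * 3))
        assert res1.marginality == pytest.approx(res2.marginality, abs=1e-12)
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-9)


class TestRasterInterface:
    @pytest.fixture()
    def stack_and_occ(self):
        rng = np.random.default_rng(6)
        a = GeoGrid(rng.normal(size=(30, 30)), 0, 30, 1.0)
        b = GeoGrid(rng.normal(size=(30, 30)), 0, 30, 1.0)
        stack = RasterStack.from_mapping({"a": a, "b": b})
        lon = rng.uniform(0, 30, 400)
        lat = rng.uniform(0, 30, 400)
        occ = OccurrenceSet(pd.DataFrame({"lon": lon, "lat": lat}))
        return stack, occ

    def test_cell_weighting_counts_repeat_visits(self, stack_and_occ):
        stack, occ = stack_and_occ
        res = enfa.enfa_fit(stack, occ, n_background=10_000, seed=0)
        assert res.marginality >= 0
        assert len(res.eigenvalues) == 2

    def test_loadings_table_ordered_by_abs_marginality(self, stack_and_occ):
        stack, occ = stack_and_occ
        res = enfa.enfa_fit(stack, occ, n_background=10_000, seed=0)
        table = res.loadings_table()
        marg = res.marginality_vector
        expected = [res.predictors[i]
                    for i in np.argsort(-np.abs(marg), kind="stable")]
        assert list(table.index) == expected
        assert list(table.columns) == ["Marg", "Spec1"]

    def test_order_stable_under_predictor_permutation(self, stack_and_occ):
        stack, occ = stack_and_occ
        res1 = enfa.enfa_fit(stack, occ, n_background=10_000, seed=0)
        permuted = RasterStack.from_mapping(
            {n: stack[n] for n in reversed(stack.names)})
        res2 = enfa.enfa_fit(permuted, occ, n_background=10_000, seed=0)
        assert list(res1.loadings_table().index) == list(res2.loadings_table().index)

    def test_single_predictor_rejected(self, stack_and_occ):
        stack, occ = stack_and_occ
        single = RasterStack.from_mapping({"a": stack["a"]})
        with pytest.raises(ValueError, match="2 predictors"):
            enfa.enfa_fit(single, occ)

    def test_degenerate_loadings_table_single_row(self):
        res = enfa.EnfaResult(predictors=["only"],
                              marginality_vector=np.array([0.7]),
                              marginality=0.7, eigenvalues=np.array([1.2]),
                              specialization=float(np.sqrt(1.2)),
                              loadings=np.array([[1.0]]),
                              variance_share=np.array([100.0]))
        table = res.loadings_table()
        assert table.shape == (1, 1)
        assert list(table.columns) == ["Marg"]

    def test_variance_shares_sum_to_100(self, stack_and_occ):
        stack, occ = stack_and_occ
        res = enfa.enfa_fit(stack, occ, n_background=10_000, seed=0)
        assert res.variance_share.sum() == pytest.approx(100.0)
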