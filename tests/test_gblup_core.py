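"""Mixed-model core: Henderson blocks, PEV/CD of contrasts, REML, GEBVs."""

import numpy as np
import pytest

from conftest import marker_fixture, random_kinship
from trsopt.geno_io import MarkerMatrix
from trsopt.gblup_core import (
    VarianceComponents,
    cd_of_contrasts,
    heritability,
    lambda_from_h2,
    pev_of_contrasts,
    predict_gebv,
    reml_estimate,
    solve_mme,
)
from trsopt.kinship import KinshipMatrix, center_markers, compute_G, recode_and_filter
from trsopt.selectors import Partition, build_contrasts


def henderson_c22(G, trs_idx, lam, n_obs):
    """Independent oracle: C22 from direct inversion of the full Henderson matrix."""
    N = G.shape[0]
    X = np.ones((n_obs, 1))
    Z = np.zeros((n_obs, N))
    for row, j in enumerate(trs_idx):
        Z[row, j] = 1.0
    K = np.block([
        [X.T @ X, X.T @ Z],
        [Z.T @ X, Z.T @ Z + lam * np.linalg.inv(G)],
    ])
    return np.linalg.inv(K)[1:, 1:]


def mean_contrasts(N, rs_idx):
    C = np.full((N, len(rs_idx)), -1.0 / N)
    for j, i in enumerate(rs_idx):
        C[i, j] += 1.0
    return C


class TestSolveMME:
    def test_single_observation_projector_is_zero(self):
        G = KinshipMatrix(np.eye(3), ("a", "b", "c"))
        sol = solve_mme(G, ("a",), lam=1.0)
        np.testing.assert_allclose(sol.M, [[0.0]])

    def test_projector_properties(self, rng):
        G = random_kinship(10, 30, rng)
        sol = solve_mme(G, G.individual_ids[:6], lam=0.5)
        M = sol.M
        np.testing.assert_allclose(M @ np.ones((6, 1)), 0.0, atol=1e-10)
        np.testing.assert_allclose(M @ M, M, atol=1e-10)
        np.testing.assert_allclose(M, M.T, atol=1e-10)

    def test_theta_symmetric_positive_definite(self, rng):
        G = random_kinship(12, 40, rng)
        sol = solve_mme(G, G.individual_ids[:5], lam=2.0)
        np.testing.assert_allclose(sol.theta, sol.theta.T, atol=1e-10)
        assert np.linalg.eigvalsh(sol.theta).min() > 0

    def test_c22_equals_full_henderson_inverse(self, rng):
        for _ in range(5):
            n = int(rng.integers(6, 14))
            G = random_kinship(n, 3 * n, rng)
            k = int(rng.integers(2, n - 1))
            tidx = np.sort(rng.choice(n, size=k, replace=False))
            lam = float(rng.uniform(0.2, 3.0))
            sol = solve_mme(G, [G.individual_ids[i] for i in tidx], lam=lam)
            C22 = henderson_c22(G.matrix, tidx, lam, k)
            np.testing.assert_allclose(sol.C22, C22, atol=1e-8)

    def test_zero_residual_fit_recovers_mean(self, rng):
        G = random_kinship(8, 30, rng)
        y = np.full(5, 3.7)  # y = X beta exactly
        sol = solve_mme(G, G.individual_ids[:5], y=y, lam=1.0)
        assert sol.beta_hat[0] == pytest.approx(np.mean(y))
        # u shrinks toward zero but need not vanish (G couples genotypes)
        assert np.abs(sol.u_hat).max() < np.abs(y).max()

    def test_empty_trs_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            solve_mme(random_kinship(5, 20, rng), ())


class TestContrastScores:
    def test_pev_hand_case_two_genotypes(self):
        # TRS = {a}, CS = {a, b}, G = I, lambda = 1: M = 0 so theta = I
        G = KinshipMatrix(np.eye(2), ("a", "b"))
        sol = solve_mme(G, ("a",), lam=1.0)
        c = np.array([-0.5, 0.5])
        scores = pev_of_contrasts(sol, c, sigma_e2=1.7)
        assert scores.pev[0] == pytest.approx(1.7)

    def test_pev_invariant_to_contrast_scale(self, rng):
        G = random_kinship(9, 30, rng)
        sol = solve_mme(G, G.individual_ids[:4], lam=1.0)
        c = mean_contrasts(9, [6])[:, 0]
        p1 = pev_of_contrasts(sol, c).pev[0]
        p5 = pev_of_contrasts(sol, 5.0 * c).pev[0]
        assert p5 == pytest.approx(p1, rel=1e-12)

    def test_adding_genotype_never_increases_pev(self, rng):
        for _ in range(5):
            G = random_kinship(10, 40, rng)
            C = mean_contrasts(10, [8, 9])
            small = solve_mme(G, G.individual_ids[:4], lam=1.0)
            grown = solve_mme(G, G.individual_ids[:5], lam=1.0)
            pev_small = pev_of_contrasts(small, C).pev
            pev_grown = pev_of_contrasts(grown, C).pev
            assert (pev_grown <= pev_small + 1e-10).all()

    def test_contrast_not_summing_to_zero_rejected(self, rng):
        G = random_kinship(5, 20, rng)
        sol = solve_mme(G, G.individual_ids[:2], lam=1.0)
        with pytest.raises(ValueError, match="sum to 0"):
            pev_of_contrasts(sol, np.array([1.0, 0, 0, 0, 0]))

    def test_cd_zero_with_single_training_genotype(self, rng):
        # one record is fully absorbed by the mean: no contrast is estimable
        G = random_kinship(6, 25, rng)
        sol = solve_mme(G, G.individual_ids[:1], lam=0.8)
        C = mean_contrasts(6, [1, 2, 3, 4, 5])
        cds = cd_of_contrasts(sol, G, C)
        np.testing.assert_allclose(cds.cd, 0.0, atol=1e-10)

    def test_cd_in_unit_interval(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 16))
            G = random_kinship(n, 3 * n, rng)
            k = int(rng.integers(1, n))
            sol = solve_mme(G, [G.individual_ids[i] for i in np.sort(rng.choice(n, k, replace=False))],
                            lam=float(rng.uniform(0.1, 5)))
            C = mean_contrasts(n, list(range(n)))
            cds = cd_of_contrasts(sol, G, C)
            assert (cds.cd >= -1e-8).all() and (cds.cd <= 1 + 1e-8).all()

    def test_two_cd_forms_identical(self, rng):
        G = random_kinship(12, 40, rng)
        sol = solve_mme(G, G.individual_ids[:7], lam=1.3)
        C = mean_contrasts(12, list(range(7, 12)))
        cd_diff = cd_of_contrasts(sol, G, C, form="difference").cd
        cd_one = cd_of_contrasts(sol, G, C, form="one_minus").cd
        np.testing.assert_allclose(cd_diff, cd_one, atol=1e-10)

    def test_cd_tends_to_one_as_lambda_vanishes(self, rng):
        # every genotype phenotyped, negligible noise: contrasts fully reliable
        G = random_kinship(8, 30, rng)
        sol = solve_mme(G, G.individual_ids, lam=1e-8)
        C = mean_contrasts(8, list(range(8)))
        cds = cd_of_contrasts(sol, G, C)
        np.testing.assert_allclose(cds.cd, 1.0, atol=1e-5)

    def test_oracle_pev_and_cd_via_full_henderson_inverse(self, rng):
        # theta route vs direct inversion of the full coefficient matrix
        worst = 0.0
        for _ in range(10):
            n = int(rng.integers(6, 20))
            G = random_kinship(n, 3 * n, rng)
            k = int(rng.integers(2, n))
            tidx = np.sort(rng.choice(n, size=k, replace=False))
            lam = float(rng.uniform(0.2, 3.0))
            sol = solve_mme(G, [G.individual_ids[i] for i in tidx], lam=lam)
            C22 = henderson_c22(G.matrix, tidx, lam, k)
            C = mean_contrasts(n, [i for i in range(n) if i not in tidx])
            pev_theta = pev_of_contrasts(sol, C).pev
            pev_oracle = np.einsum("ij,ij->j", C, C22 @ C) / np.einsum("ij,ij->j", C, C)
            cd_theta = cd_of_contrasts(sol, G, C).cd
            cGc = np.einsum("ij,ij->j", C, G.matrix @ C)
            cd_oracle = 1.0 - lam * np.einsum("ij,ij->j", C, C22 @ C) / cGc
            worst = max(worst, np.abs(pev_theta - pev_oracle).max(),
                        np.abs(cd_theta - cd_oracle).max())
        assert worst < 1e-8


class TestPredictGEBV:
    def test_training_member_prediction_is_its_own_u(self, rng):
        G = random_kinship(8, 30, rng)
        y = rng.normal(size=4)
        sol = solve_mme(G, G.individual_ids[:4], y=y, lam=1.0)
        np.testing.assert_allclose(predict_gebv(sol, G.individual_ids[:4]), sol.u_hat[:4])

    def test_unknown_target_rejected(self, rng):
        G = random_kinship(5, 20, rng)
        sol = solve_mme(G, G.individual_ids[:3], y=np.zeros(3), lam=1.0)
        with pytest.raises(KeyError, match="zz"):
            predict_gebv(sol, ["zz"])

    def test_noise_free_duplicated_genotypes_predicted_exactly(self, rng):
        mm = marker_fixture(15, 60, rng, inbred=True)
        dup_calls = np.vstack([mm.calls, mm.calls])
        ids = mm.individual_ids + tuple(f"copy{i}" for i in range(15))
        panel = MarkerMatrix(ids, mm.marker_ids, dup_calls)
        G = compute_G(center_markers(recode_and_filter(panel)))
        assert G.epsilon > 0  # duplicated lines force the ridge
        y = rng.normal(size=15)
        sol = solve_mme(G, ids[:15], y=y, lam=1e-6)
        pred = predict_gebv(sol, ids[15:])
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_gblup_equals_ridge_regression_on_markers(self, rng):
        # with G = WW'/f and penalty lambda*f on marker effects the two
        # formulations give identical predictions (all genotypes phenotyped)
        n = 10
        mm = recode_and_filter(marker_fixture(n, 40, rng))
        m = mm.n_markers
        cm = center_markers(mm, p=np.full(m, 0.35))  # external p: G nonsingular
        G = compute_G(cm, epsilon=0.0)
        lam = 0.7
        y = rng.normal(size=n)
        sol = solve_mme(G, G.individual_ids, y=y, lam=lam)
        M = np.eye(n) - np.ones((n, n)) / n
        m_hat = np.linalg.solve(cm.W.T @ M @ cm.W + lam * cm.f * np.eye(m), cm.W.T @ M @ y)
        np.testing.assert_allclose(sol.u_hat, cm.W @ m_hat, atol=1e-6)


class TestREML:
    def test_constant_phenotype_flags_boundary(self, rng):
        G = random_kinship(30, 100, rng)
        vc = reml_estimate(np.full(30, 2.0), G)
        assert vc.boundary
        assert vc.sigma_g2 == pytest.approx(0.0, abs=1e-6)

    def test_lambda_recovery(self):
        # g ~ N(0, G), e ~ N(0, I): sigma_e2 / sigma_g2 = 1 by construction
        rng = np.random.default_rng(7)
        mm = marker_fixture(300, 600, rng, inbred=True)
        G = compute_G(center_markers(recode_and_filter(mm)))
        g = np.linalg.cholesky(G.matrix) @ rng.normal(size=300)
        y = g + rng.normal(size=300)
        vc = reml_estimate(y, G)
        assert 0.5 <= vc.sigma_e2 / vc.sigma_g2 <= 2.0

    def test_h2_recovery_on_simulated_panels(self):
        # light version of the parameter-recovery study (deep one in acceptance)
        ests = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mm = marker_fixture(150, 400, rng, inbred=True)
            G = compute_G(center_markers(recode_and_filter(mm)))
            g = np.linalg.cholesky(G.matrix) @ rng.normal(size=150)
            y = g + rng.normal(size=150)  # sigma_g2 = sigma_e2 = 1 -> h2 = 0.5
            ests.append(reml_estimate(y, G).h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.12)

    def test_too_few_observations_rejected(self, rng):
        G = random_kinship(5, 20, rng)
        with pytest.raises(ValueError, match="at least 10"):
            reml_estimate(np.zeros(5), G)


class TestHeritability:
    @pytest.mark.parametrize(
        "vc,expected",
        [
            (dict(sigma_g2=1, sigma_ge2=0, sigma_e2=1, e=1, r=1), 0.5),
            (dict(sigma_g2=1, sigma_ge2=2, sigma_e2=2, e=2, r=2), 0.4),
            (dict(sigma_g2=1, sigma_ge2=5, sigma_e2=5, e=10**6, r=10**6), 1.0),
        ],
    )
    def test_formula(self, vc, expected):
        comp = VarianceComponents(**vc)
        assert heritability(comp) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_components_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            VarianceComponents(sigma_g2=0.0, sigma_e2=0.0)

    def test_lambda_from_h2(self):
        assert lambda_from_h2(0.5) == pytest.approx(1.0)
        assert lambda_from_h2(0.8) == pytest.approx(0.25)
        assert lambda_from_h2(1.0) == pytest.approx(1e-6)  # floored, not zero
        with pytest.raises(ValueError):
            lambda_from_h2(0.0)


def test_mean_contrast_helper_matches_selector_contrasts(rng):
    part = Partition(cs_ids=("a", "b", "c", "d"), trs_ids=("a", "b", "d"))
    C = build_contrasts(part)
    np.testing.assert_allclose(C[:, 0], [-0.25, -0.25, 0.75, -0.25])
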