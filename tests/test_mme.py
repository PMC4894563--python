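"""Model assembly, Henderson solver and restricted likelihood."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmgp.kinship import RelationshipMatrix, additive_A
from mmgp.mme import (
    ModelSpec,
    RandomTerm,
    assemble,
    information_criteria,
    reml_loglik,
    solve_mme,
)

from conftest import gls_solution, random_spec


def one_way_spec(a=6, r=3, s2u=2.0, s2e=1.0, seed=1):
    """Balanced one-way random-effects layout with identity structure."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(s2u), a)
    y = 5.0 + np.repeat(u, r) + rng.normal(0, np.sqrt(s2e), a * r)
    X = np.ones((a * r, 1))
    Z = np.kron(np.eye(a), np.ones((r, 1)))
    K = RelationshipMatrix.identity([f"g{i}" for i in range(a)])
    return ModelSpec(y=y, X=X, terms=[RandomTerm("g", Z, K)])


class TestAssemble:
    def test_indicator_matches_hand_built(self):
        df = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0, 4.0],
                "env": ["E1", "E2", "E1", "E2"],
                "geno": ["b", "a", "a", "c"],
            }
        )
        K = RelationshipMatrix.identity(["a", "b", "c"])
        spec = assemble(df, response="y", fixed=("env",), random=(("g", "geno", K),))
        # intercept + treatment dummy for env
        np.testing.assert_allclose(spec.X[:, 0], 1.0)
        np.testing.assert_allclose(spec.X[:, 1], [0, 1, 0, 1])
        Z_hand = np.array(
            [[0, 1, 0], [1, 0, 0], [1, 0, 0], [0, 0, 1]], dtype=float
        )
        np.testing.assert_allclose(spec.terms[0].Z, Z_hand)
        assert (spec.terms[0].Z.sum(axis=1) == 1).all()

    def test_unobserved_levels_keep_columns(self):
        labels = [f"h{i}" for i in range(20)]
        K = RelationshipMatrix.identity(labels)
        df = pd.DataFrame({"y": np.arange(5.0), "hyb": labels[:5]})
        spec = assemble(df, response="y", random=(("h", "hyb", K),))
        assert spec.terms[0].Z.shape == (5, 20)

    def test_missing_rows_masked_but_levels_kept(self):
        labels = [f"h{i}" for i in range(8)]
        K = RelationshipMatrix.identity(labels)
        y = [1.0, np.nan, 2.0, np.nan, 3.0, 1.0, 2.0, 1.0]
        df = pd.DataFrame({"y": y, "hyb": labels})
        spec = assemble(df, response="y", random=(("h", "hyb", K),))
        assert spec.n_observed == 6
        assert spec.terms[0].Z.shape == (8, 8)

    def test_level_absent_from_structure_errors(self):
        K = RelationshipMatrix.identity(["a", "b"])
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "zzz"]})
        with pytest.raises(ValueError, match="zzz"):
            assemble(df, response="y", random=(("g", "g", K),))

    def test_all_missing_errors(self):
        K = RelationshipMatrix.identity(["a"])
        df = pd.DataFrame({"y": [np.nan, np.nan], "g": ["a", "a"]})
        with pytest.raises(ValueError, match="missing"):
            assemble(df, response="y", random=(("g", "g", K),))


class TestSolveMME:
    def test_vanishing_random_variance_recovers_ols(self):
        spec = random_spec(3, n=25)
        sol = solve_mme(spec, {"t0": 1e-12, "residual": 1.0})
        beta_ols = np.linalg.lstsq(spec.X, spec.y, rcond=None)[0]
        np.testing.assert_allclose(sol.beta, beta_ols, atol=1e-8)
        assert np.max(np.abs(sol.u["t0"])) < 1e-8

    def test_balanced_one_way_shrinkage(self):
        a, r, s2u, s2e = 6, 4, 2.0, 1.0
        spec = one_way_spec(a, r, seed=2)
        vc = {"g": s2u, "residual": s2e}
        sol = solve_mme(spec, vc)
        shrink = r * s2u / (r * s2u + s2e)
        ybar_i = spec.y.reshape(a, r).mean(axis=1)
        # GLS intercept is the grand mean in the balanced case
        expect_u = shrink * (ybar_i - spec.y.mean())
        np.testing.assert_allclose(sol.u["g"], expect_u, rtol=1e-8)
        beta_gls, u_gls = gls_solution(spec, vc)
        np.testing.assert_allclose(sol.beta, beta_gls, rtol=1e-9)
        np.testing.assert_allclose(sol.u["g"], u_gls["g"], rtol=1e-9)

    @pytest.mark.parametrize("seed,n_terms,missing",
                             [(1, 1, 0.0), (2, 2, 0.0), (3, 3, 0.2),
                              (4, 2, 0.3), (5, 1, 0.1)])
    def test_matches_dense_gls_oracle(self, seed, n_terms, missing):
        spec = random_spec(seed, n=40, n_terms=n_terms, n_levels=15,
                           missing_frac=missing)
        rng = np.random.default_rng(seed + 100)
        vc = {t.name: rng.uniform(0.3, 2.0) for t in spec.terms}
        vc["residual"] = rng.uniform(0.5, 1.5)
        sol = solve_mme(spec, vc)
        beta, u = gls_solution(spec, vc)
        np.testing.assert_allclose(sol.beta, beta, rtol=1e-6)
        for t in spec.terms:
            np.testing.assert_allclose(sol.u[t.name], u[t.name],
                                       rtol=1e-6, atol=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_gls_equivalence_property(self, seed):
        spec = random_spec(seed, n=min(50, 20 + seed % 31), n_terms=1 + seed % 2,
                           n_levels=12)
        vc = {t.name: 1.0 for t in spec.terms}
        vc["residual"] = 0.7
        sol = solve_mme(spec, vc)
        beta, u = gls_solution(spec, vc)
        np.testing.assert_allclose(sol.beta, beta, rtol=1e-6, atol=1e-8)
        for t in spec.terms:
            np.testing.assert_allclose(sol.u[t.name], u[t.name],
                                       rtol=1e-6, atol=1e-8)

    def test_fitted_plus_residuals_identity(self):
        spec = random_spec(7, n=30, missing_frac=0.2)
        sol = solve_mme(spec, {"t0": 1.0, "residual": 1.0})
        obs = spec.mask
        np.testing.assert_allclose(sol.fitted[obs] + sol.residuals[obs],
                                   spec.y[obs], rtol=1e-8)
        assert np.isnan(sol.residuals[~obs]).all()

    def test_response_scaling_equivariance(self):
        spec = random_spec(11, n=30)
        vc = {"t0": 1.3, "residual": 0.8}
        sol = solve_mme(spec, vc)
        c = 3.7
        spec2 = spec.with_response(spec.y * c)
        vc2 = {k: v * c**2 for k, v in vc.items()}
        sol2 = solve_mme(spec2, vc2)
        np.testing.assert_allclose(sol2.beta, c * sol.beta, rtol=1e-8)
        np.testing.assert_allclose(sol2.u["t0"], c * sol.u["t0"], rtol=1e-8)
        np.testing.assert_allclose(
            sol2.residuals[spec.mask] / np.sqrt(vc2["residual"]),
            sol.residuals[spec.mask] / np.sqrt(vc["residual"]), rtol=1e-8)

    def test_independent_unobserved_level_is_droppable(self):
        # block-diagonal K: the isolated unobserved level has BLUP 0 and
        # removing it leaves every observed-level BLUP unchanged
        rng = np.random.default_rng(8)
        q = 6
        mkvals = rng.integers(-1, 2, size=(q, 40)).astype(float)
        K5 = additive_A(
            __import__("mmgp").MarkerMatrix(
                [f"g{i}" for i in range(q - 1)], [f"m{j}" for j in range(40)],
                mkvals[: q - 1])
        )
        Kb = np.zeros((q, q))
        Kb[: q - 1, : q - 1] = K5.values
        Kb[q - 1, q - 1] = 1.0
        K = RelationshipMatrix([f"g{i}" for i in range(q)], Kb)
        n = 15
        lv = rng.integers(0, q - 1, n)
        Z = np.zeros((n, q))
        Z[np.arange(n), lv] = 1.0
        y = rng.normal(size=n) + Z[:, : q - 1] @ rng.normal(size=q - 1)
        spec = ModelSpec(y=y, X=np.ones((n, 1)), terms=[RandomTerm("g", Z, K)])
        vc = {"g": 1.0, "residual": 1.0}
        sol = solve_mme(spec, vc)
        assert abs(sol.u["g"][-1]) < 1e-10
        K_red = RelationshipMatrix([f"g{i}" for i in range(q - 1)],
                                   Kb[: q - 1, : q - 1])
        spec_red = ModelSpec(y=y, X=np.ones((n, 1)),
                             terms=[RandomTerm("g", Z[:, : q - 1], K_red)])
        sol_red = solve_mme(spec_red, vc)
        np.testing.assert_allclose(sol.u["g"][: q - 1], sol_red.u["g"], rtol=1e-6)

    def test_duplicated_individuals_rank_deficient_K_solves(self):
        # duplicated marker rows make K rank deficient; jitter policy copes
        from mmgp import MarkerMatrix

        rng = np.random.default_rng(9)
        base = rng.integers(-1, 2, size=(4, 30)).astype(float)
        vals = np.vstack([base, base[0], base[0]])
        mm = MarkerMatrix([f"g{i}" for i in range(6)],
                          [f"m{j}" for j in range(30)], vals)
        K = additive_A(mm)
        n = 12
        lv = rng.integers(0, 6, n)
        Z = np.zeros((n, 6))
        Z[np.arange(n), lv] = 1.0
        y = rng.normal(size=n)
        spec = ModelSpec(y=y, X=np.ones((n, 1)), terms=[RandomTerm("g", Z, K)])
        sol = solve_mme(spec, {"g": 1.0, "residual": 1.0})
        assert np.isfinite(sol.u["g"]).all()

    def test_rank_deficient_X_drops_aliased_columns(self):
        spec0 = random_spec(13, n=25)
        X = np.column_stack([spec0.X, spec0.X[:, 1]])  # duplicated column
        spec = ModelSpec(y=spec0.y, X=X, terms=spec0.terms)
        with pytest.warns(UserWarning, match="rank deficient"):
            sol = solve_mme(spec, {"t0": 1.0, "residual": 1.0})
        assert len(sol.beta) == 2


class TestRemlLoglik:
    def test_direct_inversion_oracle_tiny(self):
        y = np.array([1.0, 2.0, 4.0])
        X = np.ones((3, 1))
        K = RelationshipMatrix.identity(["a", "b", "c"])
        spec = ModelSpec(y=y, X=X, terms=[RandomTerm("g", np.eye(3), K)])
        s2u, s2e = 1.5, 0.7
        V = s2u * np.eye(3) + s2e * np.eye(3)
        Vi = np.linalg.inv(V)
        P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
        expect = -0.5 * (
            np.log(np.linalg.det(V))
            + np.log(np.linalg.det(X.T @ Vi @ X))
            - np.log(np.linalg.det(X.T @ X))
            + y @ P @ y
            + 2 * math.log(2 * math.pi)
        )
        got = reml_loglik(spec, {"g": s2u, "residual": s2e})
        assert got == pytest.approx(expect, rel=1e-10)

    def test_fixed_basis_invariance(self):
        spec = random_spec(21, n=30)
        vc = {"t0": 1.0, "residual": 1.0}
        ll = reml_loglik(spec, vc)
        B = np.array([[2.0, 1.0], [0.5, 3.0]])
        spec2 = ModelSpec(y=spec.y, X=spec.X @ B, terms=spec.terms)
        assert reml_loglik(spec2, vc) == pytest.approx(ll, rel=1e-10)

    def test_anova_closed_form_balanced_layout(self):
        # REML of a balanced one-way layout equals the ANOVA log-likelihood
        # evaluated through an independent scalar formula
        a, r = 5, 3
        spec = one_way_spec(a, r, seed=4)
        y = spec.y
        s2u, s2e = 1.1, 0.9
        # eigenvalues of V = s2e I + s2u ZZ' on the error-contrast space
        lam_between = s2e + r * s2u  # multiplicity a-1 (after removing mean)
        lam_within = s2e  # multiplicity a(r-1)
        ybar_i = y.reshape(a, r).mean(1)
        ss_b = r * np.sum((ybar_i - y.mean()) ** 2)
        ss_w = np.sum((y.reshape(a, r) - ybar_i[:, None]) ** 2)
        n = a * r
        # log|V| = a·log λ_b + a(r−1)·log λ_w; for X = 1,
        # log|X'V⁻¹X| − log|X'X| = log(n/λ_b) − log n = −log λ_b,
        # and y'Py = SS_between/λ_b + SS_within/λ_w
        expect = -0.5 * (
            (a - 1) * np.log(lam_between)
            + a * (r - 1) * np.log(lam_within)
            + ss_b / lam_between
            + ss_w / lam_within
            + (n - 1) * math.log(2 * math.pi)
        )
        got = reml_loglik(spec, {"g": s2u, "residual": s2e})
        assert got == pytest.approx(expect, rel=1e-10)


class TestInformationCriteria:
    def test_arithmetic(self):
        aic, bic = information_criteria(0.0, 1, int(round(math.e**2)))
        assert aic == pytest.approx(2.0)
        assert bic == pytest.approx(math.log(round(math.e**2)))
        aic, bic = information_criteria(-10.0, 2, 100)
        assert aic == pytest.approx(24.0)
        assert bic == pytest.approx(20.0 + 2 * math.log(100))

    def test_requires_more_obs_than_params(self):
        with pytest.raises(ValueError):
            information_criteria(0.0, 5, 5)

    def test_consistent_with_fit_loglik(self):
        from mmgp import fit

        spec = random_spec(31, n=40)
        res = fit(spec, method="AI")
        aic, bic = information_criteria(res.loglik, len(res.vc), spec.n_observed)
        assert res.aic == pytest.approx(aic)
        assert res.bic == pytest.approx(bic)
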