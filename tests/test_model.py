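import numpy as np
import pandas as pd
import pytest

from helpers import gls_blup_mt, gls_blup_st, random_pedigree, tabular_a
from mtgblup.kinship import RelationshipMatrix, build_a_inverse
from mtgblup.model import AnimalModel, ModelError, SingularSystemError, VarianceComponents


def _dense_k(n, rng, scale=0.3):
    L = rng.normal(size=(n, n)) * scale + np.eye(n)
    return RelationshipMatrix(kind="genomic_G", ids=np.arange(n), matrix=L @ L.T)


def _st_data(rec, y):
    return pd.DataFrame({"animal_id": rec, "t1": y})


class TestVarianceComponents:
    def test_validation(self):
        with pytest.raises(ModelError):
            VarianceComponents(H=np.array([[1.0, 0.5], [0.4, 1.0]]), R=np.eye(2))
        vc = VarianceComponents(H=np.diag([1.0, 2.0]), R=np.diag([3.0, 8.0]))
        assert np.allclose(vc.heritabilities, [0.25, 0.2])
        assert vc.genetic_correlation == 0.0

    def test_scalar_case(self):
        vc = VarianceComponents(H=1.0, R=7 / 3)
        assert np.isclose(vc.heritabilities[0], 0.3)


class TestSingleTraitSolve:
    def test_matches_closed_form_blup(self, rng):
        K = _dense_k(9, rng)
        rec = np.array([0, 2, 3, 5, 6, 8])
        y = rng.normal(size=rec.size)
        res = AnimalModel(_st_data(rec, y), K, ["t1"]).fit(components=(0.8, 1.9))
        mu, ghat = gls_blup_st(np.asarray(K.matrix), rec, y, 0.8, 1.9)
        assert abs(res.intercepts[0] - mu) < 1e-8
        assert np.allclose(res._solutions[:, 0], ghat, atol=1e-8)

    def test_infinite_shrinkage_limit(self, rng):
        K = _dense_k(6, rng)
        y = rng.normal(size=6)
        res = AnimalModel(_st_data(np.arange(6), y), K, ["t1"]).fit(
            components=(1e-10, 1.0)
        )
        assert np.allclose(res._solutions, 0.0, atol=1e-5)
        assert abs(res.intercepts[0] - y.mean()) < 1e-5

    def test_duplicate_records_identity_k_leaves_others_at_zero(self):
        K = RelationshipMatrix(kind="genomic_G", ids=np.arange(4), matrix=np.eye(4))
        data = _st_data([1, 1, 1], [2.0, 2.5, 1.5])
        res = AnimalModel(data, K, ["t1"]).fit(components=(1.0, 1.0))
        assert np.allclose(res._solutions[[0, 2, 3], 0], 0.0, atol=1e-10)
        assert res._solutions[1, 0] != 0.0

    def test_nonpositive_genetic_variance_rejected(self, rng):
        K = _dense_k(4, rng)
        m = AnimalModel(_st_data(np.arange(4), rng.normal(size=4)), K, ["t1"])
        with pytest.raises(ModelError):
            m.fit(components=(-1.0, 1.0))


class TestMultiTraitSolve:
    def test_diagonal_components_decouple_to_single_trait(self, rng):
        K = _dense_k(8, rng)
        Y = rng.normal(size=(8, 2))
        data = pd.DataFrame({"animal_id": np.arange(8), "t1": Y[:, 0], "t2": Y[:, 1]})
        res = AnimalModel(data, K, ["t1", "t2"]).fit(
            components=(np.diag([0.7, 1.1]), np.diag([1.3, 2.2]))
        )
        st1 = AnimalModel(data[["animal_id", "t1"]], K, ["t1"]).fit(components=(0.7, 1.3))
        st2 = AnimalModel(data[["animal_id", "t2"]], K, ["t2"]).fit(components=(1.1, 2.2))
        assert np.allclose(res._solutions[:, 0], st1._solutions[:, 0], atol=1e-9)
        assert np.allclose(res._solutions[:, 1], st2._solutions[:, 0], atol=1e-9)

    def test_missing_records_match_gls_oracle(self, rng):
        K = _dense_k(7, rng)
        H = np.array([[1.0, 0.45], [0.45, 0.7]])
        R = np.array([[1.2, 0.3], [0.3, 2.4]])
        Y = np.full((5, 2), np.nan)
        Y[:, 0] = rng.normal(size=5)
        Y[[0, 2], 1] = rng.normal(size=2)
        units = np.array([0, 1, 3, 4, 6])
        data = pd.DataFrame({"animal_id": units, "t1": Y[:, 0], "t2": Y[:, 1]})
        res = AnimalModel(data, K, ["t1", "t2"]).fit(components=(H, R))
        beta, ghat = gls_blup_mt(np.asarray(K.matrix), units, Y, H, R)
        assert np.allclose(res.intercepts, beta, atol=1e-8)
        assert np.allclose(res._solutions, ghat, atol=1e-8)

    def test_near_perfect_correlation_transfers_predictions(self, rng):
        # with r_g ~ 1 and equal variances, trait-2 predictions follow
        # trait-1 even when every trait-2 record is missing
        K = _dense_k(10, rng)
        rg = 0.999
        H = np.array([[1.0, rg], [rg, 1.0]])
        R = np.diag([1.5, 1.5])
        data = pd.DataFrame(
            {"animal_id": np.arange(10), "t1": rng.normal(size=10), "t2": np.nan}
        )
        data.loc[0, "t2"] = data.loc[0, "t1"]  # one anchor record
        res = AnimalModel(data, K, ["t1", "t2"]).fit(components=(H, R))
        ratio = res._solutions[1:, 1] / res._solutions[1:, 0]
        assert np.allclose(ratio, 1.0, atol=0.05)

    def test_exactly_singular_h_raises(self, rng):
        K = _dense_k(5, rng)
        H = np.ones((2, 2))
        data = pd.DataFrame(
            {"animal_id": np.arange(5), "t1": rng.normal(size=5),
             "t2": rng.normal(size=5)}
        )
        with pytest.raises(SingularSystemError):
            AnimalModel(data, K, ["t1", "t2"]).fit(components=(H, np.eye(2)))


class TestPedigreeGenomicEquivalence:
    def test_same_solutions_when_g_equals_a(self, rng):
        sire, dam = random_pedigree(40, rng)
        ped = pd.DataFrame({"animal": np.arange(40), "sire": sire, "dam": dam})
        ainv = build_a_inverse(ped)
        A = tabular_a(sire, dam)
        Kg = RelationshipMatrix(kind="genomic_G", ids=np.arange(40), matrix=A)
        rec = np.arange(10, 35)
        y = rng.normal(size=rec.size)
        rp = AnimalModel(_st_data(rec, y), ainv, ["t1"]).fit(components=(0.9, 2.0))
        rg = AnimalModel(_st_data(rec, y), Kg, ["t1"]).fit(components=(0.9, 2.0))
        assert np.allclose(rp._solutions, rg._solutions, atol=1e-8)
        assert abs(rp.llf - rg.llf) < 1e-6

    def test_validation_predictions_follow_conditional_expectation(self, rng):
        K = _dense_k(12, rng)
        rec = np.arange(8)
        unrec = np.arange(8, 12)
        y = rng.normal(size=8)
        res = AnimalModel(_st_data(rec, y), K, ["t1"]).fit(components=(1.0, 1.5))
        Kf = np.asarray(K.matrix)
        expected = Kf[np.ix_(unrec, rec)] @ np.linalg.solve(
            Kf[np.ix_(rec, rec)], res._solutions[rec, 0]
        )
        assert np.allclose(res._solutions[unrec, 0], expected, atol=1e-8)


class TestREML:
    def test_parameter_recovery_over_replicates(self, rng):
        sg2, se2 = 1.0, 7 / 3  # heritability 0.3
        ests = []
        for _ in range(5):
            n = 300
            K = _dense_k(n, rng, scale=0.2)
            Lc = np.linalg.cholesky(np.asarray(K.matrix))
            g = Lc @ rng.normal(size=n) * np.sqrt(sg2)
            y = 1.0 + g + rng.normal(size=n) * np.sqrt(se2)
            vc = AnimalModel(_st_data(np.arange(n), y), K, ["t1"]).estimate_reml("ai")
            ests.append([vc.H[0, 0], vc.R[0, 0]])
        mean = np.mean(ests, axis=0)
        assert abs(mean[0] - sg2) < 0.25
        assert abs(mean[1] - se2) < 0.45

    def test_ai_agrees_with_direct_search_and_em(self, rng):
        n = 120
        K = _dense_k(n, rng, scale=0.25)
        Lc = np.linalg.cholesky(np.asarray(K.matrix))
        y = Lc @ rng.normal(size=n) + rng.normal(size=n) * 1.4
        m = AnimalModel(_st_data(np.arange(n), y), K, ["t1"])
        ai = m.estimate_reml("ai")
        ds = m.estimate_reml("direct_search")
        em = m.estimate_reml("em", maxiter=500)
        qn = m.estimate_reml("quasi_newton")
        for other in (ds, em, qn):
            assert np.allclose(ai.H, other.H, rtol=1e-3, atol=1e-4)
            assert np.allclose(ai.R, other.R, rtol=1e-3, atol=1e-4)

    def test_loglik_never_decreases_from_start(self, rng):
        n = 80
        K = _dense_k(n, rng)
        y = rng.normal(size=n)
        m = AnimalModel(_st_data(np.arange(n), y), K, ["t1"])
        start = (np.atleast_2d(0.4), np.atleast_2d(0.6))
        vc = m.estimate_reml("ai", start=start)
        assert vc.log_likelihood >= m.loglike(start) - 1e-8

    def test_zero_variance_response_rejected(self, rng):
        K = _dense_k(5, rng)
        m = AnimalModel(_st_data(np.arange(5), np.full(5, 3.0)), K, ["t1"])
        with pytest.raises(ModelError):
            m.estimate_reml("ai")

    def test_multi_trait_recovery(self, rng):
        n = 250
        K = _dense_k(n, rng, scale=0.2)
        H = np.array([[1.0, 0.5], [0.5, 1.0]])
        R = np.diag([7 / 3, 4.0])
        Lg = np.linalg.cholesky(np.kron(np.asarray(K.matrix), H))
        g = (Lg @ rng.normal(size=2 * n)).reshape(n, 2)
        Y = g + rng.multivariate_normal(np.zeros(2), R, size=n)
        data = pd.DataFrame({"animal_id": np.arange(n), "t1": Y[:, 0], "t2": Y[:, 1]})
        vc = AnimalModel(data, K, ["t1", "t2"]).estimate_reml("ai")
        assert vc.converged
        assert abs(vc.genetic_correlation - 0.5) < 0.25
        assert np.allclose(np.diag(vc.H), 1.0, atol=0.45)


class TestReliability:
    def test_unlinked_unrecorded_animal_has_zero_reliability(self, rng):
        K = RelationshipMatrix(kind="genomic_G", ids=np.arange(3), matrix=np.eye(3))
        res = AnimalModel(_st_data([0, 1], [1.0, -1.0]), K, ["t1"]).fit(
            components=(1.0, 1.0)
        )
        rel = res.reliability()
        assert rel.loc[2, "t1"] == pytest.approx(0.0, abs=1e-10)

    def test_single_record_reliability_approaches_h2(self, rng):
        # with many animals (intercept well estimated), one record per
        # animal under K = I gives r2 ~ sigma_g2 / (sigma_g2 + sigma_e2)
        n = 400
        K = RelationshipMatrix(kind="genomic_G", ids=np.arange(n), matrix=np.eye(n))
        res = AnimalModel(_st_data(np.arange(n), rng.normal(size=n)), K, ["t1"]).fit(
            components=(1.0, 7 / 3)
        )
        rel = res.reliability().to_numpy()
        assert np.allclose(rel, 0.3, atol=0.01)

    def test_reliability_monotone_in_records(self, rng):
        K = _dense_k(5, rng)
        one = AnimalModel(_st_data([0], [1.2]), K, ["t1"]).fit(components=(1.0, 1.0))
        two = AnimalModel(_st_data([0, 0], [1.2, 0.8]), K, ["t1"]).fit(
            components=(1.0, 1.0)
        )
        r1 = one.reliability(ids=[0]).iloc[0, 0]
        r2 = two.reliability(ids=[0]).iloc[0, 0]
        assert r2 >= r1 - 1e-12

    def test_bounds_and_empirical_redirect(self, rng):
        K = _dense_k(6, rng)
        res = AnimalModel(_st_data(np.arange(6), rng.normal(size=6)), K, ["t1"]).fit(
            components=(1.0, 2.0)
        )
        rel = res.reliability().to_numpy()
        assert np.all((rel >= 0) & (rel <= 1))
        with pytest.raises(ModelError):
            res.reliability(kind="empirical")


def test_iterative_solver_matches_exact_beyond_limit(rng):
    # above the exact-factorization limit, fixed-component solving falls
    # back to preconditioned conjugate gradients
    sire, dam = random_pedigree(300, rng)
    ped = pd.DataFrame({"animal": np.arange(300), "sire": sire, "dam": dam})
    ainv = build_a_inverse(ped)
    rec = np.arange(50, 250)
    y = rng.normal(size=rec.size)
    data = _st_data(rec, y)
    exact = AnimalModel(data, ainv, ["t1"]).fit(components=(1.0, 2.0))
    cg = AnimalModel(data, ainv, ["t1"], mme_exact_limit=100).fit(
        components=(1.0, 2.0)
    )
    assert np.allclose(cg._solutions, exact._solutions, atol=1e-7)
    with pytest.raises(ModelError):
        cg.reliability(ids=[0])
    with pytest.raises(ModelError):
        AnimalModel(data, ainv, ["t1"], mme_exact_limit=100).estimate_reml("quasi_newton")


def test_summary_mentions_model_and_components(rng):
    K = _dense_k(5, rng)
    res = AnimalModel(_st_data(np.arange(5), rng.normal(size=5)), K, ["t1"]).fit(
        components=(1.0, 2.0)
    )
    text = res.summary()
    assert "ST-genomic" in text and "heritabilities" in text
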