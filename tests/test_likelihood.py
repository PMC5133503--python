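import numpy as np
import pytest

from longvc import (SimConfig, VCParameters, build_covariance, fit_ml,
                    loglik, make_dataset, simulate_replicate)
from longvc.likelihood import DesignError, NumericalError
from conftest import dataset_from, dense_mvn_loglik


def random_instance(seed, max_members=10, k=None):
    """Small random pedigree dataset with random PSD parameters."""
    rng = np.random.default_rng(seed)
    k = k if k is not None else int(rng.integers(1, 4))
    size = int(rng.integers(5, max_members + 1))
    cfg = SimConfig(n_pedigrees=1, total_size=size, k=k,
                    causal_variants=(), n_null_variants=2, h2=0.3)
    rep = simulate_replicate(cfg, seed=rng.integers(2 ** 31))
    ds = dataset_from(rep, covariates=("age",))
    A = rng.normal(size=(k, k))
    G = A @ A.T * 0.3 + 0.05 * np.eye(k)
    B = rng.normal(size=(k, k))
    E = B @ B.T * 0.3 + 0.3 * np.eye(k)
    mb = rng.normal(size=(k, ds.C.shape[1]))
    return ds, G, E, mb, rng


class TestBuildCovariance:
    def test_two_unrelated_closed_form(self):
        phi2 = np.eye(2)  # 2*Phi for two unrelated individuals
        omega = build_covariance(np.array([[1.0]]), np.array([[1.0]]), phi2)
        assert np.allclose(omega, 2.0 * np.eye(2))

    def test_parent_offspring_off_diagonal(self):
        phi2 = 2.0 * np.array([[0.5, 0.25], [0.25, 0.5]])
        sg2 = 1.7
        omega = build_covariance(np.array([[sg2]]), np.array([[0.4]]), phi2)
        assert omega[0, 1] == pytest.approx(2 * 0.25 * sg2)

    def test_uncorrelated_visits_block_decouple(self):
        """With rho_g = rho_e = 0 the two visits are independent and the
        joint log-likelihood is the sum of the marginals."""
        rep = simulate_replicate(
            SimConfig(n_pedigrees=1, total_size=8, k=2, causal_variants=(),
                      n_null_variants=1), seed=5)
        ds = dataset_from(rep, covariates=("age",))
        G = np.diag([0.5, 0.8])
        E = np.diag([0.7, 0.6])
        mb = np.array([[0.1, 0.02], [-0.2, 0.01]])
        joint = loglik(ds, VCParameters(G=G, E=E, mean_betas=mb))
        parts = 0.0
        for t in range(2):
            ds_t = ds.with_traits(ds.Y[:, t:t + 1])
            parts += loglik(ds_t, VCParameters(
                G=G[t:t + 1, t:t + 1], E=E[t:t + 1, t:t + 1],
                mean_betas=mb[t:t + 1]))
        assert joint == pytest.approx(parts, abs=1e-8)

    def test_missing_cells_deleted(self):
        phi2 = np.eye(3)
        mask = np.array([[True], [False], [True]])
        omega = build_covariance(np.array([[1.0]]), np.array([[0.5]]), phi2,
                                 mask=mask)
        assert omega.shape == (2, 2)

    def test_not_positive_definite_reported(self):
        phi2 = np.eye(2)
        with pytest.raises(NumericalError, match="eigenvalue"):
            build_covariance(np.array([[-2.0]]), np.array([[0.1]]), phi2)


class TestLoglikOracle:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_dense_mvn(self, seed):
        """Blockwise likelihood equals a brute-force dense evaluation."""
        ds, G, E, mb, _ = random_instance(seed)
        ours = loglik(ds, VCParameters(G=G, E=E, mean_betas=mb))
        oracle = dense_mvn_loglik(ds, G, E, mb)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_matches_dense_mvn_with_missing(self):
        ds, G, E, mb, rng = random_instance(99, k=3)
        Y = ds.Y.copy()
        Y[rng.random(Y.shape) < 0.2] = np.nan
        ds2 = ds.with_traits(Y)
        ours = loglik(ds2, VCParameters(G=G, E=E, mean_betas=mb))
        oracle = dense_mvn_loglik(ds2, G, E, mb)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_three_unrelated_hand_computed(self):
        """n = 3 founders, k = 1: density equals the product of normals
        with variance sigma_g^2 + sigma_e^2."""
        from scipy.stats import norm

        from longvc import Individual, Pedigree, compute_kinship, \
            validate_pedigree

        ped = validate_pedigree(Pedigree([
            Individual("a", sex="male"), Individual("b", sex="female"),
            Individual("c", sex="male")]))
        kin = compute_kinship(ped)
        y = np.array([0.3, -1.2, 0.7])
        ds = make_dataset(kin, ped.ids, y, np.empty((3, 0)), [])
        params = VCParameters(G=np.array([[1.5]]), E=np.array([[0.5]]),
                              mean_betas=np.array([[0.1]]))
        expected = norm.logpdf(y, loc=0.1, scale=np.sqrt(2.0)).sum()
        assert loglik(ds, params) == pytest.approx(expected, abs=1e-10)


class TestFitML:
    def test_rank_deficient_design_names_columns(self, small_replicate):
        from longvc.association import build_candidate_covariates

        rep = small_replicate
        cov = build_candidate_covariates(rep.phenotypes)[["age", "sex"]]
        cov = cov.assign(zero=0.0)
        ds = make_dataset(rep.kinship, rep.phenotypes.ids,
                          rep.phenotypes.values, cov)
        with pytest.raises(DesignError, match="zero"):
            fit_ml(ds)

    def test_zero_genetic_variance_closed_form(self):
        """Data with no polygenic signal: the maximized log-likelihood
        matches the environment-only closed form."""
        from longvc import Individual, Pedigree, compute_kinship, \
            validate_pedigree

        rng = np.random.default_rng(4)
        members = []
        for i in range(120):  # founders only: no genetic covariance
            members.append(Individual(f"f{i}", sex="male"))
        ped = validate_pedigree(Pedigree(members))
        kin = compute_kinship(ped)
        y = rng.standard_normal(120)
        ds = make_dataset(kin, ped.ids, y, np.empty((120, 0)), [])
        res = fit_ml(ds)
        # for founders 2*Phi = I: sigma_g and sigma_e are not separately
        # identifiable, so compare to the iid-normal MLE log-likelihood
        var_mle = np.var(y)
        closed = (-0.5 * 120 * (np.log(2 * np.pi * var_mle) + 1.0))
        assert res.loglik == pytest.approx(closed, abs=1e-4)

    def test_k1_multivariate_equals_univariate(self):
        """The k = 1 reduction: batched multivariate code and dedicated
        univariate code path maximize to the same log-likelihood."""
        from longvc.likelihood import _eig_nll, _design_eig

        cfg = SimConfig(n_pedigrees=4, total_size=120, n_null_variants=4,
                        causal_variants=((0.3, 0.05),), k=1)
        for seed in range(3):
            rep = simulate_replicate(cfg, seed=100 + seed,
                                     shared=None)
            ds = dataset_from(rep, covariates=("age", "sex"))
            res_uni = fit_ml(ds)  # k == 1 dispatches to the scalar path
            lam = ds.eigenvalues()
            X = _design_eig(ds, None, "none")
            # evaluate the k x k batched implementation at the optimum
            nll_multi = _eig_nll(res_uni.theta, ds, X, lam, False)
            assert -nll_multi == pytest.approx(res_uni.loglik, abs=1e-6)

    def test_reorder_invariance(self, small_replicate):
        rep = small_replicate
        ds = dataset_from(rep)
        r1 = fit_ml(ds)
        rng = np.random.default_rng(0)
        perm = rng.permutation(rep.phenotypes.n)
        from longvc.association import build_candidate_covariates

        cov = build_candidate_covariates(rep.phenotypes)[["age", "sex"]]
        ids_p = [rep.phenotypes.ids[i] for i in perm]
        ds2 = make_dataset(rep.kinship, ids_p, rep.phenotypes.values[perm],
                           cov.iloc[perm])
        r2 = fit_ml(ds2)
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-5)

    def test_covariate_rescaling_invariance(self, small_replicate):
        """Affine rescaling of a covariate leaves the likelihood alone
        and rescales its coefficient inversely."""
        rep = small_replicate
        from longvc.association import build_candidate_covariates

        cov = build_candidate_covariates(rep.phenotypes)[["age", "sex"]]
        ds1 = make_dataset(rep.kinship, rep.phenotypes.ids,
                           rep.phenotypes.values, cov)
        cov2 = cov.assign(age=cov["age"] * 10.0)
        ds2 = make_dataset(rep.kinship, rep.phenotypes.ids,
                           rep.phenotypes.values, cov2)
        r1, r2 = fit_ml(ds1), fit_ml(ds2)
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-5)
        age_col = ds1.covariate_names.index("age")
        assert r1.params.mean_betas[:, age_col] == pytest.approx(
            10.0 * r2.params.mean_betas[:, age_col], rel=1e-3, abs=1e-5)

    def test_parameter_recovery_moderate(self, small_shared):
        """h2 and rho_g recovered within loose bounds on a 120-individual
        study averaged over a few replicates (full-scale recovery is
        exercised in the acceptance suite)."""
        h2s, rhos = [], []
        for seed in range(6):
            rep = simulate_replicate(SMALL_RECOVERY, seed=300 + seed,
                                     shared=None)
            ds = dataset_from(rep)
            res = fit_ml(ds)
            h2s.append(res.params.h2.mean())
            rhos.append(res.params.rho("g")[0, 1])
        assert abs(np.mean(h2s) - SMALL_RECOVERY.h2) < 0.15
        assert np.mean(rhos) > 0.75  # truth: rho_g = 1


SMALL_RECOVERY = SimConfig(n_pedigrees=4, total_size=160, causal_variants=(),
                           n_null_variants=1, h2=0.4)
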