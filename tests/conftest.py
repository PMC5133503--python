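import numpy as np
import pytest

from longvc import (Individual, Pedigree, SimConfig, make_dataset,
                    simulate_replicate, validate_pedigree)
from longvc.association import build_candidate_covariates
from longvc.simulate import make_shared


@pytest.fixture
def trio() -> Pedigree:
    return validate_pedigree(Pedigree([
        Individual("dad", sex="male"),
        Individual("mom", sex="female"),
        Individual("kid", "dad", "mom"),
    ]))


@pytest.fixture
def nuclear() -> Pedigree:
    """Two full sibs, one maternal half sib."""
    return validate_pedigree(Pedigree([
        Individual("dad", sex="male"),
        Individual("mom", sex="female"),
        Individual("dad2", sex="male"),
        Individual("sib1", "dad", "mom"),
        Individual("sib2", "dad", "mom"),
        Individual("half", "dad2", "mom"),
    ]))


def random_pedigree(size: int, seed: int) -> Pedigree:
    """One random multi-generation pedigree of exactly ``size`` members."""
    from longvc import generate_pedigrees

    return generate_pedigrees(n_pedigrees=1, total_size=size,
                              max_generations=4, seed=seed)


SMALL = SimConfig(n_pedigrees=4, total_size=120, n_null_variants=4,
                  causal_variants=((0.3, 0.05),))


@pytest.fixture(scope="session")
def small_shared():
    """Fixed pedigree + genotypes for a 120-individual, 4-family study."""
    return make_shared(SMALL, seed=11)


@pytest.fixture(scope="session")
def small_replicate(small_shared):
    return simulate_replicate(SMALL, seed=12, shared=small_shared)


@pytest.fixture(scope="session")
def big_replicate():
    """One replicate at the default full study design (849 individuals)."""
    cfg = SimConfig()
    shared = make_shared(cfg, seed=21)
    return simulate_replicate(cfg, seed=22, shared=shared)


def dataset_from(rep, covariates=("age", "sex"), traits="all"):
    """Small helper used across test modules."""
    cov = build_candidate_covariates(rep.phenotypes)[list(covariates)]
    if traits == "all":
        Y = rep.phenotypes.values
    elif traits == "average":
        Y = rep.phenotypes.visit_mean()
    else:
        Y = rep.phenotypes.values[:, traits]
    return make_dataset(rep.kinship, rep.phenotypes.ids, Y, cov)


def dense_mvn_loglik(ds, G, E, mean_betas, g=None, snv_beta=None,
                     kernel=None, gamma=None):
    """Independent brute-force oracle: stack the full covariance with
    np.kron and evaluate the multivariate-normal density with scipy."""
    from scipy.stats import multivariate_normal

    n, k = ds.Y.shape
    phi2 = np.zeros((n, n))
    for sl, p in zip(ds.blocks, ds.phi2):
        phi2[sl, sl] = p
    omega = np.kron(np.atleast_2d(G), phi2) + np.kron(np.atleast_2d(E), np.eye(n))
    if kernel is not None:
        omega = omega + np.kron(np.atleast_2d(gamma), kernel)
    mean = (ds.C @ np.atleast_2d(mean_betas).T).T
    if g is not None:
        b = np.atleast_1d(snv_beta)
        if b.size == 1:
            b = np.repeat(b, k)
        mean = mean + b[:, None] * np.asarray(g)[None, :]
    y = ds.Y.T.ravel()
    obs = ~np.isnan(y)
    return multivariate_normal.logpdf(
        y[obs], mean=mean.ravel()[obs], cov=omega[np.ix_(obs, obs)])
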