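"""Synthetic family-study generator.

Emulates the design of a large family-based longitudinal blood-pressure
study: ~20 extended pedigrees totalling ~850 individuals over 3-4
generations, biallelic SNVs gene-dropped through the pedigrees, and a
quantitative trait measured at k visits with

    y_it = mu_t + sum_c beta_c g_ic + covariate effects + a_it + e_it

where the additive-polygenic vectors (a_i1..a_ik) have covariance
``G (x) 2*Phi`` across individuals and visits and the environmental
vectors are independent across individuals with visit covariance ``E``.
SNV effect sizes are specified as fractions of the (genetic + residual)
trait variance; the per-allele effect for a variant with minor allele
frequency p explaining fraction V is ``beta = sqrt(V * var_total /
(2 p (1 - p)))``.  By default the genetic correlation across visits is
1.0 (time-stable genetic effects), the regime under which constraining a
variant's effect to be equal across visits is expected to help.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, LongitudinalPhenotypes
from .pedigree import (FEMALE, MALE, Individual, KinshipMatrix, Pedigree,
                       compute_kinship, validate_pedigree)

__all__ = [
    "SimConfig",
    "SimReplicate",
    "generate_pedigrees",
    "gene_drop",
    "gene_drop_matrix",
    "monte_carlo_kinship",
    "simulate_phenotypes",
    "simulate_replicate",
    "run_study",
]

#: trait-variance fractions for the nine causal variants emulated by default
DEFAULT_CAUSAL_FRACTIONS = (
    0.0278, 0.0206, 0.0149, 0.0143, 0.011, 0.0081, 0.004, 0.0027, 0.0017,
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Variance fractions are proportions of the within-visit trait variance
    ``var_total`` (fixed-covariate effects sit on top of that budget).
    """

    n_pedigrees: int = 20
    total_size: int = 849
    max_generations: int = 4
    k: int = 3
    #: (minor allele frequency, variance fraction) per causal variant
    causal_variants: tuple[tuple[float, float], ...] = tuple(
        (0.2, v) for v in DEFAULT_CAUSAL_FRACTIONS
    )
    n_null_variants: int = 20
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.4
    rho_g: float = 1.0
    rho_e: float = 0.4
    var_total: float = 1.0
    mu: float = 0.0
    age_mean: float = 45.0
    age_sd: float = 12.0
    visit_gap: float = 5.0
    beta_age: float = 0.02
    beta_sex: float = 0.3
    beta_smoke: float = 0.2
    smoking_prev: float = 0.2
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        v_sum = sum(v for _, v in self.causal_variants)
        if not v_sum + self.h2 < 1.0:
            raise ValueError(
                "infeasible variance budget: causal fractions + h2 must be < 1"
            )
        for p, _ in self.causal_variants:
            if not 0.0 < p <= 0.5:
                raise ValueError(f"minor allele frequency {p} outside (0, 0.5]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def env_var(self) -> float:
        v_sum = sum(v for _, v in self.causal_variants)
        return self.var_total * (1.0 - self.h2 - v_sum)


@dataclass
class SimReplicate:
    """One simulated dataset plus the generating truth."""

    pedigree: Pedigree
    kinship: KinshipMatrix
    genotypes: GenotypeMatrix
    phenotypes: LongitudinalPhenotypes
    truth: dict


# ---------------------------------------------------------------------------
# pedigree generation


def _split_sizes(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Partition ``total`` into ``parts`` sizes >= 3 summing exactly."""
    if total < 3 * parts:
        raise ValueError(
            f"impossible template: {total} individuals cannot fill "
            f"{parts} pedigrees of at least trio size"
        )
    w = rng.uniform(0.6, 1.4, size=parts)
    sizes = np.maximum(3, np.round(total * w / w.sum()).astype(int))
    while sizes.sum() != total:
        j = int(rng.integers(parts))
        if sizes.sum() > total and sizes[j] > 3:
            sizes[j] -= 1
        elif sizes.sum() < total:
            sizes[j] += 1
    return sizes.tolist()


def _build_family(fid: str, size: int, max_gen: int,
                  rng: np.random.Generator) -> list[Individual]:
    """Grow one extended pedigree to exactly ``size`` members."""
    if size < 3:
        raise ValueError("pedigree template must allow at least a trio")
    if max_gen < 2:
        raise ValueError("extended pedigrees need at least 2 generations")
    members: list[Individual] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{fid}-{counter}"

    def add(father=None, mother=None, sex=None) -> Individual:
        if sex is None:
            sex = MALE if rng.random() < 0.5 else FEMALE
        ind = Individual(new_id(), father, mother, sex, family_id=fid)
        members.append(ind)
        return ind

    pa = add(sex=MALE)
    ma = add(sex=FEMALE)
    queue: deque[tuple[Individual, Individual, int]] = deque([(pa, ma, 1)])
    couples: list[tuple[Individual, Individual, int]] = [(pa, ma, 1)]
    while len(members) < size:
        if queue:
            father, mother, gen = queue.popleft()
        else:
            father, mother, gen = couples[int(rng.integers(len(couples)))]
        n_kids = int(min(2 + rng.poisson(1.2), size - len(members)))
        for _ in range(max(1, n_kids)):
            if len(members) >= size:
                break
            kid = add(father.id, mother.id)
            marry = gen + 1 < max_gen and rng.random() < 0.75
            if marry and len(members) < size:
                spouse_sex = FEMALE if kid.sex == MALE else MALE
                spouse = add(sex=spouse_sex)
                pair = ((kid, spouse, gen + 1) if kid.sex == MALE
                        else (spouse, kid, gen + 1))
                queue.append(pair)
                couples.append(pair)
    return members


def generate_pedigrees(n_pedigrees: int = 20, total_size: int = 849,
                       max_generations: int = 4, *,
                       seed: int | np.random.Generator = 0) -> Pedigree:
    """Generate a validated multi-family pedigree of exact total size."""
    rng = np.random.default_rng(seed)
    sizes = _split_sizes(total_size, n_pedigrees, rng)
    members: list[Individual] = []
    for f, s in enumerate(sizes, start=1):
        members.extend(_build_family(f"F{f:02d}", s, max_generations, rng))
    return validate_pedigree(Pedigree(members))


# ---------------------------------------------------------------------------
# gene dropping


def _drop_alleles(ped: Pedigree, founder_alleles, rng: np.random.Generator):
    """Transmit founder alleles through the pedigree.

    ``founder_alleles(ind)`` returns a (2, d) array for a founder; returns
    an (n, 2, d) allele array in pedigree (topological) order.
    """
    if not ped.validated:
        raise ValueError("gene dropping requires a validated pedigree")
    idx = {m.id: i for i, m in enumerate(ped.members)}
    first = founder_alleles(ped.members[0])
    d = first.shape[1]
    alleles = np.empty((len(ped), 2, d), dtype=first.dtype)
    alleles[0] = first
    cols = np.arange(d)
    for i, m in enumerate(ped.members):
        if i == 0:
            continue
        if m.is_founder:
            alleles[i] = founder_alleles(m)
        else:
            fa = alleles[idx[m.father_id]]
            mo = alleles[idx[m.mother_id]]
            alleles[i, 0] = fa[rng.integers(0, 2, size=d), cols]
            alleles[i, 1] = mo[rng.integers(0, 2, size=d), cols]
    return alleles


def gene_drop_matrix(ped: Pedigree, mafs, *,
                     rng: np.random.Generator) -> np.ndarray:
    """Dosages (n, m) for independent biallelic variants with given MAFs.

    Founder alleles are Bernoulli(maf); offspring inherit one random
    allele from each parent (Mendelian transmission).
    """
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))

    def founder_alleles(_ind):
        return (rng.random((2, mafs.size)) < mafs).astype(np.int8)

    alleles = _drop_alleles(ped, founder_alleles, rng)
    return alleles.sum(axis=1).astype(float)


def gene_drop(ped: Pedigree, maf: float, *, rng: np.random.Generator) -> np.ndarray:
    """Dosage vector for a single gene-dropped variant."""
    return gene_drop_matrix(ped, [maf], rng=rng)[:, 0]


def monte_carlo_kinship(ped: Pedigree, n_drops: int = 100_000, *,
                        rng: np.random.Generator) -> KinshipMatrix:
    """Estimate kinship by dropping uniquely labelled founder alleles.

    phi(i, j) is estimated as the mean over drops of the fraction of the
    four allele pairings of i and j that are identical by descent.  An
    independent check on :func:`longvc.pedigree.compute_kinship` (allele
    transmission versus the tabular recursion).
    """
    label = [0]

    def founder_alleles(_ind):
        out = np.empty((2, n_drops), dtype=np.int32)
        out[0] = 2 * label[0]
        out[1] = 2 * label[0] + 1
        label[0] += 1
        return out

    alleles = _drop_alleles(ped, founder_alleles, rng)
    n = len(ped)
    phi = np.zeros((n, n))
    for i in range(n):
        ai = alleles[i]
        phi[i, i] = 0.25 * (2.0 + 2.0 * np.mean(ai[0] == ai[1]))
        for j in range(i + 1, n):
            aj = alleles[j]
            eq = ((ai[0] == aj[0]).mean() + (ai[0] == aj[1]).mean()
                  + (ai[1] == aj[0]).mean() + (ai[1] == aj[1]).mean())
            phi[i, j] = phi[j, i] = 0.25 * eq
    return KinshipMatrix(ped.ids, phi)


# ---------------------------------------------------------------------------
# phenotype simulation


def _equicorr(k: int, rho: float) -> np.ndarray:
    return (1.0 - rho) * np.eye(k) + rho * np.ones((k, k))


def _psd_sqrt(m: np.ndarray) -> np.ndarray:
    """Symmetric square root with eigenvalue clipping (handles rho = 1)."""
    w, u = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    return u * np.sqrt(w) @ u.T


def simulate_genotypes(ped: Pedigree, config: SimConfig, *,
                       rng: np.random.Generator) -> tuple[GenotypeMatrix, list[str]]:
    """Gene-drop the configured causal and null variants.

    Returns the genotype matrix plus the causal variant ids (``snv_c1``..),
    null variants are ``snv_n1``...
    """
    import pandas as pd

    c_mafs = [p for p, _ in config.causal_variants]
    lo, hi = config.null_maf_range
    n_mafs = rng.uniform(lo, hi, size=config.n_null_variants)
    mafs = np.array(list(c_mafs) + list(n_mafs))
    dos = gene_drop_matrix(ped, mafs, rng=rng)
    causal_ids = [f"snv_c{i + 1}" for i in range(len(c_mafs))]
    null_ids = [f"snv_n{i + 1}" for i in range(config.n_null_variants)]
    variants = pd.DataFrame({
        "chrom": ["1"] * len(mafs),
        "pos": np.arange(1, len(mafs) + 1) * 1000,
        "id": causal_ids + null_ids,
        "ref": "A",
        "alt": "G",
    })
    return GenotypeMatrix(ped.ids, variants, dos), causal_ids


def simulate_phenotypes(ped: Pedigree, kin: KinshipMatrix,
                        genos: GenotypeMatrix, config: SimConfig, *,
                        rng: np.random.Generator,
                        causal_ids: list[str] | None = None,
                        ) -> tuple[LongitudinalPhenotypes, dict]:
    """Draw one replicate of the longitudinal trait.

    The polygenic term is sampled per pedigree block as ``L_f Z S_g`` with
    ``L_f`` the Cholesky factor of ``2*Phi_f`` and ``S_g`` the symmetric
    square root of the k x k genetic visit covariance; the environmental
    term is iid across individuals with visit covariance ``E``.
    """
    import pandas as pd

    n, k = len(ped), config.k
    if causal_ids is None:
        causal_ids = [v for v in genos.variants["id"] if v.startswith("snv_c")]
    betas = {}
    fixed = np.zeros((n, k))
    for (p, vfrac), vid in zip(config.causal_variants, causal_ids):
        beta = math.sqrt(vfrac * config.var_total / (2.0 * p * (1.0 - p)))
        betas[vid] = beta
        g = genos.dosage(vid)
        fixed += beta * np.where(np.isnan(g), 2 * p, g)[:, None]

    G = config.h2 * config.var_total * _equicorr(k, config.rho_g)
    E = config.env_var * _equicorr(k, config.rho_e)
    s_g = _psd_sqrt(G)
    s_e = _psd_sqrt(E)
    a = np.zeros((n, k))
    for block in kin.blocks:
        phi2 = 2.0 * kin.phi[np.ix_(block, block)]
        l_f = np.linalg.cholesky(phi2 + 1e-10 * np.eye(len(block)))
        a[block] = l_f @ rng.standard_normal((len(block), k)) @ s_g
    e = rng.standard_normal((n, k)) @ s_e

    age0 = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 18, 90)
    sex = np.array([1.0 if m.sex == FEMALE else 0.0 for m in ped.members])
    smoke = (rng.random(n) < config.smoking_prev).astype(float)
    ages = age0[:, None] + config.visit_gap * np.arange(k)[None, :]
    fixed += (config.mu
              + config.beta_age * (ages - config.age_mean)
              + config.beta_sex * sex[:, None]
              + config.beta_smoke * smoke[:, None])

    y = fixed + a + e
    if config.missing_rate > 0:
        y[rng.random((n, k)) < config.missing_rate] = np.nan
    cov = pd.DataFrame({"age": age0, "sex": sex, "smoke": smoke},
                       index=pd.Index(ped.ids, name="id"))
    phen = LongitudinalPhenotypes(ped.ids, "SBP", y, cov)
    truth = {
        "betas": betas,
        "G": G,
        "E": E,
        "h2": config.h2,
        "rho_g": config.rho_g,
        "rho_e": config.rho_e,
        "var_total": config.var_total,
        "covariate_betas": {"age": config.beta_age, "sex": config.beta_sex,
                            "smoke": config.beta_smoke},
    }
    return phen, truth


def simulate_replicate(config: SimConfig, *, seed, shared=None) -> SimReplicate:
    """Generate one full replicate (pedigree + genotypes + phenotypes).

    ``shared`` may carry a (pedigree, kinship, genotypes, causal_ids)
    tuple so that repeated phenotype replicates reuse fixed genotypes,
    mirroring a study in which genotypes are measured once and the trait
    model is re-simulated.
    """
    rng = np.random.default_rng(seed)
    if shared is None:
        ped = generate_pedigrees(config.n_pedigrees, config.total_size,
                                 config.max_generations, seed=rng)
        kin = compute_kinship(ped)
        genos, causal_ids = simulate_genotypes(ped, config, rng=rng)
    else:
        ped, kin, genos, causal_ids = shared
    phen, truth = simulate_phenotypes(ped, kin, genos, config, rng=rng,
                                      causal_ids=causal_ids)
    return SimReplicate(ped, kin, genos, phen, truth)


def make_shared(config: SimConfig, *, seed):
    """Fixed pedigree + genotypes reused across phenotype replicates."""
    rng = np.random.default_rng(seed)
    ped = generate_pedigrees(config.n_pedigrees, config.total_size,
                             config.max_generations, seed=rng)
    kin = compute_kinship(ped)
    genos, causal_ids = simulate_genotypes(ped, config, rng=rng)
    return ped, kin, genos, causal_ids


def run_study(config: SimConfig, *, n_replicates: int,
              tests=("average", "constrained", "unconstrained"),
              thresholds=(1e-3, 5e-5, 5e-9),
              variants: list[str] | None = None,
              seed=0, fixed_genotypes: bool = True,
              alphas=(0.05, 0.01), progress: bool = False):
    """Power / type-I study over phenotype replicates.

    Runs the selected association tests on each replicate, tallies
    p-values against the thresholds (strict ``<``), and reports empirical
    null rejection rates at ``alphas`` over the null variants.  Returns
    ``(tally_frame, null_rates, results_frame)``.
    """
    from .association import AssociationRunner, tally_replicates

    ss = np.random.SeedSequence(seed)
    shared_seed, *rep_seeds = ss.spawn(n_replicates + 1)
    shared = make_shared(config, seed=shared_seed) if fixed_genotypes else None

    all_results = []
    for r in range(n_replicates):
        rep = simulate_replicate(config, seed=rep_seeds[r], shared=shared)
        runner = AssociationRunner(rep.kinship, rep.phenotypes,
                                   covariates=["age", "sex", "smoke"])
        vids = variants if variants is not None else list(rep.genotypes.variants["id"])
        for vid in vids:
            for res in runner.test_variant(rep.genotypes.dosage(vid), vid,
                                           tests=tests):
                d = res.to_dict()
                d["replicate"] = r
                all_results.append(d)
        if progress:
            print(f"replicate {r + 1}/{n_replicates} done", flush=True)

    import pandas as pd

    frame = pd.DataFrame(all_results)
    if frame.empty:
        return frame, {}, frame
    tally = tally_replicates(frame, thresholds=thresholds)
    null_mask = frame["variant"].str.startswith("snv_n")
    null_rates = {}
    for test in tests:
        sub = frame[null_mask & (frame["test"] == test)]
        null_rates[test] = {
            alpha: float((sub["p"] < alpha).mean()) if len(sub) else float("nan")
            for alpha in alphas
        }
    return tally, null_rates, frame
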