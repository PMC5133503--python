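"""Measured-genotype association tests for longitudinal traits.

Three strategies are provided for a quantitative trait measured at k
visits in pedigrees:

* ``average`` — univariate measured-genotype test on the per-individual
  mean of the available visits (LRT, 1 df);
* ``constrained`` — joint model of all visits with the variant's mean
  effect beta forced equal across visits (LRT, 1 df), appropriate when
  genetic effects are stable over time;
* ``unconstrained`` — per-visit betas estimated freely and tested
  jointly against all-zero (LRT, k df).

All three model relatedness through the polygenic variance component
``G (x) 2*Phi`` and share a marginal covariate screen: a candidate is
carried forward if it improves the polygenic model of the averaged
trait at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import LongitudinalPhenotypes
from .likelihood import Dataset, FitResult, fit_ml, make_dataset
from .pedigree import KinshipMatrix

__all__ = [
    "AssociationResult",
    "AssociationRunner",
    "lrt_pvalue",
    "screen_covariates",
    "tally_replicates",
    "DEFAULT_CANDIDATES",
]

#: marginal screening candidates: baseline age (centered), sex, their
#: interaction, quadratic age terms, and smoking status
DEFAULT_CANDIDATES = ("age", "sex", "age_x_sex", "age2", "age2_x_sex", "smoke")


def lrt_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability for a likelihood-ratio statistic.

    Small negative statistics (optimizer slack, > -1e-6) are clipped to
    zero; larger negative values indicate an optimization failure
    upstream and raise.
    """
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic {stat:.3e}: alternative fit worse than "
            "null beyond numerical slack"
        )
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(max(stat, 0.0), df))


@dataclass
class AssociationResult:
    """One variant x test outcome."""

    variant: str
    test: str
    stat: float
    df: int
    p: float
    beta: float | np.ndarray | None
    loglik_null: float
    loglik_alt: float
    n: int
    converged: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        beta = self.beta
        if isinstance(beta, np.ndarray):
            beta = ";".join(f"{b:.6g}" for b in beta)
        return {
            "variant": self.variant, "test": self.test, "stat": self.stat,
            "df": self.df, "p": self.p, "beta": beta,
            "loglik_null": self.loglik_null, "loglik_alt": self.loglik_alt,
            "n": self.n, "converged": self.converged, "note": self.note,
        }


def build_candidate_covariates(phen: LongitudinalPhenotypes) -> pd.DataFrame:
    """Derived covariate columns: centered age, indicators, interactions."""
    cov = phen.covariates
    out = pd.DataFrame(index=cov.index)
    if "age" in cov.columns:
        age_c = cov["age"] - cov["age"].mean()
        out["age"] = age_c
        out["age2"] = age_c ** 2
    if "sex" in cov.columns:
        out["sex"] = cov["sex"]
    if {"age", "sex"} <= set(cov.columns):
        out["age_x_sex"] = out["age"] * cov["sex"]
        out["age2_x_sex"] = out["age2"] * cov["sex"]
    if "smoke" in cov.columns:
        out["smoke"] = cov["smoke"]
    for extra in cov.columns.difference(["age", "sex", "smoke"]):
        out[extra] = cov[extra]
    return out


def screen_covariates(kinship: KinshipMatrix, phen: LongitudinalPhenotypes,
                      candidates=DEFAULT_CANDIDATES,
                      alpha: float = 0.05) -> list[str]:
    """Marginal covariate screen on the time-averaged trait.

    Each candidate is tested one at a time as a fixed effect in the
    polygenic (no-SNV) univariate model of the averaged trait; those
    with LRT p < ``alpha`` are retained.  Constant candidates are
    skipped with a warning.
    """
    table = build_candidate_covariates(phen)
    y = phen.visit_mean()
    ds0 = make_dataset(kinship, phen.ids, y, np.empty((phen.n, 0)), [])
    null = fit_ml(ds0)
    selected = []
    pos = {i: j for j, i in enumerate(phen.ids)}
    for name in candidates:
        if name not in table.columns:
            continue
        x = table[name].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"covariate {name!r} is constant; skipped")
            continue
        ds1 = make_dataset(kinship, phen.ids, y, x[:, None], [name])
        alt = fit_ml(ds1, init_theta=null.theta)
        stat = 2.0 * (alt.loglik - null.loglik)
        if lrt_pvalue(stat, 1) < alpha:
            selected.append(name)
    return selected


class AssociationRunner:
    """Shared state for testing many variants on one phenotype replicate.

    Builds the multivariate and averaged-trait datasets once, fits the
    SNV-free null models once, and warm-starts every alternative fit
    from the corresponding null, which makes the likelihood nesting
    logL_free >= logL_shared >= logL_null structural.

    Parameters
    ----------
    covariates:
        ``"auto"`` runs the marginal screen; otherwise a list of column
        names from :func:`build_candidate_covariates`.
    impute:
        ``"mean"`` replaces missing dosages with twice the sample ALT
        frequency; ``"drop"`` removes those individuals per variant.
    """

    def __init__(self, kinship: KinshipMatrix, phen: LongitudinalPhenotypes,
                 covariates="auto", maf_floor: float = 0.0,
                 impute: str = "mean"):
        if impute not in ("mean", "drop"):
            raise ValueError("impute must be 'mean' or 'drop'")
        self.kinship = kinship
        self.phen = phen
        self.maf_floor = maf_floor
        self.impute = impute
        if covariates == "auto":
            covariates = screen_covariates(kinship, phen)
        table = build_candidate_covariates(phen)
        bad = [c for c in covariates if c not in table.columns]
        if bad:
            raise KeyError(f"unknown covariates {bad}")
        self.covariate_names = list(covariates)
        self._cov = table[self.covariate_names]
        self.ds_multi = make_dataset(kinship, phen.ids, phen.values,
                                     self._cov)
        self.ds_avg = make_dataset(kinship, phen.ids, phen.visit_mean(),
                                   self._cov)
        self._pos = {i: j for j, i in enumerate(phen.ids)}
        self._null: dict[str, FitResult] = {}

    @property
    def k(self) -> int:
        return self.phen.k

    def null_fit(self, which: str) -> FitResult:
        if which not in self._null:
            ds = self.ds_avg if which == "average" else self.ds_multi
            self._null[which] = fit_ml(ds)
        return self._null[which]

    def _aligned_dosage(self, g: np.ndarray, ds: Dataset) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        idx = [self._pos[i] for i in ds.ids]
        gd = g[idx]
        miss = np.isnan(gd)
        if miss.any():
            af = np.nanmean(gd) / 2.0
            gd = np.where(miss, 2.0 * af, gd)
        return gd

    def _degenerate(self, variant: str, test: str, note: str,
                    null: FitResult, df: int) -> AssociationResult:
        return AssociationResult(variant, test, 0.0, df, 1.0, None,
                                 null.loglik, null.loglik,
                                 null.n_obs, converged=True, note=note)

    def test_variant(self, g: np.ndarray, variant: str = "",
                     tests=("average", "constrained", "unconstrained"),
                     ) -> list[AssociationResult]:
        """Run the selected tests for one dosage vector."""
        results = []
        for test in tests:
            results.append(self._one_test(g, variant, test))
        return results

    def _one_test(self, g, variant: str, test: str) -> AssociationResult:
        if test not in ("average", "constrained", "unconstrained"):
            raise ValueError(f"unknown test {test!r}")
        if test != "average" and self.k < 2:
            raise ValueError(f"{test} test requires k >= 2 visits")
        ds = self.ds_avg if test == "average" else self.ds_multi
        which = "average" if test == "average" else "multi"
        null = self.null_fit(which)
        df = self.k if test == "unconstrained" else 1
        gd = self._aligned_dosage(g, ds)
        af = float(np.mean(gd) / 2.0)
        maf = min(af, 1.0 - af)
        if np.std(gd) == 0.0:
            return self._degenerate(variant, test, "monomorphic", null, df)
        if maf < self.maf_floor:
            return self._degenerate(variant, test,
                                    f"maf {maf:.4g} below floor", null, df)
        snv_mode = "free" if test == "unconstrained" else "shared"
        if self.impute == "drop" and np.isnan(np.asarray(g, dtype=float)).any():
            ds, gd, null = self._listwise(ds, g)
        alt = fit_ml(ds, g=gd, snv_mode=snv_mode, init_theta=null.theta)
        stat = 2.0 * (alt.loglik - null.loglik)
        p = lrt_pvalue(stat, df)
        return AssociationResult(
            variant, test, max(stat, 0.0), df, p, alt.params.snv_beta,
            null.loglik, alt.loglik, alt.n_obs,
            converged=null.converged and alt.converged,
        )

    def _listwise(self, ds: Dataset, g):
        g = np.asarray(g, dtype=float)
        keep_ids = [i for i in ds.ids if not np.isnan(g[self._pos[i]])]
        sub = make_dataset(self.kinship, keep_ids,
                           np.array([ds.Y[ds.ids.index(i)] for i in keep_ids]),
                           np.array([ds.C[ds.ids.index(i), 1:] for i in keep_ids]),
                           ds.covariate_names[1:])
        gd = np.array([g[self._pos[i]] for i in sub.ids])
        return sub, gd, fit_ml(sub)


def tally_replicates(results: pd.DataFrame,
                     thresholds=(1e-3, 5e-5, 5e-9)) -> pd.DataFrame:
    """Count replicates meeting each p-value threshold (strict ``<``).

    ``results`` needs columns variant, test, p, replicate.  Variant/test
    cells absent from some replicates count as non-significant and a
    warning is emitted.
    """
    n_rep = results["replicate"].nunique()
    rows = []
    for (variant, test), grp in results.groupby(["variant", "test"],
                                                sort=True):
        if len(grp) < n_rep:
            warnings.warn(
                f"{variant}/{test}: only {len(grp)} of {n_rep} replicates "
                "present; missing cells counted as non-significant"
            )
        row = {"variant": variant, "test": test, "n_replicates": n_rep}
        for thr in thresholds:
            row[f"n_p_lt_{thr:g}"] = int((grp["p"] < thr).sum())
        rows.append(row)
    return pd.DataFrame(rows)
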