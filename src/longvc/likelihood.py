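"""Maximum-likelihood engine for pedigree variance-component models.

The trait vector stacked over individuals and visits is modelled as
multivariate normal,

    y ~ N(X beta,  Omega),   Omega = G (x) 2*Phi + E (x) I_n [+ s s' (x) K]

with G and E the k x k genetic and environmental visit covariance
matrices, ``2*Phi`` the additive relationship matrix from the pedigree,
and optionally a region-local empirical kinship kernel K whose visit
loadings s give the gene-specific variance component (sigma2_geff =
s_t^2 per visit).  Kronecker products are visit-major: index t*n + i.

Estimation is full ML.  Mean parameters are profiled out by generalized
least squares at every evaluation, so the optimizer works only on the
covariance parameters, which are parameterized through log-Cholesky
factors of G and E (positive semidefiniteness by construction, variance
boundaries reachable as the log-diagonal floor).

Two evaluation paths produce identical likelihoods:

* complete data without a kernel: eigendecompose ``2*Phi`` once per
  pedigree block; in the rotated basis the problem factors into n
  independent k x k normal problems, evaluated batched with analytic
  gradients;
* missing visits or a kernel present: dense per-pedigree covariance
  blocks with Cholesky solves and numerical gradients.

Omega is block-diagonal across pedigrees throughout, so cost is the sum
of cubes of pedigree sizes, never the cube of the sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import minimize

from .pedigree import KinshipMatrix

__all__ = [
    "Dataset",
    "VCParameters",
    "FitResult",
    "DesignError",
    "NumericalError",
    "make_dataset",
    "build_covariance",
    "loglik",
    "fit_ml",
]

_LOG2PI = math.log(2.0 * math.pi)
_DIAG_LB, _DIAG_UB = -8.0, 6.0  # bounds on log-Cholesky diagonals
_BIG = 1e12


class DesignError(ValueError):
    """Mean-model design matrix problem (rank deficiency etc.)."""


class NumericalError(RuntimeError):
    """Covariance matrix not positive definite or a solve failed."""


# ---------------------------------------------------------------------------
# dataset


@dataclass
class Dataset:
    """Analysis-ready view: trait matrix, covariates, kinship blocks.

    Individuals are ordered so that pedigree blocks are contiguous;
    ``blocks`` are slices into that order and ``phi2`` the corresponding
    ``2*Phi`` blocks.  ``C`` includes the leading intercept column.
    """

    ids: list[str]
    Y: np.ndarray
    C: np.ndarray
    covariate_names: list[str]
    blocks: list[slice]
    phi2: list[np.ndarray]
    _eig: list[tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False)
    _rotC: np.ndarray | None = field(default=None, repr=False)
    _rotY: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def k(self) -> int:
        return self.Y.shape[1]

    @property
    def complete(self) -> bool:
        return not np.isnan(self.Y).any()

    def eig(self):
        """Per-block eigendecompositions of 2*Phi (cached)."""
        if self._eig is None:
            self._eig = [np.linalg.eigh(p) for p in self.phi2]
        return self._eig

    def eigenvalues(self) -> np.ndarray:
        return np.concatenate([w for w, _ in self.eig()])

    def rotate(self, v: np.ndarray) -> np.ndarray:
        """Apply the blockwise U^T rotation to per-individual rows."""
        out = np.empty_like(v, dtype=float)
        for sl, (_, u) in zip(self.blocks, self.eig()):
            out[sl] = u.T @ v[sl]
        return out

    def rotated_C(self) -> np.ndarray:
        if self._rotC is None:
            self._rotC = self.rotate(self.C)
        return self._rotC

    def rotated_Y(self) -> np.ndarray:
        if self._rotY is None:
            self._rotY = self.rotate(self.Y)
        return self._rotY

    def with_traits(self, Y_new: np.ndarray) -> "Dataset":
        """Same individuals/covariance structure, different trait view."""
        return Dataset(self.ids, np.asarray(Y_new, dtype=float),
                       self.C, self.covariate_names, self.blocks, self.phi2,
                       _eig=self._eig, _rotC=self._rotC)


def make_dataset(kinship: KinshipMatrix, ids: list[str], Y: np.ndarray,
                 covariates, covariate_names: list[str] | None = None,
                 ) -> Dataset:
    """Assemble a :class:`Dataset`, dropping unusable individuals.

    ``covariates`` is an (n, c) array or DataFrame *without* intercept;
    individuals with no observed visit or a missing covariate are
    dropped.  Ids must all be present in the kinship matrix.
    """
    import pandas as pd

    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if isinstance(covariates, pd.DataFrame):
        covariate_names = list(covariates.columns)
        covariates = covariates.to_numpy(dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.size == 0:
        covariates = np.empty((len(ids), 0))
    if covariate_names is None:
        covariate_names = [f"x{j + 1}" for j in range(covariates.shape[1])]

    missing = [i for i in ids if i not in kinship._index]
    if missing:
        raise KeyError(
            f"{len(missing)} phenotyped individuals absent from the pedigree "
            f"(first: {missing[0]!r}); silent founders would corrupt the "
            "kinship matrix"
        )
    keep = ~(np.isnan(Y).all(axis=1) | np.isnan(covariates).any(axis=1))
    ids = [i for i, k in zip(ids, keep) if k]
    Y, covariates = Y[keep], covariates[keep]

    kin = kinship.submatrix(ids)
    # merge singleton components (unrelated individuals) into one
    # diagonal block so per-block overhead stays proportional to the
    # number of actual pedigrees
    kin_blocks = [b for b in kin.blocks if len(b) > 1]
    singles = [b for b in kin.blocks if len(b) == 1]
    if singles:
        kin_blocks.append(np.concatenate(singles))
    order = (np.concatenate(kin_blocks) if kin_blocks
             else np.arange(len(ids)))
    ids_o = [ids[i] for i in order]
    Y_o, C_o = Y[order], covariates[order]
    blocks, phi2 = [], []
    start = 0
    for b in kin_blocks:
        sl = slice(start, start + len(b))
        blocks.append(sl)
        phi2.append(2.0 * kin.phi[np.ix_(b, b)])
        start += len(b)
    C_full = np.column_stack([np.ones(len(ids_o)), C_o])
    return Dataset(ids_o, Y_o, C_full, ["intercept"] + covariate_names,
                   blocks, phi2)


# ---------------------------------------------------------------------------
# parameters

@dataclass
class VCParameters:
    """Estimated mean and covariance parameters.

    ``mean_betas`` is (k, c): per-visit intercept and covariate
    coefficients.  ``snv_beta`` is a scalar for a shared (constrained)
    allelic effect, a length-k vector when estimated per visit, or None.
    ``kernel_loadings`` s gives the gene-kernel visit covariance s s'.
    """

    G: np.ndarray
    E: np.ndarray
    mean_betas: np.ndarray | None = None
    covariate_names: list[str] | None = None
    snv_beta: float | np.ndarray | None = None
    kernel_loadings: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.G.shape[0]

    @property
    def sigma2_geff(self) -> np.ndarray | None:
        if self.kernel_loadings is None:
            return None
        return np.asarray(self.kernel_loadings) ** 2

    def total_variance(self) -> np.ndarray:
        tot = np.diag(self.G) + np.diag(self.E)
        if self.kernel_loadings is not None:
            tot = tot + self.sigma2_geff
        return tot

    @property
    def h2(self) -> np.ndarray:
        return np.diag(self.G) / self.total_variance()

    @property
    def h2_geff(self) -> np.ndarray | None:
        if self.kernel_loadings is None:
            return None
        return self.sigma2_geff / self.total_variance()

    def rho(self, which: str = "g") -> np.ndarray:
        """Cross-visit correlation matrix of G or E (NaN where variance 0)."""
        m = self.G if which == "g" else self.E
        sd = np.sqrt(np.diag(m))
        with np.errstate(divide="ignore", invalid="ignore"):
            return m / np.outer(sd, sd)


@dataclass
class FitResult:
    """Outcome of one ML fit."""

    params: VCParameters
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    boundary: bool
    theta: np.ndarray = field(repr=False, default=None)
    n_obs: int = 0


# ---------------------------------------------------------------------------
# parameter packing (log-Cholesky)


def _n_chol(k: int) -> int:
    return k + k * (k - 1) // 2


def _theta_to_chol(theta: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.diag_indices(k)] = np.exp(theta[:k])
    if k > 1:
        r, c = np.tril_indices(k, -1)
        L[r, c] = theta[k:]
    return L


def _chol_to_theta(L: np.ndarray) -> np.ndarray:
    k = L.shape[0]
    out = np.empty(_n_chol(k))
    out[:k] = np.log(np.clip(np.diag(L), math.exp(_DIAG_LB), None))
    if k > 1:
        r, c = np.tril_indices(k, -1)
        out[k:] = L[r, c]
    return out


def _chol_grad(dM: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Chain a full-matrix gradient wrt M = L L' onto the theta scale."""
    k = L.shape[0]
    dL = 2.0 * dM @ L
    out = np.empty(_n_chol(k))
    out[:k] = np.diag(dL) * np.diag(L)
    if k > 1:
        r, c = np.tril_indices(k, -1)
        out[k:] = dL[r, c]
    return out


def _cov_init(ds: Dataset, h2_guess: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Moment-based starting values from covariate-adjusted residuals."""
    k = ds.k
    resid = np.full_like(ds.Y, np.nan)
    for t in range(k):
        obs = ~np.isnan(ds.Y[:, t])
        if obs.sum() <= ds.C.shape[1]:
            raise ValueError(f"too few observations at visit {t + 1}")
        coef, *_ = np.linalg.lstsq(ds.C[obs], ds.Y[obs, t], rcond=None)
        resid[obs, t] = ds.Y[obs, t] - ds.C[obs] @ coef
    df = np.ma.masked_invalid(resid)
    S = np.ma.cov(df, rowvar=False, allow_masked=True)
    S = np.atleast_2d(np.asarray(S))
    if not np.all(np.isfinite(S)) or np.any(np.diag(S) <= 0):
        raise ValueError("degenerate trait data (zero or undefined variance)")
    # shrink correlations slightly so the split parts stay PD
    d = np.sqrt(np.diag(S))
    R = 0.9 * S / np.outer(d, d) + 0.1 * np.eye(k)
    S = R * np.outer(d, d)
    return h2_guess * S, (1.0 - h2_guess) * S


# ---------------------------------------------------------------------------
# design matrices


def _design_eig(ds: Dataset, g: np.ndarray | None, snv_mode: str) -> np.ndarray:
    """Rotated batched design (n, k, p) for the eigen path."""
    n, k = ds.n, ds.k
    C = ds.rotated_C()
    c = C.shape[1]
    p = k * c + {"none": 0, "shared": 1, "free": k}[snv_mode]
    X = np.zeros((n, k, p))
    for t in range(k):
        X[:, t, t * c:(t + 1) * c] = C
    if snv_mode != "none":
        gr = ds.rotate(np.asarray(g, dtype=float))
        if snv_mode == "shared":
            X[:, :, k * c] = gr[:, None]
        else:
            for t in range(k):
                X[:, t, k * c + t] = gr
    return X


def _design_block(ds: Dataset, sl: slice, g, snv_mode: str) -> np.ndarray:
    """Stacked visit-major design ((n_f * k) x p) for one pedigree block."""
    k = ds.k
    C = ds.C[sl]
    nf, c = C.shape
    p = k * c + {"none": 0, "shared": 1, "free": k}[snv_mode]
    X = np.zeros((nf * k, p))
    for t in range(k):
        X[t * nf:(t + 1) * nf, t * c:(t + 1) * c] = C
    if snv_mode != "none":
        gb = np.asarray(g, dtype=float)[sl]
        if snv_mode == "shared":
            X[:, k * c] = np.tile(gb, k)
        else:
            for t in range(k):
                X[t * nf:(t + 1) * nf, k * c + t] = gb
    return X


def _check_design(ds: Dataset, g, snv_mode: str) -> None:
    cols = ds.C if snv_mode == "none" else np.column_stack([ds.C, g])
    names = list(ds.covariate_names) + ([] if snv_mode == "none" else ["snv"])
    r = np.linalg.matrix_rank(cols)
    if r < cols.shape[1]:
        _, rdiag, piv = scipy.linalg.qr(cols, mode="economic", pivoting=True)
        tol = np.abs(rdiag[0, 0]) * max(cols.shape) * np.finfo(float).eps
        bad = [names[piv[j]] for j in range(cols.shape[1])
               if j >= r or abs(rdiag[j, j]) < tol]
        raise DesignError(f"rank-deficient mean design; collinear columns: "
                          f"{sorted(set(bad))}")


# ---------------------------------------------------------------------------
# likelihood evaluation: eigen path (complete data, no kernel)


def _profile_from_parts(A_full: np.ndarray, logdet: float, n_obs: int):
    p = A_full.shape[0] - 1
    A, b, q = A_full[:p, :p], A_full[:p, p], A_full[p, p]
    try:
        beta = scipy.linalg.solve(A, b, assume_a="pos")
    except (scipy.linalg.LinAlgError, ValueError):
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    quad = q - b @ beta
    nll = 0.5 * (n_obs * _LOG2PI + logdet + quad)
    return nll, beta


def _eig_nll(theta, ds: Dataset, X: np.ndarray, lam: np.ndarray,
             want_grad: bool):
    k = ds.k
    nc = _n_chol(k)
    Lg = _theta_to_chol(theta[:nc], k)
    Le = _theta_to_chol(theta[nc:2 * nc], k)
    G, E = Lg @ Lg.T, Le @ Le.T
    M = lam[:, None, None] * G[None] + E[None]
    try:
        ch = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return (_BIG, np.zeros_like(theta)) if want_grad else _BIG
    logdet = 2.0 * float(np.log(np.diagonal(ch, axis1=1, axis2=2)).sum())
    Yr = ds.rotated_Y()
    rhs = np.concatenate([X, Yr[:, :, None]], axis=2)
    sol = np.linalg.solve(M, rhs)
    A_full = np.einsum("nkp,nkq->pq", rhs, sol)
    nll, beta = _profile_from_parts(A_full, logdet, ds.n * k)
    if not want_grad:
        return nll
    p = X.shape[2]
    u = sol[:, :, p] - sol[:, :, :p] @ beta
    Minv = np.linalg.inv(M)
    S = Minv - u[:, :, None] * u[:, None, :]
    dG = 0.5 * np.einsum("n,nij->ij", lam, S)
    dE = 0.5 * S.sum(axis=0)
    grad = np.concatenate([_chol_grad(dG, Lg), _chol_grad(dE, Le)])
    return nll, grad


def _uni_nll(theta, ds: Dataset, X: np.ndarray, lam: np.ndarray,
             want_grad: bool):
    """Dedicated scalar (k = 1) implementation of the eigen path."""
    sg2 = math.exp(2.0 * theta[0])
    se2 = math.exp(2.0 * theta[1])
    m = lam * sg2 + se2
    if np.any(m <= 0):
        return (_BIG, np.zeros_like(theta)) if want_grad else _BIG
    y = ds.rotated_Y()[:, 0]
    Xm = X[:, 0, :]
    w = 1.0 / m
    rhs = np.column_stack([Xm, y])
    A_full = rhs.T @ (rhs * w[:, None])
    logdet = float(np.log(m).sum())
    nll, beta = _profile_from_parts(A_full, logdet, ds.n)
    if not want_grad:
        return nll
    r = y - Xm @ beta
    u2 = (r * w) ** 2
    s = w - u2
    d_sg2 = 0.5 * float(lam @ s)
    d_se2 = 0.5 * float(s.sum())
    return nll, np.array([2.0 * sg2 * d_sg2, 2.0 * se2 * d_se2])


# ---------------------------------------------------------------------------
# likelihood evaluation: generic dense path (kernel and/or missing data)


def build_covariance(G: np.ndarray, E: np.ndarray, phi2: np.ndarray,
                     kernel: np.ndarray | None = None,
                     gamma: np.ndarray | None = None,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Dense visit-major covariance for one pedigree block.

    ``Omega = G (x) phi2 + E (x) I [+ gamma (x) K]`` with rows/columns
    for masked-out (missing) cells deleted; ``mask`` is (n, k) True for
    observed.  Raises :class:`NumericalError` if the result is not
    positive definite.
    """
    nf = phi2.shape[0]
    omega = np.kron(G, phi2) + np.kron(E, np.eye(nf))
    if kernel is not None:
        if gamma is None:
            raise ValueError("kernel supplied without visit loadings")
        omega = omega + np.kron(np.atleast_2d(gamma), kernel)
    if mask is not None:
        obs = np.asarray(mask, dtype=bool).T.ravel()
        omega = omega[np.ix_(obs, obs)]
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        wmin = float(np.linalg.eigvalsh(omega)[0])
        raise NumericalError(
            f"covariance block not positive definite (min eigenvalue {wmin:.3e})"
        )
    return omega


def _kernel_gamma(theta_k: np.ndarray, k: int, kernel_mode: str):
    if kernel_mode == "shared":
        s = np.full(k, math.exp(theta_k[0]))
    else:
        s = np.asarray(theta_k, dtype=float)
    return np.outer(s, s), s


def _generic_nll(theta, ds: Dataset, g, snv_mode: str,
                 kernel_blocks, kernel_mode: str, want_grad: bool = False):
    """Dense per-pedigree evaluation; analytic gradient via the
    envelope theorem (mean parameters at their GLS optimum)."""
    k = ds.k
    nc = _n_chol(k)
    Lg = _theta_to_chol(theta[:nc], k)
    Le = _theta_to_chol(theta[nc:2 * nc], k)
    G, E = Lg @ Lg.T, Le @ Le.T
    gamma = s_vec = None
    if kernel_mode != "none":
        gamma, s_vec = _kernel_gamma(theta[2 * nc:], k, kernel_mode)
    logdet = 0.0
    A_full = None
    n_obs = 0
    cache = []
    for bi, sl in enumerate(ds.blocks):
        nf = sl.stop - sl.start
        omega = np.kron(G, ds.phi2[bi]) + np.kron(E, np.eye(nf))
        if gamma is not None:
            omega = omega + np.kron(gamma, kernel_blocks[bi])
        Xb = _design_block(ds, sl, g, snv_mode)
        yb = ds.Y[sl].T.ravel()
        obs = ~np.isnan(yb)
        if not obs.all():
            omega = omega[np.ix_(obs, obs)]
            Xb, yb = Xb[obs], yb[obs]
        n_obs += int(obs.sum())
        try:
            cf = scipy.linalg.cho_factor(omega, lower=True,
                                         check_finite=False)
        except (scipy.linalg.LinAlgError, ValueError):
            if want_grad:
                return _BIG, np.zeros_like(theta)
            return _BIG
        logdet += 2.0 * float(np.log(np.diag(cf[0])).sum())
        rhs = np.column_stack([Xb, yb])
        sol = scipy.linalg.cho_solve(cf, rhs, check_finite=False)
        contrib = rhs.T @ sol
        A_full = contrib if A_full is None else A_full + contrib
        if want_grad:
            cache.append((bi, cf, Xb, yb, obs, nf))
    nll, beta = _profile_from_parts(A_full, logdet, n_obs)
    if not want_grad:
        return nll
    dG = np.zeros((k, k))
    dE = np.zeros((k, k))
    dGam = np.zeros((k, k)) if gamma is not None else None
    for bi, cf, Xb, yb, obs, nf in cache:
        r = yb - Xb @ beta
        u = scipy.linalg.cho_solve(cf, r, check_finite=False)
        winv = scipy.linalg.cho_solve(cf, np.eye(len(r)), check_finite=False)
        W = winv - np.outer(u, u)
        if not obs.all():
            full = np.zeros((k * nf, k * nf))
            idx = np.nonzero(obs)[0]
            full[np.ix_(idx, idx)] = W
            W = full
        W4 = W.reshape(k, nf, k, nf)
        dG += 0.5 * np.einsum("sitj,ij->ts", W4, ds.phi2[bi])
        dE += 0.5 * np.einsum("siti->ts", W4)
        if dGam is not None:
            dGam += 0.5 * np.einsum("sitj,ij->ts", W4, kernel_blocks[bi])
    grad_parts = [_chol_grad(dG, Lg), _chol_grad(dE, Le)]
    if dGam is not None:
        ds_vec = 2.0 * dGam @ s_vec
        if kernel_mode == "shared":
            grad_parts.append(np.array([float(ds_vec @ s_vec)]))
        else:
            grad_parts.append(ds_vec)
    return nll, np.concatenate(grad_parts)


def _lowrank_nll(theta, ds: Dataset, g, snv_mode: str,
                 Z: np.ndarray, kernel_mode: str, want_grad: bool = False,
                 return_beta: bool = False):
    """Exact dense-kernel evaluation via the matrix inversion lemma.

    The kernel contribution ``s s' (x) Z Z'`` has rank m (the number of
    region variants), so with ``U = s (x) Z`` and block-diagonal
    ``A = G (x) 2*Phi + E (x) I``,

        Omega^-1 = A^-1 - A^-1 U (I_m + U' A^-1 U)^-1 U' A^-1
        log|Omega| = log|A| + log|I_m + U' A^-1 U|

    keeps every solve per-pedigree even though the kernel couples
    families.  Gradients are analytic (envelope theorem for the
    profiled mean).
    """
    k = ds.k
    nc = _n_chol(k)
    Lg = _theta_to_chol(theta[:nc], k)
    Le = _theta_to_chol(theta[nc:2 * nc], k)
    G, E = Lg @ Lg.T, Le @ Le.T
    _, s_vec = _kernel_gamma(theta[2 * nc:], k, kernel_mode)
    m = Z.shape[1]
    km = k * m

    logdetA = 0.0
    n_obs = 0
    M0 = None            # [X,y]' A^-1 [X,y]
    TV = np.zeros((km, 0))
    PV = np.zeros((km, km))
    cache = []
    p = None
    for bi, sl in enumerate(ds.blocks):
        nf = sl.stop - sl.start
        A = np.kron(G, ds.phi2[bi]) + np.kron(E, np.eye(nf))
        Xb = _design_block(ds, sl, g, snv_mode)
        yb = ds.Y[sl].T.ravel()
        Zb = Z[sl]
        Vb = np.zeros((nf * k, km))
        for a in range(k):
            Vb[a * nf:(a + 1) * nf, a * m:(a + 1) * m] = Zb
        obs = ~np.isnan(yb)
        if not obs.all():
            A = A[np.ix_(obs, obs)]
            Xb, yb, Vb = Xb[obs], yb[obs], Vb[obs]
        n_obs += int(obs.sum())
        if p is None:
            p = Xb.shape[1]
            TV = np.zeros((km, p + 1))
        try:
            cf = scipy.linalg.cho_factor(A, lower=True, check_finite=False)
        except (scipy.linalg.LinAlgError, ValueError):
            if want_grad:
                return _BIG, np.zeros_like(theta)
            return _BIG
        logdetA += 2.0 * float(np.log(np.diag(cf[0])).sum())
        rhs = np.column_stack([Xb, yb, Vb])
        sol = scipy.linalg.cho_solve(cf, rhs, check_finite=False)
        M0 = (rhs[:, :p + 1].T @ sol[:, :p + 1] if M0 is None
              else M0 + rhs[:, :p + 1].T @ sol[:, :p + 1])
        TV += Vb.T @ sol[:, :p + 1]
        PV += Vb.T @ sol[:, p + 1:]
        cache.append((bi, cf, Xb, yb, Vb, obs, nf, sol))

    # contract the visit index of V with the loadings: U = sum_a s_a V_a
    PV4 = PV.reshape(k, m, k, m)
    UAU = np.einsum("a,ambn,b->mn", s_vec, PV4, s_vec)
    UAXy = np.einsum("a,amp->mp", s_vec, TV.reshape(k, m, p + 1))
    cap = np.eye(m) + UAU
    try:
        cap_cf = scipy.linalg.cho_factor(cap, lower=True, check_finite=False)
    except (scipy.linalg.LinAlgError, ValueError):
        if want_grad:
            return _BIG, np.zeros_like(theta)
        return _BIG
    logdet = logdetA + 2.0 * float(np.log(np.diag(cap_cf[0])).sum())
    cap_inv_UAXy = scipy.linalg.cho_solve(cap_cf, UAXy, check_finite=False)
    A_full = M0 - UAXy.T @ cap_inv_UAXy
    nll, beta = _profile_from_parts(A_full, logdet, n_obs)
    if return_beta:
        return beta
    if not want_grad:
        return nll

    # residual pieces: w = A^-1 r per block, global capacitance correction
    UAr = np.zeros(m)
    w_blocks = []
    for bi, cf, Xb, yb, Vb, obs, nf, sol in cache:
        wb = sol[:, p] - sol[:, :p] @ beta
        w_blocks.append(wb)
        UAr += np.einsum("a,am->m", s_vec,
                         (Vb.T @ wb).reshape(k, m))
    c = scipy.linalg.cho_solve(cap_cf, UAr, check_finite=False)

    dG = np.zeros((k, k))
    dE = np.zeros((k, k))
    Vau = np.zeros((k, m))   # V_a' u accumulated over blocks
    for (bi, cf, Xb, yb, Vb, obs, nf, sol), wb in zip(cache, w_blocks):
        solV = sol[:, p + 1:]
        Qb = np.einsum("a,ram->rm", s_vec,
                       solV.reshape(-1, k, m))
        ub = wb - Qb @ c
        Ainv = scipy.linalg.cho_solve(cf, np.eye(len(wb)),
                                      check_finite=False)
        Wb = Ainv - Qb @ scipy.linalg.cho_solve(cap_cf, Qb.T,
                                                check_finite=False) \
            - np.outer(ub, ub)
        if not obs.all():
            full = np.zeros((k * nf, k * nf))
            idx = np.nonzero(obs)[0]
            full[np.ix_(idx, idx)] = Wb
            Wb = full
            ufull = np.zeros(k * nf)
            ufull[idx] = ub
            ub = ufull
            Vfull = np.zeros((k * nf, km))
            Vfull[idx] = Vb
            Vb = Vfull
        W4 = Wb.reshape(k, nf, k, nf)
        dG += 0.5 * np.einsum("sitj,ij->ts", W4, ds.phi2[bi])
        dE += 0.5 * np.einsum("siti->ts", W4)
        Vau += (Vb.T @ ub).reshape(k, m)

    # d/ds_a with dOmega/ds_a = V_a U' + U V_a'
    R = np.einsum("b,bman->amn", s_vec, PV4)       # R[a] = U' A^-1 V_a
    Uu = s_vec @ Vau
    ds_vec = np.empty(k)
    for a in range(k):
        UOVa = R[a] - UAU @ scipy.linalg.cho_solve(cap_cf, R[a],
                                                   check_finite=False)
        ds_vec[a] = float(np.trace(UOVa) - Vau[a] @ Uu)
    grad_parts = [_chol_grad(dG, Lg), _chol_grad(dE, Le)]
    if kernel_mode == "shared":
        grad_parts.append(np.array([float(ds_vec @ s_vec)]))
    else:
        grad_parts.append(ds_vec)
    return nll, np.concatenate(grad_parts)


# ---------------------------------------------------------------------------
# fitting


def _extract_beta(ds: Dataset, theta, g, snv_mode, kernel_blocks, kernel_mode,
                  kernel_factor=None):
    """Recompute the profiled GLS mean estimate at the optimum."""
    k = ds.k
    nc = _n_chol(k)
    if kernel_mode != "none" and kernel_factor is not None:
        return _lowrank_nll(theta, ds, g, snv_mode,
                            np.asarray(kernel_factor, dtype=float),
                            kernel_mode, return_beta=True)
    if kernel_mode == "none" and ds.complete:
        lam = ds.eigenvalues()
        X = _design_eig(ds, g, snv_mode)
        Lg = _theta_to_chol(theta[:nc], k)
        Le = _theta_to_chol(theta[nc:2 * nc], k)
        M = lam[:, None, None] * (Lg @ Lg.T)[None] + (Le @ Le.T)[None]
        rhs = np.concatenate([X, ds.rotated_Y()[:, :, None]], axis=2)
        sol = np.linalg.solve(M, rhs)
        A_full = np.einsum("nkp,nkq->pq", rhs, sol)
        _, beta = _profile_from_parts(A_full, 0.0, ds.n * k)
        return beta
    Lg = _theta_to_chol(theta[:nc], k)
    Le = _theta_to_chol(theta[nc:2 * nc], k)
    G, E = Lg @ Lg.T, Le @ Le.T
    gamma = None
    if kernel_mode != "none":
        gamma, _ = _kernel_gamma(theta[2 * nc:], k, kernel_mode)
    A_full = None
    for bi, sl in enumerate(ds.blocks):
        nf = sl.stop - sl.start
        omega = np.kron(G, ds.phi2[bi]) + np.kron(E, np.eye(nf))
        if gamma is not None:
            omega = omega + np.kron(gamma, kernel_blocks[bi])
        Xb = _design_block(ds, sl, g, snv_mode)
        yb = ds.Y[sl].T.ravel()
        obs = ~np.isnan(yb)
        omega = omega[np.ix_(obs, obs)]
        rhs = np.column_stack([Xb[obs], yb[obs]])
        cf = scipy.linalg.cho_factor(omega, lower=True, check_finite=False)
        sol = scipy.linalg.cho_solve(cf, rhs, check_finite=False)
        contrib = rhs.T @ sol
        A_full = contrib if A_full is None else A_full + contrib
    _, beta = _profile_from_parts(A_full, 0.0, 1)
    return beta


def _split_kernel(ds: Dataset, kernel: np.ndarray | list | None):
    """Kernel as per-block matrices aligned with the dataset blocks."""
    if kernel is None:
        return None
    if isinstance(kernel, list):
        return kernel
    return [np.asarray(kernel)[sl, sl] for sl in ds.blocks]


def loglik(ds: Dataset, params: VCParameters, *, g=None,
           snv_mode: str = "none", kernel=None) -> float:
    """Exact log-likelihood at fixed parameters (no profiling).

    The mean is taken from ``params.mean_betas`` (and ``snv_beta``); the
    covariance from G, E and, if a kernel is given, the kernel loadings.
    """
    k = ds.k
    if params.mean_betas is None:
        raise ValueError("params.mean_betas required to evaluate loglik")
    mean = ds.C @ params.mean_betas.T
    if snv_mode != "none" and g is not None:
        b = np.atleast_1d(np.asarray(params.snv_beta, dtype=float))
        if b.size == 1:
            b = np.repeat(b, k)
        mean = mean + np.asarray(g, dtype=float)[:, None] * b[None, :]
    resid = ds.Y - mean
    kb = _split_kernel(ds, kernel)
    gamma = None
    if params.kernel_loadings is not None:
        s = np.asarray(params.kernel_loadings, dtype=float)
        gamma = np.outer(s, s)
    total = 0.0
    for bi, sl in enumerate(ds.blocks):
        nf = sl.stop - sl.start
        omega = np.kron(params.G, ds.phi2[bi]) + np.kron(params.E, np.eye(nf))
        if gamma is not None and kb is not None:
            omega = omega + np.kron(gamma, kb[bi])
        rb = resid[sl].T.ravel()
        obs = ~np.isnan(rb)
        omega = omega[np.ix_(obs, obs)]
        rb = rb[obs]
        cf = scipy.linalg.cho_factor(omega, lower=True, check_finite=False)
        logdet = 2.0 * float(np.log(np.diag(cf[0])).sum())
        quad = float(rb @ scipy.linalg.cho_solve(cf, rb, check_finite=False))
        total += -0.5 * (obs.sum() * _LOG2PI + logdet + quad)
    return total


def _initial_thetas(ds: Dataset, kernel_mode: str,
                    init_theta: np.ndarray | None) -> list[np.ndarray]:
    k = ds.k
    nc = _n_chol(k)
    n_kern = {"none": 0, "shared": 1, "free": k}[kernel_mode]
    total = 2 * nc + n_kern
    thetas = []
    if init_theta is not None:
        t0 = np.asarray(init_theta, dtype=float)
        if t0.size == 2 * nc and n_kern:
            # warm start from a kernel-free fit: start the kernel small
            pad = (np.full(1, -4.0) if kernel_mode == "shared"
                   else np.full(k, 0.02))
            t0 = np.concatenate([t0, pad])
        if t0.size != total:
            raise ValueError("init_theta has the wrong length")
        thetas.append(t0)
    for h2g in (0.4, 0.15, 0.55):
        G0, E0 = _cov_init(ds, h2g)
        tg = _chol_to_theta(np.linalg.cholesky(G0))
        te = _chol_to_theta(np.linalg.cholesky(E0))
        parts = [tg, te]
        if n_kern:
            parts.append(np.full(1, -4.0) if kernel_mode == "shared"
                         else np.full(k, 0.02))
        thetas.append(np.concatenate(parts))
    return thetas


def fit_ml(ds: Dataset, *, g: np.ndarray | None = None,
           snv_mode: str = "none", kernel=None, kernel_mode: str = "none",
           kernel_factor: np.ndarray | None = None,
           init_theta: np.ndarray | None = None,
           max_restarts: int = 2) -> FitResult:
    """Maximize the VC likelihood for one model specification.

    ``snv_mode``: 'none' (null model), 'shared' (one allelic effect for
    all visits — the constrained model; for k = 1 the measured-genotype
    model), or 'free' (per-visit effects).  ``kernel_mode`` likewise
    controls the gene-kernel component; pass either ``kernel`` (a dense
    individuals x individuals matrix, used per pedigree block) or
    ``kernel_factor`` (an n x m factor Z with K = Z Z', aligned to
    ``ds.ids``, evaluated exactly across families via the matrix
    inversion lemma).  ``init_theta`` warm-starts the
    covariance parameters (e.g. from the null fit), which also makes the
    nesting logL_alt >= logL_null structural.  Deterministic given data
    and starting values; non-convergence is flagged, never raised.
    """
    if snv_mode not in ("none", "shared", "free"):
        raise ValueError(f"unknown snv_mode {snv_mode!r}")
    if kernel_mode not in ("none", "shared", "free"):
        raise ValueError(f"unknown kernel_mode {kernel_mode!r}")
    if snv_mode != "none" and g is None:
        raise ValueError("snv_mode requires a dosage vector g")
    if snv_mode == "free" and ds.k < 2:
        raise ValueError("per-visit SNV effects require k >= 2 visits")
    if kernel_mode != "none" and kernel is None and kernel_factor is None:
        raise ValueError("kernel_mode requires a kernel matrix or factor")
    if ds.n < 2:
        raise ValueError("need at least 2 phenotyped individuals")
    if g is not None:
        g = np.asarray(g, dtype=float)
        if np.isnan(g).any():
            raise ValueError("dosages must be imputed before fitting")
    _check_design(ds, g, snv_mode)

    k = ds.k
    nc = _n_chol(k)
    kernel_blocks = _split_kernel(ds, kernel)
    use_eig = kernel_mode == "none" and ds.complete

    if use_eig:
        lam = ds.eigenvalues()
        X = _design_eig(ds, g, snv_mode)
        if k == 1:
            fun = lambda th: _uni_nll(th, ds, X, lam, True)  # noqa: E731
        else:
            fun = lambda th: _eig_nll(th, ds, X, lam, True)  # noqa: E731
        jac = True
    elif kernel_mode != "none" and kernel_factor is not None:
        Z = np.asarray(kernel_factor, dtype=float)
        if Z.shape[0] != ds.n:
            raise ValueError("kernel_factor rows must match the dataset")
        fun = lambda th: _lowrank_nll(th, ds, g, snv_mode,  # noqa: E731
                                      Z, kernel_mode, True)
        jac = True
    else:
        fun = lambda th: _generic_nll(th, ds, g, snv_mode,  # noqa: E731
                                      kernel_blocks, kernel_mode, True)
        jac = True

    n_kern = {"none": 0, "shared": 1, "free": k}[kernel_mode]
    bounds = []
    for _ in range(2):
        bounds += [(_DIAG_LB, _DIAG_UB)] * k + [(None, None)] * (nc - k)
    if kernel_mode == "shared":
        bounds += [(_DIAG_LB, _DIAG_UB)]
    elif kernel_mode == "free":
        bounds += [(None, None)] * k

    thetas = _initial_thetas(ds, kernel_mode, init_theta)
    best = None
    tried = 0
    for t0 in thetas:
        if tried > max_restarts and best is not None and best.success:
            break
        tried += 1
        res = minimize(fun, t0, jac=jac, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success and init_theta is not None:
            break  # warm start converged; canned restarts not needed
        if best.success and best.fun < _BIG / 2:
            break
    res = best

    theta = res.x
    Lg = _theta_to_chol(theta[:nc], k)
    Le = _theta_to_chol(theta[nc:2 * nc], k)
    G, E = Lg @ Lg.T, Le @ Le.T
    s = None
    if kernel_mode != "none":
        _, s = _kernel_gamma(theta[2 * nc:], k, kernel_mode)
    beta = _extract_beta(ds, theta, g, snv_mode, kernel_blocks, kernel_mode,
                         kernel_factor)
    c = ds.C.shape[1]
    mean_betas = np.empty((k, c))
    for t in range(k):
        mean_betas[t] = beta[t * c:(t + 1) * c]
    snv_beta = None
    if snv_mode == "shared":
        snv_beta = float(beta[k * c])
    elif snv_mode == "free":
        snv_beta = np.asarray(beta[k * c:k * c + k])
    params = VCParameters(G=G, E=E, mean_betas=mean_betas,
                          covariate_names=list(ds.covariate_names),
                          snv_beta=snv_beta, kernel_loadings=s)
    diag_idx = np.concatenate([np.arange(k), nc + np.arange(k)])
    at_floor = np.any(theta[diag_idx.astype(int)] <= _DIAG_LB + 1e-3)
    if kernel_mode == "shared":
        at_floor = at_floor or theta[2 * nc] <= _DIAG_LB + 1e-3
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else float("nan")
    return FitResult(params=params, loglik=-float(res.fun),
                     converged=bool(res.success), n_iter=int(res.nit),
                     grad_norm=grad_norm, boundary=bool(at_floor),
                     theta=theta, n_obs=int(np.sum(~np.isnan(ds.Y))))
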