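"""Variance-component (SKAT-type) score test for CpG blocks.

The trait x is the response of a linear (mixed) model with covariates C; the
block of p CpGs enters through a random effect whose variance is tested
against zero.  With kernel K = Z Z' (Z the centered, optionally scaled,
weighted block matrix) the score statistic is

    Q = x' P0 K P0 x,

where P0 is the projection of the fitted null model,
``P0 = V^{-1} - V^{-1} C (C' V^{-1} C)^{-1} C' V^{-1}``.  For unrelated
samples V = sigma_e^2 I; for families V = sigma_g^2 * 2*Phi + sigma_e^2 I
with Phi the pedigree kinship matrix and (sigma_g^2, sigma_e^2) estimated by
REML.  Under the null Q follows a mixture sum_j lambda_j chi2_1 with
lambda_j the nonzero eigenvalues of P0^{1/2} K P0^{1/2}; tail probabilities
come from numerical inversion of the characteristic function with a
moment-matching (Liu) fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

from .io_formats import ValidationError
from .kinship import KinshipMatrix

_EIG_REL_TOL = 1e-10


@dataclass
class NullModel:
    """Fitted covariate-only model used by the score tests."""

    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    P0: np.ndarray
    loglik: float
    x: np.ndarray
    C: np.ndarray
    boundary: bool = False
    P0x: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.P0x = self.P0 @ self.x

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass
class QuadFormResult:
    Q: float
    eigenvalues: np.ndarray
    pvalue: float
    method_used: str  # "davies" | "liu" | "degenerate"


def _check_design(C: np.ndarray, n: int) -> np.ndarray:
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != n:
        C = C.T
    if C.shape[0] != n:
        raise ValidationError("C has wrong sample dimension")
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValidationError("covariate matrix C is rank deficient")
    return C


def fit_null_lm(x: np.ndarray, C: np.ndarray) -> NullModel:
    """OLS null model for unrelated samples; sigma_e2 = RSS / (n - r)."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    C = _check_design(C, n)
    r = C.shape[1]
    beta, *_ = np.linalg.lstsq(C, x, rcond=None)
    resid = x - C @ beta
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(x @ x)):
        raise ValidationError("degenerate fit: x lies in the column space of C")
    sigma_e2 = rss / (n - r)
    H = C @ np.linalg.solve(C.T @ C, C.T)
    P0 = (np.eye(n) - H) / sigma_e2
    loglik = -0.5 * ((n - r) * np.log(sigma_e2) + (n - r))
    return NullModel(beta=beta, sigma_g2=0.0, sigma_e2=sigma_e2, P0=P0,
                     loglik=loglik, x=x, C=C)


def _reml_profile(
    xt: np.ndarray, Ct: np.ndarray, d: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray, float, bool]:
    """Profile REML over the variance ratio delta = sigma_g2 / sigma_e2.

    Inputs are already rotated into the eigenbasis of 2*Phi (eigenvalues
    ``d``).  A coarse log10-grid search over [1e-5, 1e5] is refined by
    bounded scalar minimization.  Returns (delta, sigma_e2, beta,
    cov_beta_unscaled, restricted loglik, boundary_flag) where cov_beta =
    sigma_e2 * cov_beta_unscaled.
    """
    n, r = Ct.shape

    def neg_reml(log10_delta: float) -> float:
        delta = 10.0 ** log10_delta
        w = 1.0 / (delta * d + 1.0)
        CtW = Ct * w[:, None]
        A = CtW.T @ Ct
        b = CtW.T @ xt
        beta = np.linalg.solve(A, b)
        resid = xt - Ct @ beta
        rss_w = float(resid @ (w * resid))
        sigma_e2 = rss_w / (n - r)
        if sigma_e2 <= 0:
            return np.inf
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return 0.5 * (
            (n - r) * np.log(sigma_e2)
            + np.sum(np.log(delta * d + 1.0))
            + logdet_A
            + (n - r)
        )

    grid = np.linspace(-5.0, 5.0, 41)
    values = np.array([neg_reml(g) for g in grid])
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg_reml, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    log10_delta = float(res.x)
    # an interior optimum that still beats the refined one can only be the
    # grid point itself (flat objective); keep the better of the two
    if values[i] < res.fun:
        log10_delta = float(grid[i])
    boundary = i == 0 or i == len(grid) - 1
    delta = 10.0 ** log10_delta
    if boundary and i == 0:
        # indistinguishable from sigma_g2 = 0; report the boundary
        delta = 0.0
    w = 1.0 / (delta * d + 1.0)
    CtW = Ct * w[:, None]
    A = CtW.T @ Ct
    beta = np.linalg.solve(A, CtW.T @ xt)
    resid = xt - Ct @ beta
    sigma_e2 = float(resid @ (w * resid)) / (n - r)
    sign, logdet_A = np.linalg.slogdet(A)
    loglik = -0.5 * (
        (n - r) * np.log(sigma_e2)
        + np.sum(np.log(delta * d + 1.0))
        + logdet_A
        + (n - r)
    )
    return delta, sigma_e2, beta, np.linalg.inv(A), loglik, boundary


def fit_null_lmm(x: np.ndarray, C: np.ndarray, kin: KinshipMatrix) -> NullModel:
    """Kinship LMM null model, x = C beta + g + e with g ~ N(0, sigma_g2 2Phi).

    Variance components are estimated by REML, profiling over the ratio
    delta = sigma_g2/sigma_e2 using the (cached) spectral decomposition of
    2*Phi.  A warning flag is set if the optimum sits on the search boundary.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    if kin.n != n:
        raise ValidationError("kinship dimension does not match samples")
    C = _check_design(C, n)
    d, U = kin.eig_2phi()
    xt = U.T @ x
    Ct = U.T @ C
    delta, sigma_e2, beta, Ainv, loglik, boundary = _reml_profile(xt, Ct, d)
    sigma_g2 = delta * sigma_e2
    if boundary:
        warnings.warn("REML optimum at the boundary of the delta search range",
                      stacklevel=2)
    vinv_diag = 1.0 / (sigma_g2 * d + sigma_e2)
    Vinv = (U * vinv_diag[None, :]) @ U.T
    VinvC = Vinv @ C
    P0 = Vinv - VinvC @ np.linalg.solve(C.T @ VinvC, VinvC.T)
    P0 = 0.5 * (P0 + P0.T)
    return NullModel(beta=beta, sigma_g2=sigma_g2, sigma_e2=sigma_e2, P0=P0,
                     loglik=loglik, x=x, C=C, boundary=boundary)


def _prepare_block(
    Y_block: np.ndarray, weights: np.ndarray | None, scale_option: str
) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(Y_block, dtype=float))
    p = Z.shape[1]
    Z = Z - Z.mean(axis=0)
    if scale_option == "center_scale":
        sd = Z.std(axis=0, ddof=1)
        nonconst = sd > 0
        Z = Z[:, nonconst] / sd[nonconst]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[nonconst]
    elif scale_option != "center":
        raise ValidationError(f"unknown scale_option {scale_option!r}")
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.shape[0] != Z.shape[1]:
            raise ValidationError("weights length does not match block size")
        if np.any(weights < 0):
            raise ValidationError("weights must be nonnegative")
        Z = Z * np.sqrt(weights)[None, :]
    return Z


def vc_score_test(
    null: NullModel,
    Y_block: np.ndarray,
    weights: np.ndarray | None = None,
    scale_option: str = "center",
) -> QuadFormResult:
    """Score test of the block variance component against zero.

    ``Q = x' P0 K P0 x`` with K = Z Z'; the null mixture weights are the
    nonzero eigenvalues of Z' P0 Z (identical to those of P0^{1/2} K
    P0^{1/2}).  Columns are centered by default; ``scale_option=
    "center_scale"`` additionally standardizes them.  ``weights`` (all 1 by
    default) multiply columns by sqrt(w_j).
    """
    Y_block = np.atleast_2d(np.asarray(Y_block, dtype=float))
    if Y_block.shape[1] == 0:
        raise ValidationError("empty block")
    if Y_block.shape[0] != null.n:
        raise ValidationError("block sample dimension does not match null model")
    Z = _prepare_block(Y_block, weights, scale_option)
    if Z.shape[1] == 0 or not np.any(Z):
        warnings.warn("all-constant block; p-value set to 1", stacklevel=2)
        return QuadFormResult(0.0, np.zeros(0), 1.0, "degenerate")
    s = Z.T @ null.P0x
    Q = float(s @ s)
    G = Z.T @ (null.P0 @ Z)
    lam = np.linalg.eigvalsh(0.5 * (G + G.T))
    lam = np.clip(lam, 0.0, None)
    lam = lam[lam > _EIG_REL_TOL * lam.max()] if lam.max() > 0 else lam[:0]
    if lam.size == 0:
        warnings.warn("block has no variation after projection; p-value 1",
                      stacklevel=2)
        return QuadFormResult(Q, lam, 1.0, "degenerate")
    pvalue, method = davies_pvalue(Q, lam)
    return QuadFormResult(Q, lam, pvalue, method)


# ---------------------------------------------------------------------------
# mixture-of-chi-square tail probabilities


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching approximation to P(sum lam_j chi2_1 > q)."""
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        ncp = s1 * a**3 - a**2
        df = a**2 - 2.0 * ncp
    else:
        ncp = 0.0
        df = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    mu_x = df + ncp
    sigma_x = np.sqrt(2.0 * (df + 2.0 * ncp))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    p = float(stats.ncx2.sf(t, df, ncp)) if ncp > 0 else float(stats.chi2.sf(t, df))
    return max(p, 1e-300)  # keep p strictly positive in extreme tails


def davies_pvalue(q: float, lambdas: np.ndarray) -> tuple[float, str]:
    """Upper-tail probability of a positive mixture of 1-df chi-squares.

    The characteristic function is inverted numerically (Imhof's integral
    representation, absolute tolerance 1e-10).  If the integrator fails, the
    estimated error dominates the value, or the result falls outside (0, 1],
    the Liu moment-matching approximation is used instead; the second return
    value records which route produced the p-value.
    """
    lam = np.asarray(lambdas, dtype=float).ravel()
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValidationError("no positive mixture weights")
    if q <= 0:
        return 1.0, "davies"
    # normalize by the leading weight (the mixture law is scale equivariant)
    s = lam.max()
    lam = lam / s
    q = q / s
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        # exactly a scaled chi-square; invert in closed form
        return float(stats.chi2.sf(q / lam[0], lam.size)), "davies"

    def integrand(u: float) -> float:
        lu = lam * u
        theta = 0.5 * np.sum(np.arctan(lu)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p(lu * lu)))
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        try:
            val, err = integrate.quad(
                integrand, 0.0, np.inf, epsabs=1e-11, epsrel=1e-11, limit=5000
            )
        except Exception:
            return _liu_pvalue(q, lam), "liu"
    p = 0.5 + val / np.pi
    if (not np.isfinite(p)) or p <= 0.0 or p > 1.0 or err > max(1e-9, 0.05 * p):
        return _liu_pvalue(q, lam), "liu"
    return float(min(p, 1.0)), "davies"
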