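"""Principal component of explained variation (PCEV) region test.

PCEV finds the linear combination ``y_pcev = Y w`` of a block of p CpGs that
maximizes h2(w), the proportion of the combination's variance explained by
the trait x after adjusting for confounders C.  h2 is the leading eigenvalue
ratio of the generalized problem V_R^{-1} V_G, where V_G is the covariance
of the x-fitted values and V_R the residual covariance.  Testing
``h2(w_pcev) = 0`` uses the data only once and avoids the type-I inflation
of naively correlating the optimized component with x.

For a single trait the hypothesis matrix has rank one, so the largest-root
statistic has an exact F form under Gaussian residuals:

    F = d * (n - r - p) / p  ~  F(p, n - r - p),  d = h2 / (1 - h2).

A permutation fallback (permuting confounder-residualized x) is provided for
settings where the normality assumption is in doubt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ValidationError

_JITTER = 1e-10


@dataclass
class PcevFit:
    w: np.ndarray  # p loadings, w' V_R w = 1
    h2: float
    component: np.ndarray  # n scores, residualized-Y @ w
    V_G: np.ndarray
    V_R: np.ndarray
    n: int
    p: int
    r: int


def _with_intercept(C: np.ndarray | None, n: int) -> np.ndarray:
    if C is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != n:
        C = C.T
    # append an intercept only if the constant vector is not already in the
    # column space (keeps transformed covariate sets full rank)
    ones = np.ones(n)
    resid = ones - C @ np.linalg.lstsq(C, ones, rcond=None)[0]
    if np.linalg.norm(resid) < 1e-8 * np.sqrt(n):
        return C
    return np.column_stack([ones, C])


def _residualize(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(C, A, rcond=None)
    return A - C @ coef


def _h2_direction(Yres: np.ndarray, xres: np.ndarray) -> tuple[float, np.ndarray]:
    """Leading eigenpair of V_R^{-1} V_G for C-residualized data."""
    n, p = Yres.shape
    xtx = float(xres @ xres)
    if xtx <= 0:
        raise ValidationError("trait is constant after residualization")
    fitted = np.outer(xres, (xres @ Yres) / xtx)
    resid = Yres - fitted
    V_G = fitted.T @ fitted / n
    V_R = resid.T @ resid / n
    # symmetric reformulation via Cholesky of V_R, with escalating jitter
    jitter = 0.0
    scale = np.trace(V_R) / p if p else 1.0
    for _ in range(12):
        try:
            L = np.linalg.cholesky(V_R + jitter * np.eye(p))
            break
        except np.linalg.LinAlgError:
            jitter = _JITTER * scale if jitter == 0.0 else jitter * 10.0
    else:  # pragma: no cover - pathological input
        raise ValidationError("residual covariance could not be factorized")
    Linv_Vg = np.linalg.solve(L, V_G)
    M = np.linalg.solve(L, Linv_Vg.T).T  # L^{-1} V_G L^{-T}
    M = 0.5 * (M + M.T)
    evals, evecs = np.linalg.eigh(M)
    d = float(max(evals[-1], 0.0))
    u = evecs[:, -1]
    w = np.linalg.solve(L.T, u)
    # normalize under the V_R metric
    norm = float(np.sqrt(w @ V_R @ w))
    if norm > 0:
        w = w / norm
    return d, w


def fit_pcev(
    Y: np.ndarray, x: np.ndarray, C: np.ndarray | None = None
) -> PcevFit:
    """Fit PCEV for one block against a single trait.

    ``Y`` is n x p methylation, ``x`` a length-n trait, ``C`` optional
    confounders (an intercept is appended if absent).  Requires
    ``p <= n - r - 2`` so the residual covariance is invertible.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    if Y.shape[0] != n:
        raise ValidationError("Y and x have mismatched sample counts")
    p = Y.shape[1]
    Cmat = _with_intercept(C, n)
    r = Cmat.shape[1]
    if np.linalg.matrix_rank(np.column_stack([x, Cmat])) < r + 1:
        raise ValidationError("[x, C] is rank deficient")
    if p > n - r - 2:
        raise ValidationError(
            f"block size p={p} too large for n={n}, r={r} "
            f"(need p <= n - r - 2 = {n - r - 2}); split the block first"
        )
    Yres = _residualize(Y, Cmat)
    xres = _residualize(x[:, None], Cmat).ravel()
    d, w = _h2_direction(Yres, xres)
    h2 = d / (1.0 + d)
    xtx = float(xres @ xres)
    fitted = np.outer(xres, (xres @ Yres) / xtx)
    resid = Yres - fitted
    return PcevFit(
        w=w,
        h2=h2,
        component=Yres @ w,
        V_G=fitted.T @ fitted / n,
        V_R=resid.T @ resid / n,
        n=n,
        p=p,
        r=r,
    )


def pcev_test_analytic(fit: PcevFit) -> float:
    """Exact single-root F test of h2 = 0 (one trait, Gaussian residuals)."""
    df2 = fit.n - fit.r - fit.p
    if df2 <= 0:
        raise ValidationError(f"nonpositive denominator df (n - r - p = {df2})")
    d = fit.h2 / (1.0 - fit.h2)
    F = d * df2 / fit.p
    return float(stats.f.sf(F, fit.p, df2))


def pcev_statistic(fit: PcevFit) -> float:
    """The F statistic of the analytic test (for reporting)."""
    df2 = fit.n - fit.r - fit.p
    return float(fit.h2 / (1.0 - fit.h2) * df2 / fit.p)


def pcev_test_permutation(
    Y: np.ndarray,
    x: np.ndarray,
    C: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for h2 = 0.

    The confounder-residualized trait is permuted ``n_perm`` times and h2
    recomputed against the residualized block;
    ``p = (1 + #{h2_perm >= h2_obs}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    Cmat = _with_intercept(C, n)
    Yres = _residualize(Y, Cmat)
    xres = _residualize(x[:, None], Cmat).ravel()
    d_obs, _ = _h2_direction(Yres, xres)
    h2_obs = d_obs / (1.0 + d_obs)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        xp = xres[rng.permutation(n)]
        d_p, _ = _h2_direction(Yres, xp)
        if d_p / (1.0 + d_p) >= h2_obs - 1e-15:
            count += 1
    return (1 + count) / (n_perm + 1)
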