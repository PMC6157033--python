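"""Per-CpG association tests.

The unrelated-sample test regresses the trait on covariates plus one CpG and
applies the two-sided t test to the CpG coefficient.  The family test fits a
kinship LMM with the same fixed effects and applies a Wald z test, with
variance components re-estimated under the alternative for each CpG (a fast
approximation reusing the covariate-only null components is available).
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .io_formats import AssociationResult, ValidationError
from .kinship import KinshipMatrix
from .vc_score import NullModel, _check_design, _reml_profile


def cpg_lm_test(
    x: np.ndarray,
    C: np.ndarray,
    y_cpg: np.ndarray,
    unit_id: str = "",
    gene_id: str = "",
    chrom: str = "",
) -> AssociationResult:
    """OLS t test of one CpG's coefficient in ``x ~ C + y_cpg``."""
    x = np.asarray(x, dtype=float).ravel()
    y_cpg = np.asarray(y_cpg, dtype=float).ravel()
    n = x.shape[0]
    C = _check_design(C, n)
    if np.ptp(y_cpg) == 0.0:
        warnings.warn(f"constant CpG {unit_id!r}; p-value set to 1", stacklevel=2)
        return AssociationResult(unit_id, gene_id, chrom, 1, "univariate_lm",
                                 0.0, n - C.shape[1] - 1, 1.0)
    design = np.column_stack([C, y_cpg])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("design [C, y_cpg] is rank deficient")
    fit = sm.OLS(x, design).fit()
    t = float(fit.tvalues[-1])
    p = float(fit.pvalues[-1])
    return AssociationResult(unit_id, gene_id, chrom, 1, "univariate_lm",
                             t, int(fit.df_resid), max(p, np.nextafter(0, 1)))


def cpg_lmm_test(
    x: np.ndarray,
    C: np.ndarray,
    y_cpg: np.ndarray,
    kin: KinshipMatrix,
    unit_id: str = "",
    gene_id: str = "",
    chrom: str = "",
    null: NullModel | None = None,
    fast_approx: bool = False,
) -> AssociationResult:
    """Wald z test of one CpG in the kinship LMM ``x = [C, y] b + g + e``.

    ``g ~ N(0, sigma_g2 * 2Phi)``.  By default the variance components are
    re-estimated under the alternative for each CpG; with
    ``fast_approx=True`` (requires ``null``) the covariate-only null
    components are reused and only the fixed effects are refit by GLS.
    """
    x = np.asarray(x, dtype=float).ravel()
    y_cpg = np.asarray(y_cpg, dtype=float).ravel()
    n = x.shape[0]
    C = _check_design(C, n)
    if kin.n != n:
        raise ValidationError("kinship dimension does not match samples")
    if np.ptp(y_cpg) == 0.0:
        warnings.warn(f"constant CpG {unit_id!r}; p-value set to 1", stacklevel=2)
        return AssociationResult(unit_id, gene_id, chrom, 1, "univariate_lmm",
                                 0.0, 1, 1.0)
    design = np.column_stack([C, y_cpg])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("design [C, y_cpg] is rank deficient")
    d, U = kin.eig_2phi()
    xt = U.T @ x
    Xt = U.T @ design
    if fast_approx:
        if null is None:
            raise ValidationError("fast_approx requires a fitted null model")
        delta = null.sigma_g2 / null.sigma_e2 if null.sigma_e2 > 0 else 0.0
        w = 1.0 / (delta * d + 1.0)
        XtW = Xt * w[:, None]
        A = XtW.T @ Xt
        beta = np.linalg.solve(A, XtW.T @ xt)
        resid = xt - Xt @ beta
        sigma_e2 = float(resid @ (w * resid)) / (n - design.shape[1])
        Ainv = np.linalg.inv(A)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, sigma_e2, beta, Ainv, _, _ = _reml_profile(xt, Xt, d)
    se = float(np.sqrt(sigma_e2 * Ainv[-1, -1]))
    t = float(beta[-1] / se)
    # t reference with residual df: exact in the identity-kinship collapse,
    # a standard small-sample refinement otherwise
    df = n - design.shape[1]
    p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationResult(unit_id, gene_id, chrom, 1, "univariate_lmm",
                             t, df, max(p, np.nextafter(0, 1)))
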