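"""Association tests, multiple-testing utilities and meta-analysis.

Quantitative burden tests are ordinary least squares on INT phenotypes with
two-sided t-test p-values; binary tests are maximum-likelihood logistic
regression with Wald statistics, with Firth's penalized logistic regression
(Jeffreys-prior penalty) as the fallback under separation or small counts.
Multiple testing: Bonferroni and Benjamini-Hochberg; scan-level inflation is
summarized by the genomic inflation factor lambda_GC.  Replication evidence
is combined with a DerSimonian-Laird inverse-variance-weighted
random-effects meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssocResult",
    "linear_burden_test",
    "logistic_burden_test",
    "firth_logistic",
    "bonferroni_threshold",
    "bh_fdr",
    "genomic_lambda",
    "ivw_random_effects_meta",
]

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # ~0.4549


@dataclass
class AssocResult:
    """One burden association: effect, uncertainty and test metadata."""

    unit_id: str
    phenotype: str
    beta: float  # beta for linear tests, log-OR for logistic/Firth
    se: float
    ci_low: float
    ci_high: float
    p: float
    test: str  # "linear-t", "logistic-wald", "firth", "ivw-re-meta"
    n: int
    carrier_count: int | None = None
    converged: bool = True
    notes: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        if self.test in ("logistic-wald", "firth"):
            return float(np.exp(self.beta))
        raise AttributeError("odds ratio defined only for logistic-type tests")

    def to_dict(self) -> dict:
        d = {
            "unit_id": self.unit_id,
            "phenotype": self.phenotype,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "test": self.test,
            "n": self.n,
            "carrier_count": self.carrier_count,
        }
        return d


def _design(burden: np.ndarray, covariates=None) -> np.ndarray:
    X = np.column_stack([np.ones(len(burden)), np.asarray(burden, dtype=float)])
    if covariates is not None:
        C = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    return X


def _covariate_names(covariates) -> list[str]:
    if covariates is None:
        return []
    if isinstance(covariates, pd.DataFrame):
        return list(covariates.columns)
    C = np.asarray(covariates)
    k = 1 if C.ndim == 1 else C.shape[1]
    return [f"cov{j}" for j in range(k)]


def linear_burden_test(
    burden: np.ndarray,
    phenotype: np.ndarray,
    covariates=None,
    unit_id: str = "unit",
    pheno_name: str = "trait",
) -> AssocResult:
    """OLS of an (INT) quantitative phenotype on burden plus covariates.

    p is a two-sided t-test on the burden coefficient; the 95% CI uses the
    t quantile at the residual degrees of freedom.
    """
    burden = np.asarray(burden, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if np.var(burden) == 0:
        raise ValueError("no carriers after filtering: burden has zero variance")
    X = _design(burden, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = ["intercept", "burden"] + _covariate_names(covariates)
        from .phenotypes import _collinear_columns

        raise ValueError(f"collinear design: {_collinear_columns(X, names)}")
    fit = sm.OLS(y, X).fit()
    beta, se = fit.params[1], fit.bse[1]
    tq = stats.t.ppf(0.975, df=fit.df_resid)
    return AssocResult(
        unit_id=unit_id,
        phenotype=pheno_name,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - tq * se),
        ci_high=float(beta + tq * se),
        p=float(fit.pvalues[1]),
        test="linear-t",
        n=len(y),
        carrier_count=int(np.sum(burden >= 1)),
    )


def logistic_burden_test(
    burden: np.ndarray,
    phenotype: np.ndarray,
    covariates=None,
    unit_id: str = "unit",
    pheno_name: str = "trait",
) -> AssocResult:
    """Maximum-likelihood logistic regression; reports log-OR and Wald CI.

    Separation or non-convergence is flagged via ``converged=False`` so the
    caller can route the unit to :func:`firth_logistic`.
    """
    burden = np.asarray(burden, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = _design(burden, covariates)
    converged = True
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # non-convergence is reported through the `converged` flag
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        beta, se = float(fit.params[1]), float(fit.bse[1])
        p = float(fit.pvalues[1])
    except Exception:
        converged, beta, se, p = False, np.nan, np.nan, np.nan
    if not np.isfinite(se) or (np.isfinite(se) and se > 1e3):
        converged = False
    res = AssocResult(
        unit_id=unit_id,
        phenotype=pheno_name,
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p=p,
        test="logistic-wald",
        n=len(y),
        carrier_count=int(np.sum(burden >= 1)),
        converged=converged,
    )
    return res


def _firth_fit(X: np.ndarray, y: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    """Newton iterations for the Jeffreys-penalized logistic likelihood.

    The modified score is U*(b) = X'(y - mu + h*(1/2 - mu)) where h are the
    leverages of the weighted hat matrix; iterate until the penalized score
    has sup-norm below `tol`.  Step-halving guards divergence.

    Non-intercept columns are standardized internally (the Firth estimate is
    equivariant under nonsingular linear maps of the design: the Jeffreys
    penalty changes only by a constant), so convergence is scale-invariant
    and the information matrix stays well conditioned; the estimate and its
    covariance are mapped back to the original scale on return.
    """
    means = X.mean(axis=0)
    means[0] = 0.0  # keep the intercept column as-is
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    scales[0] = 1.0
    Z = (X - means) / scales
    beta_z, cov_z, converged = _firth_fit_raw(Z, y, tol=tol, max_iter=max_iter)
    k = X.shape[1]
    A = np.zeros((k, k))  # beta_original = A @ beta_standardized
    A[0, 0] = 1.0
    for j in range(1, k):
        A[0, j] = -means[j] / scales[j]
        A[j, j] = 1.0 / scales[j]
    return A @ beta_z, A @ cov_z @ A.T, converged


def _firth_fit_raw(X: np.ndarray, y: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    n, k = X.shape
    beta = np.zeros(k)

    def penalized_loglik(b):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        info = (X * W[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        ll = np.sum(y * eta - np.log1p(np.exp(eta)))
        return ll + 0.5 * logdet

    ll_old = penalized_loglik(beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        W = mu * (1 - mu)
        XW = X * W[:, None]
        info = XW.T @ X
        info_inv = np.linalg.pinv(info)
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(W)[:, None], info_inv, X * np.sqrt(W)[:, None])
        score = X.T @ (y - mu + h * (0.5 - mu))
        if np.max(np.abs(score)) < tol:
            return beta, info_inv, True
        step = info_inv @ score
        # step-halving on the penalized likelihood
        for _half in range(20):
            cand = beta + step
            ll_new = penalized_loglik(cand)
            if ll_new >= ll_old - 1e-10:
                break
            step = step / 2.0
        beta = beta + step
        ll_old = penalized_loglik(beta)
    # converged if the final score is small even at max_iter
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    W = mu * (1 - mu)
    info = (X * W[:, None]).T @ X
    info_inv = np.linalg.pinv(info)
    h = np.einsum("ij,jk,ik->i", X * np.sqrt(W)[:, None], info_inv, X * np.sqrt(W)[:, None])
    score = X.T @ (y - mu + h * (0.5 - mu))
    return beta, info_inv, bool(np.max(np.abs(score)) < tol)


def firth_logistic(
    burden: np.ndarray,
    phenotype: np.ndarray,
    covariates=None,
    unit_id: str = "unit",
    pheno_name: str = "trait",
    p_method: str = "wald",
) -> AssocResult:
    """Firth's penalized logistic regression for the burden coefficient.

    The Jeffreys-prior penalty (1/2 log det of the Fisher information)
    guarantees finite estimates under complete or quasi-complete separation.
    p_method: "wald" (default) or "plr" (penalized likelihood ratio).
    """
    burden = np.asarray(burden, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = _design(burden, covariates)
    beta_vec, cov, converged = _firth_fit(X, y)
    if not converged:
        raise RuntimeError(
            "Firth iterations did not converge: "
            f"n={len(y)}, k={X.shape[1]}, carriers={int(np.sum(burden >= 1))}"
        )
    beta = float(beta_vec[1])
    se = float(np.sqrt(cov[1, 1]))
    if p_method == "wald":
        z = beta / se
        p = float(2 * stats.norm.sf(abs(z)))
    elif p_method == "plr":
        # refit with the burden coefficient fixed at 0
        X0 = np.delete(X, 1, axis=1)
        b0, _, _ = _firth_fit(X0, y)

        def pll(Xm, bm):
            eta = Xm @ bm
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            W = mu * (1 - mu)
            info = (Xm * W[:, None]).T @ Xm
            _, logdet = np.linalg.slogdet(info)
            return np.sum(y * eta - np.log1p(np.exp(eta))) + 0.5 * logdet

        lr = 2 * (pll(X, beta_vec) - pll(X0, b0))
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    else:
        raise ValueError("p_method must be 'wald' or 'plr'")
    return AssocResult(
        unit_id=unit_id,
        phenotype=pheno_name,
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p=p,
        test="firth",
        n=len(y),
        carrier_count=int(np.sum(burden >= 1)),
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median association chi2 over its null median."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    chi2_stats = stats.chi2.isf(p, df=1)
    return float(np.median(chi2_stats) / CHI2_1_MEDIAN)


def ivw_random_effects_meta(
    betas: np.ndarray,
    ses: np.ndarray,
    unit_id: str = "meta",
    pheno_name: str = "trait",
) -> AssocResult:
    """DerSimonian-Laird inverse-variance-weighted random-effects meta.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/se^2; combined weights 1/(se^2 + tau^2); two-sided normal p.
    With a single study the input is returned unchanged (warning).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    k = betas.size
    if k < 2:
        import warnings

        warnings.warn("single study: returning it unchanged", stacklevel=2)
        beta, se = float(betas[0]), float(ses[0])
    else:
        w = 1.0 / ses**2
        beta_fe = np.sum(w * betas) / np.sum(w)
        Q = np.sum(w * (betas - beta_fe) ** 2)
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
        w_re = 1.0 / (ses**2 + tau2)
        beta = float(np.sum(w_re * betas) / np.sum(w_re))
        se = float(np.sqrt(1.0 / np.sum(w_re)))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    res = AssocResult(
        unit_id=unit_id,
        phenotype=pheno_name,
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p=p,
        test="ivw-re-meta",
        n=k,
    )
    if k >= 2:
        res.notes["tau2"] = tau2
        res.notes["Q"] = float(Q)
    return res
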