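"""Two-step whole-genome regression with LOCO offsets.

Step 1 fits a stacked block ridge regression on common genotypes: within
each block, ridge predictors across a grid of shrinkage levels are estimated
with k-fold cross-validation and the out-of-fold predictions are stacked;
a level-1 cross-validated ridge then combines, for each chromosome, the
block predictions from all *other* chromosomes into a leave-one-chromosome-
out (LOCO) genetic prediction of the phenotype.  Step 2 tests a burden by
ordinary least squares of (phenotype - LOCO offset) on burden + covariates.
The offset absorbs polygenic background and sample relatedness, keeping the
burden test calibrated in structured cohorts.

Ridge penalties are parameterized as heritability proxies:
lambda = m * (1 - h2) / h2, with m the number of predictors entering the
fit.  Genotypes are mean-imputed and scaled by sqrt(2 p (1 - p)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssocResult
from .variants import BurdenVector

__all__ = ["WgrConfig", "step1_ridge_loco", "step2_offset_test"]


@dataclass
class WgrConfig:
    block_size: int = 1000
    h2_grid: tuple[float, ...] = (0.01, 0.1, 0.25, 0.5, 0.75)
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.h2_grid:
            raise ValueError("shrinkage grid must be non-empty")


def _standardize(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages, center, scale by sqrt(2p(1-p))."""
    G = np.asarray(G, dtype=float).copy()
    col_mean = np.nanmean(G, axis=0)
    nan_idx = np.where(np.isnan(G))
    if nan_idx[0].size:
        G[nan_idx] = col_mean[nan_idx[1]]
    p = col_mean / 2.0
    scale = np.sqrt(np.maximum(2 * p * (1 - p), 1e-12))
    return (G - col_mean) / scale


def _ridge_solve(X: np.ndarray, y: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Ridge coefficients for several penalties; returns (m, n_lams)."""
    XtX = X.T @ X
    Xty = X.T @ y
    out = np.empty((X.shape[1], lams.size))
    for j, lam in enumerate(lams):
        out[:, j] = np.linalg.solve(XtX + lam * np.eye(X.shape[1]), Xty)
    return out


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(folds)
    return folds


def step1_ridge_loco(
    genotypes: pd.DataFrame | np.ndarray,
    chroms: np.ndarray,
    phenotype: np.ndarray,
    config: WgrConfig | None = None,
) -> pd.DataFrame:
    """Stacked block ridge producing LOCO predictions (samples x chroms).

    `phenotype` must already be covariate-adjusted and standardized (INT +
    residualization upstream).  Column c of the output never touches the
    genotypes on chromosome c.
    """
    config = config or WgrConfig()
    G = genotypes.to_numpy() if isinstance(genotypes, pd.DataFrame) else genotypes
    chroms = np.asarray(chroms)
    y = np.asarray(phenotype, dtype=float)
    n, m = G.shape
    if chroms.shape[0] != m:
        raise ValueError("chromosome labels must match the number of variants")
    chrom_levels = list(pd.unique(chroms))
    if len(chrom_levels) < 2:
        raise ValueError("LOCO undefined with a single chromosome")
    if n < config.k_folds:
        raise ValueError("fewer samples than folds")

    Gs = _standardize(G)
    rng = np.random.default_rng(config.seed)
    folds = _fold_assignment(n, config.k_folds, rng)
    h2 = np.asarray(config.h2_grid, dtype=float)

    # level 0: per-block out-of-fold ridge predictions across the grid
    blocks: list[tuple[str, np.ndarray]] = []  # (chrom, column indices)
    for c in chrom_levels:
        idx = np.flatnonzero(chroms == c)
        for start in range(0, idx.size, config.block_size):
            blocks.append((c, idx[start : start + config.block_size]))

    W = np.zeros((n, len(blocks) * h2.size))
    block_chrom = np.empty(len(blocks) * h2.size, dtype=object)
    for b, (c, cols) in enumerate(blocks):
        Xb = Gs[:, cols]
        lams = cols.size * (1 - h2) / h2
        sl = slice(b * h2.size, (b + 1) * h2.size)
        block_chrom[sl] = c
        for k in range(config.k_folds):
            te = folds == k
            betas = _ridge_solve(Xb[~te], y[~te], lams)
            W[te, sl] = Xb[te] @ betas

    # level 1: per chromosome-left-out, cross-validated ridge stacking
    loco = np.zeros((n, len(chrom_levels)))
    for ci, c in enumerate(chrom_levels):
        keep = block_chrom != c
        F = W[:, keep]
        lams = F.shape[1] * (1 - h2) / h2
        sse = np.zeros(h2.size)
        for k in range(config.k_folds):
            te = folds == k
            betas = _ridge_solve(F[~te], y[~te], lams)
            resid = y[te, None] - F[te] @ betas
            sse += np.sum(resid**2, axis=0)
        best = int(np.argmin(sse))
        beta = _ridge_solve(F, y, lams[best : best + 1])[:, 0]
        loco[:, ci] = F @ beta

    index = (
        genotypes.index
        if isinstance(genotypes, pd.DataFrame)
        else [f"S{i + 1}" for i in range(n)]
    )
    return pd.DataFrame(loco, columns=[str(c) for c in chrom_levels], index=index)


def step2_offset_test(
    burden: BurdenVector | np.ndarray,
    phenotype: np.ndarray,
    covariates,
    loco: pd.DataFrame | None,
    chrom: str | None = None,
    unit_id: str | None = None,
    pheno_name: str = "trait",
) -> AssocResult:
    """Burden test conditioning on the LOCO prediction as an offset.

    OLS of (phenotype - loco[:, chrom]) on burden + covariates; reports
    beta, SE, 95% CI (+-1.96 SE) and a two-sided t-test p-value.  With
    ``loco=None`` (or an all-zero column) this reduces to the plain linear
    burden test.
    """
    if isinstance(burden, BurdenVector):
        b = burden.values.astype(float)
        unit_id = unit_id or burden.unit_id
        chrom = chrom or burden.chrom
    else:
        b = np.asarray(burden, dtype=float)
        unit_id = unit_id or "unit"
    if np.var(b) == 0:
        raise ValueError("no carriers after filtering: burden has zero variance")
    y = np.asarray(phenotype, dtype=float)
    if loco is not None:
        if chrom is None:
            raise ValueError("the unit's chromosome is required with a LOCO offset")
        if str(chrom) not in loco.columns:
            raise ValueError(f"no LOCO column for chromosome {chrom!r}")
        y = y - loco[str(chrom)].to_numpy()

    C = None
    if covariates is not None:
        C = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if C.ndim == 1:
            C = C[:, None]
    X = np.column_stack([np.ones(len(y)), b] + ([C] if C is not None else []))
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient step-2 design")
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov_beta = sigma2 * np.linalg.inv(X.T @ X)
    beta = float(coef[1])
    se = float(np.sqrt(cov_beta[1, 1]))
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), df=dof))
    return AssocResult(
        unit_id=unit_id,
        phenotype=pheno_name,
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p=p,
        test="linear-t",
        n=len(y),
        carrier_count=int(np.sum(b >= 1)),
    )
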