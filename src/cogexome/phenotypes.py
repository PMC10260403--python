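"""Phenotype preparation: covariate design, INT, residualization, outliers.

All association analyses adjust for sex, age, age^2, sex-by-age,
sex-by-age^2, the top principal components and recruitment center
indicators.  Quantitative traits are rank-based inverse-normal transformed
(INT) before regression; descriptive carrier summaries residualize first and
transform the residuals.  Both orders are available and must be selected
explicitly by the caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_covariates",
    "rank_int",
    "residualize",
    "exclude_outliers",
]


def build_covariates(
    sex: np.ndarray,
    age: np.ndarray,
    pcs: np.ndarray,
    centers: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the standard covariate design matrix (no intercept column).

    Columns: sex, age, age^2, sex*age, sex*age^2, pc1..pcK, and one 0/1
    indicator per recruitment-center level beyond the first (reference
    coding).  Rows with any missing covariate are the caller's concern;
    complete cases are assumed.

    Parameters
    ----------
    sex : 0/1 coded vector.
    age : age in years.
    pcs : samples x K matrix of principal components.
    centers : categorical labels, or None to omit center indicators.
    """
    sex = np.asarray(sex, dtype=float)
    age = np.asarray(age, dtype=float)
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    if pcs.shape[0] != sex.shape[0]:
        pcs = pcs.T
    n = sex.shape[0]
    if age.shape[0] != n or pcs.shape[0] != n:
        raise ValueError("sex, age and pcs must have equal length")

    cols: dict[str, np.ndarray] = {
        "sex": sex,
        "age": age,
        "age2": age**2,
        "sex_age": sex * age,
        "sex_age2": sex * age**2,
    }
    for k in range(pcs.shape[1]):
        cols[f"pc{k + 1}"] = pcs[:, k]
    df = pd.DataFrame(cols)

    if centers is not None:
        centers = np.asarray(centers)
        if centers.shape[0] != n:
            raise ValueError("centers must have the same length as sex")
        levels = pd.unique(centers)
        if len(levels) < 2:
            raise ValueError("need >= 2 center levels or centers omitted")
        # first observed level is the reference
        for lev in levels[1:]:
            df[f"center_{lev}"] = (centers == lev).astype(float)
    return df


def rank_int(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform.

    z_i = Phi^-1((r_i - offset) / (n - 2*offset + 1)) with average ranks for
    ties.  The Blom constant offset=3/8 is the default; offset=1/2
    (van der Waerden-like) and offset=0 are also accepted.  Missing (NaN)
    entries stay missing and do not enter the rank computation.
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    mask = ~np.isnan(values)
    x = values[mask]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("all values identical; INT undefined")
    ranks = stats.rankdata(x, method="average")
    out[mask] = stats.norm.ppf((ranks - offset) / (x.size - 2 * offset + 1))
    return out


def residualize(pheno: np.ndarray, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residuals of `pheno` on an intercept plus `covariates`.

    Raises on rank-deficient designs, naming the offending columns so the
    caller can drop or merge them.
    """
    y = np.asarray(pheno, dtype=float)
    X = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
    names = (
        list(covariates.columns)
        if isinstance(covariates, pd.DataFrame)
        else [f"x{j}" for j in range(X.shape[1])]
    )
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("residualize expects complete cases")
    Xc = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc, ["intercept"] + names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    return y - Xc @ beta


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Identify columns made redundant by earlier ones (pivoted QR)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    dropped = piv[np.sum(diag > tol):]
    return [names[j] for j in sorted(dropped)]


def exclude_outliers(values: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Inclusion mask: False where |x - mean| > k * SD (single pass).

    Mean and SD are computed once over non-missing values; the rule is not
    re-applied after exclusion.  A constant vector has SD 0 and nothing
    exceeds the band, so everything is retained.  Missing values are
    excluded from the mask.
    """
    values = np.asarray(values, dtype=float)
    if np.sum(~np.isnan(values)) < 2:
        raise ValueError("need at least 2 values")
    mu = np.nanmean(values)
    sd = np.nanstd(values)
    with np.errstate(invalid="ignore"):
        keep = np.abs(values - mu) <= k * sd
    keep[np.isnan(values)] = False
    return keep
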