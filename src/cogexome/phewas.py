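"""Phenome-wide scan of a single gene's rare-variant burden.

Binary phenotypes with fewer than ``min_cases`` cases are dropped and tested
by logistic regression; any with p below ``firth_p`` are re-tested with
Firth's penalized logistic regression, whose result replaces the plain one.
Quantitative phenotypes with fewer than ``min_obs`` observations are
dropped; the rest have >5 SD outliers excluded, are inverse-normal
transformed and tested by linear regression.  The phenome-wide threshold is
alpha over the catalogue size by default (the convention large biobank scans
print), with the alpha-over-tests-run variant also reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import (
    AssocResult,
    firth_logistic,
    linear_burden_test,
    logistic_burden_test,
)
from .phenotypes import exclude_outliers, rank_int
from .variants import BurdenVector

logger = logging.getLogger(__name__)

__all__ = ["PhenotypeCatalogue", "PhewasResult", "run_phewas"]


@dataclass
class PhenotypeCatalogue:
    """A phenome: per-phenotype metadata plus a samples x phenotypes table."""

    meta: pd.DataFrame  # phenotype_id, name, category, type {binary,quantitative}
    values: pd.DataFrame  # samples x phenotype_id, NaN = missing

    def __post_init__(self) -> None:
        if self.meta["phenotype_id"].duplicated().any():
            raise ValueError("phenotype ids must be unique")
        missing = set(self.meta["phenotype_id"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"catalogue values missing for: {sorted(missing)}")
        bad = set(self.meta["type"]) - {"binary", "quantitative"}
        if bad:
            raise ValueError(f"unknown phenotype types: {bad}")

    @property
    def size(self) -> int:
        return self.meta.shape[0]


@dataclass
class PhewasResult:
    results: pd.DataFrame
    threshold: float  # alpha / catalogue size (default convention)
    threshold_tests_run: float  # alpha / number of tests actually run
    n_tests_run: int


def run_phewas(
    burden: BurdenVector | np.ndarray,
    catalogue: PhenotypeCatalogue,
    covariates: pd.DataFrame,
    min_cases: int = 100,
    min_obs: int = 100,
    firth_p: float = 0.01,
    outlier_k: float = 5.0,
    alpha: float = 0.05,
) -> PhewasResult:
    """Scan one burden across a phenotype catalogue with the standard rules."""
    if catalogue.size == 0:
        raise ValueError("catalogue is empty")
    b = burden.values.astype(float) if isinstance(burden, BurdenVector) else np.asarray(burden, dtype=float)
    unit = burden.unit_id if isinstance(burden, BurdenVector) else "unit"
    if int(np.sum(b >= 1)) < 1:
        raise ValueError("burden has no carriers")
    C = covariates.to_numpy(dtype=float)

    rows: list[dict] = []
    n_run = 0
    for ph in catalogue.meta.itertuples(index=False):
        y_all = catalogue.values[ph.phenotype_id].to_numpy(dtype=float)
        obs = ~np.isnan(y_all)
        if ph.type == "binary":
            y = y_all[obs]
            cases = int(np.sum(y == 1))
            if cases < min_cases:
                continue
            if len(np.unique(y)) < 2:
                logger.info("phenotype %s has a single class; skipped", ph.phenotype_id)
                continue
            res = logistic_burden_test(
                b[obs], y, C[obs], unit_id=unit, pheno_name=ph.phenotype_id
            )
            n_run += 1
            if (not res.converged) or (np.isfinite(res.p) and res.p < firth_p):
                res = firth_logistic(
                    b[obs], y, C[obs], unit_id=unit, pheno_name=ph.phenotype_id
                )
        else:
            if int(obs.sum()) < min_obs:
                continue
            keep = obs.copy()
            keep[obs] &= exclude_outliers(y_all[obs], k=outlier_k)
            y = rank_int(y_all[keep])
            res = linear_burden_test(
                b[keep], y, C[keep], unit_id=unit, pheno_name=ph.phenotype_id
            )
            n_run += 1
        row = res.to_dict()
        row.update({"name": ph.name, "category": ph.category, "type": ph.type})
        rows.append(row)

    results = pd.DataFrame(rows)
    return PhewasResult(
        results=results,
        threshold=alpha / catalogue.size,
        threshold_tests_run=alpha / n_run if n_run else np.nan,
        n_tests_run=n_run,
    )
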