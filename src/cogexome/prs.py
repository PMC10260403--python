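"""Polygenic scoring and the joint PRS + rare-carrier model.

The polygenic score is a weighted sum of effect-allele dosages using
externally derived per-variant weights.  Rare damaging carrier status
(PTV, or missense with MPC > 2, in LoF-intolerant genes) enters a joint
linear model with the PRS; the model reports conditional effects, partial
R^2 per predictor and, optionally, PRS-by-carrier interaction tests and
PRS-quantile phenotype summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "score_prs",
    "carrier_flags",
    "JointModelResult",
    "joint_model",
    "quantile_summary",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def score_prs(
    genotypes: pd.DataFrame,
    variant_info: pd.DataFrame,
    weights: pd.DataFrame,
) -> np.ndarray:
    """Per-sample weighted allele sum.

    Parameters
    ----------
    genotypes : samples x variants ALT-dosage matrix (NaN = missing; missing
        dosages contribute the variant's mean dosage).
    variant_info : variant_id, ref, alt for the genotyped variants.
    weights : variant_id, effect_allele, weight.

    Strand-ambiguous variants (A/T, C/G) are dropped, as are weight rows
    whose effect allele matches neither ref nor alt; counts are logged.
    An empty usable intersection is an error.
    """
    info = variant_info.set_index("variant_id")
    score = np.zeros(genotypes.shape[0])
    used = dropped_ambiguous = dropped_mismatch = 0
    for row in weights.itertuples(index=False):
        vid = row.variant_id
        if vid not in genotypes.columns or vid not in info.index:
            continue
        ref, alt = info.loc[vid, "ref"], info.loc[vid, "alt"]
        if (ref, alt) in _AMBIGUOUS:
            dropped_ambiguous += 1
            continue
        dosage = genotypes[vid].to_numpy(dtype=float)
        if np.isnan(dosage).any():
            dosage = np.where(np.isnan(dosage), np.nanmean(dosage), dosage)
        if row.effect_allele == alt:
            x = dosage
        elif row.effect_allele == ref:
            x = 2.0 - dosage
        else:
            dropped_mismatch += 1
            continue
        score += row.weight * x
        used += 1
    if dropped_ambiguous or dropped_mismatch:
        logger.info(
            "score_prs dropped %d strand-ambiguous and %d allele-mismatched variants",
            dropped_ambiguous,
            dropped_mismatch,
        )
    if used == 0:
        raise ValueError("no usable overlap between weights and genotypes")
    return score


def carrier_flags(
    genotypes: pd.DataFrame,
    annotations: pd.DataFrame,
    maf_max: float = 1e-5,
    pli_min: float = 0.9,
    pli_inclusive: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """(PTV carrier, damaging-missense carrier) flags per sample.

    Damaging missense means MPC > 2 (tiers 1-2).  Both flags are restricted
    to variants with in-cohort MAF < maf_max in LoF-intolerant genes; the
    pLI rule is strict (pLI > pli_min) by default, with `pli_inclusive`
    switching to pLI >= pli_min.
    """
    from .variants import classify_annotations

    ann = annotations
    if "variant_class" not in ann.columns:
        ann = classify_annotations(ann)
    pli_ok = ann["pli"] >= pli_min if pli_inclusive else ann["pli"] > pli_min
    qualifying = ann[(ann["maf"] < maf_max) & pli_ok]

    def _flag(sub: pd.DataFrame) -> np.ndarray:
        ids = [v for v in sub["variant_id"] if v in genotypes.columns]
        if not ids:
            return np.zeros(genotypes.shape[0], dtype=bool)
        return np.nan_to_num(genotypes[ids].to_numpy(dtype=float)).sum(axis=1) >= 1

    ptv = _flag(qualifying[qualifying["variant_class"] == "PTV"])
    mis = _flag(qualifying[qualifying["variant_class"].isin(["missense_t1", "missense_t2"])])
    return ptv, mis


@dataclass
class JointModelResult:
    """Conditional effects and variance contributions of the joint model."""

    beta: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    partial_r2: dict[str, float]
    r2_full: float
    n: int
    interaction_beta: dict[str, float] = field(default_factory=dict)
    interaction_p: dict[str, float] = field(default_factory=dict)


def _ols(X: np.ndarray, y: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    dof = len(y) - X.shape[1]
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return coef, np.sqrt(np.diag(cov)), sse, dof


def joint_model(
    phenotype: np.ndarray,
    prs: np.ndarray,
    ptv_flag: np.ndarray,
    missense_flag: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    interaction: bool = False,
    standardize_prs: bool = True,
) -> JointModelResult:
    """Joint OLS of an INT phenotype on PRS and rare-carrier status.

    Conditional effects are per PRS standard deviation and per carrier
    state.  The partial R^2 of a predictor is
    (SSE_reduced - SSE_full) / SSE_reduced for the model refit without it.
    With ``interaction=True``, PRS x carrier product terms are added and
    their Wald p-values reported.  A flag with zero carriers is dropped
    with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    prs = np.asarray(prs, dtype=float)
    if standardize_prs:
        prs = (prs - prs.mean()) / prs.std()
    preds: dict[str, np.ndarray] = {"prs": prs}
    for name, flag in (("ptv", ptv_flag), ("missense", missense_flag)):
        flag = np.asarray(flag, dtype=float)
        if flag.sum() == 0:
            warnings.warn(f"{name} flag has zero carriers; term dropped", stacklevel=2)
            continue
        preds[name] = flag

    C = None
    if covariates is not None:
        C = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if C.ndim == 1:
            C = C[:, None]

    names = list(preds)
    def build(cols: list[str], inter: list[str] = ()) -> np.ndarray:
        parts = [np.ones(len(y))] + [preds[c] for c in cols]
        parts += [preds["prs"] * preds[c] for c in inter]
        if C is not None:
            parts.append(C)
        return np.column_stack(parts)

    X_full = build(names)
    coef, ses, sse_full, dof = _ols(X_full, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    beta = {nm: float(coef[i + 1]) for i, nm in enumerate(names)}
    se = {nm: float(ses[i + 1]) for i, nm in enumerate(names)}
    pvals = {
        nm: float(2 * stats.t.sf(abs(beta[nm] / se[nm]), df=dof)) for nm in names
    }
    partial = {}
    for nm in names:
        reduced = [c for c in names if c != nm]
        _, _, sse_red, _ = _ols(build(reduced), y)
        partial[nm] = float((sse_red - sse_full) / sse_red)

    result = JointModelResult(
        beta=beta,
        se=se,
        p=pvals,
        partial_r2=partial,
        r2_full=float(1 - sse_full / sst),
        n=len(y),
    )
    if interaction:
        inter_names = [nm for nm in names if nm != "prs"]
        X_int = build(names, inter=inter_names)
        coef_i, ses_i, _, dof_i = _ols(X_int, y)
        off = 1 + len(names)
        for j, nm in enumerate(inter_names):
            b = float(coef_i[off + j])
            s = float(ses_i[off + j])
            result.interaction_beta[f"prs_x_{nm}"] = b
            result.interaction_p[f"prs_x_{nm}"] = float(
                2 * stats.t.sf(abs(b / s), df=dof_i)
            )
    return result


def quantile_summary(
    prs: np.ndarray,
    phenotype: np.ndarray,
    ptv_flag: np.ndarray,
    missense_flag: np.ndarray | None = None,
    q: float = 0.2,
    top_binary: bool = False,
) -> pd.DataFrame:
    """Median standardized residualized phenotype per PRS group and stratum.

    ``q`` is the quantile width (0.2 -> quintiles, 0.02 -> 2% bins);
    ``top_binary=True`` instead splits the top 10% PRS versus the rest.
    Carrier strata: 'ptv' wins over 'missense' wins over 'noncarrier'.
    """
    prs = np.asarray(prs, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n_groups = int(round(1.0 / q))
    if abs(n_groups * q - 1.0) > 1e-9:
        raise ValueError("q must evenly divide [0, 1]")
    stratum = np.where(np.asarray(ptv_flag, bool), "ptv", "noncarrier")
    if missense_flag is not None:
        stratum = np.where(
            (~np.asarray(ptv_flag, bool)) & np.asarray(missense_flag, bool),
            "missense",
            stratum,
        )
    if top_binary:
        cut = np.quantile(prs, 0.9)
        group = np.where(prs > cut, "top10", "rest")
    else:
        group = pd.qcut(prs, n_groups, labels=False)
    df = pd.DataFrame({"group": group, "stratum": stratum, "value": y})
    out = (
        df.groupby(["group", "stratum"], observed=True)["value"]
        .agg(median="median", n="size")
        .reset_index()
    )
    return out
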