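"""Variant QC, functional classification and burden construction.

Variants are classified into a functional class (PTV, three MPC-based
missense tiers, synonymous, other) crossed with a gene-constraint stratum
(pLI >= 0.9 high, pLI < 0.9 low, unknown).  Burdens are per-sample cumulative
minor-allele counts over qualifying variants, at exome-wide, gene-set or
per-gene granularity.  Boundary conventions follow the printed rules
strictly: MAF < 1e-5, MPC > 3, 3 >= MPC > 2, pLI >= 0.9, >= 10 carriers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: consequences counted as protein-truncating when LoF-confidence is high
PTV_CONSEQUENCES = frozenset({"stop_gained", "splice_donor", "splice_acceptor", "frameshift"})

CLASSES = ("PTV", "missense_t1", "missense_t2", "missense_t3", "synonymous", "other")

__all__ = [
    "PTV_CONSEQUENCES",
    "CLASSES",
    "BurdenVector",
    "qc_filter_common",
    "hwe_chisq",
    "classify_variant",
    "classify_annotations",
    "filter_rare",
    "mac_to_maf",
    "build_burden",
    "filter_units_by_carriers",
    "read_gmt",
]


@dataclass
class BurdenVector:
    """Per-sample cumulative minor-allele count for one testing unit."""

    unit_id: str
    variant_class: str
    pli_stratum: str  # "high", "low", "unknown", or "any"
    values: np.ndarray
    chrom: str | None = None

    @property
    def carrier_count(self) -> int:
        return int(np.sum(self.values >= 1))

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])


def qc_filter_common(
    call_rate: np.ndarray, hwe_p: np.ndarray, maf: np.ndarray
) -> np.ndarray:
    """Boolean keep-mask for common-variant QC.

    Keeps variants with call rate >= 90%, HWE test P >= 1e-15 and
    MAF >= 1%; i.e. drops call rate < 0.9, HWE P < 1e-15 or MAF < 0.01.
    """
    call_rate = np.asarray(call_rate, dtype=float)
    hwe_p = np.asarray(hwe_p, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if not (call_rate.shape == hwe_p.shape == maf.shape):
        raise ValueError("inputs must have the same length")
    return (call_rate >= 0.9) & (hwe_p >= 1e-15) & (maf >= 0.01)


def hwe_chisq(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square Hardy-Weinberg goodness-of-fit p-value.

    Expected genotype proportions are computed at the observed allele
    frequency.  A monomorphic sample is in exact equilibrium by convention
    (p = 1).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def classify_variant(
    consequence: str,
    lof_confidence: str | None = None,
    mpc: float | None = None,
    pli: float | None = None,
) -> tuple[str, str]:
    """Map one annotation to its (class, pLI stratum).

    Rules: a PTV consequence with high-confidence LoF -> PTV; missense with
    MPC > 3 -> tier 1; 3 >= MPC > 2 -> tier 2; other missense, including
    missing MPC -> tier 3; synonymous -> synonymous; anything else (or a
    low-confidence PTV call) -> other.  Stratum is high iff pLI >= 0.9,
    unknown when pLI is missing.
    """
    mpc_val = np.nan if mpc is None else float(mpc)
    if consequence in PTV_CONSEQUENCES:
        cls = "PTV" if lof_confidence == "HC" else "other"
    elif consequence == "missense":
        if not np.isnan(mpc_val) and mpc_val > 3:
            cls = "missense_t1"
        elif not np.isnan(mpc_val) and mpc_val > 2:  # 3 >= MPC > 2
            cls = "missense_t2"
        else:
            cls = "missense_t3"
    elif consequence == "synonymous":
        cls = "synonymous"
    else:
        logger.info("unknown consequence %r classified as 'other'", consequence)
        cls = "other"

    if pli is None or (isinstance(pli, float) and np.isnan(pli)):
        stratum = "unknown"
    else:
        stratum = "high" if float(pli) >= 0.9 else "low"
    return cls, stratum


def classify_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Vector version of :func:`classify_variant` over an annotation table.

    Returns a copy with ``variant_class`` and ``pli_stratum`` columns.
    """
    ann = annotations.copy()
    classes = []
    strata = []
    for row in ann.itertuples(index=False):
        mpc = getattr(row, "mpc", np.nan)
        pli = getattr(row, "pli", np.nan)
        lof = getattr(row, "lof_confidence", None)
        if isinstance(lof, float) and np.isnan(lof):
            lof = None
        cls, stratum = classify_variant(
            row.consequence,
            lof,
            None if (mpc is None or (isinstance(mpc, float) and np.isnan(mpc))) else mpc,
            None if (pli is None or (isinstance(pli, float) and np.isnan(pli))) else pli,
        )
        classes.append(cls)
        strata.append(stratum)
    ann["variant_class"] = classes
    ann["pli_stratum"] = strata
    return ann


def filter_rare(annotations: pd.DataFrame, maf_threshold: float = 1e-5) -> pd.DataFrame:
    """Keep variants with in-cohort MAF strictly below the threshold."""
    if annotations["maf"].isna().any():
        raise ValueError("maf must be populated for all variants")
    return annotations[annotations["maf"] < maf_threshold]


def mac_to_maf(mac_threshold: int, n_individuals: int) -> float:
    """Minor-allele-count cutoff expressed as a frequency: MAC / (2N)."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return mac_threshold / (2.0 * n_individuals)


def _qualifying(
    annotations: pd.DataFrame,
    variant_class: str | None,
    pli_stratum: str | None,
) -> pd.DataFrame:
    ann = annotations
    if "variant_class" not in ann.columns:
        ann = classify_annotations(ann)
    if variant_class is not None:
        ann = ann[ann["variant_class"] == variant_class]
    if pli_stratum is not None:
        ann = ann[ann["pli_stratum"] == pli_stratum]
    return ann


def build_burden(
    genotypes: pd.DataFrame,
    annotations: pd.DataFrame,
    grouping: str = "gene",
    variant_class: str | None = "PTV",
    pli_stratum: str | None = None,
    gene_sets: dict[str, list[str]] | None = None,
) -> list[BurdenVector]:
    """Cumulative minor-allele counts over qualifying variants.

    Parameters
    ----------
    genotypes : samples x variants dosage DataFrame (0/1/2, NaN = missing).
        Missing dosages contribute 0 to the sum: carriers are defined by
        observed alternate alleles.
    annotations : table with at least variant_id, gene, and (or enough to
        derive) variant_class / pli_stratum columns.
    grouping : "exome-wide", "gene", or "gene-set".
    variant_class : restrict to one functional class (None = all).
    pli_stratum : restrict to "high" / "low" / "unknown" (None = all).
    gene_sets : required for grouping="gene-set"; mapping set name -> genes.
    """
    ann = _qualifying(annotations, variant_class, pli_stratum)
    ann = ann[ann["variant_id"].isin(genotypes.columns)]
    n = genotypes.shape[0]
    cls_label = variant_class or "any"
    stratum_label = pli_stratum or "any"

    def _sum(variant_ids: pd.Series | list[str]) -> np.ndarray:
        ids = [v for v in variant_ids if v in genotypes.columns]
        if not ids:
            return np.zeros(n)
        return np.nan_to_num(genotypes[ids].to_numpy(dtype=float)).sum(axis=1)

    results: list[BurdenVector] = []
    if grouping == "exome-wide":
        if ann.empty:
            warnings.warn("no qualifying variants; zero burden", stacklevel=2)
        results.append(
            BurdenVector("exome-wide", cls_label, stratum_label, _sum(ann["variant_id"]))
        )
    elif grouping == "gene":
        if ann.empty:
            warnings.warn("no qualifying variants; no gene burdens", stacklevel=2)
        for gene, sub in ann.groupby("gene", sort=True):
            chroms = sub["chrom"].unique() if "chrom" in sub.columns else [None]
            results.append(
                BurdenVector(
                    str(gene), cls_label, stratum_label, _sum(sub["variant_id"]),
                    chrom=None if chroms[0] is None else str(chroms[0]),
                )
            )
    elif grouping == "gene-set":
        if gene_sets is None:
            raise ValueError("gene_sets required for gene-set grouping")
        for name, genes in gene_sets.items():
            sub = ann[ann["gene"].isin(genes)]
            if sub.empty:
                warnings.warn(f"gene set {name!r} has no qualifying variants", stacklevel=2)
            results.append(BurdenVector(name, cls_label, stratum_label, _sum(sub["variant_id"])))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return results


def filter_units_by_carriers(
    burdens: list[BurdenVector], min_carriers: int = 10
) -> list[BurdenVector]:
    """Drop testing units with fewer than `min_carriers` carriers."""
    return [b for b in burdens if b.carrier_count >= min_carriers]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
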