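"""Synthetic cohorts with the statistical structure the pipeline assumes.

A cohort has: common genotypes (dosage 0/1/2) supplying a polygenic
background; ultrarare coding variants generated per gene by drawing carriers
directly (one singleton heterozygous variant per carrier by default), each
labelled with a functional class and a gene-constraint (pLI) stratum;
covariates (sex, age, PCs, recruitment center); a standardized quantitative
liability combining covariate effects, the polygenic component, per-gene
burden effects and Gaussian noise (total variance 1); and, optionally, a
binary trait obtained by thresholding that liability at a target prevalence.

The true generating quantities (gene effects, polygenic component) are
carried alongside the observables so recovery and calibration tests can
compare estimates against truth.

The ultrarare regime is parameterized by a per-gene carrier rate rather than
a population MAF: at desk-scale sample sizes a fixed MAF threshold such as
1e-5 is vacuous, so the generator records the realized in-cohort MAF and the
downstream rarity filter operates on that.  The default carrier rate 1/1900
matches the per-gene PTV carrier rate of a LoF-tolerant gene in a large
biobank.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .variants import CLASSES

__all__ = [
    "SimConfig",
    "Cohort",
    "simulate_common_genotypes",
    "simulate_rare_variants",
    "simulate_phenotypes",
    "simulate_cohort",
    "simulate_binary_logistic",
]

DEFAULT_CLASS_MIX = {
    # roughly the class composition of ultrarare coding variants in a large
    # exome study: ~7% PTV, ~59% missense (mostly tier 3), ~34% synonymous
    "PTV": 0.07,
    "missense_t1": 0.03,
    "missense_t2": 0.09,
    "missense_t3": 0.47,
    "synonymous": 0.34,
}

_PTV_CONSEQ = ("stop_gained", "splice_donor", "splice_acceptor", "frameshift")
_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort; seed-fixed output is bit-identical."""

    n_samples: int = 10_000
    n_common_variants: int = 2_000
    n_chromosomes: int = 22
    n_genes: int = 100
    carrier_rate: float = 1.0 / 1900.0
    rare_maf_max: float = 1e-5
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    pli_high_fraction: float = 0.18
    polygenic_h2: float = 0.3
    gene_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.05, "age": -0.10}
    )
    center_effect_sd: float = 0.02
    binary_prevalence: float | None = None
    common_maf_range: tuple[float, float] = (0.01, 0.5)
    fixed_common_maf: float | None = None
    structured_frequencies: bool = False
    n_centers: int = 5
    n_pcs: int = 20
    sibling_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_common_variants < 1 or self.n_chromosomes < 1:
            raise ValueError("dimensions must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not 0 <= self.carrier_rate <= 1:
            raise ValueError("carrier_rate must lie in [0, 1]")
        for name in ("pli_high_fraction", "polygenic_h2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.binary_prevalence is not None and not 0 < self.binary_prevalence < 1:
            raise ValueError("binary_prevalence must lie in (0, 1)")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total})")
        unknown = set(self.class_mix) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown variant classes in class_mix: {unknown}")
        if 2 * self.sibling_pairs > self.n_samples:
            raise ValueError("2 * sibling_pairs exceeds n_samples")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class Cohort:
    """A simulated cohort: observables plus the generating truth."""

    common_genotypes: pd.DataFrame  # samples x variants, dosage 0/1/2
    common_info: pd.DataFrame  # variant_id, chrom, pos, maf
    rare_genotypes: pd.DataFrame  # samples x rare variants
    annotations: pd.DataFrame  # rare-variant annotation table
    phenotypes: pd.DataFrame  # sample_id, covariates, trait (+ status)
    truth_gene_effects: pd.DataFrame  # gene, beta
    truth_polygenic: np.ndarray  # per-sample polygenic component
    config: SimConfig | None = None

    @property
    def n_samples(self) -> int:
        return self.phenotypes.shape[0]

    def covariate_frame(self) -> pd.DataFrame:
        """Standard covariate design built from the phenotype table."""
        from .phenotypes import build_covariates

        ph = self.phenotypes
        pc_cols = [c for c in ph.columns if c.startswith("pc")]
        return build_covariates(
            ph["sex"].to_numpy(),
            ph["age"].to_numpy(),
            ph[pc_cols].to_numpy(),
            ph["center"].to_numpy() if ph["center"].nunique() > 1 else None,
        )


def _chromosome_blocks(n_items: int, n_chromosomes: int) -> np.ndarray:
    """Assign items to chromosomes in contiguous, near-equal blocks."""
    sizes = np.full(n_chromosomes, n_items // n_chromosomes)
    sizes[: n_items % n_chromosomes] += 1
    return np.repeat([f"chr{c + 1}" for c in range(n_chromosomes)], sizes)


def simulate_common_genotypes(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Common-variant dosage matrix under Hardy-Weinberg sampling.

    MAFs are drawn uniformly on ``common_maf_range`` (or fixed at
    ``fixed_common_maf``); variants occupy contiguous chromosome blocks.
    The leading ``2 * sibling_pairs`` samples are full siblings generated
    through shared parental haplotypes; the rest are unrelated.  When
    ``structured_frequencies`` is set, a latent ancestry gradient perturbs
    per-sample allele frequencies, creating PC-detectable structure.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_common_variants
    if config.fixed_common_maf is not None:
        mafs = np.full(m, config.fixed_common_maf)
    else:
        mafs = rng.uniform(*config.common_maf_range, size=m)
    chroms = _chromosome_blocks(m, config.n_chromosomes)

    if config.structured_frequencies:
        gradient = rng.normal(size=n)
        shift = 0.2 * np.sqrt(mafs * (1 - mafs))
        p_i = np.clip(mafs[None, :] + gradient[:, None] * shift[None, :], 0.001, 0.999)
        dosage = rng.binomial(2, p_i).astype(np.int8)
    else:
        dosage = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)

    # overwrite the leading block with sibling pairs drawn from shared parents
    for j in range(config.sibling_pairs):
        father = rng.binomial(1, mafs, size=(2, m))
        mother = rng.binomial(1, mafs, size=(2, m))
        for k in range(2):
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            dosage[2 * j + k] = (
                father[pick_f, np.arange(m)] + mother[pick_m, np.arange(m)]
            ).astype(np.int8)

    variant_ids = [f"cv{j + 1}" for j in range(m)]
    genotypes = pd.DataFrame(
        dosage, columns=variant_ids, index=[f"S{i + 1}" for i in range(n)]
    )
    info = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chroms,
            "pos": np.arange(1, m + 1) * 1000,
            "maf": mafs,
        }
    )
    return genotypes, info


def simulate_rare_variants(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ultrarare coding variants: per-gene carriers, singleton heterozygotes.

    Per gene, the carrier count is Binomial(n_samples, carrier_rate) and
    carriers are drawn without replacement; each carrier receives one
    heterozygous singleton variant whose functional class is drawn from
    ``class_mix``.  Genes are placed on chromosomes in contiguous blocks; a
    ``pli_high_fraction`` share of genes is LoF-intolerant (pLI >= 0.9).
    The realized in-cohort MAF (1 / 2n for a singleton) is recorded.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_samples
    gene_ids = [f"GENE{g + 1:04d}" for g in range(config.n_genes)]
    gene_chroms = _chromosome_blocks(config.n_genes, config.n_chromosomes)
    n_high = int(round(config.pli_high_fraction * config.n_genes))
    high_genes = set(rng.choice(config.n_genes, size=n_high, replace=False))

    class_names = list(config.class_mix)
    class_probs = np.array([config.class_mix[c] for c in class_names])

    columns: dict[str, np.ndarray] = {}
    records: list[dict] = []
    vid = 0
    for g, gene in enumerate(gene_ids):
        pli = rng.uniform(0.9, 1.0) if g in high_genes else rng.uniform(0.0, 0.9)
        n_car = rng.binomial(n, config.carrier_rate)
        carriers = rng.choice(n, size=n_car, replace=False)
        base_pos = 1_000_000 * (g + 1)
        for k, carrier in enumerate(np.sort(carriers)):
            vid += 1
            variant_id = f"rv{vid}"
            col = np.zeros(n, dtype=np.int8)
            col[carrier] = 1
            columns[variant_id] = col
            cls = class_names[rng.choice(len(class_names), p=class_probs)]
            if cls == "PTV":
                consequence = _PTV_CONSEQ[rng.integers(0, len(_PTV_CONSEQ))]
                lof, mpc = "HC", np.nan
            elif cls == "missense_t1":
                consequence, lof, mpc = "missense", "NA", rng.uniform(3.0, 5.0)
            elif cls == "missense_t2":
                consequence, lof, mpc = "missense", "NA", rng.uniform(2.0, 3.0) + 1e-9
            elif cls == "missense_t3":
                consequence, lof = "missense", "NA"
                mpc = rng.uniform(0.0, 2.0) if rng.random() < 0.5 else np.nan
            else:
                consequence, lof, mpc = "synonymous", "NA", np.nan
            ref, alt = rng.choice(4, size=2, replace=False)
            records.append(
                {
                    "variant_id": variant_id,
                    "chrom": gene_chroms[g],
                    "pos": base_pos + 100 * (k + 1),
                    "ref": _BASES[ref],
                    "alt": _BASES[alt],
                    "gene": gene,
                    "consequence": consequence,
                    "lof_confidence": lof,
                    "mpc": mpc,
                    "pli": pli,
                    "maf": 1.0 / (2 * n),
                }
            )

    index = [f"S{i + 1}" for i in range(n)]
    genotypes = pd.DataFrame(columns, index=index) if columns else pd.DataFrame(index=index)
    ann_cols = [
        "variant_id", "chrom", "pos", "ref", "alt", "gene",
        "consequence", "lof_confidence", "mpc", "pli", "maf",
    ]
    annotations = pd.DataFrame(records, columns=ann_cols)
    return genotypes, annotations


def _simulate_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1}" for i in range(n)],
            "sex": rng.integers(0, 2, size=n),
            "age": np.round(rng.uniform(40, 70, size=n), 1),
            **{f"pc{k + 1}": rng.normal(size=n) for k in range(config.n_pcs)},
            "center": np.array(
                [f"C{c + 1}" for c in rng.integers(0, config.n_centers, size=n)]
            ),
        }
    )


def simulate_phenotypes(
    common_genotypes: pd.DataFrame,
    rare_genotypes: pd.DataFrame,
    annotations: pd.DataFrame,
    config: SimConfig,
) -> Cohort:
    """Build covariates and liability-based phenotypes over given genotypes.

    Quantitative trait = covariate effects + polygenic component (variance
    ``polygenic_h2``, built from standardized common genotypes with random
    normal weights) + sum of per-gene burden effects + Gaussian noise scaled
    so the total variance is 1.  A binary trait, when requested, thresholds
    the same liability at the quantile implied by ``binary_prevalence``.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_samples
    cov = _simulate_covariates(config, rng)

    systematic = np.zeros(n)
    eff = config.covariate_effects or {}
    if eff.get("sex"):
        sex = cov["sex"].to_numpy(dtype=float)
        systematic += eff["sex"] * (sex - sex.mean()) / max(sex.std(), 1e-12)
    if eff.get("age"):
        age = cov["age"].to_numpy(dtype=float)
        systematic += eff["age"] * (age - age.mean()) / age.std()
    if config.center_effect_sd > 0 and config.n_centers > 1:
        center_effects = rng.normal(0, config.center_effect_sd, size=config.n_centers)
        idx = cov["center"].str.slice(1).astype(int).to_numpy() - 1
        systematic += center_effects[idx]

    if config.polygenic_h2 > 0:
        G = common_genotypes.to_numpy(dtype=float)
        p = G.mean(axis=0) / 2.0
        scale = np.sqrt(np.maximum(2 * p * (1 - p), 1e-12))
        Gs = (G - 2 * p) / scale
        u = Gs @ rng.normal(size=G.shape[1])
        sd = u.std()
        if sd > 0:
            u = u / sd * np.sqrt(config.polygenic_h2)
        polygenic = u
    else:
        polygenic = np.zeros(n)
    systematic = systematic + polygenic

    missing = set(config.gene_effects) - set(annotations.get("gene", pd.Series(dtype=str)))
    if missing:
        raise ValueError(f"gene_effects reference unknown genes: {sorted(missing)}")
    for gene, beta in config.gene_effects.items():
        vids = annotations.loc[annotations["gene"] == gene, "variant_id"]
        vids = [v for v in vids if v in rare_genotypes.columns]
        if vids:
            systematic = systematic + beta * rare_genotypes[vids].to_numpy(dtype=float).sum(axis=1)

    noise_var = 1.0 - float(np.var(systematic))
    if noise_var <= 0:
        raise ValueError(
            "explained variance exceeds 1; reduce effect sizes or polygenic_h2"
        )
    trait = systematic + rng.normal(0, np.sqrt(noise_var), size=n)

    pheno = cov.copy()
    pheno["trait"] = trait
    if config.binary_prevalence is not None:
        cutoff = np.quantile(trait, 1.0 - config.binary_prevalence)
        pheno["status"] = (trait > cutoff).astype(int)

    truth = pd.DataFrame(
        {"gene": list(config.gene_effects), "beta": list(config.gene_effects.values())}
    )
    return Cohort(
        common_genotypes=common_genotypes,
        common_info=pd.DataFrame(),
        rare_genotypes=rare_genotypes,
        annotations=annotations,
        phenotypes=pheno,
        truth_gene_effects=truth,
        truth_polygenic=polygenic,
        config=config,
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """End-to-end generation: common + rare genotypes, then phenotypes."""
    common, info = simulate_common_genotypes(config)
    rare, ann = simulate_rare_variants(config)
    cohort = simulate_phenotypes(common, rare, ann, config)
    cohort.common_info = info
    return cohort


def simulate_binary_logistic(
    burden: np.ndarray,
    log_or: float,
    prevalence: float = 0.1,
    covariate_part: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Binary outcome with an exactly specified burden odds ratio.

    A liability-threshold trait cannot carry a prescribed odds ratio, so
    known-OR scenarios use a logit-linear generator:
    logit P(case) = logit(prevalence) + log_or * burden (+ covariate part).
    """
    rng = np.random.default_rng(seed)
    burden = np.asarray(burden, dtype=float)
    eta = np.log(prevalence / (1 - prevalence)) + log_or * burden
    if covariate_part is not None:
        eta = eta + np.asarray(covariate_part, dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(burden.shape[0]) < p).astype(int)
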