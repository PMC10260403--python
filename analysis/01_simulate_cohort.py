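"""Stage 1: generate the working synthetic cohort and write it to data/cohort.

The cohort mimics the structure the pipeline assumes: a polygenic
common-variant background (h2 = 0.3), ultrarare coding variants in 200
genes (~40 carriers per gene), covariates, 300 sibling pairs, and two
genes with injected burden effects on the standardized quantitative trait:
GENE0007 (beta = -0.8) and GENE0042 (beta = -0.5).  A binary trait with
20% prevalence is thresholded from the same liability.
"""

from pathlib import Path

from cogexome.io import write_cohort
from cogexome.simulate import SimConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]

CONFIG = SimConfig(
    n_samples=10_000,
    n_common_variants=2_000,
    n_chromosomes=20,
    n_genes=200,
    carrier_rate=1.0 / 250.0,
    polygenic_h2=0.3,
    sibling_pairs=300,
    gene_effects={"GENE0007": -0.8, "GENE0042": -0.5},
    binary_prevalence=0.2,
    seed=20_240_601,
)


def main() -> None:
    cohort = simulate_cohort(CONFIG)
    out = ROOT / "data" / "cohort"
    paths = write_cohort(cohort, out)
    print(f"cohort: {cohort.n_samples} samples, "
          f"{cohort.common_genotypes.shape[1]} common variants, "
          f"{cohort.rare_genotypes.shape[1]} rare variants in "
          f"{cohort.annotations['gene'].nunique()} genes")
    print(f"trait variance: {cohort.phenotypes['trait'].var():.3f} "
          f"(target 1.0); case fraction: {cohort.phenotypes['status'].mean():.3f}")
    for name, p in paths.items():
        print(f"  wrote {name}: {p.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
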