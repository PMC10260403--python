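import numpy as np
import pandas as pd
import pytest

from cogexome import SimConfig, simulate
from cogexome.phenotypes import build_covariates


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with one causal gene, reused across read-only tests."""
    cfg = SimConfig(
        n_samples=3000,
        n_common_variants=400,
        n_chromosomes=10,
        n_genes=40,
        carrier_rate=0.01,
        polygenic_h2=0.2,
        gene_effects={"GENE0001": -0.4},
        binary_prevalence=0.25,
        seed=42,
    )
    return simulate.simulate_cohort(cfg)


@pytest.fixture()
def toy_genotypes():
    """Small dense dosage matrix with missingness, plus annotations."""
    rng = np.random.default_rng(7)
    n, m = 30, 20
    dosage = rng.integers(0, 3, size=(n, m)).astype(float)
    dosage[rng.random((n, m)) < 0.05] = np.nan
    vids = [f"v{j}" for j in range(m)]
    genos = pd.DataFrame(dosage, columns=vids, index=[f"S{i}" for i in range(n)])
    genes = rng.choice(["G1", "G2", "G3"], size=m)
    classes = rng.choice(
        ["stop_gained", "missense", "synonymous"], size=m, p=[0.3, 0.5, 0.2]
    )
    ann = pd.DataFrame(
        {
            "variant_id": vids,
            "chrom": "chr1",
            "pos": np.arange(1, m + 1),
            "gene": genes,
            "consequence": classes,
            "lof_confidence": ["HC" if c == "stop_gained" else "NA" for c in classes],
            "mpc": [
                rng.uniform(0, 5) if c == "missense" else np.nan for c in classes
            ],
            "pli": rng.uniform(0, 1, size=m),
            "maf": rng.uniform(0, 1e-4, size=m),
        }
    )
    return genos, ann


@pytest.fixture()
def basic_covariates():
    rng = np.random.default_rng(11)
    n = 500
    return build_covariates(
        rng.integers(0, 2, n).astype(float),
        rng.uniform(40, 70, n),
        rng.normal(size=(n, 4)),
        rng.choice(["C1", "C2", "C3"], size=n),
    )
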