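"""Stage 5: phenome-wide scan of the top gene's rare-allele burden.

The exposure is the GENE0007 burden from the working cohort.  The
catalogue mixes the cohort's own traits with synthetic phenotypes: 30
binary "diagnosis" phenotypes at varying case counts (those under 100
cases are excluded by the scan) and 20 quantitative "biomarkers" (one
constructed to depend on the burden, the rest null).  Binary phenotypes
with Wald p below 0.01 are refit with Firth regression; the phenome-wide
threshold is 0.05 over the catalogue size.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cogexome.io import read_cohort
from cogexome.phewas import PhenotypeCatalogue, run_phewas
from cogexome.variants import build_burden

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = read_cohort(ROOT / "data" / "cohort")
    n = cohort.n_samples
    burden = {
        b.unit_id: b
        for b in build_burden(cohort.rare_genotypes, cohort.annotations, "gene",
                              variant_class=None)
    }["GENE0007"]

    rng = np.random.default_rng(55)
    meta, values = [], {}
    meta.append({"phenotype_id": "trait", "name": "primary quantitative trait",
                 "category": "cognitive", "type": "quantitative"})
    values["trait"] = cohort.phenotypes["trait"].to_numpy()
    meta.append({"phenotype_id": "status", "name": "liability-threshold disease",
                 "category": "icd10", "type": "binary"})
    values["status"] = cohort.phenotypes["status"].to_numpy(dtype=float)
    for j in range(30):
        frac = rng.uniform(0.005, 0.3)
        meta.append({"phenotype_id": f"dx{j:02d}", "name": f"diagnosis {j}",
                     "category": "icd10", "type": "binary"})
        values[f"dx{j:02d}"] = rng.binomial(1, frac, n).astype(float)
    for j in range(20):
        y = rng.normal(size=n)
        if j == 0:  # one biomarker truly affected by the burden
            y = y - 0.6 * burden.values
        meta.append({"phenotype_id": f"bm{j:02d}", "name": f"biomarker {j}",
                     "category": "biomarker", "type": "quantitative"})
        values[f"bm{j:02d}"] = y
    catalogue = PhenotypeCatalogue(pd.DataFrame(meta), pd.DataFrame(values))

    out = run_phewas(burden.values, catalogue, cohort.covariate_frame())
    table = out.results.sort_values("p")
    path = ROOT / "results" / "phewas.tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)

    n_sig = int((table["p"] < out.threshold).sum())
    print(f"catalogue size {catalogue.size}; {out.n_tests_run} tests run; "
          f"phenome-wide threshold {out.threshold:.2e}; {n_sig} significant")
    cols = ["phenotype", "test", "beta", "se", "p", "n"]
    print(table[cols].head(6).to_string(index=False))
    print(f"wrote {path.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
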