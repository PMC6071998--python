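#!/usr/bin/env python
"""Population structure: PCA of the post-QC genotypes, percent-variance
accounting, K-means over the leading PCs with BIC model choice, and
discriminant functions between the inferred clusters."""

from pathlib import Path

import numpy as np
import pandas as pd

from girscan import io, structure

DATA = Path("results/data")
QC = Path("results/qc")
OUT = Path("results/structure")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    g = io.read_genotypes(DATA / "cohort.vcf", format="vcf")
    keep = np.isin(g.markers.snp_id, io.read_table(QC / "snps_post_qc.tsv")["snp_id"])
    g = g.subset_snps(keep)
    labels = io.read_labels(DATA / "labels.tsv")

    n_pc = min(100, g.n_samples - 1)
    pca = structure.run_pca(g, n_pc=n_pc, scale=True)
    eig = pd.DataFrame(
        {
            "component": np.arange(1, len(pca.eigenvalues) + 1),
            "eigenvalue": pca.eigenvalues,
            "percent_variance": pca.percent_variance,
        }
    )
    io.write_table(eig.round(6), OUT / "eigenvalues.tsv")
    print(f"PC1 eigenvalue {pca.eigenvalues[0]:.2f} ({pca.percent_variance[0]:.2f}% of variance); "
          f"PC2 {pca.eigenvalues[1]:.2f} ({pca.percent_variance[1]:.2f}%)")

    model = structure.select_k_bic(pca.scores, list(range(1, 7)), seed=17)
    print("BIC by K:", {k: round(b, 2) for k, b in zip(model.k_grid, model.bic)})
    print(f"best K = {model.best_k}")
    df_scores = structure.discriminant_functions(pca.scores, model.assignments, n_df=10)

    out = pd.DataFrame(
        {
            "sample_id": g.samples,
            "population": [labels.of(s) for s in g.samples],
            "cluster": model.assignments,
            "PC1": np.round(pca.scores[:, 0], 6),
            "PC2": np.round(pca.scores[:, 1], 6),
            "DF1": np.round(df_scores[:, 0], 6),
        }
    )
    io.write_table(out, OUT / "scores.tsv")
    xt = pd.crosstab(out["population"], out["cluster"])
    print("cluster x population table:")
    print(xt.to_string())


if __name__ == "__main__":
    main()
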