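#!/usr/bin/env python
"""Candidate regions and genes: 500-kb windows around significant SNPs from
each method, overlap with the simulated gene/QTL annotation, cross-method
consensus, and comparison against the simulation truth."""

from pathlib import Path

import pandas as pd

from girscan import annotate, io

DATA = Path("results/data")
DIV = Path("results/diversity")
SCANS = Path("results/scans")
OUT = Path("results/candidates")


def sig_frame(df, score_col, method, population):
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos_bp": df["pos_bp"],
            "snp_id": df["snp_id"],
            "score": df[score_col],
            "method": method,
            "population": population,
        }
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frames = []
    div = io.read_table(DIV / "per_locus.tsv")
    frames.append(sig_frame(div[div["outlier"]], "Fst", "fst", "both"))
    for pop in ("beef", "dairy"):
        ihs = io.read_table(SCANS / f"ihs_{pop}.tsv")
        frames.append(sig_frame(ihs[ihs["significant"] == True], "ihs", "ihs", pop))  # noqa: E712
    xp = io.read_table(SCANS / "xpehh.tsv")
    xsig = xp[xp["significant"] == True]  # noqa: E712
    for direction, pop in (("reference", "dairy"), ("observed", "beef")):
        frames.append(sig_frame(xsig[xsig["direction"] == direction], "xpehh", "xpehh", pop))
    sig_all = pd.concat(frames, ignore_index=True)
    print(f"significant SNPs entering windows: {len(sig_all)} "
          f"({dict(sig_all['method'].value_counts())})")

    windows = annotate.make_windows(sig_all, half_width=250_000)
    io.write_table(windows, OUT / "windows.tsv")
    genes = io.read_intervals(DATA / "genes.bed")
    hits_by_method = {}
    for method in sorted(set(windows["source_method"])):
        hits_by_method[method] = annotate.overlap_intervals(
            windows[windows["source_method"] == method], genes
        )
        io.write_table(hits_by_method[method], OUT / f"gene_hits_{method}.tsv")
    consensus = annotate.consensus_genes(hits_by_method)
    io.write_table(consensus, OUT / "consensus_genes.tsv")
    multi = consensus[consensus["n_methods"] >= 2]
    print(f"{len(consensus)} annotated records hit; {len(multi)} supported by >=2 methods:")
    if len(multi):
        print(multi[["name", "category", "chrom", "methods"]].to_string(index=False))

    truth = io.read_table(DATA / "truth.tsv")
    sel = truth[truth["selected"] == True]  # noqa: E712
    rows = []
    for _, r in sel.iterrows():
        near = sig_all[(sig_all["chrom"] == r["chrom"]) & ((sig_all["pos_bp"] - r["pos_bp"]).abs() <= 250_000)]
        rows.append((r["snp_id"], int(r["chrom"]), ",".join(sorted(set(near["method"]))) or "-"))
    te = pd.DataFrame(rows, columns=["true_sweep", "chrom", "detected_by"])
    io.write_table(te, OUT / "truth_evaluation.tsv")
    print("truth evaluation (methods with a significant SNP within 250 kb of each sweep):")
    print(te.to_string(index=False))


if __name__ == "__main__":
    main()
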