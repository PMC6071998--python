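#!/usr/bin/env python
"""Quality control of the simulated cohort: monomorphic, call-rate, MAF and
Hardy-Weinberg heterozygosity-deviation filters on SNPs, then sample
call rate.  Reports attrition per rule and writes per-SNP allele
frequencies overall and per population."""

from pathlib import Path

import pandas as pd

from girscan import io, qc

DATA = Path("results/data")
OUT = Path("results/qc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    g = io.read_genotypes(DATA / "cohort.vcf", format="vcf")
    labels = io.read_labels(DATA / "labels.tsv")
    print(f"input: {g.n_samples} samples x {g.n_snps} SNPs")
    g, snp_rep = qc.filter_snps(g)
    g, sample_rep = qc.filter_samples(g)
    report = pd.concat([snp_rep.to_frame(), sample_rep.to_frame()], ignore_index=True)
    io.write_table(report, OUT / "qc_report.tsv")
    io.write_table(qc.allele_frequencies(g, labels).round(6), OUT / "allele_frequencies.tsv")
    # persist the post-QC marker list so later stages filter identically
    io.write_table(g.markers.table[["snp_id"]], OUT / "snps_post_qc.tsv")
    print(report.to_string(index=False))
    print(f"retained: {g.n_samples} samples and {g.n_snps} SNPs")


if __name__ == "__main__":
    main()
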