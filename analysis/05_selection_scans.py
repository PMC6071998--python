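#!/usr/bin/env python
"""Haplotype selection scans: within-population iHS (with ancestral-allele
recoding, frequency-bin standardisation and -log10 p transform) and the
cross-population XP-EHH test (dairy as reference, beef as observed)."""

from pathlib import Path

import numpy as np

from girscan import io, scan

DATA = Path("results/data")
QC = Path("results/qc")
OUT = Path("results/scans")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = io.read_haplotypes(DATA / "cohort.vcf", format="vcf_phased")
    panel = panel.subset_snps(
        np.isin(panel.markers.snp_id, io.read_table(QC / "snps_post_qc.tsv")["snp_id"])
    )
    labels = io.read_labels(DATA / "labels.tsv")
    panel, recode_report = io.recode_ancestral(panel)
    if len(recode_report):
        print(f"{len(recode_report)} SNPs set missing during ancestral recoding")
    panel = panel.subset_snps(~(panel.haplotypes == io.MISSING).any(axis=0))

    cfg = scan.ScanConfig(freq_bin_width=0.05)
    panels = panel.split_by_population(labels)
    for pop, sub in panels.items():
        res = scan.ihs_scan(sub, cfg)
        scored = res["pihs"].dropna()
        emp = scan.empirical_null_cutoff(scored.to_numpy(), mode="empirical_null")
        res["significant"] = res["pihs"] > emp.pihs_cutoff
        io.write_table(res.round(6), OUT / f"ihs_{pop}.tsv")
        top = res.loc[res["pihs"].idxmax()] if scored.size else None
        print(f"iHS {pop}: {int((res['status'] == 'ok').sum())} SNPs scored; "
              f"empirical-null cutoff piHS >= {emp.pihs_cutoff:.2f} "
              f"(eta0 = {emp.eta0:.3f}) -> {int(res['significant'].sum())} significant")
        if top is not None:
            print(f"  top SNP {top['snp_id']} (chr{top['chrom']}:{int(top['pos_bp'])}) "
                  f"iHS = {top['ihs']:.2f}, piHS = {top['pihs']:.2f}")

    xp = scan.xpehh_scan(panels["dairy"], panels["beef"], cfg)
    io.write_table(xp.round(6), OUT / "xpehh.tsv")
    sig = xp[xp["significant"]]
    print(f"XP-EHH: {int(xp['xpehh'].notna().sum())} SNPs scored; "
          f"{len(sig)} significant at p < {cfg.xpehh_alpha} "
          f"({int((sig['direction'] == 'reference').sum())} attributed to dairy, "
          f"{int((sig['direction'] == 'observed').sum())} to beef)")


if __name__ == "__main__":
    main()
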