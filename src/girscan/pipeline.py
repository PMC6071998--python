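"""End-to-end pipeline: QC -> structure -> diversity/Fst -> iHS -> XP-EHH ->
candidate windows and gene overlap, with deterministic TSV outputs and a JSON
run manifest.

The pipeline either simulates its own cohort (writing the simulated inputs as
a phased VCF, a label TSV, a truth table and a BED of synthetic genes, then
reading them back through the ordinary readers) or consumes user-supplied
files.  All stage outputs are TSVs with fixed column order; rerunning with
the same configuration and seed reproduces them byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, diversity, io, qc, scan, simulate, structure

log = logging.getLogger("girscan")


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 1
    # input files; ignored when simulate_cohort is true
    simulate_cohort: bool = True
    phased_vcf: str | None = None
    labels_file: str | None = None
    intervals_file: str | None = None
    autosomes: list[int] = field(default_factory=lambda: list(range(1, 30)))
    # stage settings
    sim: simulate.SimConfig | None = None
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    scan: scan.ScanConfig = field(default_factory=scan.ScanConfig)
    # ~100 PCs, as is conventional for DAPC-style clustering: the k-means BIC
    # curve only develops a minimum at the true K when the retained dimension
    # is large relative to n/ln(n)
    n_pc: int = 100
    k_grid: list[int] = field(default_factory=lambda: list(range(1, 7)))
    n_starts: int = 10
    n_df: int = 10
    half_width: int = 250_000
    ihs_cutoff_mode: str = "empirical_null"  # or "fixed"
    ihs_fixed_p: float = 0.01
    reference_population: str | None = None  # for XP-EHH; default: last population

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            sim_raw = dict(kwargs["sim"])
            if "selected_loci" in sim_raw:
                sim_raw["selected_loci"] = [simulate.SelectedLocus(**d) for d in sim_raw["selected_loci"]]
            kwargs["sim"] = simulate.SimConfig(**sim_raw)
        if "qc" in kwargs and kwargs["qc"] is not None:
            kwargs["qc"] = qc.QCConfig(**kwargs["qc"])
        if "scan" in kwargs and kwargs["scan"] is not None:
            kwargs["scan"] = scan.ScanConfig(**kwargs["scan"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.simulate_cohort:
            for name in ("phased_vcf", "labels_file"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when simulate_cohort is false")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
            if self.intervals_file is not None and not Path(self.intervals_file).exists():
                raise FileNotFoundError(f"intervals_file: {self.intervals_file} does not exist")


def _write(df: pd.DataFrame, out_dir: Path, name: str, manifest: dict) -> None:
    path = out_dir / name
    io.write_table(df, path)
    manifest["outputs"].append(name)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages_completed": [],
        "outputs": [],
        "counts": {},
        "thresholds": {},
    }

    def finish_stage(name: str) -> None:
        manifest["stages_completed"].append(name)
        (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        log.info("stage %s complete", name)

    try:
        # -- inputs -----------------------------------------------------
        if cfg.simulate_cohort:
            sim_cfg = cfg.sim or simulate.SimConfig()
            sim_cfg.seed = cfg.seed
            result = simulate.simulate_divergence(sim_cfg)
            data_dir = out_dir / "data"
            data_dir.mkdir(exist_ok=True)
            io.write_vcf_phased(simulate.merge_panels(result.panels), data_dir / "cohort.vcf")
            io.write_labels(result.labels, data_dir / "labels.tsv")
            io.write_table(result.truth.table, data_dir / "truth.tsv")
            io.write_intervals(simulate.truth_intervals(result), data_dir / "genes.bed")
            phased_vcf = data_dir / "cohort.vcf"
            labels_file = data_dir / "labels.tsv"
            intervals_file = data_dir / "genes.bed"
            truth_table = result.truth.table
            finish_stage("simulate")
        else:
            phased_vcf = Path(cfg.phased_vcf)
            labels_file = Path(cfg.labels_file)
            intervals_file = Path(cfg.intervals_file) if cfg.intervals_file else None
            truth_table = None

        geno = io.read_genotypes(phased_vcf, format="vcf", autosomes=cfg.autosomes)
        labels = io.read_labels(labels_file)
        finish_stage("load")

        # -- qc ---------------------------------------------------------
        geno, snp_report = qc.filter_snps(geno, cfg.qc)
        geno, sample_report = qc.filter_samples(geno, cfg.qc)
        qc_frame = pd.concat([snp_report.to_frame(), sample_report.to_frame()], ignore_index=True)
        _write(qc_frame, out_dir, "qc_report.tsv", manifest)
        manifest["counts"]["snps_post_qc"] = geno.n_snps
        manifest["counts"]["samples_post_qc"] = geno.n_samples
        freqs = qc.allele_frequencies(geno, labels)
        _write(freqs.round(6), out_dir, "allele_frequencies.tsv", manifest)
        finish_stage("qc")

        # -- structure ---------------------------------------------------
        n_pc = min(cfg.n_pc, geno.n_samples - 1, geno.n_snps)
        pca = structure.run_pca(geno, n_pc=n_pc, scale=True)
        eig = pd.DataFrame(
            {
                "component": np.arange(1, len(pca.eigenvalues) + 1),
                "eigenvalue": pca.eigenvalues,
                "percent_variance": pca.percent_variance,
            }
        )
        _write(eig.round(6), out_dir, "pca_eigenvalues.tsv", manifest)
        model = structure.select_k_bic(pca.scores, cfg.k_grid, seed=cfg.seed, n_starts=cfg.n_starts)
        if model.best_k >= 2:
            model.discriminant_scores = structure.discriminant_functions(
                pca.scores, model.assignments, cfg.n_df
            )
        sc = pd.DataFrame(
            {
                "sample_id": geno.samples,
                "population": [labels.of(s) for s in geno.samples],
                "cluster": model.assignments,
            }
        )
        for j in range(min(4, pca.scores.shape[1])):
            sc[f"PC{j + 1}"] = np.round(pca.scores[:, j], 6)
        if model.discriminant_scores is not None:
            for j in range(model.discriminant_scores.shape[1]):
                sc[f"DF{j + 1}"] = np.round(model.discriminant_scores[:, j], 6)
        _write(sc, out_dir, "structure_scores.tsv", manifest)
        _write(
            pd.DataFrame({"K": model.k_grid, "BIC": np.round(model.bic, 6)}),
            out_dir,
            "structure_bic.tsv",
            manifest,
        )
        manifest["counts"]["best_k"] = int(model.best_k)
        finish_stage("structure")

        # -- diversity / Fst ---------------------------------------------
        div = diversity.per_locus_stats(geno, labels, corrected=True)
        div, n_clamped = diversity.clamp_negative_fst(div)
        div, thresholds = diversity.fst_outliers(div, k_sd=3.0, scope="per_chromosome")
        _write(div.round(6), out_dir, "diversity.tsv", manifest)
        _write(thresholds.round(6), out_dir, "fst_thresholds.tsv", manifest)
        _write(
            diversity.per_chromosome_heterozygosity(geno, labels).round(6),
            out_dir,
            "heterozygosity_by_chromosome.tsv",
            manifest,
        )
        _write(diversity.population_fis(geno, labels).round(6), out_dir, "population_fis.tsv", manifest)
        manifest["counts"]["fst_negative_clamped"] = int(n_clamped)
        manifest["counts"]["fst_outliers"] = int(div["outlier"].sum())
        manifest["thresholds"]["mean_fst"] = float(np.round(div["Fst"].mean(), 6))
        finish_stage("diversity")

        # -- iHS per population ------------------------------------------
        panel = io.read_haplotypes(phased_vcf, format="vcf_phased", autosomes=cfg.autosomes)
        keep = np.isin(panel.markers.snp_id, geno.markers.snp_id)
        panel = panel.subset_snps(keep)
        panel, recode_report = io.recode_ancestral(panel)
        manifest["counts"]["snps_set_missing_on_recode"] = int(len(recode_report))
        informative = ~(panel.haplotypes == io.MISSING).any(axis=0)
        panel = panel.subset_snps(informative)
        ihs_sig: dict[str, pd.DataFrame] = {}
        for pop, sub in panel.split_by_population(labels).items():
            res = scan.ihs_scan(sub, cfg.scan)
            scored = res["pihs"].dropna()
            if cfg.ihs_cutoff_mode == "fixed" or len(scored) < 100:
                cut = scan.empirical_null_cutoff([], mode="fixed", p_value=cfg.ihs_fixed_p)
            else:
                cut = scan.empirical_null_cutoff(scored.to_numpy(), mode="empirical_null")
            res["significant"] = res["pihs"] > cut.pihs_cutoff
            _write(res.round(6), out_dir, f"ihs_{pop}.tsv", manifest)
            manifest["thresholds"][f"ihs_pihs_cutoff_{pop}"] = float(np.round(cut.pihs_cutoff, 6))
            manifest["counts"][f"ihs_significant_{pop}"] = int(res["significant"].sum())
            ihs_sig[pop] = res[res["significant"]]
        finish_stage("ihs")

        # -- XP-EHH -------------------------------------------------------
        pops = labels.populations
        ref_pop = cfg.reference_population or pops[-1]
        obs_pop = next(p for p in pops if p != ref_pop)
        panels = panel.split_by_population(labels)
        xp = scan.xpehh_scan(panels[ref_pop], panels[obs_pop], cfg.scan)
        _write(xp.round(6), out_dir, "xpehh.tsv", manifest)
        manifest["counts"]["xpehh_significant"] = int(xp["significant"].sum())
        manifest["thresholds"]["xpehh_alpha"] = cfg.scan.xpehh_alpha
        finish_stage("xpehh")

        # -- windows / annotation -----------------------------------------
        sig_frames = []
        fst_sig = div[div["outlier"]]
        if len(fst_sig):
            sig_frames.append(
                pd.DataFrame(
                    {
                        "chrom": fst_sig["chrom"],
                        "pos_bp": fst_sig["pos_bp"],
                        "snp_id": fst_sig["snp_id"],
                        "score": fst_sig["Fst"],
                        "method": "fst",
                        "population": "both",
                    }
                )
            )
        for pop, sig in ihs_sig.items():
            if len(sig):
                sig_frames.append(
                    pd.DataFrame(
                        {
                            "chrom": sig["chrom"],
                            "pos_bp": sig["pos_bp"],
                            "snp_id": sig["snp_id"],
                            "score": sig["ihs"],
                            "method": "ihs",
                            "population": pop,
                        }
                    )
                )
        xp_sig = xp[xp["significant"]]
        if len(xp_sig):
            sig_frames.append(
                pd.DataFrame(
                    {
                        "chrom": xp_sig["chrom"],
                        "pos_bp": xp_sig["pos_bp"],
                        "snp_id": xp_sig["snp_id"],
                        "score": xp_sig["xpehh"],
                        "method": "xpehh",
                        "population": np.where(
                            xp_sig["direction"] == "reference", ref_pop, obs_pop
                        ),
                    }
                )
            )
        sig_all = (
            pd.concat(sig_frames, ignore_index=True)
            if sig_frames
            else pd.DataFrame(columns=["chrom", "pos_bp", "snp_id", "score", "method", "population"])
        )
        windows = annotate.make_windows(sig_all, half_width=cfg.half_width)
        _write(windows, out_dir, "candidate_windows.tsv", manifest)
        bed = windows.copy()
        if len(bed):
            bed_iv = io.IntervalSet(
                pd.DataFrame(
                    {
                        "chrom": bed["chrom"],
                        "start_bp": bed["start_bp"],
                        "end_bp": bed["end_bp"],
                        "name": bed["source_method"] + ":" + bed["population"] + ":" + bed["peak_snp"],
                        "category": "gene",
                    }
                )
            )
            io.write_intervals(bed_iv, out_dir / "candidate_windows.bed")
            manifest["outputs"].append("candidate_windows.bed")
        hits_by_method: dict[str, pd.DataFrame] = {}
        if intervals_file is not None:
            genes = io.read_intervals(intervals_file, autosomes=cfg.autosomes)
            for method in sorted(set(windows["source_method"])) if len(windows) else []:
                hits_by_method[method] = annotate.overlap_intervals(
                    windows[windows["source_method"] == method], genes
                )
                _write(hits_by_method[method], out_dir, f"gene_hits_{method}.tsv", manifest)
            consensus = annotate.consensus_genes(hits_by_method)
            _write(consensus, out_dir, "consensus_genes.tsv", manifest)
            manifest["counts"]["consensus_genes_2plus"] = int((consensus["n_methods"] >= 2).sum())
        finish_stage("annotate")

        # -- truth comparison ---------------------------------------------
        if truth_table is not None:
            sel = truth_table[truth_table["selected"]]
            rows = []
            for _, r in sel.iterrows():
                near = sig_all[
                    (sig_all["chrom"] == r["chrom"])
                    & ((sig_all["pos_bp"] - r["pos_bp"]).abs() <= cfg.half_width)
                ]
                rows.append(
                    (
                        r["snp_id"],
                        int(r["chrom"]),
                        int(r["pos_bp"]),
                        ",".join(sorted(set(near["method"]))) if len(near) else "",
                        len(near),
                    )
                )
            _write(
                pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp", "detected_by", "n_sig_snps_within_window"]),
                out_dir,
                "truth_evaluation.tsv",
                manifest,
            )
            finish_stage("truth_evaluation")
    except Exception:
        (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise
    manifest["status"] = "complete"
    (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
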