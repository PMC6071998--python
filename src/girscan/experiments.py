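"""Replicated recovery experiments for the simulated study conditions.

These are the package's calibration experiments: they rerun the full
simulate -> analyse path many times and measure how reliably the analysis
recovers what the simulator planted.  They are used by the test suite and
by the analysis drivers.

Sweep-recovery design (fixed):
    8 chromosomes x 750 SNPs (5 Mb each, ~6.7 kb spacing), Ne = 200 in both
    populations, split 50 generations, burn-in 50 generations from a
    linkage-equilibrium base (400 founder haplotypes), one locus under
    additive selection s = 0.1 in the first population starting from
    frequency 0.05 (single-origin standing variation), 100 diploids sampled
    per population.  Detection region: +-250 kb around the sweep locus (the
    candidate-window half-width).  iHS standardised in 0.05-wide
    derived-frequency bins; Fst outliers by the genome-wide mean + 3 SD rule.

Under these conditions the sweep usually runs nearly to completion
(median final frequency ~0.85), which is the regime where the
within-population haplotype test loses power by construction; the
frequency-differentiation test stays near-perfect.  The experiment reports
both marginal and joint recovery rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diversity as dv, io, scan, simulate as sm

SWEEP_REGION_BP = 250_000


def sweep_replicate(seed: int) -> dict:
    """One replicate of the sweep-recovery experiment (see module docstring)."""
    cfg = sm.SimConfig(
        seed=seed,
        n_chrom=8,
        snps_per_chrom=750,
        Ne_ancestral=200,
        Ne_pop1=200,
        Ne_pop2=200,
        t_split=50,
        t_burnin=50,
        n_founder_haplotypes=400,
        selected_loci=[sm.SelectedLocus(chrom=1, index=375, s_pop1=0.1, s_pop2=0.0, init_freq=0.05)],
        n_sample_pop1=100,
        n_sample_pop2=100,
    )
    res = sm.simulate_divergence(cfg)
    truth = res.truth.table
    sel = truth[truth["selected"]].iloc[0]

    panel, _ = io.recode_ancestral(sm.merge_panels(res.panels))
    panel = panel.subset_snps(~(panel.haplotypes == io.MISSING).any(axis=0))
    selected_pop = panel.subset_samples(
        [s for s in panel.samples if res.labels.of(s) == cfg.pop_names[0]]
    )
    ihs = scan.ihs_scan(selected_pop, scan.ScanConfig(freq_bin_width=0.05))
    scored = ihs.dropna(subset=["ihs"])
    top1 = np.quantile(np.abs(scored["ihs"]), 0.99)

    g = sm.merge_genotypes(res.genotypes)
    div = dv.per_locus_stats(g, res.labels, corrected=True)
    div, _ = dv.clamp_negative_fst(div)
    div, _ = dv.fst_outliers(div, scope="genome_wide")

    near_ihs = scored[
        (scored["chrom"] == sel["chrom"])
        & ((scored["pos_bp"] - sel["pos_bp"]).abs() <= SWEEP_REGION_BP)
    ]
    near_fst = div[
        (div["chrom"] == sel["chrom"]) & ((div["pos_bp"] - sel["pos_bp"]).abs() <= SWEEP_REGION_BP)
    ]
    return {
        "seed": seed,
        "final_freq": float(sel[f"final_freq_{cfg.pop_names[0]}"]),
        "fst_hit": bool(near_fst["outlier"].any()),
        "ihs_hit": bool(len(near_ihs) and (np.abs(near_ihs["ihs"]) >= top1).any()),
        "ihs_top1_threshold": float(top1),
        "near_max_abs_ihs": float(np.abs(near_ihs["ihs"]).max()) if len(near_ihs) else 0.0,
    }


def sweep_recovery(n_replicates: int = 50, base_seed: int = 0) -> pd.DataFrame:
    """Run the sweep-recovery experiment; one row per replicate."""
    rows = [sweep_replicate(base_seed + i) for i in range(n_replicates)]
    return pd.DataFrame(rows)


def summarize_sweep_recovery(table: pd.DataFrame) -> dict:
    both = table["fst_hit"] & table["ihs_hit"]
    return {
        "n_replicates": int(len(table)),
        "fst_rate": float(table["fst_hit"].mean()),
        "ihs_rate": float(table["ihs_hit"].mean()),
        "joint_rate": float(both.mean()),
        "median_final_freq": float(table["final_freq"].median()),
    }


def neutral_drift_recovery(
    n_replicates: int = 50, base_seed: int = 0, Ne: int = 100, t_split: int = 20
) -> dict:
    """Replicated neutral divergence vs the closed form 1-(1-1/(2Ne))^t.

    Each replicate simulates two equal-size populations with no selection
    and estimates the drift-referenced divergence from the whole-population
    final frequencies (see :func:`girscan.diversity.drift_fst_from_freqs`).
    """
    thetas = []
    for i in range(n_replicates):
        cfg = sm.SimConfig(
            seed=base_seed + i,
            n_chrom=2,
            snps_per_chrom=300,
            Ne_ancestral=Ne,
            Ne_pop1=Ne,
            Ne_pop2=Ne,
            t_split=t_split,
            t_burnin=0,
            n_founder_haplotypes=2 * Ne,
            selected_loci=[],
            n_sample_pop1=min(50, Ne),
            n_sample_pop2=min(50, Ne),
        )
        t = sm.simulate_divergence(cfg).truth.table
        thetas.append(dv.drift_fst_from_freqs(t["final_freq_beef"], t["final_freq_dairy"]))
    thetas = np.asarray(thetas)
    return {
        "n_replicates": n_replicates,
        "mean_theta": float(thetas.mean()),
        "mc_se": float(thetas.std(ddof=1) / np.sqrt(n_replicates)),
        "expected": sm.expected_fst(Ne, t_split),
    }
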