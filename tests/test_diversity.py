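"""Diversity statistics: hand values, brute-force oracle, outlier rule, drift recovery."""

import numpy as np
import pandas as pd
import pytest

from girscan import diversity as dv, io, simulate as sm
from tests.conftest import small_sim_config


def genotypes_from_freqs(counts_by_pop):
    """Build a GenotypeMatrix + labels from per-pop genotype count triples.

    ``counts_by_pop`` maps pop -> list per SNP of (n0, n1, n2) genotype counts.
    """
    pops = sorted(counts_by_pop)
    m = len(next(iter(counts_by_pop.values())))
    rows, names, labels = [], [], []
    for pop in pops:
        per_snp = counts_by_pop[pop]
        n_ind = sum(per_snp[0])
        block = np.zeros((n_ind, m), dtype=np.int8)
        for j, (n0, n1, n2) in enumerate(per_snp):
            block[:, j] = [0] * n0 + [1] * n1 + [2] * n2
        for k in range(n_ind):
            names.append(f"{pop}{k}")
            labels.append(pop)
        rows.append(block)
    mm = io.MarkerMap.from_arrays([f"s{j}" for j in range(m)], [1] * m, [100 * (j + 1) for j in range(m)])
    g = io.GenotypeMatrix(names, mm, np.vstack(rows))
    lab = io.PopulationLabels(pd.Series(labels, index=pd.Index(names, name="sample_id")))
    return g, lab


class TestPerLocusStats:
    def test_no_differentiation_hwe(self):
        # p1 = p2 = 0.5 with Ho = Hs -> Fst_raw = 0 and Fis = 0
        g, lab = genotypes_from_freqs({"a": [(1, 2, 1)], "b": [(1, 2, 1)]})
        t = dv.per_locus_stats(g, lab)
        assert t["Fst_raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert t["Fis"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternative_alleles(self):
        g, lab = genotypes_from_freqs({"a": [(0, 0, 4)], "b": [(4, 0, 0)]})
        t = dv.per_locus_stats(g, lab)
        assert t["Hs"].iloc[0] == pytest.approx(0.0)
        assert t["Ht"].iloc[0] == pytest.approx(0.5)
        assert t["Fst_raw"].iloc[0] == pytest.approx(1.0)

    def test_hand_values_p2_p8(self):
        # p1 = 0.2, p2 = 0.8 uncorrected: Hs = 0.32, Ht = 0.5, Fst = 0.36
        g, lab = genotypes_from_freqs({"a": [(3, 2, 0)], "b": [(0, 2, 3)]})
        t = dv.per_locus_stats(g, lab)
        assert t["Hs"].iloc[0] == pytest.approx(0.32)
        assert t["Ht"].iloc[0] == pytest.approx(0.5)
        assert t["Fst_raw"].iloc[0] == pytest.approx(0.36)

    def test_population_all_missing_flagged_undefined(self):
        g, lab = genotypes_from_freqs({"a": [(2, 2, 0)], "b": [(2, 2, 0)]})
        g.calls[[0, 1, 2, 3], 0] = io.MISSING  # population "a" entirely missing
        t = dv.per_locus_stats(g, lab)
        assert bool(t["undefined"].iloc[0])
        assert np.isnan(t["Fst_raw"].iloc[0])

    def test_brute_force_oracle(self, sim_cohort):
        """Vectorised statistics match an explicit per-SNP loop to 1e-12."""
        g = sm.merge_genotypes(sim_cohort.genotypes).subset_snps(np.arange(10))
        labels = sim_cohort.labels
        for corrected in (False, True):
            t = dv.per_locus_stats(g, labels, corrected=corrected)
            pops = labels.populations
            for j in range(10):
                ho_k, hs_k, p_k, n_k = [], [], [], []
                for pop in pops:
                    sub = g.calls[labels.mask(g.samples, pop), j]
                    sub = sub[sub != io.MISSING]
                    n = len(sub)
                    p = sub.sum() / (2 * n)
                    ho = (sub == 1).mean()
                    hs = 2 * p * (1 - p)
                    if corrected:
                        hs = n / (n - 1) * (2 * p * (1 - p) - ho / (2 * n))
                    ho_k.append(ho), hs_k.append(hs), p_k.append(p), n_k.append(n)
                mho, mhs = np.mean(ho_k), np.mean(hs_k)
                pbar = np.mean(p_k)
                ht = 2 * pbar * (1 - pbar)
                if corrected:
                    nh = len(pops) / sum(1 / n for n in n_k)
                    ht += mhs / (nh * len(pops)) - mho / (2 * nh * len(pops))
                assert t["Ho"].iloc[j] == pytest.approx(mho, abs=1e-12)
                assert t["Hs"].iloc[j] == pytest.approx(mhs, abs=1e-12)
                assert t["Ht"].iloc[j] == pytest.approx(ht, abs=1e-12)
                if ht > 0:
                    assert t["Fst_raw"].iloc[j] == pytest.approx((ht - mhs) / ht, abs=1e-12)

    def test_uncorrected_bounds(self, sim_cohort):
        g = sm.merge_genotypes(sim_cohort.genotypes)
        t = dv.per_locus_stats(sm.merge_genotypes(sim_cohort.genotypes), sim_cohort.labels)
        d = t.dropna(subset=["Fst_raw"])
        assert (d["Hs"] >= -1e-12).all() and (d["Hs"] <= d["Ht"] + 1e-12).all()
        assert (d["Ht"] <= 0.5 + 1e-12).all()
        assert (d["Fst_raw"] >= -1e-12).all() and (d["Fst_raw"] <= 1 + 1e-12).all()


class TestClampAndOutliers:
    def test_clamp_counts_and_values(self):
        t = pd.DataFrame({"Fst_raw": [-0.004, 0.36, -0.1]})
        out, n = dv.clamp_negative_fst(t)
        assert n == 2
        assert out["Fst"].tolist() == [0.0, 0.36, 0.0]

    def test_all_negative_gives_zero_mean(self):
        t = pd.DataFrame({"Fst_raw": [-0.2, -0.01]})
        out, _ = dv.clamp_negative_fst(t)
        assert out["Fst"].mean() == 0.0

    def test_constant_fst_no_outliers(self):
        t = pd.DataFrame({"chrom": [1] * 5, "Fst_raw": [0.03] * 5})
        t, _ = dv.clamp_negative_fst(t)
        t, thr = dv.fst_outliers(t)
        assert not t["outlier"].any()

    def test_single_spike_flagged(self):
        t = pd.DataFrame({"chrom": [1] * 101, "Fst_raw": [0.03] * 100 + [0.5]})
        t, _ = dv.clamp_negative_fst(t)
        t, thr = dv.fst_outliers(t)
        assert t["outlier"].sum() == 1
        assert t.loc[t["outlier"], "Fst_raw"].iloc[0] == 0.5
        assert thr["threshold"].iloc[0] == pytest.approx(
            np.mean(t["Fst"]) + 3 * np.std(t["Fst"], ddof=1)
        )

    def test_simulated_sweep_locus_is_outlier(self, sim_cohort):
        g = sm.merge_genotypes(sim_cohort.genotypes)
        t = dv.per_locus_stats(g, sim_cohort.labels, corrected=True)
        t, _ = dv.clamp_negative_fst(t)
        t, _ = dv.fst_outliers(t)
        truth = sim_cohort.truth.table
        sel = truth[truth["selected"]].iloc[0]
        near = t[(t["chrom"] == sel["chrom"]) & ((t["pos_bp"] - sel["pos_bp"]).abs() <= 100_000)]
        assert near["outlier"].any()

    def test_short_chromosome_warns(self):
        t = pd.DataFrame({"chrom": [1], "Fst_raw": [0.1]})
        t, _ = dv.clamp_negative_fst(t)
        with pytest.warns(UserWarning):
            t, thr = dv.fst_outliers(t)
        assert not t["outlier"].any()


class TestHeterozygosity:
    def test_identical_homozygotes_zero(self):
        g, lab = genotypes_from_freqs({"a": [(4, 0, 0), (0, 0, 4)], "b": [(2, 2, 0), (2, 2, 0)]})
        t = dv.per_chromosome_heterozygosity(g, lab)
        assert t["Ho_a"].iloc[0] == 0.0

    def test_single_snp_chromosome(self):
        g, lab = genotypes_from_freqs({"a": [(2, 2, 0)], "b": [(0, 4, 0)]})
        t = dv.per_chromosome_heterozygosity(g, lab)
        assert t["Ho_a"].iloc[0] == pytest.approx(0.5)
        assert t["Ho_b"].iloc[0] == pytest.approx(1.0)
        assert t["diff"].iloc[0] == pytest.approx(-0.5)

    def test_closed_herd_less_heterozygous(self):
        """Smaller-Ne population shows lower genome-wide mean Ho at matched settings."""
        cfg = small_sim_config(seed=9, selected_loci=[], Ne_pop1=60, Ne_pop2=240, t_split=40)
        res = sm.simulate_divergence(cfg)
        g = sm.merge_genotypes(res.genotypes)
        t = dv.per_chromosome_heterozygosity(g, res.labels)
        assert t["Ho_beef"].mean() < t["Ho_dairy"].mean()


class TestDriftRecovery:
    def test_neutral_fst_matches_closed_form(self):
        """Mean divergence over replicates within 3 MC SEs of 1-(1-1/(2Ne))^t."""
        thetas = []
        for seed in range(25):
            cfg = sm.SimConfig(
                seed=seed, n_chrom=2, snps_per_chrom=300, Ne_ancestral=100, Ne_pop1=100,
                Ne_pop2=100, t_split=20, t_burnin=0, n_founder_haplotypes=200,
                selected_loci=[], n_sample_pop1=50, n_sample_pop2=50,
            )
            t = sm.simulate_divergence(cfg).truth.table
            thetas.append(dv.drift_fst_from_freqs(t["final_freq_beef"], t["final_freq_dairy"]))
        mean = np.mean(thetas)
        se = np.std(thetas, ddof=1) / np.sqrt(len(thetas))
        assert abs(mean - sm.expected_fst(100, 20)) <= 3 * se
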