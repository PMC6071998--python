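"""Selection scans: EHH oracle, iHH integration, iHS/XP-EHH and cutoffs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from girscan import io, scan, simulate as sm
from tests.conftest import small_sim_config


def panel_from_rows(rows, positions=None, chrom=None):
    rows = np.asarray(rows, dtype=np.int8)
    n_hap, m = rows.shape
    assert n_hap % 2 == 0
    positions = positions or [1000 * (j + 1) for j in range(m)]
    chrom = chrom or [1] * m
    mm = io.MarkerMap.from_arrays([f"s{j}" for j in range(m)], chrom, positions)
    samples = [f"x{i}" for i in range(n_hap // 2)]
    return io.HaplotypePanel(samples, mm, rows, coding="ancestral_derived")


def brute_force_ehh(h, carriers, focal, m):
    """Pair-counting oracle: fraction of carrier pairs identical over the
    markers strictly between focal and m (inclusive of m)."""
    if focal <= m:
        span = range(focal + 1, m + 1)
    else:
        span = range(m, focal)
    pairs = list(itertools.combinations(carriers, 2))
    if not pairs:
        return np.nan
    same = sum(1 for a, b in pairs if all(h[a, j] == h[b, j] for j in span))
    return same / len(pairs)


class TestEhhDecay:
    def test_focal_is_one_and_identical_carriers_stay_one(self):
        rows = np.array(
            [
                [1, 1, 1, 1],
                [1, 1, 1, 1],
                [1, 1, 1, 1],
                [1, 1, 1, 1],
                [0, 0, 1, 0],
                [0, 1, 0, 0],
            ]
        )
        panel = panel_from_rows(rows)
        curve = scan.ehh_decay(panel, 0, "derived")
        assert curve.right_ehh[0] == 1.0
        assert (curve.right_ehh == 1.0).all()

    def test_two_two_split_gives_one_third(self):
        # 4 carriers splitting 2/2 at the first flank SNP: (1+1)/6
        rows = np.array(
            [
                [1, 0],
                [1, 0],
                [1, 1],
                [1, 1],
                [0, 0],
                [0, 1],
            ]
        )
        panel = panel_from_rows(rows)
        curve = scan.ehh_decay(panel, 0, "derived", scan.ScanConfig(ehh_floor=0.01))
        assert curve.right_ehh[1] == pytest.approx(1 / 3)

    def test_brute_force_oracle_small_panels(self):
        """EHH curves match exhaustive pair counting on random <=8-hap panels."""
        rng = np.random.default_rng(17)
        cfg = scan.ScanConfig(ehh_floor=1e-9, max_gap_bp=10**9)
        for trial in range(25):
            rows = rng.integers(0, 2, size=(8, 10)).astype(np.int8)
            panel = panel_from_rows(rows)
            focal = int(rng.integers(0, 10))
            for core, allele in (("ancestral", 0), ("derived", 1), ("site", None)):
                carriers = (
                    np.arange(8) if core == "site" else np.flatnonzero(rows[:, focal] == allele)
                )
                curve = scan.ehh_decay(panel, focal, core, cfg)
                if carriers.size < 2:
                    assert not curve.defined
                    continue
                for pos, ehh in ((curve.right_pos, curve.right_ehh), (curve.left_pos, curve.left_ehh)):
                    for p, e in zip(pos[1:], ehh[1:]):
                        m = int(np.flatnonzero(panel.markers.pos_bp == p)[0])
                        assert e == pytest.approx(brute_force_ehh(rows, carriers, focal, m))

    def test_monotone_nonincreasing_and_bounded(self, sim_panel_coded):
        cfg = scan.ScanConfig()
        rng = np.random.default_rng(3)
        for focal in rng.integers(0, sim_panel_coded.n_snps, size=12):
            curve = scan.ehh_decay(sim_panel_coded, int(focal), "site", cfg)
            for ehh in (curve.left_ehh, curve.right_ehh):
                assert (np.diff(ehh) <= 1e-12).all()
                assert (ehh >= 0).all() and (ehh <= 1).all()

    def test_fewer_than_two_carriers_flagged(self):
        rows = np.array([[1, 0], [0, 0], [0, 1], [0, 0]])
        panel = panel_from_rows(rows)
        curve = scan.ehh_decay(panel, 0, "derived")
        assert not curve.defined
        assert np.isnan(scan.integrate_ehh(curve))

    def test_gap_rule_ends_flank(self):
        rows = np.array([[1, 1, 1], [1, 1, 0], [0, 1, 1], [0, 0, 1]])
        panel = panel_from_rows(rows, positions=[1000, 2000, 40_000])
        curve = scan.ehh_decay(panel, 0, "derived", scan.ScanConfig(max_gap_bp=20_000))
        assert curve.right_pos[-1] == 2000  # the 38 kb gap ends the walk

    def test_missing_panel_rejected(self):
        rows = np.array([[1, -1], [1, 0], [0, 0], [0, 1]])
        panel = panel_from_rows(rows)
        with pytest.raises(ValueError, match="complete"):
            scan.ehh_decay(panel, 0, "derived")


class TestIntegrateEhh:
    def test_rectangle(self):
        c = scan.EHHCurve(0, "site", 4)
        c.left_pos, c.left_ehh = np.array([5000, 4000, 3000]), np.array([1.0, 1.0, 1.0])
        c.right_pos, c.right_ehh = np.array([5000, 6000, 7000]), np.array([1.0, 1.0, 1.0])
        assert scan.integrate_ehh(c) == pytest.approx(4000.0)

    def test_single_trapezoid(self):
        c = scan.EHHCurve(0, "site", 4)
        c.right_pos, c.right_ehh = np.array([0, 1000]), np.array([1.0, 0.5])
        c.left_pos, c.left_ehh = np.array([0]), np.array([1.0])
        assert scan.integrate_ehh(c) == pytest.approx(750.0)

    def test_linear_in_distance(self):
        c = scan.EHHCurve(0, "site", 4)
        c.right_pos, c.right_ehh = np.array([0, 500, 1500]), np.array([1.0, 0.6, 0.2])
        c.left_pos, c.left_ehh = np.array([0]), np.array([1.0])
        base = scan.integrate_ehh(c)
        c.right_pos = c.right_pos * 2
        assert scan.integrate_ehh(c) == pytest.approx(2 * base)


class TestTransforms:
    # (standardised score, printed -log10 two-sided p) pairs, within- and
    # cross-population top regions
    TABLE_PAIRS = [
        (-3.42, 3.20), (3.44, 3.23), (-3.92, 4.05), (-3.61, 3.51), (3.97, 4.14),
        (3.57, 3.45), (3.79, 3.82), (-4.22, 4.62), (-3.51, 3.34), (-3.47, 3.29),
        (3.86, 3.95), (-3.85, 3.93), (3.68, 3.63), (4.00, 4.20), (4.08, 4.34),
        (3.72, 3.70), (-3.69, 3.65), (-4.43, 5.03), (-4.21, 4.59), (4.32, 4.81),
        (2.20, 1.56), (2.24, 1.60), (2.33, 1.71), (2.19, 1.55), (2.22, 1.58),
        (2.29, 1.66), (2.28, 1.65), (2.44, 1.83), (2.17, 1.53),
        (-6.66, 10.56), (-6.72, 10.75), (-6.64, 10.51), (-6.67, 10.61),
        (-7.02, 11.65), (-6.90, 11.29), (-6.84, 11.11), (-6.79, 10.96),
        (-6.81, 11.02), (-6.65, 10.54),
    ]

    def test_zero_maps_to_zero(self):
        assert scan.pihs_transform(0.0) == 0.0

    def test_reference_pairs_to_printed_precision(self):
        """Published score/p pairs agree allowing for the scores' own 2-dp rounding."""
        from scipy.stats import norm

        for x, expected in self.TABLE_PAIRS:
            got = scan.pihs_transform(x)
            slope = norm.pdf(abs(x)) / norm.sf(abs(x)) / np.log(10)
            tol = 0.005 * slope + 0.0051
            assert abs(got - expected) <= tol, (x, got, expected)

    @given(st.floats(min_value=-30, max_value=30, allow_nan=False))
    @settings(deadline=None, max_examples=60)
    def test_symmetric_nonnegative_monotone(self, x):
        v = scan.pihs_transform(x)
        assert v >= 0.0
        assert v == pytest.approx(scan.pihs_transform(-x), rel=1e-12)
        assert scan.pihs_transform(abs(x) + 0.5) > v

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            scan.pihs_transform(float("nan"))


class TestIhsScan:
    def test_bin_standardisation_mean_zero_sd_one(self, sim_panel_coded):
        res = scan.ihs_scan(sim_panel_coded, scan.ScanConfig(freq_bin_width=0.05))
        ok = res[res["status"] == "ok"].dropna(subset=["ihs"])
        for b, grp in ok.groupby("freq_bin"):
            if len(grp) >= 2:
                assert grp["ihs"].mean() == pytest.approx(0.0, abs=1e-9)
                assert grp["ihs"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_equal_ihh_gives_zero_unihs(self):
        # perfectly symmetric panel: ancestral and derived flanks mirror
        rows = np.array(
            [
                [1, 1, 0, 1, 1],
                [1, 0, 1, 0, 1],
                [0, 1, 1, 1, 0],
                [0, 0, 0, 0, 0],
            ]
        )
        panel = panel_from_rows(rows)
        res = scan.ihs_scan(panel, scan.ScanConfig(maf=0.0, freq_bin_width=0.5))
        mid = res.iloc[2]
        assert mid["ihh_a"] == pytest.approx(mid["ihh_d"])
        assert mid["unihs"] == pytest.approx(0.0)

    def test_maf_filter_and_skip_reasons(self, sim_panel_coded):
        res = scan.ihs_scan(sim_panel_coded, scan.ScanConfig(maf=0.05, freq_bin_width=0.05))
        q = res["freq_derived"]
        assert (res.loc[np.minimum(q, 1 - q) < 0.05, "status"] == "maf").all()
        assert res.loc[res["status"] == "maf", "ihs"].isna().all()

    def test_requires_recoded_panel(self, sim_cohort):
        raw = sm.merge_panels(sim_cohort.panels)
        with pytest.raises(ValueError, match="ancestral"):
            scan.ihs_scan(raw)

    def test_neutral_tail_calibration(self):
        """|iHS| > 1.96 in ~5% of SNPs under neutrality (3 MC SEs over replicates)."""
        # the Gaussian tail calibration needs enough haplotypes per core and
        # enough SNPs per frequency bin; small panels run measurably light
        fracs = []
        for seed in range(6):
            cfg = sm.SimConfig(
                seed=500 + seed, n_chrom=4, snps_per_chrom=750, Ne_ancestral=200,
                Ne_pop1=200, Ne_pop2=200, t_split=25, t_burnin=40,
                n_founder_haplotypes=400, selected_loci=[],
                n_sample_pop1=137, n_sample_pop2=137,
            )
            res = sm.simulate_divergence(cfg)
            panel, _ = io.recode_ancestral(sm.merge_panels(res.panels))
            panel = panel.subset_snps(~(panel.haplotypes == io.MISSING).any(axis=0))
            beef = panel.subset_samples([s for s in panel.samples if res.labels.of(s) == "beef"])
            v = scan.ihs_scan(beef, scan.ScanConfig(freq_bin_width=0.10))["ihs"].dropna()
            fracs.append(float((np.abs(v) > 1.96).mean()))
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - 0.05) <= 3 * se

    def test_incomplete_sweep_tops_chromosome(self):
        """An ongoing sweep attains the chromosome's top |iHS| rank."""
        hits = 0
        for seed in range(5):
            cfg = small_sim_config(
                seed=200 + seed, n_chrom=3, snps_per_chrom=400,
                selected_loci=[sm.SelectedLocus(chrom=1, index=200, s_pop1=0.15, s_pop2=0.0, init_freq=0.2)],
                t_split=20, n_sample_pop1=70, n_sample_pop2=70,
            )
            res = sm.simulate_divergence(cfg)
            truth = res.truth.table
            sel = truth[truth["selected"]].iloc[0]
            if not (0.4 <= sel["final_freq_beef"] <= 0.95):  # sweep must be incomplete
                continue
            panel, _ = io.recode_ancestral(sm.merge_panels(res.panels))
            panel = panel.subset_snps(~(panel.haplotypes == io.MISSING).any(axis=0))
            beef = panel.subset_samples([s for s in panel.samples if res.labels.of(s) == "beef"])
            ihs = scan.ihs_scan(beef, scan.ScanConfig(freq_bin_width=0.05)).dropna(subset=["ihs"])
            chrom1 = ihs[ihs["chrom"] == 1]
            top = chrom1.loc[chrom1["ihs"].abs().idxmax()]
            if abs(top["pos_bp"] - sel["pos_bp"]) <= 250_000:
                hits += 1
        assert hits >= 1


class TestXpehhScan:
    def test_antisymmetric_under_population_swap(self, sim_cohort):
        panels = {
            p: panel
            for p, panel in sm.merge_panels(sim_cohort.panels)
            .split_by_population(sim_cohort.labels)
            .items()
        }
        cfg = scan.ScanConfig()
        fwd = scan.xpehh_scan(panels["dairy"], panels["beef"], cfg)
        rev = scan.xpehh_scan(panels["beef"], panels["dairy"], cfg)
        ok = fwd["xpehh"].notna() & rev["xpehh"].notna()
        assert np.allclose(fwd.loc[ok, "xpehh"], -rev.loc[ok, "xpehh"], atol=1e-9)

    def test_median_centred_and_significance_rule(self, sim_cohort):
        panels = sm.merge_panels(sim_cohort.panels).split_by_population(sim_cohort.labels)
        res = scan.xpehh_scan(panels["dairy"], panels["beef"])
        scores = res["xpehh"].dropna()
        assert np.median(scores) == pytest.approx(0.0, abs=1e-9)
        sig = res[res["significant"]]
        assert (sig["pxpehh"] > 2.0).all()  # -log10(0.01)
        neg = res[(res["xpehh"] < 0) & res["xpehh"].notna()]
        assert (neg["direction"] == "reference").all()

    def test_sign_convention_configurable(self, sim_cohort):
        panels = sm.merge_panels(sim_cohort.panels).split_by_population(sim_cohort.labels)
        res = scan.xpehh_scan(
            panels["dairy"], panels["beef"], scan.ScanConfig(sign_convention="positive_is_reference")
        )
        neg = res[(res["xpehh"] < 0) & res["xpehh"].notna()]
        assert (neg["direction"] == "observed").all()

    def test_mismatched_maps_rejected(self, sim_cohort):
        panels = sm.merge_panels(sim_cohort.panels).split_by_population(sim_cohort.labels)
        trimmed = panels["beef"].subset_snps(np.arange(panels["beef"].n_snps) > 0)
        with pytest.raises(ValueError, match="marker map"):
            scan.xpehh_scan(panels["dairy"], trimmed)


class TestCutoffs:
    def test_fixed_mode_printed_thresholds(self):
        assert round(scan.empirical_null_cutoff([], mode="fixed", p_value=0.008).pihs_cutoff, 2) == 2.10
        assert scan.empirical_null_cutoff([], mode="fixed", p_value=1.0).pihs_cutoff == pytest.approx(0.0)

    def test_uniform_null_is_conservative(self):
        rng = np.random.default_rng(123)
        p = rng.uniform(size=10_000)
        pihs = -np.log10(p)
        cut = scan.empirical_null_cutoff(pihs, mode="empirical_null")
        assert 0.9 <= cut.eta0 <= 1.0
        assert cut.p_cutoff < 0.01

    def test_signal_mixture_yields_separating_cutoff(self):
        rng = np.random.default_rng(7)
        null_p = rng.uniform(size=5000)
        signal_p = 10 ** (-rng.uniform(4, 8, size=300))
        pihs = -np.log10(np.concatenate([null_p, signal_p]))
        cut = scan.empirical_null_cutoff(pihs, mode="empirical_null")
        assert cut.p_cutoff < 0.05
        n_called = (10.0**-pihs <= cut.p_cutoff).sum()
        assert 200 <= n_called <= 1200

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            scan.empirical_null_cutoff(np.full(200, 1.5), mode="empirical_null")
        with pytest.raises(ValueError, match="at least 100"):
            scan.empirical_null_cutoff(np.array([1.0, 2.0]), mode="empirical_null")
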