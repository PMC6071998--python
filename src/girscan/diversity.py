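"""Per-locus diversity statistics (Ho, Hs, Ht, Fis, Fst) and Fst outliers.

For each biallelic SNP with population frequencies p_k and observed
heterozygote frequencies Ho_k:

    Ho = mean_k Ho_k
    Hs = mean_k 2 p_k (1 - p_k)
    Ht = 2 pbar (1 - pbar),  pbar = unweighted mean of the p_k
    Fst = (Ht - Hs) / Ht          (Nei's gene-diversity partition)
    Fis = 1 - Ho / Hs

Populations enter with equal weight regardless of sample size (hierarchical
convention).  With ``corrected=True`` the small-sample corrections of Nei's
unbiased estimators are applied:

    Hs_k' = n_k/(n_k - 1) * (2 p_k q_k - Ho_k / (2 n_k))
    Ht'   = 2 pbar qbar + mean_k Hs_k' / (nh * r) - Ho / (2 nh * r)

with n_k the genotyped individuals in population k, nh their harmonic mean
and r the number of populations.  The corrected estimator can produce small
negative Fst values at undifferentiated loci; these are clamped to zero by
:func:`clamp_negative_fst` since negative fixation has no biological reading.

Outliers are flagged by a control-chart rule: Fst above mean + k.SD of the
defined Fst values, by default separately within each autosome.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationLabels


def _per_population_arrays(
    g: GenotypeMatrix, labels: PopulationLabels
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Per-population (n_k, p_k, Ho_k) arrays, each shaped (n_pops, n_snps)."""
    pops = labels.populations
    n = np.zeros((len(pops), g.n_snps))
    p = np.full((len(pops), g.n_snps), np.nan)
    ho = np.full((len(pops), g.n_snps), np.nan)
    for k, pop in enumerate(pops):
        sub = g.calls[labels.mask(g.samples, pop)]
        obs = sub != MISSING
        nk = obs.sum(axis=0)
        dose = np.where(obs, sub, 0).sum(axis=0)
        het = ((sub == 1) & obs).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n[k] = nk
            p[k] = np.where(nk > 0, dose / (2.0 * nk), np.nan)
            ho[k] = np.where(nk > 0, het / nk, np.nan)
    return pops, n, p, ho


def per_locus_stats(
    g: GenotypeMatrix, labels: PopulationLabels, corrected: bool = False
) -> pd.DataFrame:
    """Per-SNP diversity table with columns Ho, Hs, Ht, Fis, Fst_raw.

    SNPs where any population has fewer than 2 genotyped samples are flagged
    ``undefined`` and carry NaN statistics; SNPs with Ht = 0 have NaN Fst_raw
    (excluded from downstream means).  Per-population frequency columns
    ``p_<pop>`` and ``Ho_<pop>`` are included.
    """
    pops, n, p, ho = _per_population_arrays(g, labels)
    r = len(pops)
    if r < 2:
        raise ValueError("diversity statistics require at least 2 populations")
    defined = (n >= 2).all(axis=0)

    q = 1.0 - p
    hs_k = 2.0 * p * q
    with np.errstate(invalid="ignore", divide="ignore"):
        if corrected:
            hs_k = n / (n - 1.0) * (2.0 * p * q - ho / (2.0 * n))
        mho = ho.mean(axis=0)
        mhs = hs_k.mean(axis=0)
        pbar = p.mean(axis=0)
        ht = 2.0 * pbar * (1.0 - pbar)
        if corrected:
            nh = r / (1.0 / n).sum(axis=0)  # harmonic mean sample size
            ht = ht + mhs / (nh * r) - mho / (2.0 * nh * r)
        fst = np.where(ht > 0, (ht - mhs) / ht, np.nan)
        fis = np.where(mhs > 0, 1.0 - mho / mhs, np.nan)

    t = g.markers.table
    out = pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "chrom": t["chrom"],
            "pos_bp": t["pos_bp"],
            "Ho": np.where(defined, mho, np.nan),
            "Hs": np.where(defined, mhs, np.nan),
            "Ht": np.where(defined, ht, np.nan),
            "Fis": np.where(defined, fis, np.nan),
            "Fst_raw": np.where(defined, fst, np.nan),
            "undefined": ~defined,
        }
    )
    for k, pop in enumerate(pops):
        out[f"p_{pop}"] = p[k]
        out[f"Ho_{pop}"] = ho[k]
    return out


def clamp_negative_fst(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Add a clamped ``Fst`` column (max(Fst_raw, 0)); return the clamp count."""
    out = table.copy()
    neg = out["Fst_raw"] < 0
    out["Fst"] = out["Fst_raw"].clip(lower=0.0)
    return out, int(neg.sum())


def fst_outliers(
    table: pd.DataFrame, k_sd: float = 3.0, scope: str = "per_chromosome"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag SNPs with Fst above mean + k_sd * SD (control-chart rule).

    ``scope="per_chromosome"`` computes one threshold per autosome;
    ``scope="genome_wide"`` a single threshold.  SD uses ddof=1.  Units with
    fewer than 2 defined Fst values get no threshold and no outliers.
    Returns the table with an ``outlier`` column and a threshold table.
    """
    if "Fst" not in table.columns:
        raise ValueError("run clamp_negative_fst first (no Fst column)")
    out = table.copy()
    out["outlier"] = False
    rows = []
    if scope == "per_chromosome":
        groups = [(int(c), g) for c, g in out.groupby("chrom")]
    elif scope == "genome_wide":
        groups = [("genome", out)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for unit, grp in groups:
        vals = grp["Fst"].dropna()
        if len(vals) < 2:
            warnings.warn(f"scope unit {unit}: fewer than 2 defined Fst values; no threshold")
            rows.append((unit, len(vals), np.nan, np.nan, np.nan, 0))
            continue
        mean, sd = vals.mean(), vals.std(ddof=1)
        thr = mean + k_sd * sd
        flag = grp["Fst"] > thr
        out.loc[grp.index[flag.fillna(False)], "outlier"] = True
        rows.append((unit, len(vals), mean, sd, thr, int(flag.sum())))
    thresholds = pd.DataFrame(
        rows, columns=["scope_unit", "n_defined", "mean_fst", "sd_fst", "threshold", "n_outliers"]
    )
    return out, thresholds


def per_chromosome_heterozygosity(
    g: GenotypeMatrix, labels: PopulationLabels
) -> pd.DataFrame:
    """Mean observed heterozygosity per (chromosome, population), wide layout.

    One row per chromosome with a column per population and a ``diff`` column
    (first minus second population in sorted name order).
    """
    pops, n, p, ho = _per_population_arrays(g, labels)
    chrom = g.markers.chrom
    rows = []
    for c in np.unique(chrom):
        sel = chrom == c
        means = [np.nanmean(ho[k, sel]) if np.isfinite(ho[k, sel]).any() else np.nan for k in range(len(pops))]
        rows.append([int(c), *means])
    out = pd.DataFrame(rows, columns=["chrom", *[f"Ho_{p}" for p in pops]])
    if len(pops) == 2:
        out["diff"] = out[f"Ho_{pops[0]}"] - out[f"Ho_{pops[1]}"]
    return out


def population_fis(
    g: GenotypeMatrix, labels: PopulationLabels, corrected: bool = True
) -> pd.DataFrame:
    """Genome-wide Fis per population: 1 - mean(Ho_k) / mean(Hs_k)."""
    pops, n, p, ho = _per_population_arrays(g, labels)
    q = 1.0 - p
    with np.errstate(invalid="ignore", divide="ignore"):
        hs = 2.0 * p * q
        if corrected:
            hs = n / (n - 1.0) * (2.0 * p * q - ho / (2.0 * n))
    rows = []
    for k, pop in enumerate(pops):
        ok = np.isfinite(ho[k]) & np.isfinite(hs[k])
        mho, mhs = ho[k, ok].mean(), hs[k, ok].mean()
        rows.append((pop, mho, mhs, 1.0 - mho / mhs if mhs > 0 else np.nan))
    return pd.DataFrame(rows, columns=["population", "mean_Ho", "mean_Hs", "Fis"])


def drift_fst_from_freqs(p1: np.ndarray, p2: np.ndarray) -> float:
    """Deme-count-corrected divergence estimator targeting 1-(1-1/(2Ne))^t.

    For two populations that split t generations ago from an ancestral pool
    and drifted independently, the per-population variance inflation is
    g = 1-(1-1/(2Ne))^t, i.e. Var(p_k) = p0 q0 g.  Nei's (Ht-Hs)/Ht computed
    from the two daughter demes has expectation ~ g/(2-g) because Ht is built
    from the daughters' mean frequency rather than the ancestral pool:
    E[Ht - Hs] = p0 q0 g but E[Ht] = 2 p0 q0 (1 - g/2).  Restoring the
    ancestral heterozygosity in the denominator,

        theta = sum_j (Ht_j - Hs_j) / sum_j (Ht_j/2 + (Ht_j - Hs_j)/2)

    has ratio-of-means expectation exactly g (the denominator's expectation is
    p0 q0 per SNP, as in the Weir-Cockerham construction for r = 2 demes).
    Frequencies are taken as known (e.g. whole simulated populations); no
    sample-size correction is applied.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = (p1 + p2) / 2.0
    hs = p1 * (1 - p1) + p2 * (1 - p2)  # = mean_k 2 p_k q_k
    ht = 2.0 * pbar * (1.0 - pbar)
    num = ht - hs
    den = ht / 2.0 + num / 2.0
    ok = den > 0
    if not ok.any():
        raise ValueError("all loci monomorphic; divergence undefined")
    return float(num[ok].sum() / den[ok].sum())
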