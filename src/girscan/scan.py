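"""Haplotype-based selection scans: EHH decay, iHS and XP-EHH.

Extended haplotype homozygosity (EHH) at a marker m relative to a focal SNP
is the probability that two randomly drawn carrier haplotypes are identical
at every marker between the focal SNP and m:

    EHH(m) = sum_h C(n_h, 2) / C(n, 2)

where the n carriers partition into groups of identical haplotypes of sizes
n_h over the interval.  For allele cores ("ancestral"/"derived") carriers are
the haplotypes bearing that allele at the focal SNP; for the allele-agnostic
"site" core every haplotype is a carrier and identity is tracked over the
flanking markers only, so EHH(focal) = 1 by construction (this is the iES
building block of the cross-population test).

iHH is the trapezoidal integral of EHH over physical distance (bp x EHH),
both flanks summed, truncated at the first marker where EHH falls below the
floor (that marker's trapezoid is included), at an inter-marker gap larger
than ``max_gap_bp``, or at the chromosome end (flagged border-truncated).

The within-population statistic standardises UniHS = ln(iHH_A / iHH_D)
within derived-allele-frequency bins; the cross-population statistic
standardises LRiES = ln(iES_ref / iES_obs) by its median and SD.  Both are
mapped to -log10 two-sided Gaussian p-values via 2*Phi(-|x|), computed on
the log scale so that scores beyond |x| ~ 6 remain accurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm

from .io import MISSING, HaplotypePanel


@dataclass
class ScanConfig:
    ehh_floor: float = 0.05
    max_gap_bp: int = 20_000
    max_extent_bp: int = 1_000_000
    maf: float = 0.01
    freq_bin_width: float = 0.01
    xpehh_alpha: float = 0.01
    sign_convention: str = "negative_is_reference"

    def __post_init__(self) -> None:
        if not (0.0 < self.ehh_floor < 1.0):
            raise ValueError("ehh_floor must lie in (0, 1)")
        if not (0.0 < self.freq_bin_width <= 0.5):
            raise ValueError("freq_bin_width must lie in (0, 0.5]")
        if self.sign_convention not in ("negative_is_reference", "positive_is_reference"):
            raise ValueError(f"unknown sign_convention {self.sign_convention!r}")


@dataclass
class EHHCurve:
    focal_index: int
    core: str  # "ancestral" | "derived" | "site"
    n_haplotypes_retained: int
    # flank arrays run outward from the focal SNP (first entry = focal, EHH=1)
    left_pos: np.ndarray = field(default_factory=lambda: np.empty(0))
    left_ehh: np.ndarray = field(default_factory=lambda: np.empty(0))
    right_pos: np.ndarray = field(default_factory=lambda: np.empty(0))
    right_ehh: np.ndarray = field(default_factory=lambda: np.empty(0))
    defined: bool = True
    border_truncated: bool = False


def _check_complete(panel: HaplotypePanel) -> None:
    if not panel.is_complete():
        raise ValueError(
            "selection scans require a complete phased panel (no missing alleles); "
            "impute/phase upstream"
        )


def _int_haplotypes(panel: HaplotypePanel) -> np.ndarray:
    """Haplotypes as small ints; raw panels are coded against allele_a."""
    if panel.coding == "ancestral_derived":
        return panel.haplotypes.astype(np.int8)
    return (panel.haplotypes == panel.markers.table["allele_a"].to_numpy()[None, :]).astype(np.int8)


def _walk(
    h: np.ndarray,
    carrier_rows: np.ndarray,
    positions: np.ndarray,
    focal: int,
    lo: int,
    hi: int,
    direction: int,
    floor: float,
    max_gap: int,
    max_extent: int,
) -> tuple[list[int], list[float], str]:
    """EHH along one flank.  Returns (positions, ehh, end_reason).

    ``lo``/``hi`` bound the focal SNP's chromosome (inclusive indices).
    The walk appends the first marker whose EHH drops below the floor, then
    stops; a gap larger than ``max_gap`` ends the flank before the far
    marker, as does a marker beyond ``max_extent`` bp from the focal SNP
    (haplotype homozygosity can plateau above the floor in few-founder
    populations, so an extent cap bounds the integral like the common
    scan-tool default of 1 Mb).
    """
    n = carrier_rows.size
    denom = n * (n - 1) / 2.0
    gid = np.zeros(n, dtype=np.int64)
    pos_out = [int(positions[focal])]
    ehh_out = [1.0]
    m = focal
    while True:
        m_next = m + direction
        if m_next < lo or m_next > hi:
            return pos_out, ehh_out, "chrom_end"
        if abs(int(positions[m_next]) - int(positions[focal])) > max_extent:
            return pos_out, ehh_out, "max_extent"
        if abs(int(positions[m_next]) - int(positions[m])) > max_gap:
            return pos_out, ehh_out, "gap"
        _, gid = np.unique(gid * 2 + h[carrier_rows, m_next], return_inverse=True)
        counts = np.bincount(gid)
        ehh = float((counts * (counts - 1)).sum() / 2.0 / denom)
        pos_out.append(int(positions[m_next]))
        ehh_out.append(ehh)
        m = m_next
        if ehh < floor:
            return pos_out, ehh_out, "floor"


@njit(cache=True)
def _ihh_flank(h, pos, focal, lo, hi, direction, floor, max_gap, max_extent, carriers):
    """Compiled single-flank walk returning (iHH, end_reason, last_ehh).

    Identical trapezoids to :func:`integrate_ehh` over the curve produced by
    the Python walk; end_reason codes: 0 chrom_end, 1 floor, 2 gap, 3 extent.
    """
    n = carriers.shape[0]
    denom = n * (n - 1) / 2.0
    gid = np.zeros(n, dtype=np.int64)
    ihh = 0.0
    prev_ehh = 1.0
    m = focal
    while True:
        m_next = m + direction
        if m_next < lo or m_next > hi:
            return ihh, 0, prev_ehh
        if abs(pos[m_next] - pos[focal]) > max_extent:
            return ihh, 3, prev_ehh
        if abs(pos[m_next] - pos[m]) > max_gap:
            return ihh, 2, prev_ehh
        key2new = np.full(2 * n, -1, dtype=np.int64)
        nid = 0
        for i in range(n):
            key = gid[i] * 2 + h[carriers[i], m_next]
            if key2new[key] == -1:
                key2new[key] = nid
                nid += 1
            gid[i] = key2new[key]
        counts = np.zeros(nid, dtype=np.int64)
        for i in range(n):
            counts[gid[i]] += 1
        pairs = 0
        for k in range(nid):
            pairs += counts[k] * (counts[k] - 1)
        ehh = pairs / 2.0 / denom
        ihh += (prev_ehh + ehh) / 2.0 * abs(pos[m_next] - pos[m])
        prev_ehh = ehh
        m = m_next
        if ehh < floor:
            return ihh, 1, prev_ehh


def _ihh_both_flanks(h, pos, focal, lo, hi, carriers, cfg):
    """(iHH, border_truncated) summing both flanks via the compiled walk."""
    total = 0.0
    border = False
    for direction in (-1, 1):
        ihh, reason, last_ehh = _ihh_flank(
            h, pos, focal, lo, hi, direction, cfg.ehh_floor, cfg.max_gap_bp, cfg.max_extent_bp, carriers
        )
        total += ihh
        border |= reason == 0 and last_ehh >= cfg.ehh_floor
    return total, border


def ehh_decay(
    panel: HaplotypePanel, focal: int, core: str, cfg: ScanConfig | None = None
) -> EHHCurve:
    """EHH decay curve on both flanks of a focal SNP.

    ``core`` is "ancestral" (allele 0), "derived" (allele 1) or "site"
    (allele-agnostic).  Allele cores require ancestral/derived coding.  Fewer
    than 2 carriers yields an undefined (flagged, not raised) curve.
    """
    cfg = cfg or ScanConfig()
    _check_complete(panel)
    if core in ("ancestral", "derived") and panel.coding != "ancestral_derived":
        raise ValueError("allele cores require a panel recoded to ancestral/derived")
    h = _int_haplotypes(panel)
    pos = panel.markers.pos_bp
    chrom = panel.markers.chrom
    c = chrom[focal]
    lo = int(np.searchsorted(chrom, c, side="left"))
    hi = int(np.searchsorted(chrom, c, side="right")) - 1
    if core == "site":
        carriers = np.arange(h.shape[0])
    else:
        allele = 0 if core == "ancestral" else 1
        carriers = np.flatnonzero(h[:, focal] == allele)
    curve = EHHCurve(focal_index=focal, core=core, n_haplotypes_retained=carriers.size)
    if carriers.size < 2:
        curve.defined = False
        return curve
    lp, le, lreason = _walk(h, carriers, pos, focal, lo, hi, -1, cfg.ehh_floor, cfg.max_gap_bp, cfg.max_extent_bp)
    rp, re, rreason = _walk(h, carriers, pos, focal, lo, hi, +1, cfg.ehh_floor, cfg.max_gap_bp, cfg.max_extent_bp)
    curve.left_pos, curve.left_ehh = np.asarray(lp), np.asarray(le)
    curve.right_pos, curve.right_ehh = np.asarray(rp), np.asarray(re)
    curve.border_truncated = (lreason == "chrom_end" and le[-1] >= cfg.ehh_floor) or (
        rreason == "chrom_end" and re[-1] >= cfg.ehh_floor
    )
    return curve


def integrate_ehh(curve: EHHCurve) -> float:
    """Trapezoidal integral of EHH over physical distance, flanks summed (bp x EHH)."""
    if not curve.defined:
        return float("nan")
    total = 0.0
    for pos, ehh in ((curve.left_pos, curve.left_ehh), (curve.right_pos, curve.right_ehh)):
        if len(pos) >= 2:
            d = np.abs(pos.astype(float) - float(pos[0]))
            total += float(np.trapezoid(ehh, d))
    return total


def pihs_transform(score):
    """-log10 of the two-sided Gaussian p-value of a standardised score.

    piHS = -log10(1 - 2|Phi(x) - 0.5|) = -log10(2 Phi(-|x|)), evaluated via
    the log survival function so large |x| (e.g. -7.02 -> 11.65) do not
    cancel catastrophically.  Symmetric in the sign of the score.
    """
    x = np.asarray(score, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("pihs_transform requires finite scores")
    out = -(np.log(2.0) + norm.logsf(np.abs(x))) / np.log(10.0)
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(score) or out.ndim == 0 else out


pxpehh_transform = pihs_transform  # the cross-population test uses the same map


def _ihh_pair(h, pos, chrom_bounds, focal, carriers_a, carriers_d, cfg):
    """(iHH_A, iHH_D, border_flag) for one focal SNP."""
    lo, hi = chrom_bounds
    a, border_a = _ihh_both_flanks(h, pos, focal, lo, hi, carriers_a, cfg)
    d, border_d = _ihh_both_flanks(h, pos, focal, lo, hi, carriers_d, cfg)
    return a, d, border_a or border_d


def ihs_scan(panel: HaplotypePanel, cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Within-population iHS scan over every SNP passing the MAF threshold.

    Returns one row per SNP with columns ``freq_derived``, ``ihh_a``,
    ``ihh_d``, ``unihs``, ``ihs`` (standardised within derived-frequency bins
    of width ``freq_bin_width``), ``pihs`` and a ``status`` column: "ok",
    "maf" (below threshold), "too_few_carriers", "zero_ihh", or
    "unstandardized_bin" (bin held fewer than 2 scored SNPs or had zero
    spread; UniHS kept, iHS/piHS NaN).
    """
    cfg = cfg or ScanConfig()
    if panel.coding != "ancestral_derived":
        raise ValueError("iHS requires a panel recoded to ancestral/derived")
    _check_complete(panel)
    h = _int_haplotypes(panel)
    pos = panel.markers.pos_bp
    chrom = panel.markers.chrom
    freq = h.mean(axis=0)

    n_snps = panel.n_snps
    ihh_a = np.full(n_snps, np.nan)
    ihh_d = np.full(n_snps, np.nan)
    border = np.zeros(n_snps, dtype=bool)
    status = np.array(["ok"] * n_snps, dtype=object)

    for c, sl in panel.markers.chrom_slices().items():
        lo, hi = sl.start, sl.stop - 1
        for focal in range(sl.start, sl.stop):
            q = freq[focal]
            if min(q, 1.0 - q) < cfg.maf:
                status[focal] = "maf"
                continue
            carriers_d = np.flatnonzero(h[:, focal] == 1)
            carriers_a = np.flatnonzero(h[:, focal] == 0)
            if carriers_a.size < 2 or carriers_d.size < 2:
                status[focal] = "too_few_carriers"
                continue
            a, d, b = _ihh_pair(h, pos, (lo, hi), focal, carriers_a, carriers_d, cfg)
            if a <= 0.0 or d <= 0.0:
                status[focal] = "zero_ihh"
                continue
            ihh_a[focal], ihh_d[focal], border[focal] = a, d, b

    with np.errstate(invalid="ignore", divide="ignore"):
        unihs = np.log(ihh_a / ihh_d)
    ihs = np.full(n_snps, np.nan)
    scored = status == "ok"
    n_bins = int(np.ceil(1.0 / cfg.freq_bin_width))
    bins = np.minimum((freq / cfg.freq_bin_width).astype(int), n_bins - 1)
    for b in np.unique(bins[scored]):
        sel = scored & (bins == b)
        vals = unihs[sel]
        if sel.sum() < 2 or np.std(vals, ddof=1) == 0.0:
            status[sel] = "unstandardized_bin"
            continue
        ihs[sel] = (vals - vals.mean()) / np.std(vals, ddof=1)
    pihs = np.full(n_snps, np.nan)
    ok = np.isfinite(ihs)
    if ok.any():
        pihs[ok] = pihs_transform(ihs[ok])

    t = panel.markers.table
    return pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "chrom": t["chrom"],
            "pos_bp": t["pos_bp"],
            "freq_derived": freq,
            "ihh_a": ihh_a,
            "ihh_d": ihh_d,
            "unihs": unihs,
            "ihs": ihs,
            "pihs": pihs,
            "status": status,
            "border_truncated": border,
            "freq_bin": bins,
        }
    )


def xpehh_scan(
    panel_ref: HaplotypePanel, panel_obs: HaplotypePanel, cfg: ScanConfig | None = None
) -> pd.DataFrame:
    """Cross-population XP-EHH scan (reference vs observed population).

    Uses the allele-agnostic site EHH per population, so no ancestral
    annotation is needed.  XP-EHH = (LRiES - median) / SD with
    LRiES = ln(iES_ref / iES_obs).  ``significant`` flags two-sided
    -log10 p above -log10(alpha); ``direction`` attributes the signal to one
    population according to ``cfg.sign_convention`` (default: negative scores
    point at the reference population, matching common reporting practice
    even though the raw log-ratio grows when the reference is the more
    homozygous population).
    """
    cfg = cfg or ScanConfig()
    _check_complete(panel_ref)
    _check_complete(panel_obs)
    if not np.array_equal(panel_ref.markers.snp_id, panel_obs.markers.snp_id) or not np.array_equal(
        panel_ref.markers.pos_bp, panel_obs.markers.pos_bp
    ):
        raise ValueError("panels must share an identical marker map")
    n_snps = panel_ref.n_snps
    ies = {}
    border = np.zeros(n_snps, dtype=bool)
    for key, panel in (("ref", panel_ref), ("obs", panel_obs)):
        h = _int_haplotypes(panel)
        pos = panel.markers.pos_bp
        vals = np.full(n_snps, np.nan)
        carriers = np.arange(h.shape[0])
        for c, sl in panel.markers.chrom_slices().items():
            lo, hi = sl.start, sl.stop - 1
            for focal in range(sl.start, sl.stop):
                tot, b = _ihh_both_flanks(h, pos, focal, lo, hi, carriers, cfg)
                vals[focal] = tot
                border[focal] |= b
        ies[key] = vals

    status = np.array(["ok"] * n_snps, dtype=object)
    bad = (ies["ref"] <= 0) | (ies["obs"] <= 0) | ~np.isfinite(ies["ref"]) | ~np.isfinite(ies["obs"])
    status[bad] = "zero_ies"
    with np.errstate(invalid="ignore", divide="ignore"):
        lries = np.where(~bad, np.log(ies["ref"] / ies["obs"]), np.nan)
    scored = ~bad
    if scored.sum() < 10:
        raise ValueError("fewer than 10 scored SNPs; XP-EHH standardisation unstable")
    med = float(np.median(lries[scored]))
    sd = float(np.std(lries[scored], ddof=1))
    if sd == 0.0:
        raise ValueError("LRiES has zero spread; XP-EHH undefined")
    xpehh = np.where(scored, (lries - med) / sd, np.nan)
    pxp = np.full(n_snps, np.nan)
    pxp[scored] = pxpehh_transform(xpehh[scored])
    significant = np.where(scored, pxp > -np.log10(cfg.xpehh_alpha), False)
    neg_is_ref = cfg.sign_convention == "negative_is_reference"
    direction = np.where(
        ~scored | (xpehh == 0),
        "",
        np.where((xpehh < 0) == neg_is_ref, "reference", "observed"),
    )
    t = panel_ref.markers.table
    return pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "chrom": t["chrom"],
            "pos_bp": t["pos_bp"],
            "ies_ref": ies["ref"],
            "ies_obs": ies["obs"],
            "lries": lries,
            "xpehh": xpehh,
            "pxpehh": pxp,
            "significant": significant.astype(bool),
            "direction": direction,
            "status": status,
            "border_truncated": border,
        }
    )


# ---------------------------------------------------------------------------
# significance cutoffs


@dataclass
class CutoffResult:
    mode: str
    pihs_cutoff: float
    p_cutoff: float
    eta0: float | None = None


def _grenander_density(p_sorted: np.ndarray) -> np.ndarray:
    """Decreasing density on [0,1]: slopes of the least concave majorant of the ECDF.

    Returns the density evaluated at each sorted p-value.  Implemented as an
    upper convex hull (monotone chain) over the ECDF points (0,0),
    (p_(i), i/n), (1,1).
    """
    n = p_sorted.size
    x = np.concatenate(([0.0], p_sorted, [1.0]))
    y = np.concatenate(([0.0], np.arange(1, n + 1) / n, [1.0]))
    hull = [0]
    for i in range(1, len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # keep hull concave: slope must be non-increasing
            if (y[i2] - y[i1]) * (x[i] - x[i2]) <= (y[i] - y[i2]) * (x[i2] - x[i1]):
                hull.pop()
            else:
                break
        hull.append(i)
    dens = np.empty(n)
    seg = 0
    for j in range(1, n + 1):  # indices of p-values in x
        while seg + 1 < len(hull) - 1 and x[hull[seg + 1]] < x[j]:
            seg += 1
        x1, x2 = x[hull[seg]], x[hull[seg + 1]]
        y1, y2 = y[hull[seg]], y[hull[seg + 1]]
        dens[j - 1] = (y2 - y1) / (x2 - x1) if x2 > x1 else np.inf
    return dens


def empirical_null_cutoff(
    pihs_values: np.ndarray,
    mode: str = "empirical_null",
    p_value: float | None = None,
    tau: float = 0.75,
    lfdr_max: float = 0.2,
) -> CutoffResult:
    """Significance cutoff on the piHS (-log10 p) scale.

    ``fixed`` mode converts a user-supplied two-sided p-value threshold
    (e.g. 0.008) to -log10(p).  ``empirical_null`` mode works from the
    observed scores: the null proportion eta0 is estimated from the p-value
    mass on [tau, 1] (Storey), a decreasing density f is fitted by the
    Grenander estimator, and the cutoff is the largest p whose local false
    discovery rate eta0/f(p) stays below ``lfdr_max``; with no such p (a
    null-like score distribution) the cutoff falls below the smallest
    observed p-value, declaring nothing significant.
    """
    if mode == "fixed":
        if p_value is None or not (0.0 < p_value <= 1.0):
            raise ValueError("fixed mode requires a p-value in (0, 1]")
        return CutoffResult(mode=mode, pihs_cutoff=-np.log10(p_value), p_cutoff=p_value)
    if mode != "empirical_null":
        raise ValueError(f"unknown cutoff mode {mode!r}")
    pihs = np.asarray(pihs_values, dtype=float)
    pihs = pihs[np.isfinite(pihs)]
    if pihs.size < 100:
        raise ValueError("empirical-null cutoff requires at least 100 scored SNPs")
    p = np.power(10.0, -pihs)
    if np.allclose(p, p[0]):
        raise ValueError("degenerate p-value distribution")
    p_sorted = np.sort(p)
    n = p_sorted.size
    eta0 = min(1.0, float((p_sorted > tau).sum() / (n * (1.0 - tau))))
    dens = _grenander_density(p_sorted)
    with np.errstate(divide="ignore"):
        lfdr = np.minimum(1.0, eta0 / dens)
    ok = np.flatnonzero(lfdr <= lfdr_max)
    p_cut = float(p_sorted[ok].max()) if ok.size else float(0.5 / n)
    return CutoffResult(mode=mode, pihs_cutoff=-np.log10(p_cut), p_cutoff=p_cut, eta0=eta0)
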