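"""Marker and sample quality control for SNP-chip genotype matrices.

Filters follow standard chip QC practice: monomorphic SNPs, SNP call rate,
minor allele frequency, and departure of the observed heterozygote frequency
from its Hardy-Weinberg expectation 2p(1-p); then sample call rate.  All
thresholds are strict inequalities ("lower than" / "greater than"), and SNP
filters are computed on the pooled sample before any per-population analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationLabels


@dataclass
class QCConfig:
    snp_call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.90
    maf_min: float = 0.01
    hwe_het_dev_max: float = 0.15
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "sample_call_rate_min", "maf_min", "hwe_het_dev_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Attrition accounting for one filtering pass along one axis."""

    axis: str  # "snp" or "sample"
    n_in: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.axis, "input", self.n_in)]
        rows += [(self.axis, f"removed_{rule}", n) for rule, n in self.removed.items()]
        rows.append((self.axis, "surviving", self.n_out))
        return pd.DataFrame(rows, columns=["axis", "rule", "count"])


def allele_frequencies(
    g: GenotypeMatrix, labels: PopulationLabels | None = None
) -> pd.DataFrame:
    """Per-SNP counted-allele frequency, overall and per population.

    The overall frequency is the pooled (allele-count-weighted) frequency.
    Strata where every call is missing yield NaN, never 0.
    """
    obs = g.calls != MISSING
    t = g.markers.table
    out = pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "chrom": t["chrom"],
            "pos_bp": t["pos_bp"],
            "call_rate": g.snp_call_rate(),
            "p": g.counted_allele_freq(),
        }
    )
    out["maf"] = np.minimum(out["p"], 1.0 - out["p"])
    if labels is not None:
        for pop in labels.populations:
            mask = labels.mask(g.samples, pop)
            sub = g.calls[mask]
            sobs = sub != MISSING
            n = sobs.sum(axis=0)
            dose = np.where(sobs, sub, 0).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[f"p_{pop}"] = np.where(n > 0, dose / (2.0 * n), np.nan)
    return out


def filter_snps(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply SNP filters in fixed order: monomorphic, call rate, MAF, HWE deviation.

    The order is fixed so attrition counts are reproducible; each rule counts
    only SNPs that survived the previous rules.  SNPs with zero non-missing
    calls count as monomorphic.
    """
    cfg = cfg or QCConfig()
    report = QCReport(axis="snp", n_in=g.n_snps)
    alive = np.ones(g.n_snps, dtype=bool)

    p = g.counted_allele_freq()
    if cfg.drop_monomorphic:
        mono = np.isnan(p) | (p == 0.0) | (p == 1.0)
        report.removed["monomorphic"] = int((alive & mono).sum())
        alive &= ~mono

    low_cr = g.snp_call_rate() < cfg.snp_call_rate_min
    report.removed["call_rate"] = int((alive & low_cr).sum())
    alive &= ~low_cr

    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
        low_maf = maf < cfg.maf_min
    report.removed["maf"] = int((alive & np.nan_to_num(low_maf, nan=False)).sum())
    alive &= ~np.nan_to_num(low_maf, nan=False)

    obs = g.calls != MISSING
    n_obs = obs.sum(axis=0)
    het = ((g.calls == 1) & obs).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_freq = np.where(n_obs > 0, het / n_obs, np.nan)
        dev = np.abs(het_freq - 2.0 * p * (1.0 - p))
        hwe_bad = dev > cfg.hwe_het_dev_max
    report.removed["hwe_het_dev"] = int((alive & np.nan_to_num(hwe_bad, nan=False)).sum())
    alive &= ~np.nan_to_num(hwe_bad, nan=False)

    if not alive.any():
        raise ValueError("no SNPs survive quality control; review thresholds")
    return g.subset_snps(alive), report


def filter_samples(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples with call rate strictly below the threshold."""
    cfg = cfg or QCConfig()
    report = QCReport(axis="sample", n_in=g.n_samples)
    keep = g.sample_call_rate() >= cfg.sample_call_rate_min
    report.removed["call_rate"] = int((~keep).sum())
    if not keep.any():
        raise ValueError("no samples survive quality control; review thresholds")
    return g.subset_samples(keep), report
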