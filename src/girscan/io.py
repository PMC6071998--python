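"""Readers, writers and in-memory containers for genotype and haplotype data.

Coordinate conventions
----------------------
All positions are held internally as 1-based inclusive base pairs, matching
the way SNP-chip maps and the bovine UMD-style assemblies report them.  BED
input (0-based, half-open) is converted at the reader boundary and converted
back on write.

Genotypes are diploid dosage codes in {0, 1, 2} counting a designated
"counted" allele per SNP (``allele_a`` in the marker map; the ALT allele for
VCF input).  Missing calls are coded ``-1``.  Haplotypes are stored two rows
per sample, either as raw single-character alleles (missing ``.``) or, after
ancestral recoding, as ``0`` = ancestral / ``1`` = derived (missing ``-1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

MISSING = -1
MISSING_ALLELE = "."
UNKNOWN_ANCESTRAL = "."
CATTLE_AUTOSOMES = frozenset(range(1, 30))

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_MAP_COLUMNS = ["snp_id", "chrom", "pos_bp", "ancestral_allele", "allele_a", "allele_b"]


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


def _complement(allele: str) -> str:
    return _COMPLEMENT.get(allele, MISSING_ALLELE)


def _is_palindromic(a: str, b: str) -> bool:
    """A/T and C/G SNPs cannot be strand-resolved from allele labels alone."""
    return {a, b} in ({"A", "T"}, {"C", "G"})


@dataclass
class MarkerMap:
    """Physical marker map for a panel of SNPs.

    ``table`` holds one row per SNP with columns ``snp_id``, ``chrom`` (integer
    autosome), ``pos_bp`` (1-based), ``ancestral_allele`` ("." when unknown)
    and the two observed alleles ``allele_a`` (the counted allele) and
    ``allele_b``.  Rows are sorted by (chrom, pos_bp) and positions are
    strictly increasing within a chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in _MAP_COLUMNS if c not in self.table.columns]
        if missing_cols:
            raise ValueError(f"marker map missing columns {missing_cols}")
        t = self.table.reset_index(drop=True)
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicated snp_id {dup!r} in marker map")
        if (t["pos_bp"] < 1).any():
            raise ValueError("marker positions must be >= 1")
        if (t["chrom"] < 1).any():
            raise ValueError("chromosome identifiers must be positive integers")
        for _, grp in t.groupby("chrom", sort=False):
            if not grp["pos_bp"].is_monotonic_increasing or grp["pos_bp"].duplicated().any():
                raise ValueError("positions must be strictly increasing within each chromosome")
        self.table = t

    @classmethod
    def from_arrays(
        cls,
        snp_id: Iterable[str],
        chrom: Iterable[int],
        pos_bp: Iterable[int],
        ancestral_allele: Iterable[str] | None = None,
        allele_a: Iterable[str] | None = None,
        allele_b: Iterable[str] | None = None,
    ) -> "MarkerMap":
        snp_id = list(snp_id)
        n = len(snp_id)
        t = pd.DataFrame(
            {
                "snp_id": snp_id,
                "chrom": np.asarray(list(chrom), dtype=np.int64),
                "pos_bp": np.asarray(list(pos_bp), dtype=np.int64),
                "ancestral_allele": list(ancestral_allele) if ancestral_allele is not None else [UNKNOWN_ANCESTRAL] * n,
                "allele_a": list(allele_a) if allele_a is not None else [MISSING_ALLELE] * n,
                "allele_b": list(allele_b) if allele_b is not None else [MISSING_ALLELE] * n,
            }
        )
        t = t.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
        return cls(t)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_id(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def ancestral_allele(self) -> np.ndarray:
        return self.table["ancestral_allele"].to_numpy()

    def chrom_slices(self) -> dict[int, slice]:
        """Contiguous row slice per chromosome (rows are chrom-sorted)."""
        out: dict[int, slice] = {}
        chrom = self.chrom
        bounds = np.flatnonzero(np.diff(chrom)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(chrom)]))
        for s, e in zip(starts, ends):
            out[int(chrom[s])] = slice(int(s), int(e))
        return out

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (samples x SNPs), codes {0,1,2,-1}."""

    samples: list[str]
    markers: MarkerMap
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), self.markers.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {self.markers.n_snps} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.markers.n_snps

    def snp_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def counted_allele_freq(self) -> np.ndarray:
        """Frequency of allele_a per SNP over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        dose = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose / (2.0 * n), np.nan)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(list(self.samples), self.markers.subset(mask), self.calls[:, mask])

    def subset_samples(self, keep: Iterable[str] | np.ndarray) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            keep_set = list(keep)
            pos = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([pos[s] for s in keep_set], dtype=int)
        return GenotypeMatrix([self.samples[i] for i in idx], self.markers, self.calls[idx])


@dataclass
class PopulationLabels:
    """Mapping sample id -> population name (two or more populations)."""

    assignments: pd.Series

    def __post_init__(self) -> None:
        s = self.assignments
        if s.index.duplicated().any():
            raise ValueError("duplicated sample id in population labels")
        counts = s.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"populations {small} have fewer than 2 samples")
        self.assignments = s.astype(str)

    @property
    def populations(self) -> list[str]:
        return sorted(self.assignments.unique())

    def of(self, sample: str) -> str:
        return str(self.assignments.loc[sample])

    def mask(self, samples: list[str], population: str) -> np.ndarray:
        missing = [s for s in samples if s not in self.assignments.index]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}")
        return np.array([self.assignments.loc[s] == population for s in samples])


@dataclass
class HaplotypePanel:
    """Phased haplotypes, two rows per sample.

    ``coding`` is ``"raw"`` (single-character alleles) or
    ``"ancestral_derived"`` (int8 codes, 0 = ancestral, 1 = derived,
    -1 = missing).
    """

    samples: list[str]
    markers: MarkerMap
    haplotypes: np.ndarray
    coding: str = "raw"

    def __post_init__(self) -> None:
        if self.coding not in ("raw", "ancestral_derived"):
            raise ValueError(f"unknown coding {self.coding!r}")
        h = np.asarray(self.haplotypes)
        if self.coding == "ancestral_derived":
            h = h.astype(np.int8)
            if not np.isin(h, (0, 1, MISSING)).all():
                raise ValueError("ancestral/derived codes must be in {0,1,-1}")
        else:
            h = h.astype("<U1")
        if h.shape != (2 * len(self.samples), self.markers.n_snps):
            raise ValueError(
                f"haplotype array shape {h.shape} inconsistent with "
                f"2x{len(self.samples)} samples x {self.markers.n_snps} SNPs"
            )
        self.haplotypes = h

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.markers.n_snps

    def sample_of_haplotype(self, row: int) -> str:
        return self.samples[row // 2]

    def is_complete(self) -> bool:
        if self.coding == "ancestral_derived":
            return not (self.haplotypes == MISSING).any()
        return not (self.haplotypes == MISSING_ALLELE).any()

    def derived_allele_freq(self) -> np.ndarray:
        if self.coding != "ancestral_derived":
            raise ValueError("derived allele frequency requires ancestral/derived coding")
        obs = self.haplotypes != MISSING
        n = obs.sum(axis=0)
        der = ((self.haplotypes == 1) & obs).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, der / n, np.nan)

    def subset_snps(self, mask: np.ndarray) -> "HaplotypePanel":
        mask = np.asarray(mask)
        return HaplotypePanel(
            list(self.samples), self.markers.subset(mask), self.haplotypes[:, mask], self.coding
        )

    def subset_samples(self, keep: Iterable[str]) -> "HaplotypePanel":
        keep = list(keep)
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = []
        for s in keep:
            rows.extend((2 * pos[s], 2 * pos[s] + 1))
        return HaplotypePanel(keep, self.markers, self.haplotypes[rows], self.coding)

    def split_by_population(self, labels: PopulationLabels) -> dict[str, "HaplotypePanel"]:
        out = {}
        for pop in labels.populations:
            keep = [s for s in self.samples if labels.of(s) == pop]
            out[pop] = self.subset_samples(keep)
        return out


@dataclass
class IntervalSet:
    """Genomic intervals (genes / QTL), 1-based inclusive coordinates."""

    table: pd.DataFrame
    n_skipped: int = 0

    def __post_init__(self) -> None:
        req = ["chrom", "start_bp", "end_bp", "name", "category"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"interval table missing columns {missing}")
        t = self.table.reset_index(drop=True)
        if len(t) and (t["start_bp"] > t["end_bp"]).any():
            bad = t[t["start_bp"] > t["end_bp"]].iloc[0]
            raise ValueError(f"interval {bad['name']!r} has start > end")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# genotype readers


def _parse_chrom(token: str) -> int | None:
    token = token.removeprefix("chr").removeprefix("Chr")
    try:
        return int(token)
    except ValueError:
        return None


def read_genotypes(
    path: str | Path,
    format: str = "ped_map",
    autosomes: Iterable[int] = CATTLE_AUTOSOMES,
) -> GenotypeMatrix:
    """Read diploid genotypes, keeping only SNPs on the listed autosomes.

    ``format="ped_map"`` expects a whitespace-separated PED file with its
    sibling MAP file (``path`` may be the ``.ped`` file or the common prefix);
    alleles are nucleotide letters with ``0`` meaning missing.  ``format="vcf"``
    accepts plain-text or bgzipped VCF; the counted allele is ALT.  Markers are
    returned sorted by (chrom, pos_bp).
    """
    autosomes = frozenset(int(c) for c in autosomes)
    if format == "ped_map":
        g = _read_ped_map(Path(path), autosomes)
    elif format == "vcf":
        g = _read_vcf_genotypes(Path(path), autosomes)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if g.n_snps == 0:
        raise ParseError(f"{path}: no SNPs left after restricting to autosomes {sorted(autosomes)[:3]}...")
    return g


def _read_ped_map(path: Path, autosomes: frozenset[int]) -> GenotypeMatrix:
    if path.suffix == ".ped":
        ped_path, map_path = path, path.with_suffix(".map")
    else:
        ped_path, map_path = path.with_suffix(".ped"), path.with_suffix(".map")
    snp_id, chrom, pos = [], [], []
    for ln, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) < 4:
            raise ParseError(f"{map_path}: line {ln}: expected 4 columns, got {len(tok)}")
        c = _parse_chrom(tok[0])
        snp_id.append(tok[1])
        chrom.append(-1 if c is None else c)
        try:
            pos.append(int(tok[3]))
        except ValueError as exc:
            raise ParseError(f"{map_path}: line {ln}: bad position {tok[3]!r}") from exc
    m_total = len(snp_id)
    keep = [i for i in range(m_total) if chrom[i] in autosomes]

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    allele_a: list[str] = [MISSING_ALLELE] * m_total
    allele_b: list[str] = [MISSING_ALLELE] * m_total
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) != 6 + 2 * m_total:
            raise ParseError(
                f"{ped_path}: line {ln}: expected {6 + 2 * m_total} fields, got {len(tok)}"
            )
        sample_ids.append(tok[1])
        codes = np.full(m_total, MISSING, dtype=np.int8)
        for j in range(m_total):
            a1, a2 = tok[6 + 2 * j], tok[7 + 2 * j]
            if a1 == "0" or a2 == "0":
                continue
            for a in (a1, a2):
                if allele_a[j] == MISSING_ALLELE:
                    allele_a[j] = a
                elif a != allele_a[j] and allele_b[j] == MISSING_ALLELE:
                    allele_b[j] = a
                elif a not in (allele_a[j], allele_b[j]):
                    raise ParseError(
                        f"{ped_path}: line {ln}: SNP {snp_id[j]} has more than two alleles"
                    )
            codes[j] = (a1 == allele_a[j]) + (a2 == allele_a[j])
        rows.append(codes)
    calls = np.vstack(rows) if rows else np.empty((0, m_total), dtype=np.int8)
    markers = MarkerMap.from_arrays(
        [snp_id[i] for i in keep],
        [chrom[i] for i in keep],
        [pos[i] for i in keep],
        allele_a=[allele_a[i] for i in keep],
        allele_b=[allele_b[i] for i in keep],
    )
    order = _order_for(markers, [snp_id[i] for i in keep])
    return GenotypeMatrix(sample_ids, markers, calls[:, keep][:, order])


def _order_for(markers: MarkerMap, original_ids: list[str]) -> np.ndarray:
    """Column permutation taking the original SNP order to the sorted map order."""
    pos = {s: i for i, s in enumerate(original_ids)}
    return np.array([pos[s] for s in markers.snp_id], dtype=int)


def _read_vcf_genotypes(path: Path, autosomes: frozenset[int]) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    snp_id, chrom, pos, anc, aa, ab = [], [], [], [], [], []
    cols = []
    n_skipped_multi = 0
    for rec_no, v in enumerate(vcf, start=1):
        c = _parse_chrom(v.CHROM)
        if c is None or c not in autosomes:
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped_multi += 1
            continue
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 >= 0 and a1 >= 0:
                codes[i] = a0 + a1
        snp_id.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chrom.append(c)
        pos.append(v.POS)
        aa.append(v.ALT[0])
        ab.append(v.REF)
        ancestral = v.INFO.get("AA")
        anc.append(str(ancestral) if ancestral is not None else UNKNOWN_ANCESTRAL)
        cols.append(codes)
    if n_skipped_multi:
        warnings.warn(f"{path}: skipped {n_skipped_multi} non-biallelic/non-SNP records")
    calls = np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    markers = MarkerMap.from_arrays(snp_id, chrom, pos, ancestral_allele=anc, allele_a=aa, allele_b=ab)
    order = _order_for(markers, snp_id)
    return GenotypeMatrix(samples, markers, calls[:, order])


# ---------------------------------------------------------------------------
# haplotype readers / writers


def read_haplotypes(
    path: str | Path,
    format: str = "vcf_phased",
    autosomes: Iterable[int] = CATTLE_AUTOSOMES,
) -> HaplotypePanel:
    """Read phased haplotypes (two rows per sample, order sample x [A, B])."""
    if format == "vcf_phased":
        return _read_vcf_phased(Path(path), frozenset(int(c) for c in autosomes))
    if format == "hap_table":
        return _read_hap_table(Path(path))
    raise ValueError(f"unknown haplotype format {format!r}")


def _read_vcf_phased(path: Path, autosomes: frozenset[int]) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_id, chrom, pos, anc, aa, ab = [], [], [], [], [], []
    cols = []
    for v in vcf:
        c = _parse_chrom(v.CHROM)
        if c is None or c not in autosomes:
            continue
        if len(v.ALT) != 1:
            raise ParseError(f"{path}: record {v.CHROM}:{v.POS} is not biallelic")
        alleles = np.full(2 * len(samples), MISSING_ALLELE, dtype="<U1")
        letters = (v.REF, v.ALT[0])
        for i, gt in enumerate(v.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[2]
            if not phased and (a0 >= 0 or a1 >= 0):
                raise ParseError(f"{path}: unphased genotype at {v.CHROM}:{v.POS} sample {samples[i]}")
            if a0 >= 0:
                alleles[2 * i] = letters[a0]
            if a1 >= 0:
                alleles[2 * i + 1] = letters[a1]
        snp_id.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chrom.append(c)
        pos.append(v.POS)
        aa.append(v.ALT[0])
        ab.append(v.REF)
        ancestral = v.INFO.get("AA")
        anc.append(str(ancestral) if ancestral is not None else UNKNOWN_ANCESTRAL)
        cols.append(alleles)
    haps = np.stack(cols, axis=1) if cols else np.empty((2 * len(samples), 0), dtype="<U1")
    markers = MarkerMap.from_arrays(snp_id, chrom, pos, ancestral_allele=anc, allele_a=aa, allele_b=ab)
    order = _order_for(markers, snp_id)
    return HaplotypePanel(samples, markers, haps[:, order], coding="raw")


def write_vcf_phased(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a raw-coded panel as a minimal phased VCF (REF=allele_b, ALT=allele_a)."""
    if panel.coding != "raw":
        raise ValueError("VCF output requires raw allele coding")
    t = panel.markers.table
    lines = ["##fileformat=VCFv4.2"]
    for c in sorted(t["chrom"].unique()):
        lines.append(f"##contig=<ID={c}>")
    lines.append('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples))
    h = panel.haplotypes
    for j in range(panel.n_snps):
        row = t.iloc[j]
        ref, alt = row["allele_b"], row["allele_a"]
        info = "." if row["ancestral_allele"] == UNKNOWN_ANCESTRAL else f"AA={row['ancestral_allele']}"
        gts = []
        for i in range(panel.n_samples):
            a, b = h[2 * i, j], h[2 * i + 1, j]
            ca = "." if a == MISSING_ALLELE else ("0" if a == ref else "1")
            cb = "." if b == MISSING_ALLELE else ("0" if b == ref else "1")
            gts.append(f"{ca}|{cb}")
        lines.append(
            f"{row['chrom']}\t{row['pos_bp']}\t{row['snp_id']}\t{ref}\t{alt}\t.\t.\t{info}\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_hap_table(path: Path) -> HaplotypePanel:
    coding = "raw"
    map_rows = []
    body: list[list[str]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("##CODING"):
            coding = line.split("\t")[1]
        elif line.startswith("##MAP"):
            tok = line.split("\t")
            if len(tok) != 7:
                raise ParseError(f"{path}: line {ln}: bad ##MAP line")
            map_rows.append(tok[1:])
        elif line.startswith("#") or not line.strip():
            continue
        else:
            body.append(line.split("\t"))
    if not map_rows:
        raise ParseError(f"{path}: no ##MAP header lines")
    markers = MarkerMap.from_arrays(
        [r[0] for r in map_rows],
        [int(r[1]) for r in map_rows],
        [int(r[2]) for r in map_rows],
        ancestral_allele=[r[3] for r in map_rows],
        allele_a=[r[4] for r in map_rows],
        allele_b=[r[5] for r in map_rows],
    )
    samples: list[str] = []
    rows = []
    for ln, tok in enumerate(body, start=1):
        if len(tok) != 2 + markers.n_snps:
            raise ParseError(f"{path}: haplotype row {ln}: expected {2 + markers.n_snps} fields")
        if tok[1] == "A":
            samples.append(tok[0])
        rows.append(tok[2:])
    arr = np.asarray(rows, dtype="<U2")
    order = _order_for(markers, [r[0] for r in map_rows])
    arr = arr[:, order]
    if coding == "ancestral_derived":
        haps = arr.astype(np.int8)
    else:
        haps = arr.astype("<U1")
    return HaplotypePanel(samples, markers, haps, coding=coding)


def write_hap_table(panel: HaplotypePanel, path: str | Path) -> None:
    t = panel.markers.table
    lines = ["##GIRSCAN_HAPTABLE\tv1", f"##CODING\t{panel.coding}"]
    for _, r in t.iterrows():
        lines.append(
            "##MAP\t"
            + "\t".join(
                str(x)
                for x in (r["snp_id"], r["chrom"], r["pos_bp"], r["ancestral_allele"], r["allele_a"], r["allele_b"])
            )
        )
    lines.append("#sample_id\thap\t" + "\t".join(t["snp_id"]))
    h = panel.haplotypes
    for i, s in enumerate(panel.samples):
        for k, tag in ((0, "A"), (1, "B")):
            lines.append(f"{s}\t{tag}\t" + "\t".join(str(x) for x in h[2 * i + k]))
    Path(path).write_text("\n".join(lines) + "\n")


def recode_ancestral(
    panel: HaplotypePanel, marker_map: MarkerMap | None = None
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Recode raw alleles to 0 = ancestral / 1 = derived.

    The ancestral allele is taken from ``marker_map`` (defaults to the panel's
    own map).  Per SNP: alleles matching the annotated ancestral allele code 0
    and the single remaining observed allele codes 1.  When the ancestral
    allele does not occur among the observed alleles, the strand-flipped
    (complemented) ancestral allele is tried, except for A/T and C/G SNPs where
    the flip is ambiguous.  SNPs with an unknown ancestral state, an
    incompatible ancestral allele, or an ambiguous strand are set entirely
    missing and listed in the returned report with a reason.
    """
    if panel.coding != "raw":
        raise ValueError("panel already recoded to ancestral/derived")
    mm = marker_map if marker_map is not None else panel.markers
    if mm.n_snps != panel.n_snps or not np.array_equal(mm.snp_id, panel.markers.snp_id):
        raise ValueError("marker map does not match panel markers")
    h = panel.haplotypes
    out = np.full(h.shape, MISSING, dtype=np.int8)
    reasons: list[tuple[str, str]] = []
    anc_used = []
    for j in range(panel.n_snps):
        col = h[:, j]
        observed = sorted(set(col) - {MISSING_ALLELE})
        anc = mm.ancestral_allele[j]
        anc_used.append(anc)
        if anc == UNKNOWN_ANCESTRAL:
            reasons.append((mm.snp_id[j], "unknown_ancestral"))
            continue
        if len(observed) > 2:
            reasons.append((mm.snp_id[j], "more_than_two_alleles"))
            continue
        if anc not in observed:
            flip = _complement(anc)
            if len(observed) == 2:
                if _is_palindromic(*observed):
                    reasons.append((mm.snp_id[j], "ambiguous_strand"))
                    continue
                if flip in observed:
                    anc = flip
                    anc_used[-1] = flip
                else:
                    reasons.append((mm.snp_id[j], "incompatible_alleles"))
                    continue
            elif len(observed) == 1:
                # fixed for a single non-ancestral allele: the derived allele
                # (after strand resolution when possible)
                if observed[0] == flip:
                    anc = flip
                    anc_used[-1] = flip
                # else: the observed allele codes as derived below
        derived = [a for a in observed if a != anc]
        out[col == anc, j] = 0
        if derived:
            out[col == derived[0], j] = 1
    report = pd.DataFrame(reasons, columns=["snp_id", "reason"])
    new_map = mm.table.copy()
    recoded = HaplotypePanel(list(panel.samples), MarkerMap(new_map), out, coding="ancestral_derived")
    return recoded, report


# ---------------------------------------------------------------------------
# labels, intervals, tables


def read_labels(path: str | Path) -> PopulationLabels:
    """TSV with header columns sample_id, population."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns sample_id, population")
    return PopulationLabels(df.set_index("sample_id")["population"])


def write_labels(labels: PopulationLabels, path: str | Path) -> None:
    df = labels.assignments.rename("population").rename_axis("sample_id").reset_index()
    write_table(df, path)


def read_intervals(path: str | Path, autosomes: Iterable[int] | None = None) -> IntervalSet:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals.

    Column 4 is the record name, column 5 (optional) its category (gene/QTL,
    default gene).  Records on chromosomes outside ``autosomes`` (when given)
    or with unparseable chromosome names are skipped with a warning and
    counted in ``n_skipped``.
    """
    rows = []
    n_skipped = 0
    auto = frozenset(int(c) for c in autosomes) if autosomes is not None else None
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        tok = line.split()
        if len(tok) < 3:
            raise ParseError(f"{path}: line {ln}: expected at least 3 BED columns")
        c = _parse_chrom(tok[0])
        if c is None or (auto is not None and c not in auto):
            n_skipped += 1
            continue
        start0, end0 = int(tok[1]), int(tok[2])
        if start0 >= end0:
            raise ParseError(f"{path}: line {ln}: start >= end in BED record")
        name = tok[3] if len(tok) > 3 else f"iv{ln}"
        category = tok[4] if len(tok) > 4 else "gene"
        rows.append((c, start0 + 1, end0, name, category))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} intervals on unknown/excluded chromosomes")
    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name", "category"])
    return IntervalSet(df, n_skipped=n_skipped)


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    """Write intervals back to BED (0-based half-open)."""
    lines = []
    for _, r in intervals.table.iterrows():
        lines.append(f"{r['chrom']}\t{r['start_bp'] - 1}\t{r['end_bp']}\t{r['name']}\t{r['category']}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV output: header row, column order as given, LF endings."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
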