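"""Forward Wright-Fisher simulator of two diverging populations.

The generator emulates a chip-genotyped pair of recently split cattle
populations: a common ancestral herd founded from a narrow base of founder
haplotypes (building realistic long-range linkage disequilibrium), a burn-in
of random mating, then a split into a smaller closed herd ("beef") and a
larger multi-source population ("dairy") that evolve independently for
``t_split`` generations.  Drift acts genome-wide; designated loci experience
additive divergent selection (fitness 1 : 1+s : 1+2s).  The marker panel is
fixed (no new mutations, like a genotyping array) with founder derived-allele
frequencies drawn uniformly on [0.05, 0.95] to mimic chip ascertainment.

Chromosomes are scaled: a handful of ~5 Mb chromosomes with ~10 kb marker
spacing, so haplotype statistics operate at chip-like marker density while a
replicate runs in well under a second.  Recombination is modelled as at most
one crossover per chromosome per meiosis (map lengths here are ~0.05 Morgan,
so double crossovers are negligible); exact Poisson crossover counts are
available behind ``poisson_recomb``.

Outputs are phased haplotype panels (raw nucleotide alleles), genotype
matrices counting the derived allele, a marker map annotated with the true
ancestral alleles, and a truth table for method evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, HaplotypePanel, IntervalSet, MarkerMap, PopulationLabels

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SelectedLocus:
    chrom: int
    index: int  # SNP index within the chromosome
    s_pop1: float
    s_pop2: float
    init_freq: float = 0.1

    def __post_init__(self) -> None:
        if not (abs(self.s_pop1) < 1 and abs(self.s_pop2) < 1):
            raise ValueError("|s| must be < 1")
        if not (0.0 < self.init_freq < 1.0):
            raise ValueError("init_freq must lie in (0, 1)")


def _default_selected() -> list[SelectedLocus]:
    # two sweeps per population on separate chromosomes, mid-chromosome
    return [
        SelectedLocus(chrom=1, index=250, s_pop1=0.10, s_pop2=0.0),
        SelectedLocus(chrom=2, index=250, s_pop1=0.0, s_pop2=0.10),
        SelectedLocus(chrom=3, index=250, s_pop1=0.08, s_pop2=0.0),
        SelectedLocus(chrom=4, index=250, s_pop1=0.0, s_pop2=0.08),
    ]


@dataclass
class SimConfig:
    """Study-condition defaults: a closed beef herd (pop1, smaller Ne) versus a
    multi-source dairy population (pop2), split ~30 generations ago, sampled
    at roughly half the cohort sizes of a typical two-herd chip study."""

    n_chrom: int = 5
    snps_per_chrom: int = 500
    chrom_length_bp: int = 5_000_000
    Ne_ancestral: int = 300
    Ne_pop1: int = 150
    Ne_pop2: int = 300
    t_split: int = 30
    t_burnin: int = 50
    n_founder_haplotypes: int = 120
    selected_loci: list[SelectedLocus] = field(default_factory=_default_selected)
    n_sample_pop1: int = 87
    n_sample_pop2: int = 137
    recomb_rate: float = 1e-8  # per bp per meiosis (~1 cM/Mb)
    init_freq_low: float = 0.05
    init_freq_high: float = 0.95
    poisson_recomb: bool = False
    pop_names: tuple[str, str] = ("beef", "dairy")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chrom", "snps_per_chrom", "chrom_length_bp", "Ne_ancestral", "Ne_pop1", "Ne_pop2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_split < 0 or self.t_burnin < 0:
            raise ValueError("generation counts must be >= 0")
        if self.n_sample_pop1 > self.Ne_pop1 or self.n_sample_pop2 > self.Ne_pop2:
            raise ValueError("sample size exceeds population size")
        for locus in self.selected_loci:
            if not (1 <= locus.chrom <= self.n_chrom):
                raise ValueError(f"selected locus on chromosome {locus.chrom} outside 1..{self.n_chrom}")
            if not (0 <= locus.index < self.snps_per_chrom):
                raise ValueError("selected locus index outside the chromosome's SNP range")


@dataclass
class SimTruth:
    table: pd.DataFrame  # per-SNP truth
    expected_fst: float  # drift expectation at the harmonic-mean Ne


@dataclass
class SimResult:
    markers: MarkerMap
    panels: dict[str, HaplotypePanel]
    genotypes: dict[str, GenotypeMatrix]
    labels: PopulationLabels
    truth: SimTruth


def expected_fst(Ne: float, t: int) -> float:
    """Closed-form drift accumulation 1 - (1 - 1/(2Ne))^t."""
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    if t < 0:
        raise ValueError("t must be >= 0")
    return 1.0 - (1.0 - 1.0 / (2.0 * Ne)) ** t


def _make_map(cfg: SimConfig, rng: np.random.Generator) -> tuple[MarkerMap, np.ndarray, np.ndarray]:
    """Marker map plus ancestral/derived nucleotide arrays."""
    snp_id, chrom, pos = [], [], []
    for c in range(1, cfg.n_chrom + 1):
        # jittered regular grid, as on a designed genotyping array: spacing
        # stays within [0.2, 1.8] x the mean, so no designed gap exceeds a
        # 20 kb gap rule at the default 10 kb density
        step = cfg.chrom_length_bp / (cfg.snps_per_chrom + 1)
        base = (np.arange(1, cfg.snps_per_chrom + 1) * step).astype(np.int64)
        p = base + rng.integers(-int(0.4 * step), int(0.4 * step) + 1, size=cfg.snps_per_chrom)
        p = np.maximum(p, 1)
        pos.extend(int(x) for x in p)
        chrom.extend([c] * cfg.snps_per_chrom)
        snp_id.extend(f"chr{c}_snp{i:04d}" for i in range(cfg.snps_per_chrom))
    m = len(snp_id)
    anc_idx = rng.integers(0, 4, size=m)
    der_shift = rng.integers(1, 4, size=m)
    anc = _BASES[anc_idx]
    der = _BASES[(anc_idx + der_shift) % 4]
    markers = MarkerMap.from_arrays(snp_id, chrom, pos, ancestral_allele=list(anc), allele_a=list(der), allele_b=list(anc))
    # from_arrays sorts by (chrom, pos); our construction is already sorted
    return markers, anc, der


def _gametes(
    H: np.ndarray,
    parents: np.ndarray,
    chrom_slices: list[tuple[int, int]],
    pos: np.ndarray,
    r: float,
    rng: np.random.Generator,
    poisson: bool,
) -> np.ndarray:
    """One recombinant gamete per parent index (vectorised over gametes)."""
    n = parents.size
    m = H.shape[1]
    out = np.empty((n, m), dtype=np.int8)
    hap_a = H[2 * parents]
    hap_b = H[2 * parents + 1]
    for s0, s1 in chrom_slices:
        p = pos[s0:s1]
        length = float(p[-1] - p[0])
        start = rng.integers(0, 2, size=n)
        if poisson:
            k = rng.poisson(r * length, size=n)
            sel = np.zeros((n, s1 - s0), dtype=np.int8)
            sel += start[:, None]
            for i in np.flatnonzero(k > 0):
                cuts = np.sort(rng.integers(p[0], p[-1], size=k[i]))
                idx = np.searchsorted(p, cuts, side="right")
                for j in idx:
                    sel[i, j:] += 1
            sel &= 1
        else:
            has_co = rng.random(n) < min(1.0, r * length)
            cut_bp = rng.integers(p[0], p[-1], size=n)
            cut_idx = np.searchsorted(p, cut_bp, side="right")
            after = np.arange(s1 - s0)[None, :] >= cut_idx[:, None]
            sel = (start[:, None] ^ (has_co[:, None] & after)).astype(np.int8)
        out[:, s0:s1] = np.where(sel == 0, hap_a[:, s0:s1], hap_b[:, s0:s1])
    return out


def _evolve(
    H: np.ndarray,
    n_next: int,
    sel: list[tuple[int, float]],
    chrom_slices: list[tuple[int, int]],
    pos: np.ndarray,
    r: float,
    rng: np.random.Generator,
    poisson: bool,
) -> np.ndarray:
    """One generation of selection, random mating (monoecious, selfing
    allowed), recombination and multinomial drift."""
    n_ind = H.shape[0] // 2
    if sel:
        w = np.ones(n_ind)
        for j, s in sel:
            dose = H[0::2, j].astype(float) + H[1::2, j]
            w *= (1.0 + s) ** dose
        prob = w / w.sum()
    else:
        prob = None
    mothers = rng.choice(n_ind, size=n_next, replace=True, p=prob)
    fathers = rng.choice(n_ind, size=n_next, replace=True, p=prob)
    g1 = _gametes(H, mothers, chrom_slices, pos, r, rng, poisson)
    g2 = _gametes(H, fathers, chrom_slices, pos, r, rng, poisson)
    out = np.empty((2 * n_next, H.shape[1]), dtype=np.int8)
    out[0::2] = g1
    out[1::2] = g2
    return out


def _seed_sweep_allele(
    H: np.ndarray, j: int, target_freq: float, flank: slice, rng: np.random.Generator
) -> None:
    """Re-seed the derived allele at column j to the target frequency on a
    shared local haplotype background (single-origin standing variation):
    carriers are the haplotypes most similar to a randomly chosen origin
    haplotype over the local flank, so the sweep starts from tight LD."""
    n = H.shape[0]
    k = max(1, round(target_freq * n))
    origin = rng.integers(0, n)
    sim = (H[:, flank] == H[origin, flank]).sum(axis=1).astype(float)
    sim += rng.random(n) * 0.5  # random tie-break
    carriers = np.argsort(-sim)[:k]
    H[:, j] = 0
    H[carriers, j] = 1


def simulate_divergence(cfg: SimConfig) -> SimResult:
    """Run the two-population divergence simulation.

    Deterministic for a fixed config (seed included).  Selected loci lost in
    both populations before sampling are recorded in the truth table, not
    raised.
    """
    rng = np.random.default_rng(cfg.seed)
    markers, anc, der = _make_map(cfg, rng)
    m = markers.n_snps
    pos = markers.pos_bp
    slices = [(sl.start, sl.stop) for sl in markers.chrom_slices().values()]

    # founder haplotypes: narrow base, chip-like ascertained frequencies
    q0 = rng.uniform(cfg.init_freq_low, cfg.init_freq_high, size=m)
    founders = (rng.random((cfg.n_founder_haplotypes, m)) < q0[None, :]).astype(np.int8)
    H = founders[rng.integers(0, cfg.n_founder_haplotypes, size=2 * cfg.Ne_ancestral)].copy()

    for _ in range(cfg.t_burnin):
        H = _evolve(H, cfg.Ne_ancestral, [], slices, pos, cfg.recomb_rate, rng, cfg.poisson_recomb)

    # locate selected loci as global SNP indices
    chrom_starts = {c: sl.start for c, sl in markers.chrom_slices().items()}
    sel_global = [(chrom_starts[L.chrom] + L.index, L) for L in cfg.selected_loci]
    for j, L in sel_global:
        lo = max(j - 10, 0)
        hi = min(j + 11, m)
        _seed_sweep_allele(H, j, L.init_freq, slice(lo, hi), rng)
    init_freq = H.mean(axis=0)

    pops: dict[str, np.ndarray] = {}
    for name, Ne, s_key in (
        (cfg.pop_names[0], cfg.Ne_pop1, "s_pop1"),
        (cfg.pop_names[1], cfg.Ne_pop2, "s_pop2"),
    ):
        # the split duplicates the ancestral pool; the first post-split
        # generation performs the resize to Ne, so exactly t_split
        # generations of drift separate each population from the ancestor
        P = H.copy()
        sel = [(j, getattr(L, s_key)) for j, L in sel_global if getattr(L, s_key) != 0.0]
        for _ in range(cfg.t_split):
            P = _evolve(P, Ne, sel, slices, pos, cfg.recomb_rate, rng, cfg.poisson_recomb)
        pops[name] = P

    final_freq = {name: P.mean(axis=0) for name, P in pops.items()}

    panels: dict[str, HaplotypePanel] = {}
    genotypes: dict[str, GenotypeMatrix] = {}
    label_index, label_values = [], []
    for name, n_sample in ((cfg.pop_names[0], cfg.n_sample_pop1), (cfg.pop_names[1], cfg.n_sample_pop2)):
        P = pops[name]
        pick = np.sort(rng.choice(P.shape[0] // 2, size=n_sample, replace=False))
        rows = np.empty(2 * n_sample, dtype=np.int64)
        rows[0::2] = 2 * pick
        rows[1::2] = 2 * pick + 1
        hap01 = P[rows]
        alleles = np.where(hap01 == 1, der[None, :], anc[None, :]).astype("<U1")
        samples = [f"{name}_{i:03d}" for i in range(n_sample)]
        panels[name] = HaplotypePanel(samples, MarkerMap(markers.table.copy()), alleles, coding="raw")
        calls = (hap01[0::2] + hap01[1::2]).astype(np.int8)
        genotypes[name] = GenotypeMatrix(samples, MarkerMap(markers.table.copy()), calls)
        label_index.extend(samples)
        label_values.extend([name] * n_sample)
    labels = PopulationLabels(pd.Series(label_values, index=pd.Index(label_index, name="sample_id")))

    s1 = np.zeros(m)
    s2 = np.zeros(m)
    selected = np.zeros(m, dtype=bool)
    for j, L in sel_global:
        s1[j], s2[j], selected[j] = L.s_pop1, L.s_pop2, True
    n1, n2 = cfg.pop_names
    truth_table = pd.DataFrame(
        {
            "snp_id": markers.snp_id,
            "chrom": markers.chrom,
            "pos_bp": markers.pos_bp,
            "ancestral_allele": anc,
            "derived_allele": der,
            "init_freq": init_freq,
            f"final_freq_{n1}": final_freq[n1],
            f"final_freq_{n2}": final_freq[n2],
            "selected": selected,
            f"s_{n1}": s1,
            f"s_{n2}": s2,
            "lost_in_both": (final_freq[n1] == 0) & (final_freq[n2] == 0),
        }
    )
    ne_h = 2.0 / (1.0 / cfg.Ne_pop1 + 1.0 / cfg.Ne_pop2)
    truth = SimTruth(table=truth_table, expected_fst=expected_fst(ne_h, cfg.t_split))
    return SimResult(markers=markers, panels=panels, genotypes=genotypes, labels=labels, truth=truth)


def merge_genotypes(genotypes: dict[str, GenotypeMatrix]) -> GenotypeMatrix:
    """Stack per-population genotype matrices sharing one marker map."""
    items = list(genotypes.values())
    first = items[0]
    for g in items[1:]:
        if not np.array_equal(g.markers.snp_id, first.markers.snp_id):
            raise ValueError("genotype matrices have different marker maps")
    samples = [s for g in items for s in g.samples]
    calls = np.vstack([g.calls for g in items])
    return GenotypeMatrix(samples, MarkerMap(first.markers.table.copy()), calls)


def merge_panels(panels: dict[str, HaplotypePanel]) -> HaplotypePanel:
    """Stack per-population haplotype panels sharing one marker map."""
    items = list(panels.values())
    first = items[0]
    samples = [s for p in items for s in p.samples]
    haps = np.vstack([p.haplotypes for p in items])
    return HaplotypePanel(samples, MarkerMap(first.markers.table.copy()), haps, coding=first.coding)


def truth_intervals(result: SimResult, rng: np.random.Generator | None = None) -> IntervalSet:
    """Synthetic gene/QTL annotation for the simulated genome.

    One "gene" spans each divergently selected locus (so sweep detection can
    be scored by gene overlap), a QTL interval covers a wider region around
    it, and neutral decoy genes are placed at regular offsets along every
    chromosome.
    """
    rng = rng or np.random.default_rng(12345)
    t = result.truth.table
    rows = []
    for _, r in t[t["selected"]].iterrows():
        rows.append((int(r["chrom"]), max(1, int(r["pos_bp"]) - 20_000), int(r["pos_bp"]) + 30_000,
                     f"SWEEPGENE_chr{int(r['chrom'])}", "gene"))
        rows.append((int(r["chrom"]), max(1, int(r["pos_bp"]) - 100_000), int(r["pos_bp"]) + 100_000,
                     f"SWEEPQTL_chr{int(r['chrom'])}", "QTL"))
    for c, sl in result.markers.chrom_slices().items():
        pos = result.markers.pos_bp[sl]
        for k, start in enumerate(range(int(pos[0]), int(pos[-1]), 1_000_000)):
            rows.append((int(c), start, start + int(rng.integers(20_000, 80_000)), f"DECOY_chr{c}_{k}", "gene"))
    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name", "category"])
    df = df.sort_values(["chrom", "start_bp"], kind="mergesort").reset_index(drop=True)
    return IntervalSet(df)
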