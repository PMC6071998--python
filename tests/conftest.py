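"""Shared fixtures: hand-built tiny panels and a session-scoped simulated cohort."""

import numpy as np
import pandas as pd
import pytest

from girscan import io, simulate as sm


@pytest.fixture
def tiny_map():
    return io.MarkerMap.from_arrays(
        snp_id=[f"s{i}" for i in range(4)],
        chrom=[1, 1, 1, 2],
        pos_bp=[100, 200, 300, 150],
        ancestral_allele=["A", "C", "G", "."],
        allele_a=["G", "T", "A", "C"],
        allele_b=["A", "C", "G", "T"],
    )


@pytest.fixture
def tiny_genotypes(tiny_map):
    calls = np.array(
        [
            [0, 1, 2, -1],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
            [0, 2, 2, 0],
        ],
        dtype=np.int8,
    )
    return io.GenotypeMatrix(["a", "b", "c", "d"], tiny_map, calls)


@pytest.fixture
def two_pop_labels():
    return io.PopulationLabels(
        pd.Series(
            ["beef", "beef", "dairy", "dairy"],
            index=pd.Index(["a", "b", "c", "d"], name="sample_id"),
        )
    )


def small_sim_config(seed=0, **overrides):
    """Desk-scale simulation used across the suite (~0.2 s per run)."""
    kwargs = dict(
        n_chrom=2,
        snps_per_chrom=250,
        Ne_ancestral=120,
        Ne_pop1=100,
        Ne_pop2=120,
        t_split=25,
        t_burnin=30,
        n_founder_haplotypes=240,
        selected_loci=[sm.SelectedLocus(chrom=1, index=125, s_pop1=0.12, s_pop2=0.0, init_freq=0.15)],
        n_sample_pop1=50,
        n_sample_pop2=60,
        seed=seed,
    )
    kwargs.update(overrides)
    return sm.SimConfig(**kwargs)


@pytest.fixture(scope="session")
def sim_cohort():
    """One simulated two-population cohort shared by read-only tests."""
    return sm.simulate_divergence(small_sim_config(seed=42))


@pytest.fixture(scope="session")
def sim_panel_coded(sim_cohort):
    panel, _ = io.recode_ancestral(sm.merge_panels(sim_cohort.panels))
    keep = ~(panel.haplotypes == io.MISSING).any(axis=0)
    return panel.subset_snps(keep)
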