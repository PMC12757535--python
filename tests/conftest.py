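"""Shared fixtures: tiny genotype matrices and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from smallpop.matrix import GenotypeMatrix
from smallpop.simulate import (
    SelectionBlock,
    SimulationScenario,
    random_hwe_cohort,
    simulate_cohort,
)


def make_matrix(gt, pos=None, chrom=None, sample_ids=None, phased=True,
                depth=None, gq=None):
    """Build a GenotypeMatrix from a (variants, samples, 2) array."""
    gt = np.asarray(gt, dtype=np.int8)
    n_var, n_smp = gt.shape[:2]
    if pos is None:
        pos = np.arange(1, n_var + 1) * 1000
    if chrom is None:
        chrom = ["chr1"] * n_var
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_smp)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_var, dtype=object),
        alt=np.array([("T",)] * n_var, dtype=object),
        gt=gt,
        phased=np.full((n_var, n_smp), phased, dtype=bool),
        depth=depth,
        gq=gq,
    )


def ts_to_matrix(ts, n_diploid, prefix="s"):
    """Convert an msprime tree sequence to a GenotypeMatrix."""
    gm = ts.genotype_matrix()
    pos = np.array([int(s.position) + 1 for s in ts.sites()])
    keep = np.concatenate([[True], np.diff(pos) > 0])
    gt = gm.reshape(gm.shape[0], n_diploid, 2).astype(np.int8)[keep]
    m = int(keep.sum())
    return GenotypeMatrix(
        sample_ids=[f"{prefix}{i:03d}" for i in range(n_diploid)],
        chrom=np.array(["chr1"] * m, dtype=object),
        pos=pos[keep],
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array([("T",)] * m, dtype=object),
        gt=gt,
        phased=np.ones((m, n_diploid), dtype=bool),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-deme cohort with both selection blocks planted."""
    scn = SimulationScenario(
        deme_sizes=(30, 12),
        n_chromosomes=2,
        chrom_length_bp=1_500_000,
        sites_per_chromosome=700,
        ancestral_size=80,
        burn_in_generations=800,
        split_generations=30,
        migration_rate=0.02,
        selfing_or_consanguinity=0.1,
        mhc_region=(0, 500_000, 1_000_000),
        balancing_block=SelectionBlock(0, 600_000, 700_000, 0.1),
        sweep_block=SelectionBlock(0, 800_000, 900_000, 0.5,
                                   onset_generations=25),
        seed=20_240_101,
    )
    g, ann, truth = simulate_cohort(scn)
    return g, ann, truth, scn


@pytest.fixture(scope="session")
def small_pops(small_cohort):
    g = small_cohort[0]
    return {
        "A": [s for s in g.sample_ids if s.startswith("A")],
        "B": [s for s in g.sample_ids if s.startswith("B")],
    }


@pytest.fixture(scope="session")
def hwe_cohort():
    """Linkage-free HWE cohort for planting experiments."""
    return random_hwe_cohort(20, 2000, seed=5)
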