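"""Replicated validation experiments on truth-known synthetic cohorts.

Each function runs a self-contained simulation experiment and returns
the summary a validation report needs: parameter-recovery error for
F_ROH, forward-vs-coalescent agreement for windowed F_ST, detection
rates for planted sweeps and balanced blocks, and the calibration of
the statistical machinery (type-I error, jackknife CI coverage).  The
coalescent comparisons use ``msprime`` purely as an independent
cross-check; it plays no role in any analysis path.

Problem sizes default to desk scale (a few-Mb chromosome, hundreds to
low thousands of candidate sites, populations of tens to ~120
diploids); every experiment takes seconds to a few minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .comparison import compare_two
from .diversity import per_site_pi, windowed_fst
from .matrix import GenotypeMatrix
from .neutrality import jackknife_ci, tajimas_d
from .roh import detect_roh, f_roh, genome_covered_bp
from .selection import XPEHHParams, xpehh_scan
from .simulate import (
    SelectionBlock,
    SimulationScenario,
    plant_inbred_individual,
    random_hwe_cohort,
    simulate_cohort,
)

__all__ = [
    "froh_recovery",
    "fst_forward_vs_coalescent",
    "sweep_detection_rate",
    "balancing_detection_rates",
    "ranksum_type_i_error",
    "jackknife_coverage",
]


def froh_recovery(
    target_f: float,
    n_reps: int = 20,
    seed: int = 0,
    tract_length_bp: int = 800_000,
) -> float:
    """Mean detected F_ROH (0.1 Mb threshold) over planted replicates.

    Tracts covering ``target_f`` of a linkage-free HWE cohort's genome
    are planted in one individual and recovered by the scanning-window
    ROH caller.
    """
    g = random_hwe_cohort(20, 2000, seed=seed)
    gbp = genome_covered_bp(g)
    vals = []
    for rep in range(n_reps):
        gp, _ = plant_inbred_individual(
            g, target_f, tract_length_bp, seed=seed * 10_000 + rep
        )
        segs = detect_roh(gp, samples=[gp.sample_ids[0]])
        fr = f_roh(segs, gbp, thresholds_mb=(0.1,),
                   samples=[gp.sample_ids[0]])
        vals.append(float(fr["f_roh"].iloc[0]))
    return float(np.mean(vals))


def _ts_to_matrix(ts, n_diploid: int, n1: int) -> GenotypeMatrix:
    gm = ts.genotype_matrix()
    pos = np.array([int(s.position) + 1 for s in ts.sites()])
    keep = np.concatenate([[True], np.diff(pos) > 0])
    gt = gm.reshape(gm.shape[0], n_diploid, 2).astype(np.int8)[keep]
    m = int(keep.sum())
    names = [f"A_{i:03d}" for i in range(n1)] + [
        f"B_{i:03d}" for i in range(n_diploid - n1)
    ]
    return GenotypeMatrix(
        sample_ids=names,
        chrom=np.array(["chr1"] * m, dtype=object),
        pos=pos[keep],
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array([("T",)] * m, dtype=object),
        gt=gt,
        phased=np.ones((m, n_diploid), dtype=bool),
    )


def fst_forward_vs_coalescent(
    n_forward: int = 16,
    n_coalescent: int = 50,
    seed: int = 0,
) -> tuple[float, float]:
    """Windowed mean Weir-Cockerham F_ST: forward WF vs coalescent.

    Identical demography both ways: ancestral size 100, clean split 40
    generations ago (0.2 x 2N) into isolated demes of 65 and 17
    diploids, no migration, no selection, no consanguinity.  Returns
    ``(forward_mean, coalescent_mean)``; the coalescent side is the
    independent oracle.
    """
    import msprime

    n1, n2 = 65, 17
    pops = {
        "A": [f"A_{i:03d}" for i in range(n1)],
        "B": [f"B_{i:03d}" for i in range(n2)],
    }
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=n1)
    dem.add_population(name="B", initial_size=n2)
    dem.add_population(name="anc", initial_size=100)
    dem.add_population_split(time=40, derived=["A", "B"], ancestral="anc")
    oracle_vals = []
    for rep in range(n_coalescent):
        ts = msprime.sim_ancestry(
            {"A": n1, "B": n2}, demography=dem,
            sequence_length=5_000_000, recombination_rate=2e-8,
            random_seed=seed * 100_000 + rep + 1,
        )
        ts = msprime.sim_mutations(
            ts, rate=7.5e-8, random_seed=seed * 100_000 + rep + 50_001,
            model=msprime.BinaryMutationModel(),
        )
        g = _ts_to_matrix(ts, n1 + n2, n1)
        oracle_vals.append(float(np.nanmean(windowed_fst(g, pops)["fst"])))

    fwd_vals = []
    for rep in range(n_forward):
        scn = SimulationScenario(
            deme_sizes=(n1, n2), n_chromosomes=1,
            chrom_length_bp=5_000_000, sites_per_chromosome=2000,
            ancestral_size=100, split_generations=40,
            migration_rate=0.0, selfing_or_consanguinity=0.0,
            balancing_block=None, sweep_block=None,
            mhc_region=(0, 2_000_000, 2_500_000),
            seed=seed * 1000 + rep,
        )
        g, _, _ = simulate_cohort(scn)
        fwd_vals.append(float(np.nanmean(windowed_fst(g, pops)["fst"])))
    return float(np.mean(fwd_vals)), float(np.mean(oracle_vals))


def _sweep_scenario(seed: int) -> SimulationScenario:
    return SimulationScenario(
        deme_sizes=(120, 120), n_chromosomes=1,
        chrom_length_bp=4_000_000, sites_per_chromosome=1200,
        ancestral_size=120, burn_in_generations=1200,
        split_generations=60, migration_rate=0.0,
        selfing_or_consanguinity=0.0, recombination_rate=5e-7,
        mhc_region=(0, 1_600_000, 2_400_000),
        balancing_block=None,
        sweep_block=SelectionBlock(0, 1_800_000, 2_200_000, 0.5,
                                   onset_generations=40),
        seed=seed,
    )


def sweep_detection_rate(n_reps: int = 20, seed: int = 0) -> float:
    """Fraction of replicates where the planted sweep is called.

    A hard sweep (s = 0.5) fixes in deme B within the last third of the
    split; detection means at least one site within 100 kb of the sweep
    center carries a bottom-5% XP-EHH (A vs B) flag.
    """
    hits = 0
    for rep in range(n_reps):
        g, _, truth = simulate_cohort(_sweep_scenario(seed * 1000 + rep))
        pops = {
            "A": [s for s in g.sample_ids if s.startswith("A")],
            "B": [s for s in g.sample_ids if s.startswith("B")],
        }
        sc = xpehh_scan(g, pops["A"], pops["B"],
                        XPEHHParams(max_extend_bp=600_000))
        _, pos = truth.sweep_site
        near = sc[np.abs(sc["pos"] - pos) <= 100_000]
        hits += bool((near["outlier_flag"] == "bottom5").any())
    return hits / n_reps


def balancing_detection_rates(
    n_reps: int = 20, s: float = 0.2, seed: int = 0
) -> tuple[float, float]:
    """(pi rate, Tajima's D rate) for a planted balanced block in deme A.

    pi rate: fraction of replicates with block pi above deme-A genome
    background; D rate: fraction with pooled block Tajima's D > 0.
    """
    pi_hits = d_hits = 0
    for rep in range(n_reps):
        scn = SimulationScenario(
            deme_sizes=(100, 17), n_chromosomes=1,
            chrom_length_bp=3_000_000, sites_per_chromosome=1000,
            ancestral_size=120, burn_in_generations=1200,
            split_generations=250, migration_rate=0.0,
            selfing_or_consanguinity=0.0, recombination_rate=2e-8,
            mhc_region=(0, 1_200_000, 1_800_000),
            balancing_block=SelectionBlock(0, 1_430_000, 1_530_000, s),
            sweep_block=None, seed=seed * 1000 + rep,
        )
        g, _, _ = simulate_cohort(scn)
        pop_a = [x for x in g.sample_ids if x.startswith("A")]
        pi = per_site_pi(g, g.sample_index(pop_a))
        in_block = (g.pos >= 1_430_001) & (g.pos <= 1_530_000)
        pi_hits += bool(
            np.nanmean(pi[in_block]) > np.nanmean(pi[~in_block])
        )
        r = tajimas_d(g, pop_a, site_idx=np.nonzero(in_block)[0])
        d_hits += bool(r.D is not None and r.D > 0)
    return pi_hits / n_reps, d_hits / n_reps


def ranksum_type_i_error(
    n_reps: int = 2000, n_per_group: int = 30, seed: int = 0
) -> float:
    """Rejection rate of the rank-sum test at alpha = 0.05 under the null."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        rej += compare_two(a, b).raw_p < 0.05
    return rej / n_reps


def jackknife_coverage(n_reps: int = 200, seed: int = 0) -> float:
    """Fraction of neutral simulations (n = 40 diploids) whose jackknife
    CI brackets the full-data Tajima's D."""
    import msprime

    cover = total = 0
    rep = 0
    while total < n_reps:
        rep += 1
        ts = msprime.sim_ancestry(
            40, population_size=100, sequence_length=50_000,
            recombination_rate=1e-8, random_seed=seed * 10_000 + rep,
        )
        ts = msprime.sim_mutations(
            ts, rate=2e-7, random_seed=seed * 10_000 + rep + 500_000,
            model=msprime.BinaryMutationModel(),
        )
        if ts.num_sites < 4:
            continue
        g = _ts_to_matrix(ts, 40, 40)
        r = jackknife_ci(g)
        if r.D is None or r.ci_low is None:
            continue
        total += 1
        cover += bool(r.ci_low <= r.D <= r.ci_high)
    return cover / total
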