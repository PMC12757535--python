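"""Forward-in-time Wright-Fisher simulator producing truth-known cohorts.

The generator emulates the statistical structure of a small, fragmented
diploid population: a bottlenecked ancestral population splits into two
demes of unequal size that then evolve with limited migration, optional
consanguineous mating (full-sib matings at a configurable rate, which
plants the long-ROH tail of recent inbreeding), a balanced polymorphism
(heterozygote advantage) in deme A, and a recent hard sweep in deme B.

The model is discrete-generation Wright-Fisher over a fixed panel of
candidate sites per chromosome: mutation flips alleles at candidate
sites (the per-bp mutation rate is concentrated onto the panel so the
total mutational flux per chromosome is preserved), recombination
places Poisson crossovers along the physical map each meiosis.  Forward
simulation is used -- rather than a coalescent -- because consanguinity
and recent selection are natural to plant forward in time; a coalescent
simulator serves only as an independent cross-check in the test suite.

Everything is driven by one ``numpy`` generator seeded from the
scenario, so a fixed seed reproduces byte-identical VCF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .variant_io import RegionAnnotation

__all__ = [
    "SelectionBlock",
    "SimulationScenario",
    "TruthTable",
    "simulate_cohort",
    "plant_inbred_individual",
    "plant_relative_pair",
]


@dataclass
class SelectionBlock:
    """A genomic interval under selection in one deme.

    ``chrom`` is a 0-based chromosome index; ``start``/``end`` are bp
    (0-based half-open).  ``s`` is the selection coefficient:
    heterozygote advantage for a balancing block, per-copy advantage
    for a sweep.  ``onset_generations`` (sweeps only) counts backwards
    from the end of the simulation.
    """

    chrom: int
    start: int
    end: int
    s: float
    onset_generations: int | None = None


@dataclass
class SimulationScenario:
    """Parameters of one simulated cohort.

    Defaults describe the study conditions the package targets: two
    recently diverged demes of 65 and 17 diploids descended from a
    bottlenecked ancestor of 200, with consanguineous mating, a
    balanced MHC-like block in deme A and a recent hard sweep in deme
    B.  ``mutation_rate`` is per bp per generation but is concentrated
    onto ``sites_per_chromosome`` candidate sites (total flux
    preserved); the default is scaled up from a realistic vertebrate
    rate so that desk-scale chromosomes carry a realistic SNP density.
    """

    n_demes: int = 2
    deme_sizes: tuple[int, ...] = (65, 17)
    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    sites_per_chromosome: int = 2_000
    mutation_rate: float = 7.5e-8
    recombination_rate: float = 2e-8
    ancestral_size: int = 200
    burn_in_generations: int | None = None  # default 10 * ancestral_size
    split_generations: int = 40
    migration_rate: float = 0.05
    selfing_or_consanguinity: float = 0.1
    balancing_block: SelectionBlock | None = field(
        default_factory=lambda: SelectionBlock(0, 2_050_000, 2_200_000, 0.05)
    )
    sweep_block: SelectionBlock | None = field(
        default_factory=lambda: SelectionBlock(
            0, 2_250_000, 2_450_000, 0.5, onset_generations=35
        )
    )
    mhc_region: tuple[int, int, int] = (0, 2_000_000, 2_500_000)
    seed: int = 0
    record_every: int = 25

    def __post_init__(self) -> None:
        if self.n_demes not in (1, 2):
            raise ValueError("n_demes must be 1 or 2")
        sizes = tuple(self.deme_sizes)[: self.n_demes]
        self.deme_sizes = sizes
        if any(n < 2 for n in sizes):
            raise ValueError("deme sizes must be >= 2")
        for name in ("mutation_rate", "recombination_rate",
                     "migration_rate", "selfing_or_consanguinity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for blk in (self.balancing_block, self.sweep_block):
            if blk is None:
                continue
            if not (0 <= blk.start < blk.end <= self.chrom_length_bp):
                raise ValueError(
                    f"selection block [{blk.start}, {blk.end}) outside "
                    f"[0, {self.chrom_length_bp})"
                )
            if not (0 <= blk.chrom < self.n_chromosomes):
                raise ValueError("selection block on missing chromosome")
        if self.ancestral_size < 2:
            raise ValueError("ancestral_size must be >= 2")

    @property
    def burn_in(self) -> int:
        if self.burn_in_generations is not None:
            return self.burn_in_generations
        return 10 * self.ancestral_size

    def to_yaml(self, path: str) -> None:
        import yaml

        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationScenario":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("balancing_block", "sweep_block"):
            if d.get(key) is not None:
                d[key] = SelectionBlock(**d[key])
        if "deme_sizes" in d:
            d["deme_sizes"] = tuple(d["deme_sizes"])
        if "mhc_region" in d:
            d["mhc_region"] = tuple(d["mhc_region"])
        return cls(**d)


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside each simulated cohort."""

    pedigree_f: pd.Series | None = None  # per-individual F (base: split)
    het_trajectory: pd.DataFrame | None = None
    balancing_sites: list[tuple[str, int]] | None = None
    sweep_site: tuple[str, int] | None = None
    sweep_final_freq: float | None = None
    balancing_final_freqs: list[float] | None = None
    blocks: pd.DataFrame | None = None
    inbred_tracts: pd.DataFrame | None = None
    planted_pairs: pd.DataFrame | None = None

    def to_tsvs(self, outdir: str, prefix: str = "truth") -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        if self.pedigree_f is not None:
            self.pedigree_f.rename("pedigree_f").to_csv(
                os.path.join(outdir, f"{prefix}_pedigree_f.tsv"), sep="\t"
            )
        for name in ("het_trajectory", "blocks", "inbred_tracts",
                     "planted_pairs"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(
                    os.path.join(outdir, f"{prefix}_{name}.tsv"),
                    sep="\t", index=False,
                )


# ----------------------------------------------------------------------
# internal simulation machinery
# ----------------------------------------------------------------------
class _Genome:
    """Candidate-site layout shared by all individuals."""

    def __init__(self, scn: SimulationScenario, rng: np.random.Generator):
        self.chrom_names = [f"chr{i + 1}" for i in range(scn.n_chromosomes)]
        self.site_pos: list[np.ndarray] = []
        offsets = [0]
        for _ in range(scn.n_chromosomes):
            pos = np.sort(
                rng.choice(
                    scn.chrom_length_bp,
                    size=min(scn.sites_per_chromosome, scn.chrom_length_bp),
                    replace=False,
                )
            ) + 1  # 1-based
            self.site_pos.append(pos.astype(np.int64))
            offsets.append(offsets[-1] + len(pos))
        self.offsets = np.array(offsets)
        self.S = int(self.offsets[-1])
        # per-site effective mutation probability: concentrate per-bp flux
        self.mu_site = (
            scn.mutation_rate * scn.chrom_length_bp / scn.sites_per_chromosome
        )
        self.xover_mean = scn.recombination_rate * scn.chrom_length_bp

    def site_index(self, chrom: int, bp: int) -> int:
        """Candidate site nearest to a physical coordinate."""
        pos = self.site_pos[chrom]
        k = int(np.clip(np.searchsorted(pos, bp), 0, len(pos) - 1))
        if k > 0 and abs(int(pos[k - 1]) - bp) < abs(int(pos[k]) - bp):
            k -= 1
        return int(self.offsets[chrom] + k)

    def block_sites(self, blk: SelectionBlock) -> np.ndarray:
        pos = self.site_pos[blk.chrom]
        on = np.nonzero((pos >= blk.start + 1) & (pos <= blk.end))[0]
        return self.offsets[blk.chrom] + on


def _make_gametes(
    rng: np.random.Generator,
    H: np.ndarray,
    parents: np.ndarray,
    genome: _Genome,
) -> np.ndarray:
    """One recombinant gamete per parent entry (vectorized)."""
    n = len(parents)
    S = genome.S
    take_b = np.zeros((n, S), dtype=bool)
    for c, pos in enumerate(genome.site_pos):
        lo, hi = genome.offsets[c], genome.offsets[c + 1]
        start = rng.integers(0, 2, size=n).astype(bool)
        take_b[:, lo:hi] = start[:, None]
        k = rng.poisson(genome.xover_mean, size=n)
        hot = np.nonzero(k)[0]
        for i in hot:
            bps = rng.integers(1, pos[-1] + 1, size=k[i])
            for bp in bps:
                j = lo + int(np.searchsorted(pos, bp))
                take_b[i, j:hi] ^= True
    hapA = H[2 * parents]
    hapB = H[2 * parents + 1]
    gam = np.where(take_b, hapB, hapA)
    # mutation: flip alleles at random (gamete, site) positions
    n_mut = rng.poisson(genome.mu_site * n * S)
    if n_mut:
        r = rng.integers(0, n, size=n_mut)
        s = rng.integers(0, S, size=n_mut)
        np.bitwise_xor.at(gam, (r, s), 1)
    return gam


def _choose_parents(
    rng: np.random.Generator,
    pool: np.ndarray,
    weights: np.ndarray | None,
    n_off: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two distinct parents per offspring, sampled prop. to fitness."""
    p = None
    if weights is not None:
        tot = weights.sum()
        p = weights / tot if tot > 0 else None
    p1 = rng.choice(pool, size=n_off, p=p)
    p2 = rng.choice(pool, size=n_off, p=p)
    for _ in range(100):
        clash = p1 == p2
        if not clash.any():
            break
        p2[clash] = rng.choice(pool, size=int(clash.sum()), p=p)
    else:
        # pool of size >= 2 guarantees an alternative
        for i in np.nonzero(p1 == p2)[0]:
            alt = pool[pool != p1[i]]
            p2[i] = rng.choice(alt)
    return p1, p2


class _Population:
    """Mutable population state during forward simulation."""

    def __init__(self, H: np.ndarray, deme_of: np.ndarray):
        self.H = H  # (2n, S) uint8
        self.deme_of = deme_of  # (n,)
        n = len(deme_of)
        self.kinship: np.ndarray | None = None  # (n, n), tracked post-split
        self.fam_id = -np.ones(n, dtype=np.int64)
        self.pedigree_f = np.zeros(n)

    @property
    def n(self) -> int:
        return len(self.deme_of)

    def start_kinship_tracking(self) -> None:
        self.kinship = np.eye(self.n) * 0.5

    def freqs(self, deme: int | None = None) -> np.ndarray:
        if deme is None:
            return self.H.mean(axis=0)
        rows = np.repeat(self.deme_of == deme, 2)
        return self.H[rows].mean(axis=0)


def _fitness(
    pop: _Population,
    scn: SimulationScenario,
    genome: _Genome,
    bal_sites: np.ndarray | None,
    sweep_site: int | None,
    sweep_active: bool,
    deme: int,
) -> np.ndarray | None:
    on = np.nonzero(pop.deme_of == deme)[0]
    w = None
    if deme == 0 and bal_sites is not None and scn.balancing_block:
        # multi-locus heterozygote advantage, multiplicative across the
        # block's balanced sites (an MHC-like supergene)
        het = (
            pop.H[2 * on][:, bal_sites] != pop.H[2 * on + 1][:, bal_sites]
        ).sum(axis=1)
        w = (1.0 + scn.balancing_block.s) ** het
    if deme == 1 and sweep_active and sweep_site is not None and scn.sweep_block:
        g = (
            pop.H[2 * on, sweep_site].astype(int)
            + pop.H[2 * on + 1, sweep_site]
        )
        ws = (1.0 + scn.sweep_block.s) ** g
        w = ws if w is None else w * ws
    return w


def _advance(
    rng: np.random.Generator,
    pop: _Population,
    scn: SimulationScenario,
    genome: _Genome,
    sizes: tuple[int, ...],
    consanguinity: float,
    migration: float,
    bal_sites: np.ndarray | None = None,
    sweep_site: int | None = None,
    sweep_active: bool = False,
) -> _Population:
    """Produce the next non-overlapping generation."""
    n_demes = len(sizes)
    P1_all, P2_all, deme_new = [], [], []
    for d in range(n_demes):
        n_off = sizes[d]
        pool_home = np.nonzero(pop.deme_of == d)[0]
        w_home = _fitness(pop, scn, genome, bal_sites, sweep_site,
                          sweep_active, d)
        if n_demes > 1 and migration > 0:
            other = 1 - d
            pool_away = np.nonzero(pop.deme_of == other)[0]
            w_away = _fitness(pop, scn, genome, bal_sites, sweep_site,
                              sweep_active, other)
            migrant = rng.random(n_off) < migration
        else:
            pool_away, w_away = None, None
            migrant = np.zeros(n_off, dtype=bool)
        n_home = int((~migrant).sum())
        p1 = np.empty(n_off, dtype=np.int64)
        p2 = np.empty(n_off, dtype=np.int64)
        if n_home:
            a, b = _choose_parents(rng, pool_home, w_home, n_home)
            p1[~migrant], p2[~migrant] = a, b
        if migrant.any():
            a, b = _choose_parents(rng, pool_away, w_away,
                                   int(migrant.sum()))
            p1[migrant], p2[migrant] = a, b
        # consanguineous matings: both parents from one full-sib family
        if consanguinity > 0:
            fam = pop.fam_id[pool_home]
            uniq, counts = np.unique(fam[fam >= 0], return_counts=True)
            big = uniq[counts >= 2]
            if len(big):
                inbred = (rng.random(n_off) < consanguinity) & ~migrant
                for i in np.nonzero(inbred)[0]:
                    f = big[rng.integers(len(big))]
                    sibs = pool_home[fam == f]
                    pick = rng.choice(len(sibs), size=2, replace=False)
                    p1[i], p2[i] = sibs[pick[0]], sibs[pick[1]]
        P1_all.append(p1)
        P2_all.append(p2)
        deme_new.append(np.full(n_off, d))
    P1 = np.concatenate(P1_all)
    P2 = np.concatenate(P2_all)
    deme_of = np.concatenate(deme_new)

    g1 = _make_gametes(rng, pop.H, P1, genome)
    g2 = _make_gametes(rng, pop.H, P2, genome)
    H_new = np.empty((2 * len(P1), genome.S), dtype=np.uint8)
    H_new[0::2] = g1
    H_new[1::2] = g2
    new = _Population(H_new, deme_of)

    # family identity for the next generation's sib-mating draws
    pair_key = P1 * pop.n + P2
    swap = P2 < P1
    pair_key[swap] = P2[swap] * pop.n + P1[swap]
    _, new.fam_id = np.unique(pair_key, return_inverse=True)

    if pop.kinship is not None:
        K = pop.kinship
        A = K[P1][:, P1] + K[P1][:, P2] + K[P2][:, P1] + K[P2][:, P2]
        K_new = 0.25 * A
        f = K[P1, P2]
        np.fill_diagonal(K_new, 0.5 * (1 + f))
        new.kinship = K_new
        new.pedigree_f = f
    return new


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------
def _default_annotation(
    scn: SimulationScenario, genome: _Genome
) -> RegionAnnotation:
    """Synthetic gene annotation: background genes plus an MHC cluster.

    Background CDS of 3 kb every 250 kb outside the MHC region; within
    the MHC region, genes of 10 kb CDS every 50 kb, labelled MHC (and
    CDS, preserving the subset relation).
    """
    rows = []
    mhc_chrom, mhc_lo, mhc_hi = scn.mhc_region
    gene_i = 0
    for c, name in enumerate(genome.chrom_names):
        p = 100_000
        while p + 3_000 < scn.chrom_length_bp:
            in_mhc = c == mhc_chrom and not (
                p + 3_000 <= mhc_lo or p >= mhc_hi
            )
            if not in_mhc:
                rows.append((name, p, p + 3_000, "CDS", f"gene{gene_i:04d}"))
                gene_i += 1
            p += 250_000
    mhc_name = genome.chrom_names[mhc_chrom]
    p = mhc_lo + 10_000
    m = 0
    while p + 10_000 < mhc_hi:
        rows.append((mhc_name, p, p + 10_000, "CDS", f"mhc{m:02d}"))
        rows.append((mhc_name, p, p + 10_000, "MHC_CDS", f"mhc{m:02d}"))
        m += 1
        p += 50_000
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cls", "name"])
    lengths = {n: scn.chrom_length_bp for n in genome.chrom_names}
    return RegionAnnotation(df, lengths)


def simulate_cohort(
    scn: SimulationScenario,
) -> tuple[GenotypeMatrix, RegionAnnotation, TruthTable]:
    """Simulate a phased cohort with planted truth.

    Returns the phased genotype matrix (biallelic segregating sites
    only), a synthetic gene annotation whose MHC cluster covers the
    selection blocks, and the truth table (pedigree inbreeding relative
    to the split founders, per-deme heterozygosity trajectory, selected
    site coordinates and final allele frequencies).

    Raises ``ValueError`` on degenerate scenarios (validated at
    construction) and when no site segregates in the final cohort.
    """
    rng = np.random.default_rng(scn.seed)
    genome = _Genome(scn, rng)

    # burn-in: one ancestral population at equilibrium
    H0 = np.zeros((2 * scn.ancestral_size, genome.S), dtype=np.uint8)
    pop = _Population(H0, np.zeros(scn.ancestral_size, dtype=np.int64))
    for _ in range(scn.burn_in):
        pop = _advance(
            rng, pop, scn, genome, (scn.ancestral_size,),
            consanguinity=0.0, migration=0.0,
        )

    het_rows = []

    def record(gen_label: int, p: _Population, n_demes: int) -> None:
        for d in range(n_demes):
            f = p.freqs(deme=d if n_demes > 1 else None)
            het_rows.append(
                (gen_label, d, float(np.mean(2 * f * (1 - f))))
            )

    bal_sites = sweep_site = None
    truth = TruthTable()
    # found the deme(s) by partitioning existing ancestral individuals
    # (no reproduction step, so the split itself costs no deme-specific
    # drift, matching an instantaneous coalescent population split)
    n_total = sum(scn.deme_sizes)
    if n_total <= pop.n:
        chosen = rng.choice(pop.n, size=n_total, replace=False)
    else:
        pop = _advance(rng, pop, scn, genome, (n_total,),
                       consanguinity=0.0, migration=0.0)
        chosen = np.arange(n_total)
    rows = np.empty(2 * n_total, dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    pop = _Population(pop.H[rows], np.zeros(n_total, dtype=np.int64))
    if scn.n_demes == 2:
        pop.deme_of = np.concatenate([
            np.zeros(scn.deme_sizes[0], dtype=np.int64),
            np.ones(scn.deme_sizes[1], dtype=np.int64),
        ])
    pop.start_kinship_tracking()

    if scn.n_demes == 1:
        for g in range(scn.split_generations):
            pop = _advance(rng, pop, scn, genome, scn.deme_sizes,
                           scn.selfing_or_consanguinity, 0.0)
            if g % scn.record_every == 0:
                record(g, pop, 1)
    else:
        if scn.balancing_block is not None:
            sites = genome.block_sites(scn.balancing_block)
            if len(sites) == 0:
                raise ValueError("balancing block contains no candidate site")
            # up to 5 balanced loci spread across the block, each taken
            # as the most intermediate-frequency site in its sub-interval
            f = pop.freqs()
            picked = []
            for chunk in np.array_split(sites, min(5, len(sites))):
                if len(chunk):
                    picked.append(
                        int(chunk[np.argmin(np.abs(f[chunk] - 0.5))])
                    )
            bal_sites = np.unique(picked)
        for g in range(scn.split_generations):
            gens_left = scn.split_generations - g
            if (
                scn.sweep_block is not None
                and scn.sweep_block.onset_generations is not None
                and gens_left == scn.sweep_block.onset_generations
            ):
                sites = genome.block_sites(scn.sweep_block)
                if len(sites) == 0:
                    raise ValueError("sweep block contains no candidate site")
                mid = (scn.sweep_block.start + scn.sweep_block.end) // 2
                sweep_site = genome.site_index(scn.sweep_block.chrom, mid)
                # hard sweep: the beneficial allele arises once, on one
                # deme-B haplotype
                pop.H[:, sweep_site] = 0
                rows_b = np.nonzero(np.repeat(pop.deme_of == 1, 2))[0]
                pop.H[rng.choice(rows_b), sweep_site] = 1
            sweep_active = sweep_site is not None
            # reintroduce a lost sweep allele so the sweep completes
            if sweep_active:
                rows_b = np.repeat(pop.deme_of == 1, 2)
                if pop.H[rows_b, sweep_site].sum() == 0:
                    idx_b = np.nonzero(rows_b)[0]
                    pop.H[rng.choice(idx_b), sweep_site] = 1
            pop = _advance(
                rng, pop, scn, genome, scn.deme_sizes,
                scn.selfing_or_consanguinity, scn.migration_rate,
                bal_sites=bal_sites, sweep_site=sweep_site,
                sweep_active=sweep_active,
            )
            if g % scn.record_every == 0 or g == scn.split_generations - 1:
                record(g, pop, 2)

    # assemble outputs -------------------------------------------------
    sample_ids = []
    counters = {0: 0, 1: 0}
    for d in pop.deme_of:
        label = "A" if d == 0 else "B"
        sample_ids.append(f"{label}_{counters[int(d)]:03d}")
        counters[int(d)] += 1

    freqs = pop.H.mean(axis=0)
    seg = (freqs > 0) & (freqs < 1)
    if not seg.any():
        raise ValueError(
            "no segregating sites in the final cohort; the scenario is "
            "degenerate (try more sites, a higher mutation rate, or a "
            "shorter bottleneck)"
        )
    keep = np.nonzero(seg)[0]
    chrom_arr = np.empty(len(keep), dtype=object)
    pos_arr = np.empty(len(keep), dtype=np.int64)
    for c in range(scn.n_chromosomes):
        lo, hi = genome.offsets[c], genome.offsets[c + 1]
        on = (keep >= lo) & (keep < hi)
        chrom_arr[on] = genome.chrom_names[c]
        pos_arr[on] = genome.site_pos[c][keep[on] - lo]

    n_ind = pop.n
    gt = np.empty((len(keep), n_ind, 2), dtype=np.int8)
    gt[:, :, 0] = pop.H[0::2][:, keep].T
    gt[:, :, 1] = pop.H[1::2][:, keep].T
    g = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=chrom_arr,
        pos=pos_arr,
        ref=np.array(["A"] * len(keep), dtype=object),
        alt=np.array([("T",)] * len(keep), dtype=object),
        gt=gt,
        phased=np.ones((len(keep), n_ind), dtype=bool),
    )

    ann = _default_annotation(scn, genome)

    truth.pedigree_f = pd.Series(pop.pedigree_f, index=sample_ids)
    truth.het_trajectory = pd.DataFrame(
        het_rows, columns=["generation", "deme", "expected_het"]
    )
    blocks = []
    if scn.balancing_block is not None and bal_sites is not None:
        b = scn.balancing_block
        name = genome.chrom_names[b.chrom]
        truth.balancing_sites = [
            (name, int(genome_site_pos(genome, s))) for s in bal_sites
        ]
        rows_a = np.repeat(pop.deme_of == 0, 2)
        truth.balancing_final_freqs = [
            float(pop.H[rows_a, s].mean()) for s in bal_sites
        ]
        blocks.append((name, b.start, b.end, "balancing", b.s))
    if scn.sweep_block is not None and sweep_site is not None:
        b = scn.sweep_block
        name = genome.chrom_names[b.chrom]
        truth.sweep_site = (name, int(genome_site_pos(genome, sweep_site)))
        truth.sweep_final_freq = float(
            pop.H[np.repeat(pop.deme_of == 1, 2), sweep_site].mean()
        )
        blocks.append((name, b.start, b.end, "sweep", b.s))
    truth.blocks = pd.DataFrame(
        blocks, columns=["chrom", "start", "end", "kind", "s"]
    )
    return g, ann, truth


def genome_site_pos(genome: _Genome, flat_idx: int) -> int:
    """Physical position (1-based) of a flat candidate-site index."""
    c = int(np.searchsorted(genome.offsets, flat_idx, side="right") - 1)
    return int(genome.site_pos[c][flat_idx - genome.offsets[c]])


# ----------------------------------------------------------------------
# planting fixtures
# ----------------------------------------------------------------------
def random_hwe_cohort(
    n_samples: int,
    n_sites_per_chrom: int,
    seed: int,
    n_chromosomes: int = 2,
    chrom_length_bp: int = 5_000_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> GenotypeMatrix:
    """Linkage-free cohort with genotypes drawn from Hardy-Weinberg.

    Every site is independent (no LD, no inbreeding, no structure), so
    baseline ROH, kinship and F_ST are all zero in expectation.  This is
    the clean substrate for planting experiments where the planted
    signal must be the only signal.
    """
    rng = np.random.default_rng(seed)
    chroms, poss = [], []
    for c in range(n_chromosomes):
        pos = np.sort(
            rng.choice(chrom_length_bp, size=n_sites_per_chrom,
                       replace=False)
        ) + 1
        poss.append(pos)
        chroms.extend([f"chr{c + 1}"] * n_sites_per_chrom)
    pos_all = np.concatenate(poss)
    n_var = len(pos_all)
    p = rng.uniform(*maf_range, size=n_var)
    gt = (
        rng.random((n_var, n_samples, 2)) < p[:, None, None]
    ).astype(np.int8)
    return GenotypeMatrix(
        sample_ids=[f"s{i:03d}" for i in range(n_samples)],
        chrom=np.array(chroms, dtype=object),
        pos=pos_all,
        ref=np.array(["A"] * n_var, dtype=object),
        alt=np.array([("T",)] * n_var, dtype=object),
        gt=gt,
        phased=np.ones((n_var, n_samples), dtype=bool),
    )


def plant_inbred_individual(
    g: GenotypeMatrix,
    target_f: float,
    tract_length_bp: int,
    seed: int,
    sample: str | None = None,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Plant homozygous-by-descent tracts in one individual.

    Non-overlapping tracts of ``tract_length_bp`` are placed uniformly
    so they cover fraction ``target_f`` of the SNP-covered genome; within
    each tract the first haplotype is copied over the second, making the
    stretch homozygous by construction.  Tract coordinates are recorded
    in the truth table.
    """
    if not (0 <= target_f <= 1):
        raise ValueError("target_f must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = g.copy()
    j = 0 if sample is None else int(g.sample_index([sample])[0])
    chroms = list(dict.fromkeys(g.chrom.tolist()))
    spans = []
    for c in chroms:
        p = g.pos[g.chrom == c]
        spans.append((c, int(p.min()), int(p.max())))
    genome_bp = sum(hi - lo + 1 for _, lo, hi in spans)
    truth = TruthTable()
    if target_f == 0:
        truth.inbred_tracts = pd.DataFrame(
            columns=["sample", "chrom", "start", "end"]
        )
        return out, truth
    if target_f == 1.0:
        tracts = [(c, lo, hi) for c, lo, hi in spans]
    else:
        total = target_f * genome_bp
        if total < tract_length_bp:
            raise ValueError(
                "target_f * genome shorter than one tract; lower "
                "tract_length_bp"
            )
        # full tracts plus one remainder so coverage is exact
        n_full = int(total // tract_length_bp)
        rem = total - n_full * tract_length_bp
        lengths = [float(tract_length_bp)] * n_full
        if rem >= 1:
            lengths.append(rem)
        free = genome_bp - sum(lengths)
        if free < 0:
            raise ValueError("tracts cannot fit in the genome")
        u = np.sort(rng.uniform(0, free, size=len(lengths)))
        starts_g = u + np.concatenate([[0], np.cumsum(lengths)[:-1]])
        tracts = []
        # map concatenated-genome coordinates back to chromosomes
        for s_g, ln_t in zip(starts_g, lengths):
            e_g = s_g + ln_t
            acc = 0
            for c, lo, hi in spans:
                ln = hi - lo + 1
                cs, ce = max(s_g - acc, 0), min(e_g - acc, ln)
                if ce > cs:
                    tracts.append((c, int(lo + cs), int(lo + ce)))
                acc += ln
    rows = []
    for c, s, e in tracts:
        on = (out.chrom == c) & (out.pos >= s) & (out.pos <= e)
        out.gt[on, j, 1] = out.gt[on, j, 0]
        rows.append((out.sample_ids[j], c, s, e))
    truth.inbred_tracts = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end"]
    )
    return out, truth


def _gamete_with_origin(
    rng: np.random.Generator,
    hapA: np.ndarray,
    hapB: np.ndarray,
    orgA: np.ndarray,
    orgB: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    recomb_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Recombine one individual's haplotypes, carrying origin labels."""
    take_b = np.zeros(len(pos), dtype=bool)
    for c in dict.fromkeys(chrom.tolist()):
        on = np.nonzero(chrom == c)[0]
        p = pos[on]
        length = int(p.max())
        cur = bool(rng.integers(0, 2))
        k = rng.poisson(recomb_rate * length)
        bps = np.sort(rng.integers(1, length + 1, size=k))
        seg = cur ^ (np.searchsorted(bps, p) % 2).astype(bool)
        take_b[on] = seg
    return (
        np.where(take_b, hapB, hapA),
        np.where(take_b, orgB, orgA),
    )


def plant_relative_pair(
    g: GenotypeMatrix,
    degree: str,
    seed: int,
    recomb_rate: float = 2e-8,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Rewrite two individuals as relatives of a requested degree.

    Genotypes of the target pair (the last two samples) are regenerated
    by Mendelian gamete-dropping from founder individuals drawn from the
    rest of the cohort: parent-offspring (expected kinship 1/4), second
    degree (half sibs, 1/8), third degree (first cousins, 1/16),
    unrelated (disjoint founders), or monozygotic (a duplicated
    individual).  The truth table records the expected and realized
    (founder-label IBD) kinship.
    """
    expected = {
        "parent-offspring": 0.25,
        "second": 0.125,
        "third": 0.0625,
        "unrelated": 0.0,
        "monozygotic": 0.5,
    }
    if degree not in expected:
        raise ValueError(
            f"unknown degree {degree!r}; choose from {sorted(expected)}"
        )
    if g.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    out = g.copy()
    i1, i2 = g.n_samples - 2, g.n_samples - 1
    n_found = {"parent-offspring": 2, "second": 3, "third": 4,
               "unrelated": 4, "monozygotic": 2}[degree]
    founders = rng.choice(g.n_samples - 2, size=n_found, replace=False)

    def haps(ind: int) -> tuple[np.ndarray, np.ndarray]:
        return g.gt[:, ind, 0].copy(), g.gt[:, ind, 1].copy()

    def org(ind: int) -> tuple[np.ndarray, np.ndarray]:
        n = g.n_variants
        return (
            np.full(n, 2 * ind, dtype=np.int32),
            np.full(n, 2 * ind + 1, dtype=np.int32),
        )

    def child(pa, pb):
        """pa, pb: (hapA, hapB, orgA, orgB) tuples for the two parents."""
        g1, o1 = _gamete_with_origin(
            rng, pa[0], pa[1], pa[2], pa[3], g.chrom, g.pos, recomb_rate
        )
        g2, o2 = _gamete_with_origin(
            rng, pb[0], pb[1], pb[2], pb[3], g.chrom, g.pos, recomb_rate
        )
        return (g1, g2, o1, o2)

    def as_tuple(ind: int):
        hA, hB = haps(ind)
        oA, oB = org(ind)
        return (hA, hB, oA, oB)

    f = [as_tuple(int(x)) for x in founders]
    if degree == "parent-offspring":
        parent = f[0]
        kid = child(parent, f[1])
        pair = (parent, kid)
    elif degree == "second":  # half sibs
        pair = (child(f[0], f[1]), child(f[0], f[2]))
    elif degree == "third":  # first cousins via two full sibs
        sib1, sib2 = child(f[0], f[1]), child(f[0], f[1])
        pair = (child(sib1, f[2]), child(sib2, f[3]))
    elif degree == "unrelated":
        pair = (child(f[0], f[1]), child(f[2], f[3]))
    else:  # monozygotic
        kid = child(f[0], f[1])
        pair = (kid, kid)

    for col, (hA, hB, _, _) in zip((i1, i2), pair):
        out.gt[:, col, 0] = hA
        out.gt[:, col, 1] = hB

    o1A, o1B = pair[0][2], pair[0][3]
    o2A, o2B = pair[1][2], pair[1][3]
    realized = float(
        np.mean(
            (o1A == o2A).astype(float) + (o1A == o2B) + (o1B == o2A)
            + (o1B == o2B)
        ) / 4.0
    )
    truth = TruthTable()
    truth.planted_pairs = pd.DataFrame(
        [
            (
                g.sample_ids[i1], g.sample_ids[i2], degree,
                expected[degree], realized,
            )
        ],
        columns=["sample1", "sample2", "degree", "expected_kinship",
                 "realized_kinship"],
    )
    return out, truth
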