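# Full example simulation scenario for `smallpop simulate` /
# `smallpop run-all --scenario`.
#
# Two demes of 65 and 17 diploids split from a bottlenecked ancestor of
# 200 diploids 40 generations ago, exchanging migrants at 5% per
# offspring, with 10% of matings between full sibs.  An MHC-like region
# on chr1 carries a balanced block (heterozygote advantage, deme A) and
# a recent hard sweep (deme B).  Rates are per bp per generation;
# mutation is concentrated onto `sites_per_chromosome` candidate sites
# per chromosome (total mutational flux preserved).

n_demes: 2
deme_sizes: [65, 17]
n_chromosomes: 2
chrom_length_bp: 5000000
sites_per_chromosome: 2000
mutation_rate: 7.5e-8
recombination_rate: 2.0e-8
ancestral_size: 200
burn_in_generations: null     # null -> 10 * ancestral_size
split_generations: 40
migration_rate: 0.05
selfing_or_consanguinity: 0.1
balancing_block:
  chrom: 0                    # 0-based chromosome index
  start: 2050000              # bp, 0-based half-open
  end: 2200000
  s: 0.05                     # heterozygote advantage
  onset_generations: null     # balancing acts from the split onward
sweep_block:
  chrom: 0
  start: 2250000
  end: 2450000
  s: 0.5                      # per-copy advantage
  onset_generations: 35       # generations before sampling
mhc_region: [0, 2000000, 2500000]   # chrom index, start, end
seed: 0
record_every: 25
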