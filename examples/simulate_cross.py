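"""Simulate a small selfed-F2 cross and inspect its ground truth.

A heterozygous F1 tree is selfed; each F2 inherits two independently
recombined F1 gametes.  The simulator records every true crossover
breakpoint and emits read-depth style observations per marker.
"""

from coscape import pipeline, simulate

cfg = pipeline.small_sim_config(seed=1, mutation_rate=3.0, co_coupling_fraction=0.0)
table, truth = simulate.simulate_f2_population(cfg)

print(f"chromosomes      : {list(cfg.chrom_lengths)}")
print(f"markers simulated: {table.n_records()} "
      f"({cfg.marker_density}/kbp over {sum(cfg.chrom_lengths.values())/1e6:.0f} Mbp)")
print(f"F2 samples       : {cfg.n_f2}")
print(f"true crossovers  : {truth.total_co()} "
      f"({truth.total_co()/cfg.n_f2:.2f} per F2; two gametes each)")
print(f"de novo mutations: {len(truth.mutations)}")
print()
s = truth.samples[0]
for chrom in cfg.chrom_lengths:
    bps = truth.breakpoints(s, chrom)
    print(f"{s} {chrom}: breakpoints at {bps.tolist()}")
# Each breakpoint is where one of the two gametes switched F1 haplotype;
# downstream callers must recover these positions from noisy genotypes alone.
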