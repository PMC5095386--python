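"""Full crossover-calling chain on a simulated cross, scored against truth.

Simulate -> allele-balance marker filter -> parent-free phasing ->
seed-and-extend block segmentation -> crossover events -> truth comparison.
"""

from coscape import blocks, markers, pipeline, simulate

cfg = pipeline.small_sim_config(seed=42)
table, truth = simulate.simulate_f2_population(cfg)

matrix = markers.filter_variants(table)
print(f"{matrix.n_markers()} of {table.n_records()} records kept as confident F1-het markers")

events, block_table, info = blocks.call_intraspecific(matrix)
for chrom, meta in info.items():
    print(f"{chrom}: phased via {meta['phase_route']}")
print(f"{len(events)} crossover events called (truth holds {truth.total_co()})")
print(events.head(5).to_string(index=False))

score = simulate.score_crossovers(events, truth)
print(f"\nrecall    = {score['recall']:.3f}")
print(f"precision = {score['precision']:.3f}")
print(f"mean |midpoint error| = {score['mean_abs_midpoint_error']:.0f} bp "
      f"(called-interval half-width averages {score['mean_half_gap']:.0f} bp)")
# recall/precision near 1 show the segmentation recovers essentially every
# simulated breakpoint at sub-kbp localization, the marker spacing permitting.
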