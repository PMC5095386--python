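# coscape

Crossover-landscape analysis of selfed-F2 sequencing crosses.

## The problem

Self-fertilizing a heterozygous F1 tree yields F2 progeny in which every
meiotic crossover (CO) is directly visible: each F2 chromosome is a mosaic
of the two F1 haplotypes, and whole-genome sequencing of the family turns
the mosaic's switch points into mappable recombination events.  `coscape`
implements the complete analysis chain for such parent–progeny designs:

* **Confident markers** — bi-allelic sites heterozygous in the F1, filtered
  by allele balance (homozygote if the reference-allele ratio is 0–5% or
  95–100%, heterozygote if 30–70%), quality ≥ 50, per-sample depth in
  [10, 80], and an informative call in more than half of the samples;
  markers in structural-variant regions are masked (intervals < 100 kbp
  whole, inversions with 200 bp flanks, larger SVs as ±400 bp breakpoint
  flanks).
* **Crossover calling** — genotype runs are clustered by *seeding and
  extension*: runs of ≥ 25 consecutive same-genotype markers spanning
  > 10 kbp seed blocks, same-genotype neighbours merge, and block edges
  extend to the furthest marker at which the cumulative match−mismatch
  score peaks.  A CO is called at every block-label switch, located by the
  interval between the flanking markers and summarized by its midpoint.
* **Parent-free phasing** — in an intraspecific cross no parental genomes
  exist, so homozygous calls are phased against an F2 that is homozygous
  along the whole chromosome (two copies of one F1 haplotype), or against a
  consensus haplotype stitched from many F2s' homozygous tracts.
* **Landscape statistics** — CO rate per F2 converts as
  rate = mean\_CO × 50 / length(Mbp) cM/Mbp (an F2 carries two meioses);
  500-kbp window counts, merging of similar windows, and a Monte-Carlo
  randomization test (10,000 genome-wide shuffles) call hotspot and
  coldspot regions at p < 0.05.  Spearman correlations use an exact
  permutation test for n ≤ 9; group rates are compared with the
  Brunner–Munzel test.
* **Mutation–CO coupling** — distance from each de novo mutation to its
  nearest same-sample CO midpoint, a proximity permutation test, and
  binned CO/mutation Spearman correlations at 0.5/1/2/5 Mbp with
  peri-centromeric bins discarded.
* **Windowed diversity** — population pairwise diversity per window
  (0 / 0.5 / 1 genotype scoring, informative-site and informative-pair
  thresholds) and its correlation with the CO landscape.
* **Synthetic crosses** — a fully ground-truthed simulator (Poisson COs,
  optional per-window intensity, binomial allele-depth sampling, genotyping
  error, pseudo-heterozygous artifact regions, optionally CO-coupled de
  novo mutations) so that every stage is testable without external data.

## Worked example

`examples/reference_cross_summary.py` runs the bundled per-chromosome
summary of a published peach experiment (an intraspecific cross with
286 COs in 24 F2s and an interspecific cross with 284 COs in 30 F2s)
through the rate and correlation machinery:

```
intraspecific : 286 COs / 24 F2s = 11.92 per F2 -> 2.64 cM/Mbp
interspecific : 284 COs / 30 F2s = 9.47 per F2 -> 2.10 cM/Mbp

length vs intraspecific rate : rho = -0.857, p = 0.0107 (exact)
combined mean COs vs length  : rho = 0.286, p = 0.5008
intra vs inter chromosome rate: rho = 0.952, p = 0.0011
```

Longer chromosomes recombine less per base pair, and the per-chromosome
rate profile is strongly repeatable between the two crosses.  The other
example scripts each demonstrate one capability end to end:

| script | shows |
| --- | --- |
| `examples/simulate_cross.py` | simulating a selfed-F2 cross with truth |
| `examples/call_crossovers.py` | marker filter → phasing → CO calls, scored vs truth |
| `examples/hotspot_scan.py` | randomization hotspot detection on a planted hotspot |
| `examples/mutation_coupling.py` | proximity test under coupled vs independent mutations |
| `examples/diversity_windows.py` | windowed pairwise diversity on a simulated panel |

A thin CLI mirrors the stages (`coscape simulate|filter|crossovers|landscape|coupling|diversity|run`).

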