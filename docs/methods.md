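# Methods

This note documents the models, algorithms, defaults and design choices
behind `coscape`, in the order of the pipeline.

## Study design and coordinates

The design is a selfed F2 family: one heterozygous F1 individual and its
self-fertilized progeny, each progeny genome the fusion of two independent
gametes of the same F1.  Markers are sites heterozygous in the F1.  All
internal coordinates are 0-based half-open; VCF input/output is 1-based;
BED output is 0-based half-open.

## Synthetic cross simulator (`coscape.simulate`)

The simulator provides ground truth for every downstream stage.  Its
defaults describe the sequencing design the package targets: eight
chromosomes totalling ~225 Mbp, 24 F2 samples, ~1.5 markers/kbp, ~50×
depth (`study_sim_config`; `small_sim_config` is a 2-chromosome, 10-F2
variant for fast tests).

* **Markers.** Positions are uniform without replacement, count =
  `round(density × length_kbp)` per chromosome (zero markers is an error
  naming the chromosome).  The F1's haplotype 1 carries a random ref/alt
  allele per marker; haplotype 2 the opposite.  Uniform placement is the
  simplest null consistent with the targeted marker densities
  (0.68–5.44/kbp across real crosses); clustering can be imposed through
  `artifact_regions` to exercise the gap-SE diagnostic.
* **Meiosis.** Crossovers per gamete per chromosome are
  Poisson(`mean_co_per_gamete`), positions uniform or drawn from a
  per-window `intensity_map`; the starting haplotype is a fair coin.
  There is **no crossover interference and no obligate chiasma** — the
  data the package emulates do not constrain an interference model, so
  pure Poisson is the documented assumption (the config is the natural
  extension point).  `mean_co_per_gamete` accepts a per-chromosome
  mapping; `study_sim_config` sets it to half the published per-F2 means,
  giving ≈ 11.9 expected COs per F2.
* **Observation model.** Per site and sample, total depth ~
  Poisson(`depth_mean`); alt reads ~ Binomial(depth, p) with p =
  `base_error`, 0.5, or 1 − `base_error` by genotype — the standard
  shotgun approximation given only a mean depth.  Genotyping error
  (default 0.001) replaces the true genotype with a random other genotype
  before the depth draw; the observable consequence (depths consistent
  with a wrong genotype) is the intended effect, and drawing before or
  after the depth sample is distributionally equivalent.  `artifact_regions`
  force alt reads ~ Binomial(depth, 0.5) in every sample, emulating
  pseudo-heterozygosity from collapsed paralogs.
* **Mutations.** Counts per F2 are Poisson(`mutation_rate`).  A
  `co_coupling_fraction` of mutations lands uniformly within
  ±`coupling_window` (default 2 kbp) of a uniformly chosen **same-sample**
  crossover — mutagenic recombination acts within one genome — with a
  logged uniform fallback when an F2 has no crossover; the rest are
  uniform genome-wide (chromosome chosen proportional to length).
  Positions colliding with markers are redrawn.
* **Determinism.** One integer seed drives every draw; identical configs
  give byte-identical outputs.

What the simulator does **not** model: read-level errors (FASTQ), indel
realism, linked-marker LD structure within haplotypes, segregation
distortion, structural variation beyond forced-het regions, or
interference.  Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
artifact of real sequencing data.

## Marker filtering (`coscape.markers`)

Genotypes come from the allele balance of genotyped reads (the AD sum);
DP enters only the depth bounds.  Bands: reference ratio ≥ 0.95 →
hom-ref, ≤ 0.05 → hom-alt, 0.30–0.70 → het (inclusive bounds), anything
else — including zero genotyped reads and depth outside [10, 80] —
MISSING.  Band boundaries are evaluated with a 1e-9 float guard so exact
decimal ratios land inside their band; an exhaustive scan against a
rational-arithmetic oracle covers all allele-depth pairs with total ≤ 120.

Decisions on ambiguous wording, fixed as defaults and configurable:

* depth bounds apply **per sample** (an out-of-range sample is MISSING at
  that site); a site-mean mode exists (`depth_mode="site_mean"`);
* ambiguous-ratio calls become MISSING rather than dropping the record,
  preserving the informative-call census;
* "more than half of samples informative" is a strict inequality — a tie
  drops the site;
* indel and SNP records are treated identically once bi-allelic.

SV masking: the union of caller outputs is used without further
filtering.  Intervals < 100 kbp are masked whole (inversions with 200 bp
flanks beyond both ends); intervals ≥ 100 kbp contribute ±400 bp around
each breakpoint only.  Out-of-chromosome spans are clipped with a warning;
unknown type tags are an error.

The marker-cluster diagnostic slides a 25-marker window (mirroring the
seed size; the windowing is otherwise a free choice) and flags windows
whose gap standard error `sd(gaps)/sqrt(n_gaps)` exceeds 100 bp strictly.
Flags are advisory: artifact regions are reported for review, not removed.

## Block segmentation and crossover calling (`coscape.blocks`)

Per sample and chromosome, MISSING markers are dropped (transparent) and
the remaining labels segmented:

1. **Seeds**: maximal same-label runs with ≥ k markers (default 25) and
   bp span strictly over `min_span` (default 10 kbp).
2. **Merge**: consecutive same-label seeds with no opposing seed between
   them fuse, absorbing intervening markers (mismatches counted); the
   result alternates labels by construction.
3. **Extend**: "extend to the furthest marker of the same genotype where
   the proportion of that genotype starts to decline" is operationalized
   as the cumulative match(+1)/mismatch(−1) score: the boundary is the
   furthest matching marker at which the cumulative score attains its
   maximum (ties → furthest).  This reading is monotone and
   order-independent.  Both gap neighbours extend independently; when
   their reaches overlap, the boundary is the split maximizing the summed
   scores (ties → the split nearest the gap midpoint).

A crossover is emitted at each adjacent-block label switch with interval
(last marker of the upstream block, first marker of the downstream block)
and midpoint `floor((left+right)/2)`.  A direct hom↔hom adjacency in
phased label space implies two crossovers within one marker interval;
it emits two events at the same interval plus a warning rather than
silently dropping signal.  There is no interactive boundary review; the
blocks table (marker and mismatch counts, resolutions) is the
machine-readable review report.

**Phasing without parents.**  A sample homozygous along a whole
chromosome carries two copies of one F1 haplotype ("haplotype 1"); every
HOM call elsewhere is labelled by match/mismatch against it.  Candidacy is
judged on the denoised HOM/HET segmentation (a raw all-HOM call vector
essentially never occurs at realistic error rates), and the most
informative candidate wins.  When no chromosome-wide homozygous sample
exists — probability decays with map length — the population-level caller
falls back to **tract stitching**: every homozygous block of every F2 is a
copy of one haplotype over its span; starting from the largest tract,
overlapping tracts are oriented by majority vote and fill the consensus
until coverage stops growing.  The label assignment is symmetric: phasing
against the complementary haplotype swaps labels but leaves crossover
midpoints unchanged (verified by test).  Markers the reference cannot
phase are dropped from the phased sequence and counted per chromosome.

For interspecific crosses both parents are available: markers where the
parents are reciprocally informative label F2 homozygotes directly;
others are dropped with a count.

## Landscape statistics (`coscape.landscape`)

* **Rate conversion.** An F2 aggregates two meioses, so map length in cM
  is `mean_co_per_F2 × 50` and rate = `mean_co × 50 / length_Mbp`.
* **Windows.** Non-overlapping 500-kbp windows (half-open; a midpoint on
  a boundary belongs to the right window; the last window is truncated).
  A midpoint beyond the chromosome length is an error.
* **Merging.** Adjacent windows merge while their count spread stays
  within `tol`; the default `tol = 0` (identical counts) is the minimal
  reading of "similar", and runs never cross chromosomes.
* **Randomization.** Each shuffle re-places all events uniformly over the
  genome (optionally excluding a mask; default none — the reference
  procedure shuffles across the whole genome).  `p_hot = (1 + #{shuffle ≥
  observed}) / (1 + n_rand)` and `p_cold` with ≤; the plus-one avoids
  p = 0 from finite shuffles.  Hotspot/coldspot at p < 0.05 per region,
  deliberately without multiplicity correction.  Calibration under a
  uniform null sits near the nominal level (~0.059 measured over 200
  replicate genomes): count discreteness pushes the test conservative
  while data-dependent merging of equal-count runs pushes it liberal, and
  the two nearly cancel at study-scale event densities.
* **Hot/cold summary.** Mean region rates, their fold ratio and a Welch
  (unequal-variance) t-test across regions — the robust default where
  only "t-test" is specified.  Identical constant groups return p = 1.
* **Spearman.** Average ranks; exact permutation p (all n! orderings,
  two-sided on |rho|) for n ≤ 9, the t-approximation above.  The exact
  test reproduces printed eight-chromosome p-values (0.0107 / 0.501 /
  0.001) that the t-approximation does not.
* **Brunner–Munzel.** scipy's t-approximation plus the rank-based
  relative effect P(a<b) + ½P(a=b); complete separation (relative effect
  0 or 1) degenerates the variance estimate and is returned as a flagged
  p = 0 rather than a NaN.
* **Telomere/peri-centromere filter.** Telomeric windows are the first
  and last window of each chromosome; peri-centromeric windows are those
  overlapping a BED interval by ≥ 1 bp.  The overlap filter is
  idempotent; telomere trimming refers to the full tiling and is applied
  once.

## Mutation–crossover coupling (`coscape.coupling`)

Distances are measured to CO **midpoints** (matching the windowing
convention; CO resolution, sub-kbp at study marker densities, is
commensurate with the 2-kbp radius of interest — an interval-edge mode
would change little).  Default mode is same-sample; pooled mode is also
reported since pooled distances lower-bound same-sample ones.  The
proximity test re-places each mutation uniformly along its own chromosome
(sample and chromosome preserved) and counts mutations within the radius;
p is one-sided with the plus-one correction.  Because within-radius
counts are small integers, ties make this permutation p conservative
(super-uniform under the null): the null-calibration suite therefore
asserts validity (no excess rejections at α) and non-degeneracy rather
than strict uniformity, which no correct discrete test could exhibit.
Power at literature-scale coupling (half of ~500 mutations within 2 kbp
of ~290 COs on a 225-Mbp genome) is essentially 1.

The binned correlation counts COs and mutations per bin at 0.5/1/2/5 Mbp,
discards peri-centromeric bins (recombination suppression would otherwise
induce a spurious positive association), and reports Spearman results per
bin size.

## Windowed diversity (`coscape.diversity`)

Sites first pass a population filter: strictly more than half missing
alleles, or a non-reference allele count below 5% of the allele total
(count < 7 for 70 diploids), drops the site.  With all-or-nothing diploid
genotype calls the allele-count and individual-count readings of
"half missing" coincide, so one code path implements both.

Per pair and site: 1 for opposite homozygotes, 0.5 for homozygote vs
heterozygote, 0 for identical genotypes (including het/het at a
bi-allelic site — identical unordered genotypes), missing → uninformative.
Per pair and window: summed differences over informative sites, counted
only when informative sites strictly exceed half the window's sites.  The
window value is the mean over informative pairs and the window is
retained when informative pairs reach half of n(n−1)/2 — for n = 70,
1207.5, i.e. ≥ 1208 of 2415 (both strictness conventions are verified by
boundary tests).  Thresholds are expressed as fractions so any panel size
is supported.  On complete data the statistic reduces to the mean
per-site genotype-dosage difference, cross-checked against a brute-force
all-pairs oracle.

## Problem sizes used by the test and acceptance suites

Study-scale recovery runs the full chain on 8 chromosomes / ~225 Mbp /
24 F2s / ~338k markers (seconds of runtime); randomization calibration
uses 200 replicate genomes at 1,000 shuffles; coupling calibration uses
200 null and 30 coupled replicates at 199 shuffles each.  These sizes give
Monte-Carlo error well inside the asserted tolerances while keeping the
whole suite around half a minute.

## Known limitations

* The extension rule is one defensible reading of a verbally specified
  procedure; alternates (e.g. windowed proportion estimates) would move
  block edges by a few markers at most but are not implemented.
* Tract-stitching phasing assumes the two F1 haplotypes are distinguishable
  at every marker (true by construction for F1-het markers) and that
  homozygous tracts overlap chainwise; a pathological chromosome with
  disconnected homozygosity would leave unphased gaps, which are counted
  and reported.
* The hotspot procedure inherits the reference design's choices (merging
  by identical counts, no multiplicity correction); its error rates are
  calibrated empirically, not exactly.
* Double crossovers closer than the marker resolution are fundamentally
  unobservable and are counted via the two-event convention only when
  phased labels force them.
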