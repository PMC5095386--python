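"""Synthetic selfed-F2 cross simulator with full ground truth.

The generative model mirrors a high-depth parent-progeny resequencing
design: a single heterozygous F1 tree is self-fertilized, and each F2
inherits two independently recombined gametes of the same F1.  Markers are
sites heterozygous in the F1; each F2's observed data are per-site read
depths and allele depths, so the whole downstream pipeline (allele-balance
genotyping, block segmentation, crossover calling) can be exercised against
a known truth.

Model components
----------------
* marker positions: uniform along each chromosome, count = density x length
  (rounded); the F1 carries two phased haplotypes with opposite alleles at
  every marker.
* meiosis: crossover count per gamete per chromosome ~ Poisson(mean);
  breakpoint positions uniform, or drawn from a per-window intensity map;
  starting haplotype a fair coin.  No crossover interference and no obligate
  chiasma (pure Poisson).
* sequencing: total depth ~ Poisson(depth_mean); alt-allele reads
  ~ Binomial(depth, p) with p = base_error, 0.5 or 1-base_error according to
  the true genotype; a genotyping-error rate replaces the true genotype by a
  random other genotype before the depth draw.
* artifacts: configured intervals are forced to an ~0.5 allele ratio in all
  samples, emulating pseudo-heterozygosity from collapsed paralogs or
  structural variants.
* de novo mutations: Poisson-distributed per F2; an optional coupling
  fraction is placed within a window of a true crossover of the same F2,
  the rest uniform genome-wide.

Everything is driven by one integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions for one simulated selfed-F2 population.

    Parameters
    ----------
    chrom_lengths
        Map chromosome name -> length in bp.
    marker_density
        Heterozygous markers per kbp (study groups ranged 0.68-5.44).
    n_f2
        Number of selfed F2 progeny.
    mean_co_per_gamete
        Expected crossovers per gamete *per chromosome*; either one float
        applied to every chromosome or a per-chromosome mapping.
    intensity_map
        Optional per-chromosome sequence of non-negative relative weights;
        the chromosome is split into ``len(weights)`` equal windows and
        breakpoints land in a window with probability proportional to its
        weight (uniform within).  ``None`` = uniform.
    depth_mean
        Mean sequencing depth (the study averaged ~51x).
    base_error
        Per-read per-site error probability.
    geno_error
        Probability that a site's true genotype is replaced by a random
        other genotype before depths are drawn.
    artifact_regions
        Map chromosome -> iterable of (start, end) bp intervals forced to
        pseudo-heterozygous allele ratios in every sample.
    mutation_rate
        Expected de novo mutations per F2 genome.
    co_coupling_fraction
        Fraction of mutations placed within ``coupling_window`` bp of a true
        crossover of the same F2 (the simulated alternative hypothesis of
        mutagenic recombination).
    coupling_window
        Half-width in bp of the coupling placement window.
    seed
        Integer RNG seed; every random draw descends from it.
    """

    chrom_lengths: dict[str, int]
    marker_density: float = 1.5
    n_f2: int = 24
    mean_co_per_gamete: float | Mapping[str, float] = 0.745
    intensity_map: Mapping[str, Sequence[float]] | None = None
    depth_mean: float = 50.0
    base_error: float = 0.01
    geno_error: float = 0.001
    artifact_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None
    mutation_rate: float = 0.0
    co_coupling_fraction: float = 0.0
    coupling_window: int = 2000
    seed: int = 0
    f1_name: str = "F1"

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must not be empty")
        for c, l in self.chrom_lengths.items():
            if l <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {l}")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be > 0")
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be >= 1")
        for name in ("base_error", "geno_error", "co_coupling_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.intensity_map is not None:
            for c, w in self.intensity_map.items():
                w = np.asarray(w, dtype=float)
                if (w < 0).any() or w.sum() <= 0:
                    raise ValueError(
                        f"intensity weights for {c!r} must be non-negative with positive sum"
                    )

    def co_mean(self, chrom: str) -> float:
        m = self.mean_co_per_gamete
        return float(m[chrom]) if isinstance(m, Mapping) else float(m)


@dataclass
class Gamete:
    """One recombined F1 gamete on one chromosome."""

    breakpoints: np.ndarray  # sorted bp positions, strictly increasing
    start_hap: int  # 1 or 2: F1 haplotype carried before the first breakpoint

    def hap_at(self, positions: np.ndarray) -> np.ndarray:
        """F1 haplotype of origin (1 or 2) at each queried position."""
        n_switch = np.searchsorted(self.breakpoints, positions, side="right")
        return np.where(n_switch % 2 == 0, self.start_hap, 3 - self.start_hap)


@dataclass
class TruthSet:
    """Ground truth of a simulated population."""

    samples: list[str]
    marker_positions: dict[str, np.ndarray]
    #: allele carried by F1 haplotype 1 at each marker (0=ref, 1=alt);
    #: haplotype 2 carries the opposite allele.
    f1_hap1_allele: dict[str, np.ndarray]
    #: (sample, chrom) -> [Gamete, Gamete]
    gametes: dict[tuple[str, str], list[Gamete]]
    #: chrom -> (n_markers, n_f2) true alt-allele counts (0/1/2)
    true_alt_count: dict[str, np.ndarray]
    mutations: pd.DataFrame | None = None

    def breakpoints(self, sample: str, chrom: str) -> np.ndarray:
        """All true breakpoints of a sample on a chromosome, pooled gametes."""
        g = self.gametes[(sample, chrom)]
        return np.sort(np.concatenate([g[0].breakpoints, g[1].breakpoints]))

    def total_co(self) -> int:
        return int(sum(len(g.breakpoints) for pair in self.gametes.values() for g in pair))

    def co_per_sample(self) -> pd.Series:
        counts = {s: 0 for s in self.samples}
        for (s, _), pair in self.gametes.items():
            counts[s] += len(pair[0].breakpoints) + len(pair[1].breakpoints)
        return pd.Series(counts)

    def phase_labels(self, sample: str, chrom: str) -> np.ndarray:
        """True phased label per marker: 0=HET, 2=hap1-hom, 3=hap2-hom."""
        pos = self.marker_positions[chrom]
        ga, gb = self.gametes[(sample, chrom)]
        ha, hb = ga.hap_at(pos), gb.hap_at(pos)
        lab = np.zeros(len(pos), dtype=np.int8)
        lab[(ha == 1) & (hb == 1)] = 2
        lab[(ha == 2) & (hb == 2)] = 3
        return lab


@dataclass
class VariantTable:
    """Raw multi-sample variant records, the simulator/VCF exchange format.

    Arrays are per chromosome; matrices are (n_records, n_samples).
    """

    samples: list[str]
    f1: str
    pos: dict[str, np.ndarray]
    qual: dict[str, np.ndarray]
    dp: dict[str, np.ndarray]
    ad_ref: dict[str, np.ndarray]
    ad_alt: dict[str, np.ndarray]
    biallelic: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.pos)

    def n_records(self) -> int:
        return int(sum(len(p) for p in self.pos.values()))


def _unique_sorted_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct uniform positions in [1, length], sorted."""
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:  # top up rare collisions
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n] if len(pos) == n else pos


def simulate_markers(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Draw marker positions and the F1's phased alleles.

    Returns ``(positions, f1_hap1_allele)``, each keyed by chromosome.  The
    marker count per chromosome is ``round(density * length_kbp)``; every
    marker is heterozygous in the F1, with haplotype 1 carrying a random
    ref/alt allele and haplotype 2 the opposite one.

    Raises
    ------
    ValueError
        If the density rounds to zero markers on some chromosome.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    positions: dict[str, np.ndarray] = {}
    hap1: dict[str, np.ndarray] = {}
    for chrom, length in config.chrom_lengths.items():
        n = int(round(config.marker_density * length / 1000.0))
        if n <= 0:
            raise ValueError(
                f"marker density {config.marker_density}/kbp yields zero markers "
                f"on chromosome {chrom!r} (length {length} bp)"
            )
        positions[chrom] = _unique_sorted_positions(rng, n, length)
        hap1[chrom] = rng.integers(0, 2, size=n).astype(np.int8)
    return positions, hap1


def simulate_gamete(config: SimConfig, chrom: str, rng: np.random.Generator) -> Gamete:
    """Simulate one gamete: Poisson crossover count, intensity-weighted positions."""
    if chrom not in config.chrom_lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    length = config.chrom_lengths[chrom]
    n_co = rng.poisson(config.co_mean(chrom))
    if config.intensity_map is not None and chrom in config.intensity_map:
        w = np.asarray(config.intensity_map[chrom], dtype=float)
        w = w / w.sum()
        win = rng.choice(len(w), size=n_co, p=w)
        win_size = length / len(w)
        bp = (win * win_size + rng.random(n_co) * win_size).astype(np.int64)
        bp = np.clip(bp, 1, length)
    else:
        bp = rng.integers(1, length + 1, size=n_co)
    bp = np.unique(bp)
    start_hap = int(rng.integers(1, 3))
    return Gamete(breakpoints=bp, start_hap=start_hap)


def simulate_f2_population(config: SimConfig) -> tuple[VariantTable, TruthSet]:
    """Simulate the full population: truth plus observed depth/allele-depth data.

    The returned :class:`VariantTable` contains the F1 column followed by the
    F2 columns and can be fed straight to :func:`coscape.markers.filter_variants`.
    """
    rng = np.random.default_rng(config.seed)
    positions, hap1 = simulate_markers(config, rng)
    f2_names = [f"F2_{i + 1:03d}" for i in range(config.n_f2)]
    samples = [config.f1_name] + f2_names

    gametes: dict[tuple[str, str], list[Gamete]] = {}
    for s in f2_names:
        for chrom in config.chrom_lengths:
            gametes[(s, chrom)] = [
                simulate_gamete(config, chrom, rng),
                simulate_gamete(config, chrom, rng),
            ]

    pos_d: dict[str, np.ndarray] = {}
    qual_d: dict[str, np.ndarray] = {}
    dp_d: dict[str, np.ndarray] = {}
    adr_d: dict[str, np.ndarray] = {}
    ada_d: dict[str, np.ndarray] = {}
    bi_d: dict[str, np.ndarray] = {}
    true_alt: dict[str, np.ndarray] = {}

    for chrom in config.chrom_lengths:
        pos = positions[chrom]
        m = len(pos)
        h1 = hap1[chrom]
        # true alt-allele count per marker per sample (F1 first: always het = 1)
        alt = np.empty((m, len(samples)), dtype=np.int8)
        alt[:, 0] = 1
        for j, s in enumerate(f2_names, start=1):
            ga, gb = gametes[(s, chrom)]
            ha, hb = ga.hap_at(pos), gb.hap_at(pos)
            allele_a = np.where(ha == 1, h1, 1 - h1)
            allele_b = np.where(hb == 1, h1, 1 - h1)
            alt[:, j] = allele_a + allele_b
        true_alt[chrom] = alt[:, 1:].copy()

        geno = alt.copy()
        if config.geno_error > 0:
            err = rng.random(geno.shape) < config.geno_error
            # replace by one of the two other genotypes, uniformly
            shift = rng.integers(1, 3, size=geno.shape).astype(np.int8)
            geno[err] = (geno[err] + shift[err]) % 3

        depth = rng.poisson(config.depth_mean, size=geno.shape).astype(np.int32)
        p_alt = np.choose(geno, [config.base_error, 0.5, 1.0 - config.base_error])
        ad_alt = rng.binomial(depth, p_alt).astype(np.int32)

        if config.artifact_regions and chrom in config.artifact_regions:
            inside = np.zeros(m, dtype=bool)
            for start, end in config.artifact_regions[chrom]:
                inside |= (pos >= start) & (pos < end)
            if inside.any():
                ad_alt[inside] = rng.binomial(depth[inside], 0.5).astype(np.int32)

        pos_d[chrom] = pos
        qual_d[chrom] = np.full(m, 500.0)
        dp_d[chrom] = depth
        adr_d[chrom] = depth - ad_alt
        ada_d[chrom] = ad_alt
        bi_d[chrom] = np.ones(m, dtype=bool)

    table = VariantTable(
        samples=samples,
        f1=config.f1_name,
        pos=pos_d,
        qual=qual_d,
        dp=dp_d,
        ad_ref=adr_d,
        ad_alt=ada_d,
        biallelic=bi_d,
        chrom_lengths=dict(config.chrom_lengths),
    )
    truth = TruthSet(
        samples=f2_names,
        marker_positions=positions,
        f1_hap1_allele=hap1,
        gametes=gametes,
        true_alt_count=true_alt,
    )
    if config.mutation_rate > 0:
        inject_mutations(config, truth, rng)
    return table, truth


def inject_mutations(
    config: SimConfig, truth: TruthSet, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Place de novo mutations, optionally coupled to same-sample crossovers.

    Per F2 the count is Poisson(mutation_rate).  A ``co_coupling_fraction``
    of mutations is placed uniformly within +-coupling_window bp of a
    uniformly chosen true crossover of that F2; the rest (and any coupled
    mutation of a crossover-free F2, which falls back with a log message)
    are uniform genome-wide.  Positions colliding with marker positions are
    redrawn.  The table is stored on ``truth.mutations`` and returned.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    marker_sets = {c: set(p.tolist()) for c, p in truth.marker_positions.items()}

    rows = []
    for s in truth.samples:
        cos: list[tuple[str, int]] = []
        for c in chroms:
            for bp in truth.breakpoints(s, c):
                cos.append((c, int(bp)))
        n_mut = rng.poisson(config.mutation_rate)
        for _ in range(n_mut):
            coupled = rng.random() < config.co_coupling_fraction
            if coupled and not cos:
                logger.info("sample %s has no crossovers; coupled mutation placed uniformly", s)
                coupled = False
            while True:
                if coupled:
                    c, bp = cos[rng.integers(len(cos))]
                    lo = max(1, bp - config.coupling_window)
                    hi = min(config.chrom_lengths[c], bp + config.coupling_window)
                    p = int(rng.integers(lo, hi + 1))
                else:
                    c = chroms[rng.choice(len(chroms), p=chrom_p)]
                    p = int(rng.integers(1, config.chrom_lengths[c] + 1))
                if p not in marker_sets[c]:
                    break
            rows.append({"sample": s, "chrom": c, "pos": p, "near_co": bool(coupled)})
    mutations = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "near_co"])
    truth.mutations = mutations
    return mutations


# ---------------------------------------------------------------------------
# file output


def write_outputs(table: VariantTable, truth: TruthSet, config: SimConfig, outdir) -> dict:
    """Write the simulated population to disk.

    Emits ``sim.vcf`` (GT/DP/AD, 1-based, sorted), ``truth_breakpoints.tsv``
    (sample, chrom, gamete, breakpoint_bp), ``truth_mutations.tsv`` and a
    ``config.yaml`` echo.  The VCF round-trips losslessly through
    :func:`coscape.markers.read_vcf`.
    """
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "sim.vcf",
        "breakpoints": outdir / "truth_breakpoints.tsv",
        "mutations": outdir / "truth_mutations.tsv",
        "config": outdir / "config.yaml",
    }

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coscape-simulate\n")
        for c, l in table.chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        gt_codes = ("0/0", "0/1", "1/1")
        for chrom in table.chroms:
            pos = table.pos[chrom]
            dp = table.dp[chrom]
            adr = table.ad_ref[chrom]
            ada = table.ad_alt[chrom]
            qual = table.qual[chrom]
            # GT written from the allele-balance of the observed depths
            tot = adr + ada
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(tot > 0, ada / np.maximum(tot, 1), np.nan)
            gt_idx = np.select(
                [ratio <= 0.05, ratio >= 0.95, (ratio >= 0.30) & (ratio <= 0.70)],
                [0, 2, 1],
                default=-1,
            )
            for i in range(len(pos)):
                cells = []
                for j in range(len(table.samples)):
                    gt = "./." if gt_idx[i, j] < 0 else gt_codes[gt_idx[i, j]]
                    cells.append(f"{gt}:{dp[i, j]}:{adr[i, j]},{ada[i, j]}")
                fh.write(
                    f"{chrom}\t{pos[i]}\t.\tA\tT\t{qual[i]:g}\t.\t.\tGT:DP:AD\t"
                    + "\t".join(cells)
                    + "\n"
                )

    bp_rows = []
    for (s, c), pair in truth.gametes.items():
        for g_idx, g in enumerate(pair):
            for bp in g.breakpoints:
                bp_rows.append((s, c, g_idx, int(bp)))
    pd.DataFrame(bp_rows, columns=["sample", "chrom", "gamete", "breakpoint_bp"]).to_csv(
        paths["breakpoints"], sep="\t", index=False
    )
    mut = truth.mutations if truth.mutations is not None else pd.DataFrame(
        columns=["sample", "chrom", "pos", "near_co"]
    )
    mut.to_csv(paths["mutations"], sep="\t", index=False)

    cfg = {
        k: (dict(v) if isinstance(v, Mapping) else v)
        for k, v in vars(config).items()
        if k != "intensity_map"
    }
    if config.intensity_map is not None:
        cfg["intensity_map"] = {c: list(map(float, w)) for c, w in config.intensity_map.items()}
    if config.artifact_regions is not None:
        cfg["artifact_regions"] = {
            c: [list(map(int, iv)) for iv in ivs] for c, ivs in config.artifact_regions.items()
        }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# truth-based scoring


def score_crossovers(
    events: pd.DataFrame, truth: TruthSet, match_window: int = 100_000
) -> dict:
    """Score called crossover events against the simulated truth.

    A true breakpoint and a called event match when they share sample and
    chromosome and the event midpoint lies within ``match_window`` bp of the
    breakpoint; matching is greedy one-to-one by distance.  The window only
    needs to exceed the marker-resolution scale and stay well below the
    inter-crossover distance (Mbp scale here).

    Returns recall, precision, the mean absolute midpoint error of matched
    pairs and the mean half-width of the called uncertainty intervals.
    """
    n_true = truth.total_co()
    n_called = len(events)
    if n_called == 0:
        return {
            "n_true": n_true,
            "n_called": 0,
            "recall": 0.0,
            "precision": float("nan"),
            "mean_abs_midpoint_error": float("nan"),
            "mean_half_gap": float("nan"),
        }
    matched_err = []
    matched_half = []
    n_matched = 0
    by_key = {k: g for k, g in events.groupby(["sample", "chrom"], sort=False)}
    for (s, c), pair in truth.gametes.items():
        true_bp = np.sort(np.concatenate([pair[0].breakpoints, pair[1].breakpoints]))
        g = by_key.get((s, c))
        if g is None or len(true_bp) == 0:
            continue
        mids = g["midpoint"].to_numpy()
        halfs = ((g["right"] - g["left"]) / 2.0).to_numpy()
        used = np.zeros(len(mids), dtype=bool)
        # greedy: process candidate pairs by increasing distance
        d = np.abs(true_bp[:, None] - mids[None, :])
        order = np.argsort(d, axis=None)
        taken_true = np.zeros(len(true_bp), dtype=bool)
        for flat in order:
            i, j = divmod(flat, len(mids))
            if d[i, j] > match_window:
                break
            if taken_true[i] or used[j]:
                continue
            taken_true[i] = True
            used[j] = True
            n_matched += 1
            matched_err.append(d[i, j])
            matched_half.append(halfs[j])
    return {
        "n_true": n_true,
        "n_called": n_called,
        "recall": n_matched / n_true if n_true else float("nan"),
        "precision": n_matched / n_called,
        "mean_abs_midpoint_error": float(np.mean(matched_err)) if matched_err else float("nan"),
        "mean_half_gap": float(np.mean(matched_half)) if matched_half else float("nan"),
    }
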