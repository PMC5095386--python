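"""Windowed population pairwise diversity and its relation to CO rate.

Diversity is the average pairwise genotype difference among all individual
pairs of a population panel, computed per window.  Per site, two different
homozygotes differ by 1, a homozygote and a heterozygote by 0.5, identical
genotypes by 0; a pair with a missing call is uninformative at that site.
Per pair and window the difference is the summed site differences divided
by the number of informative sites, provided strictly more than half of
the window's sites are informative for that pair; the window value is the
mean over informative pairs, and a window is retained only when at least
half of all possible pairs are informative (for a 70-individual panel:
>= 1208 of 2415 pairs).

Sites first pass a population filter: more than half missing alleles, or a
non-reference allele count below 5% of the allele total (count < 7 for 70
diploids), drops the site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import landscape
from .markers import GenotypeCall

logger = logging.getLogger(__name__)

WINDOW_SIZE_DEFAULT = 500_000


@dataclass
class PopulationMatrix:
    """Individuals x bi-allelic sites with genotype calls, per chromosome."""

    samples: list[str]
    pos: dict[str, np.ndarray]
    genos: dict[str, np.ndarray]  # (n_sites, n_individuals) GenotypeCall codes

    @property
    def chroms(self) -> list[str]:
        return list(self.pos)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    def n_sites(self) -> int:
        return int(sum(len(p) for p in self.pos.values()))


def read_population_vcf(path) -> PopulationMatrix:
    """Load a population VCF (bi-allelic records only) into a genotype matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    pos: dict[str, list] = {}
    genos: dict[str, list] = {}
    code = {0: GenotypeCall.HOM_REF, 1: GenotypeCall.HET, 2: GenotypeCall.HOM_ALT,
            3: GenotypeCall.MISSING}
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        g = np.array([code[int(t)] for t in v.gt_types], dtype=np.int8)
        pos.setdefault(v.CHROM, []).append(v.POS)
        genos.setdefault(v.CHROM, []).append(g)
    return PopulationMatrix(
        samples=samples,
        pos={c: np.asarray(p, dtype=np.int64) for c, p in pos.items()},
        genos={c: np.vstack(g) for c, g in genos.items()},
    )


def default_min_alt_count(n_individuals: int, frac: float = 0.05) -> int:
    """Minimum non-reference allele count: ``frac`` of the 2n allele total."""
    return math.ceil(frac * 2 * n_individuals)


def site_filter(
    matrix: PopulationMatrix,
    min_alt_count: int | None = None,
    max_missing_frac: float = 0.5,
) -> PopulationMatrix:
    """Drop low-quality population sites.

    A site is dropped when strictly more than ``max_missing_frac`` of its
    alleles are missing, or its non-reference allele count (hets + 2 x alt
    homozygotes) is below ``min_alt_count`` (default: 5% of all alleles,
    i.e. 7 for 70 diploids).  With all-or-nothing diploid calls the
    missing-allele and missing-individual fractions coincide.
    """
    if min_alt_count is None:
        min_alt_count = default_min_alt_count(matrix.n_individuals)
    pos_out, genos_out = {}, {}
    n_drop = 0
    for c in matrix.chroms:
        g = matrix.genos[c]
        missing_frac = (g == GenotypeCall.MISSING).mean(axis=1)
        alt_count = (g == GenotypeCall.HET).sum(axis=1) + 2 * (
            g == GenotypeCall.HOM_ALT
        ).sum(axis=1)
        keep = (missing_frac <= max_missing_frac) & (alt_count >= min_alt_count)
        n_drop += int((~keep).sum())
        pos_out[c] = matrix.pos[c][keep]
        genos_out[c] = g[keep]
    logger.info("site filter removed %d sites", n_drop)
    return replace(matrix, pos=pos_out, genos=genos_out)


def pairwise_site_diff(g1: int, g2: int) -> float:
    """Per-site genotype difference between two individuals.

    1 for two different homozygotes, 0.5 for homozygote vs heterozygote,
    0 for identical genotypes, NaN when either call is missing (the site is
    uninformative for the pair).
    """
    if g1 == GenotypeCall.MISSING or g2 == GenotypeCall.MISSING:
        return float("nan")
    return abs(int(g1) - int(g2)) / 2.0


def window_retained(n_informative_pairs: int, n_individuals: int, min_pair_frac: float = 0.5) -> bool:
    """Retention rule: at least ``min_pair_frac`` of all n(n-1)/2 pairs informative.

    For 70 individuals the threshold is 0.5 x 2415 = 1207.5, so windows with
    fewer than 1208 informative pairs are discarded.
    """
    total = n_individuals * (n_individuals - 1) // 2
    return n_informative_pairs >= min_pair_frac * total


def window_diversity(
    matrix: PopulationMatrix,
    chrom_lengths: Mapping[str, int] | None = None,
    window_size: int = WINDOW_SIZE_DEFAULT,
    min_site_frac: float = 0.5,
    min_pair_frac: float = 0.5,
) -> pd.DataFrame:
    """Mean pairwise diversity per window.

    Per pair and window: summed site differences over the number of sites
    informative for the pair, counted only when the informative-site
    fraction strictly exceeds ``min_site_frac``.  The window diversity is
    the mean over informative pairs; ``retained`` applies
    :func:`window_retained`.  Windows without sites are non-retained and
    flagged by ``n_sites = 0``.
    """
    n = matrix.n_individuals
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rows = []
    for chrom in matrix.chroms:
        pos = matrix.pos[chrom]
        g = matrix.genos[chrom]
        if chrom_lengths is not None and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            length = int(pos.max()) + 1 if len(pos) else window_size
        n_win = int(np.ceil(length / window_size))
        win_idx = np.minimum(pos // window_size, n_win - 1).astype(int) if len(pos) else np.array([], dtype=int)
        for w in range(n_win):
            sel = win_idx == w
            n_sites = int(sel.sum())
            start = w * window_size
            end = min(start + window_size, length)
            if n_sites == 0:
                rows.append(
                    {"chrom": chrom, "idx": w, "start": start, "end": end,
                     "diversity": float("nan"), "n_informative_pairs": 0,
                     "n_sites": 0, "retained": False}
                )
                continue
            sub = g[sel]
            valid = sub != GenotypeCall.MISSING
            diffs = []
            n_inf_pairs = 0
            for i, j in pairs:
                both = valid[:, i] & valid[:, j]
                n_inf = int(both.sum())
                if n_inf <= min_site_frac * n_sites:  # strict "more than half"
                    continue
                d = np.abs(sub[both, i].astype(int) - sub[both, j].astype(int)) / 2.0
                diffs.append(d.sum() / n_inf)
                n_inf_pairs += 1
            retained = n_inf_pairs > 0 and window_retained(n_inf_pairs, n, min_pair_frac)
            rows.append(
                {"chrom": chrom, "idx": w, "start": start, "end": end,
                 "diversity": float(np.mean(diffs)) if diffs else float("nan"),
                 "n_informative_pairs": n_inf_pairs, "n_sites": n_sites,
                 "retained": retained}
            )
    return pd.DataFrame(rows)


def diversity_co_correlation(
    div_windows: pd.DataFrame, co_windows: pd.DataFrame
) -> "landscape.SpearmanResult":
    """Spearman correlation between retained window diversity and CO counts.

    Joins on (chrom, idx); requires both frames to use the same windowing.
    """
    retained = div_windows[div_windows["retained"]]
    merged = retained.merge(co_windows[["chrom", "idx", "count"]], on=["chrom", "idx"])
    if len(merged) == 0:
        raise ValueError("no overlapping windows between diversity and CO tables")
    return landscape.spearman(merged["diversity"], merged["count"])
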