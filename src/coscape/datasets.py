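"""Reference crossover summaries from a published peach parent-progeny experiment.

Two selfed-F2 crosses of a heterozygous F1 peach tree were whole-genome
sequenced and their crossovers (COs) mapped: an intraspecific cross within
domesticated *Prunus persica* (24 F2s, 286 COs) and an interspecific
*P. davidiana* x *P. persica* cross (30 F2s, 284 COs).  The per-chromosome
mean CO counts per F2 and the corresponding CO rates in cM/Mbp are bundled
here as the package's worked example and as the calibration input for the
study-scale simulator.

Chromosome physical lengths are not part of the published summary table but
are implied by it: a rate in cM/Mbp, a mean CO count per F2 and the
cM-per-CO conversion (an F2 carries two gametes, so map length in cM is
``mean_co * 50``) pin the length down as ``mean_co * 50 / rate``.
:func:`derived_chromosome_lengths_mbp` reconstructs them; they sum to
~225.4 Mbp, the assembled peach genome size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CHROMOSOMES: tuple[str, ...] = (
    "Pp01", "Pp02", "Pp03", "Pp04", "Pp05", "Pp06", "Pp07", "Pp08",
)


@dataclass(frozen=True)
class CrossSummary:
    """Per-chromosome CO summary of one cross (one row pair of the table)."""

    label: str
    n_f2: int
    total_co: int
    #: mean crossovers per F2 sample, per chromosome
    mean_co: tuple[float, ...]
    #: CO rate per chromosome, cM/Mbp per meiosis per sample
    rate_cm_per_mbp: tuple[float, ...]
    #: printed genome-wide mean CO count per F2
    genome_mean_co: float
    #: printed genome-wide rate, cM/Mbp
    genome_rate: float


INTRASPECIFIC = CrossSummary(
    label="intraspecific",
    n_f2=24,
    total_co=286,
    mean_co=(2.08, 1.63, 1.54, 1.33, 1.58, 1.08, 1.46, 1.21),
    rate_cm_per_mbp=(2.18, 2.67, 2.82, 2.58, 4.28, 1.76, 3.26, 2.68),
    genome_mean_co=11.92,
    genome_rate=2.64,
)

INTERSPECIFIC = CrossSummary(
    label="interspecific",
    n_f2=30,
    total_co=284,
    mean_co=(1.60, 1.27, 1.23, 1.10, 1.17, 1.00, 1.07, 1.03),
    rate_cm_per_mbp=(1.67, 2.08, 2.25, 2.13, 3.15, 1.63, 2.38, 2.29),
    genome_mean_co=9.47,
    genome_rate=2.10,
)

#: average recombination rate over detected hotspot regions, cM/Mbp
HOTSPOT_MEAN_RATE = 8.04
#: average recombination rate over detected coldspot regions, cM/Mbp
COLDSPOT_MEAN_RATE = 0.48
#: combined span of the 14 coldspot regions, Mbp
COLDSPOT_SPAN_MBP = 53.8
#: combined span of the 26 hotspot regions, Mbp
HOTSPOT_SPAN_MBP = 19.0
N_HOTSPOTS = 26
N_COLDSPOTS = 14

#: whole-genome diversity between the two haplotypes of each F1, in percent:
#: young intraspecific F1, old (wild) intraspecific F1, interspecific F1.
F1_HAPLOTYPE_DIVERSITY_PCT = {
    "intraspecific_young": 0.29,
    "intraspecific_old": 0.27,
    "interspecific": 1.24,
}

#: reliable SNP + indel marker totals and resulting densities (markers/kbp)
MARKER_DENSITY_PER_KBP = {
    "intraspecific_young": 1.51,
    "intraspecific_old": 0.68,
    "interspecific": 5.44,
}


def derived_chromosome_lengths_mbp(summary: CrossSummary = INTRASPECIFIC) -> np.ndarray:
    """Physical chromosome lengths (Mbp) implied by a cross summary.

    Inverts rate = mean_co * 50 / length for each chromosome.
    """
    mean = np.asarray(summary.mean_co, dtype=float)
    rate = np.asarray(summary.rate_cm_per_mbp, dtype=float)
    return mean * 50.0 / rate


def genome_length_mbp(summary: CrossSummary = INTRASPECIFIC) -> float:
    """Total genome length (Mbp) implied by a cross summary (~225.4)."""
    return float(derived_chromosome_lengths_mbp(summary).sum())


def study_chrom_lengths_bp() -> dict[str, int]:
    """Chromosome-length table (bp) for study-scale simulations."""
    lengths = derived_chromosome_lengths_mbp()
    return {c: int(round(l * 1e6)) for c, l in zip(CHROMOSOMES, lengths)}
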