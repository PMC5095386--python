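"""Genotype-block segmentation and crossover calling by seeding and extension.

Along each F2 chromosome the ordered marker genotypes form long runs — the
inherited blocks — interrupted where a meiotic crossover switched the
underlying haplotype pair.  Segmentation proceeds in three steps:

1. *Seeding*: maximal runs of at least ``k`` consecutive same-label markers
   spanning more than ``min_span`` bp become seeds (defaults 25 markers /
   10 kbp).
2. *Merging*: adjacent seeds with the same label, with no differently
   labelled seed between them, fuse into blocks, absorbing the intervening
   noisy markers, until all adjacent blocks carry different labels.
3. *Extension*: each block edge walks outward through the unassigned gap;
   the boundary is placed at the furthest matching marker at which the
   cumulative match-minus-mismatch score is maximal (the point where the
   proportion of the block's genotype starts to decline).  Both gap
   neighbours extend independently; overlaps are resolved at the split
   maximizing the sum of both scores.

A crossover (CO) is emitted at every adjacent-block label switch; its
location is the interval between the flanking member markers, summarized by
the midpoint.

For a selfed F2 of an intraspecific cross no parental genomes exist, so
homozygous calls cannot immediately be assigned to a haplotype.  Phasing
uses the progeny themselves: a sample that is homozygous along a whole
chromosome carries two copies of one F1 haplotype ("haplotype 1"), and
every other sample's homozygous calls are labelled by comparison with it.
When no such sample exists, a reference haplotype is stitched together from
the homozygous tracts of many F2s (majority-vote orientation on overlaps).
In an interspecific cross the parents are available and homozygous calls
are labelled directly against them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markers import GenotypeCall, MarkerMatrix

logger = logging.getLogger(__name__)

# label space (one shared integer coding)
HET = 0
HOM = 1  # unphased homozygote (intraspecific, pre-phasing)
HOM_A = 2  # haplotype-1 / parent-A homozygote
HOM_B = 3  # haplotype-2 / parent-B homozygote

LABEL_NAMES = {HET: "HET", HOM: "HOM", HOM_A: "HOM_A", HOM_B: "HOM_B"}


class ReferenceHaplotypeError(RuntimeError):
    """No all-homozygous sample available to anchor intraspecific phasing."""


@dataclass
class GenotypeSequence:
    """One sample x chromosome: ordered informative markers with labels."""

    sample: str
    chrom: str
    pos: np.ndarray  # sorted bp positions of informative markers
    labels: np.ndarray  # int8 codes from the label space above
    n_unphased: int = 0  # homozygous markers dropped for lack of phase information

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class Block:
    """Maximal same-genotype marker run after merging and extension."""

    sample: str
    chrom: str
    first: int  # index of first member marker in the sequence
    last: int  # index of last member marker (inclusive)
    start: int  # bp of first member marker
    end: int  # bp of last member marker
    label: int
    n_markers: int
    n_mismatch: int  # non-label markers absorbed


@dataclass
class CrossoverEvent:
    """A genotype switch between adjacent blocks."""

    sample: str
    chrom: str
    left: int  # bp of last marker of the upstream block
    right: int  # bp of first marker of the downstream block
    midpoint: int
    from_label: int
    to_label: int

    @property
    def resolution(self) -> int:
        return self.right - self.left


Seed = tuple[int, int, int]  # (first_idx, last_idx, label)


def find_seeds(seq: GenotypeSequence, k: int = 25, min_span: int = 10_000) -> list[Seed]:
    """Maximal runs of >= k same-label markers spanning more than min_span bp."""
    if k < 2:
        raise ValueError("seed size k must be >= 2")
    if min_span <= 0:
        raise ValueError("min_span must be > 0")
    lab = seq.labels
    n = len(lab)
    if n == 0:
        return []
    change = np.nonzero(np.diff(lab))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [n - 1]])
    seeds = []
    for i0, i1 in zip(starts, ends):
        if i1 - i0 + 1 >= k and seq.pos[i1] - seq.pos[i0] > min_span:
            seeds.append((int(i0), int(i1), int(lab[i0])))
    return seeds


def merge_seeds(seeds: Sequence[Seed], seq: GenotypeSequence) -> list[Block]:
    """Fuse consecutive same-label seeds into alternating blocks.

    Markers lying between fused seeds are absorbed; those not matching the
    block label are counted in ``n_mismatch``.
    """
    blocks: list[Block] = []
    for i0, i1, lab in seeds:
        if blocks and blocks[-1].label == lab:
            b = blocks[-1]
            b.last = i1
            b.end = int(seq.pos[i1])
            span = seq.labels[b.first : i1 + 1]
            b.n_markers = len(span)
            b.n_mismatch = int((span != lab).sum())
        else:
            blocks.append(
                Block(
                    sample=seq.sample,
                    chrom=seq.chrom,
                    first=i0,
                    last=i1,
                    start=int(seq.pos[i0]),
                    end=int(seq.pos[i1]),
                    label=lab,
                    n_markers=i1 - i0 + 1,
                    n_mismatch=0,
                )
            )
    return blocks


def _extension_reach(labels: np.ndarray, target: int) -> tuple[int, np.ndarray]:
    """How far a block may extend over ``labels`` (ordered walking outward).

    Returns ``(j, scores)`` where ``j`` is the number of markers absorbed:
    the furthest *matching* marker at which the cumulative
    match-minus-mismatch score attains its maximum (ties broken outward),
    and ``scores`` the cumulative score after each marker (length
    ``len(labels)+1``, scores[0] = 0).
    """
    steps = np.where(labels == target, 1, -1)
    scores = np.concatenate([[0], np.cumsum(steps)])
    best = scores.max()
    if best <= 0:
        return 0, scores
    match_idx = np.nonzero((labels == target) & (scores[1:] == best))[0]
    return (int(match_idx[-1]) + 1 if len(match_idx) else 0), scores


def extend_blocks(blocks: list[Block], seq: GenotypeSequence) -> list[Block]:
    """Extend every block edge into the flanking unassigned gaps.

    Interior gaps are contested by both neighbours: each extends
    independently, and if their reaches overlap the boundary is placed at
    the split maximizing the summed scores (ties -> the split nearest the
    gap midpoint).  Chromosome-end gaps are one-sided.
    """
    if not blocks:
        return blocks
    lab = seq.labels
    n = len(lab)

    def absorb(block: Block, lo: int, hi: int) -> None:
        # absorb sequence indices [lo, hi] into block
        if hi < lo:
            return
        block.first = min(block.first, lo)
        block.last = max(block.last, hi)
        block.start = int(seq.pos[block.first])
        block.end = int(seq.pos[block.last])
        span = lab[block.first : block.last + 1]
        block.n_markers = len(span)
        block.n_mismatch = int((span != block.label).sum())

    # leading gap
    first = blocks[0]
    gap = lab[:first.first][::-1]  # walk outward = leftward
    j, _ = _extension_reach(gap, first.label)
    if j:
        absorb(first, first.first - j, first.first - 1)
    # trailing gap
    last = blocks[-1]
    gap = lab[last.last + 1 : n]
    j, _ = _extension_reach(gap, last.label)
    if j:
        absorb(last, last.last + 1, last.last + j)
    # interior gaps
    for left, right in zip(blocks, blocks[1:]):
        g0, g1 = left.last + 1, right.first - 1  # inclusive gap index range
        m = g1 - g0 + 1
        if m <= 0:
            continue
        gap = lab[g0 : g1 + 1]
        jl, scores_l = _extension_reach(gap, left.label)
        jr, scores_r = _extension_reach(gap[::-1], right.label)
        if jl + jr > m:
            # contested: split t = markers assigned to the left block
            total = scores_l + scores_r[::-1]
            best = total.max()
            cand = np.nonzero(total == best)[0]
            t = int(cand[np.argmin(np.abs(cand - m / 2.0))])
            jl, jr = t, m - t
        if jl:
            absorb(left, g0, g0 + jl - 1)
        if jr:
            absorb(right, g1 - jr + 1, g1)
    return blocks


def segment(seq: GenotypeSequence, k: int = 25, min_span: int = 10_000) -> list[Block]:
    """Seed, merge and extend: full segmentation of one sequence."""
    return extend_blocks(merge_seeds(find_seeds(seq, k, min_span), seq), seq)


def call_crossovers(blocks: Sequence[Block]) -> list[CrossoverEvent]:
    """One CO per adjacent-block label switch.

    A direct HOM_A <-> HOM_B adjacency needs two crossovers within one
    marker interval (each haplotype switched); it emits two events at the
    same interval and a warning, since such calls deserve review.
    """
    events: list[CrossoverEvent] = []
    n_double = 0
    for a, b in zip(blocks, blocks[1:]):
        left = a.end
        right = b.start
        ev = CrossoverEvent(
            sample=a.sample,
            chrom=a.chrom,
            left=left,
            right=right,
            midpoint=(left + right) // 2,
            from_label=a.label,
            to_label=b.label,
        )
        if {a.label, b.label} == {HOM_A, HOM_B}:
            events.extend([ev, ev])
            n_double += 1
        else:
            events.append(ev)
    if n_double:
        warnings.warn(
            f"{n_double} homozygote-to-homozygote switch(es) counted as double crossovers"
        )
    return events


# ---------------------------------------------------------------------------
# sequences from a marker matrix


def hom_het_sequence(matrix: MarkerMatrix, sample: str, chrom: str) -> GenotypeSequence:
    """Unphased HOM/HET sequence of one sample (MISSING markers dropped)."""
    calls = matrix.sample_calls(sample, chrom)
    keep = calls != GenotypeCall.MISSING
    labels = np.where(calls[keep] == GenotypeCall.HET, HET, HOM).astype(np.int8)
    return GenotypeSequence(sample=sample, chrom=chrom, pos=matrix.pos[chrom][keep], labels=labels)


def select_reference_haplotype(
    matrix: MarkerMatrix, chrom: str, k: int = 25, min_span: int = 10_000
) -> str:
    """Pick the F2 whose whole chromosome is one homozygous block.

    Such a sample carries two copies of a single F1 haplotype and anchors
    the phasing.  Candidacy is judged on the *denoised* HOM/HET block
    segmentation (isolated miscalls are absorbed by seeding and merging);
    among candidates the one with the most informative markers wins.

    Raises
    ------
    ReferenceHaplotypeError
        If no candidate exists; consider the tract-stitching fallback
        (:func:`build_reference_haplotype`) or a different chromosome split.
    """
    best, best_n = None, -1
    for s in matrix.f2_samples:
        seq = hom_het_sequence(matrix, s, chrom)
        if len(seq) == 0:
            continue
        blocks = segment(seq, k, min_span)
        if blocks and all(b.label == HOM for b in blocks):
            if len(seq) > best_n:
                best, best_n = s, len(seq)
    if best is None:
        raise ReferenceHaplotypeError(
            f"no F2 is homozygous along {chrom}; use build_reference_haplotype() "
            "to stitch a reference from homozygous tracts"
        )
    return best


def _hom_allele(calls: np.ndarray) -> np.ndarray:
    """Allele (0=ref, 1=alt) of homozygous calls; -1 where not homozygous."""
    out = np.full(len(calls), -1, dtype=np.int8)
    out[calls == GenotypeCall.HOM_REF] = 0
    out[calls == GenotypeCall.HOM_ALT] = 1
    return out


def reference_alleles_from_sample(matrix: MarkerMatrix, chrom: str, sample: str) -> np.ndarray:
    """Haplotype-1 allele per marker from an all-homozygous reference sample."""
    return _hom_allele(matrix.sample_calls(sample, chrom))


def build_reference_haplotype(
    matrix: MarkerMatrix,
    chrom: str,
    k: int = 25,
    min_span: int = 10_000,
    min_overlap: int = 10,
) -> np.ndarray:
    """Stitch a reference haplotype from homozygous tracts of many F2s.

    Every homozygous block of every F2 is (up to noise) a copy of one of the
    two F1 haplotypes over its span.  Starting from the largest tract, each
    further tract overlapping the current consensus is oriented by majority
    vote over the overlap (same haplotype or the complementary one) and its
    alleles fill uncovered markers.  Passes repeat until no tract can be
    placed.  Returns the haplotype-1 allele per marker (-1 where no tract
    reaches).
    """
    n = len(matrix.pos[chrom])
    tracts: list[np.ndarray] = []
    order: list[int] = []
    for s in matrix.f2_samples:
        seq = hom_het_sequence(matrix, s, chrom)
        if len(seq) == 0:
            continue
        alle = _hom_allele(matrix.sample_calls(s, chrom))
        for b in segment(seq, k, min_span):
            if b.label != HOM:
                continue
            t = np.full(n, -1, dtype=np.int8)
            lo = np.searchsorted(matrix.pos[chrom], seq.pos[b.first])
            hi = np.searchsorted(matrix.pos[chrom], seq.pos[b.last], side="right")
            t[lo:hi] = alle[lo:hi]
            tracts.append(t)
            order.append(int((t >= 0).sum()))
    if not tracts:
        raise ReferenceHaplotypeError(f"no homozygous tracts found on {chrom}")
    idx = np.argsort(order)[::-1]
    ref = np.full(n, -1, dtype=np.int8)
    ref[:] = tracts[idx[0]]
    placed = {int(idx[0])}
    progress = True
    while progress:
        progress = False
        for i in idx:
            i = int(i)
            if i in placed:
                continue
            t = tracts[i]
            both = (ref >= 0) & (t >= 0)
            if both.sum() < min_overlap:
                continue
            agree = int((ref[both] == t[both]).sum())
            oriented = t if agree * 2 >= both.sum() else np.where(t >= 0, 1 - t, -1).astype(np.int8)
            fill = (ref < 0) & (oriented >= 0)
            if fill.any():
                ref[fill] = oriented[fill]
                progress = True
            placed.add(i)
    covered = float((ref >= 0).mean())
    logger.info("stitched reference haplotype on %s covers %.1f%% of markers", chrom, covered * 100)
    return ref


def phase_intraspecific(
    matrix: MarkerMatrix, chrom: str, ref_alleles: np.ndarray
) -> dict[str, GenotypeSequence]:
    """Relabel each F2's homozygous calls against the reference haplotype.

    A HOM call matching the reference allele becomes HOM_A (haplotype 1),
    otherwise HOM_B; HET calls are kept.  Markers where the reference is
    uninformative leave the homozygous call unphasable: it is dropped from
    the phased sequence and counted in ``n_unphased``.
    """
    out = {}
    pos = matrix.pos[chrom]
    for s in matrix.f2_samples:
        calls = matrix.sample_calls(s, chrom)
        alle = _hom_allele(calls)
        labels = np.full(len(calls), -9, dtype=np.int8)
        labels[calls == GenotypeCall.HET] = HET
        hom = alle >= 0
        phased = hom & (ref_alleles >= 0)
        labels[phased & (alle == ref_alleles)] = HOM_A
        labels[phased & (alle != ref_alleles)] = HOM_B
        unphased = hom & (ref_alleles < 0)
        keep = labels != -9
        keep &= ~unphased
        out[s] = GenotypeSequence(
            sample=s,
            chrom=chrom,
            pos=pos[keep],
            labels=labels[keep],
            n_unphased=int(unphased.sum()),
        )
    return out


def genotype_interspecific(
    matrix: MarkerMatrix,
    chrom: str,
    parent_a_calls: np.ndarray,
    parent_b_calls: np.ndarray,
) -> tuple[dict[str, GenotypeSequence], int]:
    """Label F2 homozygous calls against the two parental genotype columns.

    Markers where the parents are not reciprocally informative (either
    parent heterozygous or missing, or both fixed for the same allele) are
    dropped; the count of dropped markers is returned alongside.
    """
    a = _hom_allele(np.asarray(parent_a_calls))
    b = _hom_allele(np.asarray(parent_b_calls))
    informative = (a >= 0) & (b >= 0) & (a != b)
    n_dropped = int((~informative).sum())
    pos = matrix.pos[chrom][informative]
    out = {}
    for s in matrix.f2_samples:
        calls = matrix.sample_calls(s, chrom)[informative]
        alle = _hom_allele(calls)
        labels = np.full(len(calls), -9, dtype=np.int8)
        labels[calls == GenotypeCall.HET] = HET
        labels[(alle >= 0) & (alle == a[informative])] = HOM_A
        labels[(alle >= 0) & (alle != a[informative])] = HOM_B
        keep = labels != -9
        out[s] = GenotypeSequence(sample=s, chrom=chrom, pos=pos[keep], labels=labels[keep])
    return out, n_dropped


# ---------------------------------------------------------------------------
# population-level calling


def _events_frame(events: Iterable[CrossoverEvent]) -> pd.DataFrame:
    rows = [
        {
            "sample": e.sample,
            "chrom": e.chrom,
            "left": e.left,
            "right": e.right,
            "midpoint": e.midpoint,
            "from_label": LABEL_NAMES[e.from_label],
            "to_label": LABEL_NAMES[e.to_label],
            "resolution": e.resolution,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "left", "right", "midpoint",
            "from_label", "to_label", "resolution",
        ],
    )


def _blocks_frame(blocks: Iterable[Block]) -> pd.DataFrame:
    rows = [
        {
            "sample": b.sample,
            "chrom": b.chrom,
            "start": b.start,
            "end": b.end,
            "label": LABEL_NAMES[b.label],
            "n_markers": b.n_markers,
            "n_mismatch": b.n_mismatch,
        }
        for b in blocks
    ]
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "label", "n_markers", "n_mismatch"]
    )


def call_intraspecific(
    matrix: MarkerMatrix,
    k: int = 25,
    min_span: int = 10_000,
    phase_strategy: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Phase and call crossovers for every F2 of an intraspecific cross.

    ``phase_strategy``: "sample" requires an all-homozygous reference sample
    per chromosome (error otherwise), "stitch" always builds the tract
    consensus, "auto" (default) tries the single sample first and falls back
    to stitching.

    Returns (events, blocks, info) where info records the phasing route and
    unphased-marker counts per chromosome.
    """
    all_events: list[CrossoverEvent] = []
    all_blocks: list[Block] = []
    info: dict[str, dict] = {}
    for chrom in matrix.chroms:
        route = phase_strategy
        ref = None
        if phase_strategy in ("sample", "auto"):
            try:
                ref_sample = select_reference_haplotype(matrix, chrom, k, min_span)
                ref = reference_alleles_from_sample(matrix, chrom, ref_sample)
                route = f"sample:{ref_sample}"
            except ReferenceHaplotypeError:
                if phase_strategy == "sample":
                    raise
                route = "stitch"
        if ref is None:
            ref = build_reference_haplotype(matrix, chrom, k, min_span)
        seqs = phase_intraspecific(matrix, chrom, ref)
        n_unphased = sum(s.n_unphased for s in seqs.values())
        for s, seq in seqs.items():
            blocks = segment(seq, k, min_span)
            all_blocks.extend(blocks)
            all_events.extend(call_crossovers(blocks))
        info[chrom] = {"phase_route": route, "n_unphased_markers": n_unphased}
    return _events_frame(all_events), _blocks_frame(all_blocks), info


def call_interspecific(
    matrix: MarkerMatrix,
    parent_a: dict[str, np.ndarray],
    parent_b: dict[str, np.ndarray],
    k: int = 25,
    min_span: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Call crossovers for every F2 of an interspecific cross.

    ``parent_a`` / ``parent_b`` map chromosome -> per-marker GenotypeCall
    codes of the two parents, aligned with ``matrix.pos``.
    """
    all_events: list[CrossoverEvent] = []
    all_blocks: list[Block] = []
    info: dict[str, dict] = {}
    for chrom in matrix.chroms:
        seqs, n_dropped = genotype_interspecific(matrix, chrom, parent_a[chrom], parent_b[chrom])
        for s, seq in seqs.items():
            blocks = segment(seq, k, min_span)
            all_blocks.extend(blocks)
            all_events.extend(call_crossovers(blocks))
        info[chrom] = {"n_parent_uninformative": n_dropped}
    return _events_frame(all_events), _blocks_frame(all_blocks), info
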