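"""Confident-marker identification from raw multi-sample variant records.

Raw caller output is turned into the marker set used for crossover
detection: bi-allelic, well-supported sites at which the F1 parent is
confidently heterozygous.  Genotypes are assigned from the allele balance
of the genotyped reads — a reference-allele ratio of 95-100% (0-5%) is a
confident homozygote and 30-70% a confident heterozygote; anything in the
ambiguous bands, at out-of-range depth, or without genotyped reads is
MISSING.  Sites also need quality >= 50 and informative calls in strictly
more than half of the samples.

Markers inside large structural-variant (SV) regions of the F1 are removed,
because collapsed paralogous or rearranged sequence produces
pseudo-heterozygous calls there: SV intervals under 100 kbp are masked
whole (inversions with 200 bp flanks), larger ones contribute only 400 bp
flanks around each breakpoint.  A diagnostic flags residual artifactual
marker clusters by the standard error of adjacent-marker distances.

Internal coordinates are 0-based half-open; VCF I/O is 1-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import VariantTable

logger = logging.getLogger(__name__)


class GenotypeCall(IntEnum):
    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


SV_TYPES = frozenset({"DEL", "DUP", "INV", "TRA"})


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the confident-marker filter.

    Defaults are the study values: quality >= 50, per-sample depth in
    [10, 80], reference-ratio bands 0-5% / 95-100% (homozygous) and 30-70%
    (heterozygous), and strictly more than half of samples informative.
    ``depth_mode`` chooses whether the depth bounds apply per sample
    (default; an out-of-range sample is MISSING at that site) or to the
    site-mean depth.
    """

    qual_min: float = 50.0
    depth_min: int = 10
    depth_max: int = 80
    hom_ref_min: float = 0.95
    hom_alt_max: float = 0.05
    het_min: float = 0.30
    het_max: float = 0.70
    min_informative_frac: float = 0.5  # strict: count > frac * n_samples
    depth_mode: str = "per_sample"  # or "site_mean"

    def __post_init__(self):
        if self.depth_mode not in ("per_sample", "site_mean"):
            raise ValueError(f"unknown depth_mode {self.depth_mode!r}")


DEFAULT_PARAMS = FilterParams()

_EPS = 1e-9  # float guard so exact decimal boundaries land inside their band


def classify_counts(
    ad_ref: np.ndarray,
    ad_alt: np.ndarray,
    depth: np.ndarray,
    params: FilterParams = DEFAULT_PARAMS,
    check_depth: bool = True,
) -> np.ndarray:
    """Vectorized allele-balance genotype classification.

    The reference ratio is computed from the allele-depth sum (genotyped
    reads); ``depth`` enters only through the depth bounds.  Returns an
    int8 array of :class:`GenotypeCall` values.
    """
    ad_ref = np.asarray(ad_ref)
    ad_alt = np.asarray(ad_alt)
    tot = ad_ref + ad_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(tot > 0, ad_ref / np.maximum(tot, 1), np.nan)
    out = np.full(np.shape(tot), GenotypeCall.MISSING, dtype=np.int8)
    het = (r >= params.het_min - _EPS) & (r <= params.het_max + _EPS)
    out[het] = GenotypeCall.HET
    out[r >= params.hom_ref_min - _EPS] = GenotypeCall.HOM_REF
    out[r <= params.hom_alt_max + _EPS] = GenotypeCall.HOM_ALT
    bad = tot == 0
    if check_depth:
        depth = np.asarray(depth)
        bad = bad | (depth < params.depth_min) | (depth > params.depth_max)
    out[bad] = GenotypeCall.MISSING
    return out


def classify_genotype(
    ad_ref: int, ad_alt: int, depth: int, params: FilterParams = DEFAULT_PARAMS
) -> GenotypeCall:
    """Classify a single call from its allele depths and depth (total function)."""
    if ad_ref < 0 or ad_alt < 0 or depth < 0:
        raise ValueError("allele depths and depth must be non-negative")
    code = classify_counts(
        np.array([ad_ref]), np.array([ad_alt]), np.array([depth]), params
    )[0]
    return GenotypeCall(int(code))


@dataclass
class MarkerMatrix:
    """Samples x ordered markers with genotype calls; the F1 column is marked.

    ``calls[chrom]`` is an int8 (n_markers, n_samples) array of
    :class:`GenotypeCall` codes; after filtering the F1 column is HET at
    every retained marker.
    """

    samples: list[str]
    f1: str
    pos: dict[str, np.ndarray]
    calls: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.pos)

    @property
    def f2_samples(self) -> list[str]:
        return [s for s in self.samples if s != self.f1]

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.pos.values()))

    def sample_calls(self, sample: str, chrom: str) -> np.ndarray:
        return self.calls[chrom][:, self.sample_index(sample)]

    def to_tsv(self, path) -> None:
        frames = []
        for c in self.chroms:
            df = pd.DataFrame(self.calls[c], columns=self.samples)
            df.insert(0, "pos", self.pos[c])
            df.insert(0, "chrom", c)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        with open(path, "w") as fh:
            fh.write(f"#f1={self.f1}\n")
            if self.chrom_lengths:
                lens = ",".join(f"{c}:{l}" for c, l in self.chrom_lengths.items())
                fh.write(f"#chrom_lengths={lens}\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerMatrix":
        f1 = None
        lengths: dict[str, int] = {}
        with open(path) as fh:
            offset = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                if key == "f1":
                    f1 = val
                elif key == "chrom_lengths":
                    for item in val.split(","):
                        c, _, l = item.partition(":")
                        lengths[c] = int(l)
                offset += 1
        df = pd.read_csv(path, sep="\t", skiprows=offset)
        samples = [c for c in df.columns if c not in ("chrom", "pos")]
        if f1 is None:
            raise ValueError(f"{path}: missing '#f1=' header line")
        pos = {}
        calls = {}
        for c, sub in df.groupby("chrom", sort=False):
            pos[c] = sub["pos"].to_numpy(dtype=np.int64)
            calls[c] = sub[samples].to_numpy(dtype=np.int8)
        return cls(samples=samples, f1=f1, pos=pos, calls=calls, chrom_lengths=lengths)


def filter_variants(
    table: VariantTable, params: FilterParams = DEFAULT_PARAMS
) -> MarkerMatrix:
    """Reduce raw variant records to the confident heterozygous-F1 marker set.

    Keeps bi-allelic records with quality >= ``qual_min`` whose per-sample
    genotype calls leave strictly more than half of the samples informative
    and whose F1 call is HET.  Input must be position-sorted and duplicate
    free per chromosome.
    """
    f1_idx = table.samples.index(table.f1)
    n_samples = len(table.samples)
    pos_out, calls_out = {}, {}
    for chrom in table.chroms:
        pos = table.pos[chrom]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"records on {chrom} are not position-sorted")
        if np.any(np.diff(pos) == 0):
            raise ValueError(f"duplicate positions on {chrom}")
        dp = table.dp[chrom]
        if params.depth_mode == "site_mean":
            site_dp = dp.mean(axis=1, keepdims=True)
            dp_for_bounds = np.broadcast_to(site_dp, dp.shape)
        else:
            dp_for_bounds = dp
        calls = classify_counts(
            table.ad_ref[chrom], table.ad_alt[chrom], dp_for_bounds, params
        )
        informative = (calls != GenotypeCall.MISSING).sum(axis=1)
        keep = (
            table.biallelic[chrom]
            & (table.qual[chrom] >= params.qual_min)
            & (informative > params.min_informative_frac * n_samples)
            & (calls[:, f1_idx] == GenotypeCall.HET)
        )
        pos_out[chrom] = pos[keep]
        calls_out[chrom] = calls[keep]
        logger.info("%s: %d of %d records retained as markers", chrom, keep.sum(), len(pos))
    return MarkerMatrix(
        samples=list(table.samples),
        f1=table.f1,
        pos=pos_out,
        calls=calls_out,
        chrom_lengths=dict(table.chrom_lengths),
    )


# ---------------------------------------------------------------------------
# SV masking


@dataclass
class MaskSet:
    """Per-chromosome sorted, merged, half-open masked intervals (0-based)."""

    intervals: dict[str, np.ndarray]  # (n, 2) int arrays

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        idx_clip = np.clip(idx, 0, len(iv) - 1)
        return (idx >= 0) & (positions < iv[idx_clip, 1])

    def total_masked(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def to_bed(self, path) -> None:
        rows = [(c, int(s), int(e)) for c, iv in self.intervals.items() for s, e in iv]
        pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
            path, sep="\t", index=False, header=False
        )


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def build_sv_mask(
    sv: pd.DataFrame,
    chrom_lengths: Mapping[str, int] | None = None,
    large_sv_bp: int = 100_000,
    inv_flank: int = 200,
    breakpoint_flank: int = 400,
) -> MaskSet:
    """Build the marker mask from a union of SV calls.

    ``sv`` needs columns ``chrom, start, end, type`` (type in DEL/DUP/INV/TRA;
    a ``caller`` column may be present and is ignored — the union of all
    callers is used without further filtering).  Intervals shorter than
    ``large_sv_bp`` are masked whole, inversions with ``inv_flank`` bp added
    beyond both ends; larger intervals contribute only ``breakpoint_flank``
    bp around each breakpoint.  Out-of-chromosome spans are clipped with a
    warning when lengths are supplied.
    """
    required = {"chrom", "start", "end", "type"}
    missing = required - set(sv.columns)
    if missing:
        raise ValueError(f"SV table missing columns: {sorted(missing)}")
    bad = set(sv["type"].str.upper()) - SV_TYPES
    if bad:
        raise ValueError(f"unknown SV type tag(s): {sorted(bad)}")

    pieces: dict[str, list[tuple[int, int]]] = {}
    for row in sv.itertuples(index=False):
        c = row.chrom
        start, end = int(row.start), int(row.end)
        t = row.type.upper()
        span = end - start
        if span < large_sv_bp:
            lo, hi = start, end
            if t == "INV":
                lo, hi = lo - inv_flank, hi + inv_flank
            pieces.setdefault(c, []).append((lo, hi))
        else:
            for bp in (start, end):
                pieces.setdefault(c, []).append(
                    (bp - breakpoint_flank, bp + breakpoint_flank)
                )
    intervals = {}
    for c, ivs in pieces.items():
        arr = np.asarray(ivs, dtype=np.int64)
        lo_clip = 0
        hi_clip = None
        if chrom_lengths is not None and c in chrom_lengths:
            hi_clip = chrom_lengths[c]
        if (arr[:, 0] < lo_clip).any() or (hi_clip is not None and (arr[:, 1] > hi_clip).any()):
            warnings.warn(f"SV intervals on {c} extend outside the chromosome; clipped")
        arr[:, 0] = np.maximum(arr[:, 0], lo_clip)
        if hi_clip is not None:
            arr[:, 1] = np.minimum(arr[:, 1], hi_clip)
        arr = arr[arr[:, 1] > arr[:, 0]]
        intervals[c] = _merge_intervals(arr)
    return MaskSet(intervals=intervals)


def read_sv_table(path) -> pd.DataFrame:
    """Read SV intervals from a TSV/BED-like file: chrom start end type [caller]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "type", "caller"][: df.shape[1]]
    df.columns = cols
    return df


def apply_mask(matrix: MarkerMatrix, mask: MaskSet) -> MarkerMatrix:
    """Drop markers whose (1-based) position falls inside a masked interval."""
    pos_out, calls_out = {}, {}
    removed = 0
    for c in matrix.chroms:
        inside = mask.contains(c, matrix.pos[c] - 1)  # mask is 0-based half-open
        keep = ~inside
        removed += int(inside.sum())
        pos_out[c] = matrix.pos[c][keep]
        calls_out[c] = matrix.calls[c][keep]
    logger.info("SV mask removed %d markers", removed)
    return replace(matrix, pos=pos_out, calls=calls_out)


def flag_marker_clusters(
    matrix: MarkerMatrix, window_k: int = 25, se_threshold: float = 100.0
) -> pd.DataFrame:
    """Flag artifactual marker clusters by the SE of adjacent-marker distances.

    Slides a ``window_k``-marker window along each chromosome and computes
    the standard error of its inter-marker gaps, ``sd(gaps)/sqrt(n_gaps)``;
    windows with SE strictly greater than ``se_threshold`` bp are flagged.
    Flags are advisory — the markers are reported, not removed.
    """
    rows = []
    for c in matrix.chroms:
        pos = matrix.pos[c]
        if len(pos) < window_k:
            continue
        gaps = np.diff(pos).astype(float)
        n_gaps = window_k - 1
        win = np.lib.stride_tricks.sliding_window_view(gaps, n_gaps)
        sd = win.std(axis=1, ddof=1)
        se = sd / np.sqrt(n_gaps)
        for i in np.nonzero(se > se_threshold)[0]:
            rows.append(
                {
                    "chrom": c,
                    "first_idx": int(i),
                    "last_idx": int(i + window_k - 1),
                    "start": int(pos[i]),
                    "end": int(pos[i + window_k - 1]),
                    "se": float(se[i]),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "first_idx", "last_idx", "start", "end", "se"])


# ---------------------------------------------------------------------------
# VCF input


def read_vcf(path, f1: str) -> VariantTable:
    """Read a multi-sample VCF into a :class:`VariantTable` via cyvcf2.

    Keeps every record (the bi-allelic requirement is enforced later by
    :func:`filter_variants` through the ``biallelic`` flag).  DP is taken
    from the FORMAT/DP field when present, else from the AD sum.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if f1 not in samples:
        raise ValueError(f"F1 sample {f1!r} not found in VCF (samples: {samples})")
    chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}

    data: dict[str, dict[str, list]] = {}
    for v in vcf:
        d = data.setdefault(
            v.CHROM, {"pos": [], "qual": [], "dp": [], "adr": [], "ada": [], "bi": []}
        )
        ad = v.format("AD")
        if ad is None:
            adr = np.zeros(len(samples), dtype=np.int32)
            ada = np.zeros(len(samples), dtype=np.int32)
        else:
            ad = np.where(ad < 0, 0, ad)
            adr = ad[:, 0].astype(np.int32)
            ada = ad[:, 1].astype(np.int32) if ad.shape[1] > 1 else np.zeros_like(adr)
        dp = v.format("DP")
        dp = (adr + ada) if dp is None else np.where(dp < 0, 0, dp).reshape(-1).astype(np.int32)
        d["pos"].append(v.POS)
        d["qual"].append(v.QUAL if v.QUAL is not None else 0.0)
        d["dp"].append(dp)
        d["adr"].append(adr)
        d["ada"].append(ada)
        d["bi"].append(len(v.ALT) == 1)
    table = VariantTable(
        samples=samples,
        f1=f1,
        pos={c: np.asarray(d["pos"], dtype=np.int64) for c, d in data.items()},
        qual={c: np.asarray(d["qual"], dtype=float) for c, d in data.items()},
        dp={c: np.vstack(d["dp"]) for c, d in data.items()},
        ad_ref={c: np.vstack(d["adr"]) for c, d in data.items()},
        ad_alt={c: np.vstack(d["ada"]) for c, d in data.items()},
        biallelic={c: np.asarray(d["bi"], dtype=bool) for c, d in data.items()},
        chrom_lengths=chrom_lengths,
    )
    return table
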