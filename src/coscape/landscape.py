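"""Recombination-landscape statistics: rates, hotspots/coldspots, comparisons.

Crossover midpoints are counted in non-overlapping 500 kbp windows; runs of
adjacent windows with similar counts are merged into candidate regions, and
each region's count is compared with a Monte-Carlo null obtained by
re-placing all events uniformly over the genome (10,000 shuffles by
default).  Regions with p < 0.05 are hotspots (excess) or coldspots
(deficit); no multiplicity correction is applied.

Rates use the F2 map-length conversion: an F2 genome carries two gametes,
so the genetic length in cM is ``mean_co_per_F2 * 50`` and the rate is
``mean_co * 50 / length_Mbp`` cM/Mbp.

Rank correlations use an exact permutation test for n <= 9 (all n!
orderings) and the t-approximation above, which reproduces printed exact
p-values on eight-chromosome summaries.  Group rate comparisons use the
Brunner-Munzel test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

WINDOW_SIZE_DEFAULT = 500_000
N_RAND_DEFAULT = 10_000
ALPHA_DEFAULT = 0.05


def co_rate(mean_co_per_f2: float, length_mbp: float) -> float:
    """Recombination rate in cM/Mbp from the mean CO count per F2.

    Each F2 is the fusion of two gametes, i.e. two meioses: the expected CO
    count per gamete is ``mean_co / 2``, the map length in cM is
    ``mean_co / 2 * 100``, hence ``mean_co * 50 / length_Mbp``.
    """
    if length_mbp <= 0:
        raise ValueError("length_mbp must be > 0")
    return mean_co_per_f2 * 50.0 / length_mbp


def bin_positions(
    df: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    size: int = WINDOW_SIZE_DEFAULT,
    pos_col: str = "midpoint",
    strict_bounds: bool = True,
) -> pd.DataFrame:
    """Count positions per half-open window [i*size, (i+1)*size) per chromosome.

    Every chromosome gets a full (possibly truncated) tiling even where no
    positions fall.  With ``strict_bounds`` a position beyond the chromosome
    length is an error (corrupt input).
    """
    if size <= 0:
        raise ValueError("window size must be > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = int(np.ceil(length / size))
        counts = np.zeros(n_win, dtype=np.int64)
        if len(df):
            sub = df[df["chrom"] == chrom]
            if len(sub):
                p = sub[pos_col].to_numpy()
                if strict_bounds and (p.max() > length or p.min() < 0):
                    raise ValueError(
                        f"position outside chromosome {chrom} (length {length})"
                    )
                idx = np.minimum(p // size, n_win - 1).astype(int)
                counts += np.bincount(idx, minlength=n_win)
        starts = np.arange(n_win, dtype=np.int64) * size
        ends = np.minimum(starts + size, length)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "idx": np.arange(n_win), "start": starts,
                 "end": ends, "count": counts}
            )
        )
    return pd.concat(rows, ignore_index=True)


def window_counts(
    events: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    size: int = WINDOW_SIZE_DEFAULT,
) -> pd.DataFrame:
    """CO-midpoint counts per non-overlapping window (conserves the total)."""
    return bin_positions(events, chrom_lengths, size, pos_col="midpoint")


def merge_similar(windows: pd.DataFrame, tol: int = 0) -> pd.DataFrame:
    """Merge maximal runs of adjacent same-chromosome windows with similar counts.

    Windows join a run while the run's count spread (max - min) stays
    within ``tol``; ``tol=0`` (default) merges identical counts only.  The
    merged region's observed count is the sum over its windows.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    regions = []
    region_id = np.empty(len(windows), dtype=np.int64)
    rid = -1
    for chrom, sub in windows.groupby("chrom", sort=False):
        counts = sub["count"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ilocs = sub.index.to_numpy()
        run_start = 0
        lo = hi = counts[0] if len(counts) else 0
        for i in range(1, len(counts) + 1):
            closes = i == len(counts)
            if not closes:
                nlo, nhi = min(lo, counts[i]), max(hi, counts[i])
                if nhi - nlo <= tol:
                    lo, hi = nlo, nhi
                    continue
            rid += 1
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(starts[run_start]),
                    "end": int(ends[i - 1]),
                    "first_idx": int(sub["idx"].iloc[run_start]),
                    "last_idx": int(sub["idx"].iloc[i - 1]),
                    "n_windows": i - run_start,
                    "observed": int(counts[run_start:i].sum()),
                }
            )
            region_id[ilocs[run_start:i] - windows.index[0]] = rid
            if not closes:
                run_start = i
                lo = hi = counts[i]
    out = pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "first_idx", "last_idx", "n_windows", "observed"],
    )
    out.attrs["window_region_id"] = region_id
    return out


def randomization_test(
    regions: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    n_events: int,
    n_rand: int = N_RAND_DEFAULT,
    seed: int = 0,
    alpha: float = ALPHA_DEFAULT,
    mask=None,
) -> pd.DataFrame:
    """Monte-Carlo hotspot/coldspot test on merged regions.

    Each of ``n_rand`` shuffles re-places all ``n_events`` midpoints
    uniformly over the (unmasked) genome and counts them per region.
    Per region, ``p_hot = (1 + #{shuffle count >= observed}) / (1 + n_rand)``
    and ``p_cold`` analogously with <=; the plus-one keeps finite shuffles
    from reporting p = 0.  A region is a hotspot (coldspot) when its p is
    below ``alpha``; no multiple-testing correction.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)

    # sampling segments: unmasked spans of each chromosome
    segments = []  # (chrom, start, end)
    for chrom, length in chrom_lengths.items():
        cur = 0
        if mask is not None and chrom in getattr(mask, "intervals", {}):
            for s, e in mask.intervals[chrom]:
                if s > cur:
                    segments.append((chrom, cur, min(s, length)))
                cur = max(cur, e)
        if cur < length:
            segments.append((chrom, cur, length))
    seg_len = np.array([e - s for _, s, e in segments], dtype=np.int64)
    if seg_len.sum() <= 0:
        raise ValueError("masked genome is empty")
    seg_cum = np.concatenate([[0], np.cumsum(seg_len)])

    # position -> region lookup per chromosome (regions tile the windows)
    region_lookup: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_regions = len(regions)
    for chrom, sub in regions.groupby("chrom", sort=False):
        region_lookup[chrom] = (sub["start"].to_numpy(), sub.index.to_numpy())

    u = rng.integers(0, seg_cum[-1], size=(n_rand, n_events))
    seg_idx = np.searchsorted(seg_cum, u, side="right") - 1
    offset = u - seg_cum[seg_idx]
    rid = np.full(u.shape, -1, dtype=np.int64)
    for k, (chrom, s, _) in enumerate(segments):
        sel = seg_idx == k
        if not sel.any() or chrom not in region_lookup:
            continue
        starts, ids = region_lookup[chrom]
        pos = offset[sel] + s
        j = np.searchsorted(starts, pos, side="right") - 1
        j = np.clip(j, 0, len(ids) - 1)
        rid[sel] = ids[j]
    valid = rid >= 0
    flat = (np.broadcast_to(np.arange(n_rand)[:, None], rid.shape)[valid] * n_regions
            + rid[valid])
    counts = np.bincount(flat, minlength=n_rand * n_regions).reshape(n_rand, n_regions)

    obs = regions["observed"].to_numpy()
    ge = (counts >= obs[None, :]).sum(axis=0)
    le = (counts <= obs[None, :]).sum(axis=0)
    p_hot = (1.0 + ge) / (1.0 + n_rand)
    p_cold = (1.0 + le) / (1.0 + n_rand)
    klass = np.where(p_hot < alpha, "hotspot", np.where(p_cold < alpha, "coldspot", "neutral"))
    out = regions.copy()
    out["p_hot"] = p_hot
    out["p_cold"] = p_cold
    out["class"] = klass
    return out


def region_rates(
    regions: pd.DataFrame, n_f2: int, alpha: float = ALPHA_DEFAULT
) -> tuple[pd.DataFrame, dict]:
    """Per-region CO rates and the hotspot/coldspot summary.

    Each region's rate is ``co_rate(observed / n_f2, span_Mbp)``.  The
    summary reports the mean hotspot and coldspot rates, their fold ratio
    and a Welch two-sample t-test across regions; with no hotspots or no
    coldspots those fields are None and a notice is set.
    """
    out = regions.copy()
    span_mbp = (out["end"] - out["start"]) / 1e6
    out["rate_cm_per_mbp"] = [
        co_rate(o / n_f2, s) for o, s in zip(out["observed"], span_mbp)
    ]
    hot = out.loc[out["class"] == "hotspot", "rate_cm_per_mbp"].to_numpy()
    cold = out.loc[out["class"] == "coldspot", "rate_cm_per_mbp"].to_numpy()
    summary: dict = {"n_hotspots": len(hot), "n_coldspots": len(cold)}
    if len(hot) == 0 or len(cold) == 0:
        summary.update(
            {"mean_hotspot_rate": None, "mean_coldspot_rate": None, "fold_ratio": None,
             "t_pvalue": None, "notice": "need at least one hotspot and one coldspot"}
        )
        return out, summary
    mh, mc = float(hot.mean()), float(cold.mean())
    if np.ptp(hot) == 0 and np.ptp(cold) == 0 and mh == mc:
        t_p = 1.0  # identical constant rates: no evidence of difference
    else:
        t_p = float(stats.ttest_ind(hot, cold, equal_var=False).pvalue)
    summary.update(
        {
            "mean_hotspot_rate": mh,
            "mean_coldspot_rate": mc,
            "fold_ratio": mh / mc if mc > 0 else float("inf"),
            "t_pvalue": t_p,
        }
    )
    return out, summary


# ---------------------------------------------------------------------------
# correlations and group comparison


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    method: str  # "exact" or "t-approx"
    flagged: bool = False  # constant input -> undefined rho


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    return float((rx * ry).sum() / denom)


def spearman(x: Sequence[float], y: Sequence[float], exact_max_n: int = 9) -> SpearmanResult:
    """Average-rank Spearman correlation, two-sided.

    For n <= ``exact_max_n`` the p-value enumerates all n! rank orderings
    (exact permutation test); above that the usual t-approximation is used.
    A constant vector leaves rho undefined and flags the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), n, "undefined", flagged=True)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= exact_max_n:
        count = 0
        total = 0
        a = np.asarray(ry)
        for perm in itertools.permutations(range(n)):
            r = _rank_corr(rx, a[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return SpearmanResult(rho, count / total, n, "exact")
    p = float(stats.spearmanr(x, y).pvalue)
    return SpearmanResult(rho, p, n, "t-approx")


@dataclass(frozen=True)
class BrunnerMunzelResult:
    statistic: float
    pvalue: float
    relative_effect: float  # P(a < b) + 0.5 P(a = b)
    flagged: bool = False


def compare_groups(a: Sequence[float], b: Sequence[float]) -> BrunnerMunzelResult:
    """Brunner-Munzel stochastic-equality test between two per-sample rate groups.

    Two-sided with the t-approximation.  The relative effect estimates
    P(a < b) + 0.5 P(a = b); 0.5 means stochastic equality.  Degenerate
    variance (e.g. identical constant groups) flags the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    ranks = stats.rankdata(np.concatenate([a, b]))
    rb = ranks[len(a):].mean()
    p_hat = float((rb - (len(b) + 1) / 2.0) / len(a))
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        pvalue = 1.0 if a[0] == b[0] else 0.0
        return BrunnerMunzelResult(float("nan"), pvalue, p_hat, flagged=True)
    if p_hat in (0.0, 1.0):
        # complete separation: the BM variance estimate degenerates
        return BrunnerMunzelResult(float("inf"), 0.0, p_hat, flagged=True)
    res = stats.brunnermunzel(a, b)
    stat, pvalue = float(res.statistic), float(res.pvalue)
    flagged = not np.isfinite(stat)
    return BrunnerMunzelResult(stat, pvalue, p_hat, flagged=flagged)


def telomere_centromere_filter(
    windows: pd.DataFrame,
    pericentromere: pd.DataFrame | None = None,
    drop_telomeres: bool = True,
) -> pd.DataFrame:
    """Drop first/last windows per chromosome and/or peri-centromeric windows.

    ``pericentromere`` is a BED-like frame (chrom, start, end); a window
    overlapping any interval by at least one bp is dropped.  The operation
    is idempotent.
    """
    keep = np.ones(len(windows), dtype=bool)
    if drop_telomeres:
        for chrom, sub in windows.groupby("chrom", sort=False):
            imin, imax = sub["idx"].min(), sub["idx"].max()
            keep[windows.index.isin(sub.index[(sub["idx"] == imin) | (sub["idx"] == imax)])] = False
    if pericentromere is not None and len(pericentromere):
        for row in pericentromere.itertuples(index=False):
            hit = (
                (windows["chrom"] == row.chrom)
                & (windows["start"] < row.end)
                & (windows["end"] > row.start)
            )
            keep &= ~hit.to_numpy()
    return windows[keep].copy()


def chromosome_stats(
    events: pd.DataFrame, chrom_lengths: Mapping[str, int], n_f2: int
) -> pd.DataFrame:
    """Per-chromosome mean CO count per F2 and rate, plus a genome-wide row."""
    rows = []
    for chrom, length in chrom_lengths.items():
        n = int((events["chrom"] == chrom).sum())
        mean = n / n_f2
        rows.append(
            {
                "chrom": chrom,
                "mean_co": mean,
                "length_mbp": length / 1e6,
                "rate_cm_per_mbp": co_rate(mean, length / 1e6),
            }
        )
    total_mbp = sum(chrom_lengths.values()) / 1e6
    mean_all = len(events) / n_f2
    rows.append(
        {
            "chrom": "All",
            "mean_co": mean_all,
            "length_mbp": total_mbp,
            "rate_cm_per_mbp": co_rate(mean_all, total_mbp),
        }
    )
    return pd.DataFrame(rows)


def read_chrom_lengths(path) -> dict[str, int]:
    """Read a chromosome-length table (.fai-style: name, length, ...)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return dict(zip(df[0].astype(str), df[1].astype(int)))
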