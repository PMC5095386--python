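"""De novo mutation vs crossover coupling tests.

If recombination were mutagenic, new mutations should cluster near
crossover (CO) breakpoints.  Two complementary analyses are provided:

* distance-to-nearest-CO per mutation, with counts within fixed radii
  (2 kbp — the scale at which prior work reported an excess — plus 10 kbp
  and 100 kbp), and a permutation test re-placing mutations uniformly along
  their chromosome;
* a binned rate correlation: CO and mutation counts per genomic bin at
  several bin sizes, peri-centromeric bins discarded, Spearman correlation.

Distances are measured to CO midpoints (the convention used for the
landscape windows); ``mode="same_sample"`` restricts to the mutation
carrier's own events (mutagenic recombination acts within one genome),
``mode="pooled"`` uses all events.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import landscape

logger = logging.getLogger(__name__)

DEFAULT_RADII = (2_000, 10_000, 100_000)
DEFAULT_BIN_SIZES = (500_000, 1_000_000, 2_000_000, 5_000_000)


def _nearest(positions: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Distance from each position to its nearest target (inf if none)."""
    if len(targets) == 0:
        return np.full(len(positions), np.inf)
    t = np.sort(np.asarray(targets, dtype=np.int64))
    idx = np.searchsorted(t, positions)
    left = np.where(idx > 0, np.abs(positions - t[np.maximum(idx - 1, 0)]), np.inf)
    right = np.where(idx < len(t), np.abs(t[np.minimum(idx, len(t) - 1)] - positions), np.inf)
    return np.minimum(left, right).astype(float)


def nearest_co_distance(
    mutations: pd.DataFrame,
    events: pd.DataFrame,
    mode: str = "same_sample",
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-mutation distance to the nearest CO midpoint on its chromosome.

    ``mode="same_sample"`` searches only the carrier's own events (an error
    if a mutation's sample is outside ``samples`` when that list is given);
    ``mode="pooled"`` searches all events.  Mutations on chromosomes
    without any eligible event get infinite distance.
    """
    if mode not in ("same_sample", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "same_sample" and samples is not None:
        unknown = set(mutations["sample"]) - set(samples)
        if unknown:
            raise ValueError(f"unknown sample(s) in mutation table: {sorted(unknown)}")
    out = mutations.copy()
    dist = np.full(len(out), np.inf)
    if mode == "same_sample":
        keys = ["sample", "chrom"]
    else:
        keys = ["chrom"]
    mids = {k: g["midpoint"].to_numpy() for k, g in events.groupby(keys, sort=False)}
    for key, g in out.groupby(keys, sort=False):
        target = mids.get(key if len(keys) > 1 else key, np.empty(0))
        d = _nearest(g["pos"].to_numpy(dtype=np.int64), np.asarray(target))
        dist[out.index.get_indexer(g.index)] = d
    out["distance"] = dist
    return out


def proximity_summary(
    distances: pd.DataFrame, radii: Sequence[int] = DEFAULT_RADII
) -> dict:
    """Counts of mutations within each radius of a CO (infinite distances excluded)."""
    d = distances["distance"].to_numpy()
    finite = d[np.isfinite(d)]
    out = {
        "n_mutations": int(len(d)),
        "n_with_event": int(len(finite)),
        "nearest_bp": float(finite.min()) if len(finite) else None,
    }
    for r in radii:
        out[f"within_{r}bp"] = int((finite <= r).sum())
    return out


def proximity_enrichment_test(
    mutations: pd.DataFrame,
    events: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    radius: int = 2_000,
    n_rand: int = 1_000,
    seed: int = 0,
    mode: str = "same_sample",
) -> dict:
    """Permutation test for mutation excess within ``radius`` bp of a CO.

    The null re-places every mutation uniformly along its own chromosome
    (sample and chromosome kept) and recounts mutations within the radius;
    one-sided ``p = (1 + #{shuffle >= observed}) / (1 + n_rand)``.  With
    zero mutations the result is flagged and p is None.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if len(mutations) == 0:
        return {"observed": 0, "expected": None, "pvalue": None, "flagged": True}
    rng = np.random.default_rng(seed)
    dist = nearest_co_distance(mutations, events, mode=mode)
    observed = int((dist["distance"] <= radius).sum())

    keys = ["sample", "chrom"] if mode == "same_sample" else ["chrom"]
    mids = {k: np.sort(g["midpoint"].to_numpy()) for k, g in events.groupby(keys, sort=False)}
    rand_counts = np.zeros(n_rand, dtype=np.int64)
    for key, g in mutations.groupby(keys, sort=False):
        chrom = key[-1] if isinstance(key, tuple) else key
        length = chrom_lengths[chrom]
        target = mids.get(key, np.empty(0))
        m = len(g)
        pos = rng.integers(1, length + 1, size=(n_rand, m))
        if len(target) == 0:
            continue
        d = _nearest(pos.ravel(), target).reshape(n_rand, m)
        rand_counts += (d <= radius).sum(axis=1)
    p = (1.0 + (rand_counts >= observed).sum()) / (1.0 + n_rand)
    return {
        "observed": observed,
        "expected": float(rand_counts.mean()),
        "pvalue": float(p),
        "n_rand": n_rand,
        "radius": radius,
        "mode": mode,
        "flagged": False,
    }


def binned_correlation(
    mutations: pd.DataFrame,
    events: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    bin_sizes: Sequence[int] = DEFAULT_BIN_SIZES,
    pericentromere: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spearman correlation of CO vs mutation counts per bin, per bin size.

    Bins overlapping peri-centromeric intervals are discarded (those
    regions are recombination-suppressed and would force a spurious
    positive association).  An empty mutation table flags every row; if a
    bin size leaves no bins an error is raised.
    """
    if not bin_sizes:
        raise ValueError("bin_sizes must be non-empty")
    rows = []
    for size in bin_sizes:
        co = landscape.bin_positions(events, chrom_lengths, size, pos_col="midpoint")
        mu = landscape.bin_positions(
            mutations, chrom_lengths, size, pos_col="pos", strict_bounds=False
        )
        if pericentromere is not None:
            co = landscape.telomere_centromere_filter(co, pericentromere, drop_telomeres=False)
            mu = mu.merge(co[["chrom", "idx"]], on=["chrom", "idx"], how="inner")
        if len(co) == 0:
            raise ValueError(f"all bins discarded at bin size {size}")
        merged = co.merge(mu, on=["chrom", "idx"], suffixes=("_co", "_mut"))
        if len(mutations) == 0 or merged["count_mut"].sum() == 0:
            rows.append(
                {"bin_size": size, "rho": float("nan"), "pvalue": float("nan"),
                 "n_bins": len(merged), "flagged": True}
            )
            continue
        res = landscape.spearman(merged["count_co"], merged["count_mut"])
        rows.append(
            {"bin_size": size, "rho": res.rho, "pvalue": res.pvalue,
             "n_bins": len(merged), "flagged": res.flagged}
        )
    return pd.DataFrame(rows)
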