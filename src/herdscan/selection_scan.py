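"""Windowed d_i selection-signature scan.

For every population pair the per-SNP Weir-Cockerham F_ST is standardized
by the pair's mean and SD over all defined SNPs; each population's d_i at
a SNP is the sum of those z-scores over all pairs involving it.  d_i is
averaged in non-overlapping 1-Mb windows, windows with fewer than four
informative SNPs are discarded, and windows whose mean strictly exceeds
the nearest-rank 99th percentile of the population's window means are
flagged.  Flagged windows are then classified as private to one
population or shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SnpMap
from .structure import wc_components

__all__ = [
    "FstPairStats",
    "per_snp_pairwise_fst",
    "standardize_pair",
    "di_track",
    "window_scan",
    "call_significant",
    "classify_windows",
    "pool_populations",
    "run_scan",
]

WINDOW_BP = 1_000_000


@dataclass
class FstPairStats:
    """Per-SNP F_ST for one population pair with its mean and SD."""

    pair: tuple[str, str]
    values: np.ndarray  # NaN where undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))


def per_snp_pairwise_fst(
    gm: GenotypeMatrix, pops: Mapping[str, str], pair: tuple[str, str]
) -> FstPairStats:
    """Single-SNP Weir-Cockerham a/(a+b+c); NaN where the total is zero."""
    a, abc = wc_components(gm, pops, pair[0], pair[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(np.isfinite(abc) & (abc != 0.0), a / abc, np.nan)
    return FstPairStats(pair=pair, values=fst)


def standardize_pair(stats: FstPairStats) -> np.ndarray:
    """(F_ST - mean)/sd per SNP; NaN preserved where F_ST is undefined."""
    sd = stats.sd
    # guard against numerically-zero SD on constant vectors
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(stats.mean)):
        raise ValueError(f"degenerate pair {stats.pair}: sd of F_ST is zero")
    return (stats.values - stats.mean) / sd


def di_track(
    population: str, z_by_pair: Mapping[tuple[str, str], np.ndarray]
) -> np.ndarray:
    """Sum of standardized pair F_ST over all pairs involving ``population``.

    SNPs with no defined pair are NaN and excluded downstream.
    """
    involved = [z for pair, z in z_by_pair.items() if population in pair]
    if not involved:
        raise ValueError(f"no pairs involve population {population!r}")
    stack = np.vstack(involved)
    any_defined = np.isfinite(stack).any(axis=0)
    di = np.nansum(stack, axis=0)
    return np.where(any_defined, di, np.nan)


def window_scan(
    di: np.ndarray,
    snp_map: SnpMap,
    window_mb: float = 1.0,
    min_snps: int = 4,
) -> pd.DataFrame:
    """Average d_i in non-overlapping windows; drop windows under min_snps.

    A SNP at bp p belongs to window floor((p-1)/window) of its chromosome,
    spanning [w*window + 1, (w+1)*window].  Only SNPs with a defined d_i
    count toward ``n_snps`` and the mean.
    """
    window_bp = int(round(window_mb * WINDOW_BP))
    defined = np.isfinite(di)
    win = (snp_map.pos_bp - 1) // window_bp
    df = pd.DataFrame(
        {
            "chrom": snp_map.chrom[defined],
            "win": win[defined],
            "di": di[defined],
        }
    )
    grouped = df.groupby(["chrom", "win"], sort=True)["di"].agg(["size", "mean"])
    grouped = grouped[grouped["size"] >= min_snps].reset_index()
    return pd.DataFrame(
        {
            "chrom": grouped["chrom"].astype(int),
            "window": grouped["win"].astype(int),
            "start_bp": grouped["win"].astype(int) * window_bp + 1,
            "end_bp": (grouped["win"].astype(int) + 1) * window_bp,
            "n_snps": grouped["size"].astype(int),
            "mean_di": grouped["mean"],
        }
    )


def call_significant(
    windows: pd.DataFrame, percentile: float = 99.0
) -> pd.DataFrame:
    """Flag windows whose mean d_i strictly exceeds the nearest-rank percentile.

    The threshold is the ceil(q * W)-th smallest of the W retained window
    means, so with tie-free means exactly W - ceil(q * W) windows flag.
    """
    if len(windows) == 0:
        raise ValueError("no retained windows")
    means = windows["mean_di"].to_numpy(dtype=float)
    w = len(means)
    rank = math.ceil(percentile / 100.0 * w)
    threshold = np.sort(means)[rank - 1]
    out = windows.copy()
    out["threshold"] = threshold
    out["significant"] = means > threshold
    return out


def classify_windows(
    flagged: Mapping[str, pd.DataFrame]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every flagged window with the set of populations flagging it.

    Returns a per-window table (chrom, window, populations, n_populations,
    private) and summary counts of private vs shared windows.
    """
    hits: dict[tuple[int, int], set[str]] = {}
    for pop, df in flagged.items():
        sig = df[df["significant"]]
        for _, r in sig.iterrows():
            hits.setdefault((int(r["chrom"]), int(r["window"])), set()).add(pop)
    rows = [
        (c, w, ",".join(sorted(pops)), len(pops), len(pops) == 1)
        for (c, w), pops in sorted(hits.items())
    ]
    table = pd.DataFrame(
        rows, columns=["chrom", "window", "populations", "n_populations", "private"]
    )
    n_private = int(table["private"].sum()) if len(table) else 0
    summary = {
        "n_flagged_windows": len(table),
        "n_private": n_private,
        "n_shared": len(table) - n_private,
    }
    return table, summary


def pool_populations(
    pops: Mapping[str, str], pooled: Mapping[str, str]
) -> dict[str, str]:
    """Relabel populations (e.g. merging two rare breeds into one group)."""
    return {iid: pooled.get(p, p) for iid, p in pops.items()}


def run_scan(
    gm: GenotypeMatrix,
    pops: Mapping[str, str],
    window_mb: float = 1.0,
    min_snps: int = 4,
    percentile: float = 99.0,
    pool: Mapping[str, str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, int]]:
    """Full scan: pairwise F_ST -> z -> d_i -> windows -> flags -> classes."""
    if pool:
        pops = pool_populations(pops, pool)
    labels = list(dict.fromkeys(pops[i] for i in gm.individuals))
    z_by_pair: dict[tuple[str, str], np.ndarray] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pair = (labels[i], labels[j])
            z_by_pair[pair] = standardize_pair(per_snp_pairwise_fst(gm, pops, pair))
    per_pop: dict[str, pd.DataFrame] = {}
    for pop in labels:
        di = di_track(pop, z_by_pair)
        windows = window_scan(di, gm.snps, window_mb=window_mb, min_snps=min_snps)
        per_pop[pop] = call_significant(windows, percentile=percentile)
    table, summary = classify_windows(per_pop)
    return per_pop, table, summary
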