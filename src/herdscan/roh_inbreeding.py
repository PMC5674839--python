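"""Runs of homozygosity and genomic / pedigree inbreeding.

ROH detection is an exact maximal-run search: every contiguous SNP
interval satisfying all constraints (het/missing budgets, adjacent-gap
cap, minimum SNP count, minimum span, segment-level density) is found,
and intervals properly contained in another qualifying interval are
suppressed.  This is deterministic and oracle-checkable, unlike the
sliding-window heuristic used by array toolkits, and may differ from it
at segment edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, SnpMap
from .pedigree import Pedigree, pci_5g, pedigree_inbreeding  # noqa: F401  (re-export)

__all__ = [
    "RohParams",
    "RohSegment",
    "GenomeLength",
    "lencz_min_snps",
    "detect_roh",
    "detect_roh_genome",
    "f_roh",
    "f_hom",
    "expected_hom",
    "pedigree_inbreeding",
    "pci_5g",
    "inbreeding_table",
    "roh_summaries",
    "roh_incidence",
    "compare_inbreeding",
]

LENGTH_CLASSES_MB = [(1, 5), (5, 10), (10, 15), (15, 20), (20, 25), (25, 30), (30, math.inf)]


@dataclass(frozen=True)
class RohParams:
    min_snps: int = 50
    min_length_kb: float = 1000.0
    min_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 1800.0
    max_missing: int = 2
    max_het: int = 0

    def __post_init__(self) -> None:
        if min(self.min_snps, self.min_length_kb, self.min_density_kb_per_snp, self.max_gap_kb) <= 0:
            raise ValueError("min_snps, lengths and density must be positive")
        if self.max_missing < 0 or self.max_het < 0:
            raise ValueError("max_missing and max_het must be >= 0")


@dataclass(frozen=True)
class RohSegment:
    individual: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


@dataclass(frozen=True)
class GenomeLength:
    """Autosomal span covered by SNPs: sum over chromosomes of max-min bp."""

    l_auto_kb: float

    def __post_init__(self) -> None:
        if self.l_auto_kb <= 0:
            raise ValueError("l_auto_kb must be positive")

    @classmethod
    def from_snp_map(cls, snp_map: SnpMap) -> "GenomeLength":
        total = 0.0
        for c in np.unique(snp_map.chrom):
            p = snp_map.pos_bp[snp_map.chrom == c]
            total += float(p.max() - p.min())
        return cls(total / 1000.0)


def lencz_min_snps(
    n_snps: int, n_individuals: int, mean_het: float, alpha: float = 0.05
) -> int:
    """Smallest run length bounding genome-wide chance-ROH false positives.

    l = ceil( ln(alpha / (n_snps * n_individuals)) / ln(1 - mean_het) ).
    """
    if not 0.0 < mean_het < 1.0:
        raise ValueError("mean_het must be strictly between 0 and 1")
    if n_snps <= 0 or n_individuals <= 0:
        raise ValueError("counts must be positive")
    ratio = math.log(alpha / (n_snps * n_individuals)) / math.log(1.0 - mean_het)
    # tolerate float noise when the bound is met at an exact integer
    return math.ceil(ratio - 1e-9)


def detect_roh(
    calls: np.ndarray,
    positions: np.ndarray,
    params: RohParams = RohParams(),
    individual: str = "",
    chrom: int = 0,
) -> list[RohSegment]:
    """All maximal qualifying homozygous runs for one individual/chromosome.

    A run qualifies when simultaneously: het count <= max_het, missing
    count <= max_missing, every adjacent gap <= max_gap_kb, n_snps >=
    min_snps, span >= min_length_kb and span/n_snps <= density cap.  Runs
    properly contained in another qualifying run are not reported.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.int64)
    if len(calls) != len(positions):
        raise ValueError("calls and positions must have equal length")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")

    het = calls == 1
    miss = calls == MISSING

    # blocks: runs can never cross a gap larger than the cap, nor (when the
    # budget is zero) a het or missing call
    breaks = np.zeros(len(calls) + 1, dtype=bool)
    breaks[0] = breaks[-1] = True
    gap_kb = np.diff(positions) / 1000.0
    big_gap = np.nonzero(gap_kb > params.max_gap_kb)[0]
    segments: list[RohSegment] = []
    blocked = np.zeros(len(calls), dtype=bool)
    if params.max_het == 0:
        blocked |= het
    if params.max_missing == 0:
        blocked |= miss

    # block boundaries over index ranges
    starts: list[int] = []
    ends: list[int] = []
    cur = 0
    cut_after = set(big_gap.tolist())
    for idx in range(len(calls)):
        if blocked[idx]:
            if idx > cur:
                starts.append(cur)
                ends.append(idx)
            cur = idx + 1
        elif idx in cut_after:
            starts.append(cur)
            ends.append(idx + 1)
            cur = idx + 1
    if cur < len(calls):
        starts.append(cur)
        ends.append(len(calls))

    for s, e in zip(starts, ends):
        m = e - s
        if m < params.min_snps:
            continue
        segments.extend(
            _maximal_runs_block(
                calls[s:e], positions[s:e], params, individual, chrom
            )
        )
    return segments


def _maximal_runs_block(
    calls: np.ndarray,
    positions: np.ndarray,
    params: RohParams,
    individual: str,
    chrom: int,
) -> list[RohSegment]:
    """Vectorized all-pairs qualification + dominance filter within a block."""
    m = len(calls)
    het_c = np.concatenate([[0], np.cumsum(calls == 1)])
    mis_c = np.concatenate([[0], np.cumsum(calls == MISSING)])
    i = np.arange(m)[:, None]
    j = np.arange(m)[None, :]
    n = j - i + 1
    span_kb = (positions[None, :] - positions[:, None]) / 1000.0
    hets = het_c[j + 1] - het_c[i]
    misses = mis_c[j + 1] - mis_c[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        density = span_kb / n
    q = (
        (j >= i)
        & (n >= params.min_snps)
        & (span_kb >= params.min_length_kb)
        & (density <= params.min_density_kb_per_snp)
        & (hets <= params.max_het)
        & (misses <= params.max_missing)
    )
    if not q.any():
        return []
    # dominance: qualifying (i', j') with i' <= i and j' >= j, other than self
    c = np.cumsum(q.astype(np.int64), axis=0)
    c = np.flip(np.cumsum(np.flip(c, axis=1), axis=1), axis=1)
    maximal = q & (c == 1)
    out = []
    for bi, bj in zip(*np.nonzero(maximal)):
        out.append(
            RohSegment(
                individual=individual,
                chrom=chrom,
                start_bp=int(positions[bi]),
                end_bp=int(positions[bj]),
                n_snps=int(bj - bi + 1),
            )
        )
    return out


def detect_roh_genome(
    gm: GenotypeMatrix, params: RohParams = RohParams()
) -> pd.DataFrame:
    """ROH for every individual across all chromosomes, as a PLINK-like table."""
    snp_map = gm.snps
    chrom_slices = {c: np.nonzero(snp_map.chrom == c)[0] for c in np.unique(snp_map.chrom)}
    rows = []
    for k, iid in enumerate(gm.individuals):
        for c, sl in chrom_slices.items():
            for seg in detect_roh(
                gm.calls[k, sl], snp_map.pos_bp[sl], params, individual=iid, chrom=int(c)
            ):
                rows.append(
                    (
                        seg.individual,
                        seg.chrom,
                        seg.start_bp,
                        seg.end_bp,
                        seg.length_kb,
                        seg.n_snps,
                    )
                )
    return pd.DataFrame(
        rows, columns=["IID", "CHR", "POS1", "POS2", "KB", "NSNP"]
    )


def f_roh(
    segments: Iterable[RohSegment] | pd.DataFrame,
    genome_length: GenomeLength,
    min_segment_kb: float = 0.0,
) -> float:
    """Summed ROH length (segments longer than the floor) over L_AUTO."""
    if isinstance(segments, pd.DataFrame):
        lengths = segments["KB"].to_numpy(dtype=float)
    else:
        lengths = np.array([s.length_kb for s in segments], dtype=float)
    total = lengths[lengths > min_segment_kb].sum() if len(lengths) else 0.0
    return float(total / genome_length.l_auto_kb)


def f_hom(n_obs_hom: float, n_exp_hom: float, n_nonmissing: int) -> float:
    """(observed - expected homozygous) / (non-missing - expected)."""
    denom = n_nonmissing - n_exp_hom
    if denom <= 0:
        raise ValueError("non-missing count must exceed expected homozygous count")
    return float((n_obs_hom - n_exp_hom) / denom)


def expected_hom(gm: GenotypeMatrix, individual: str) -> float:
    """Expected homozygous-locus count from merged-sample frequencies.

    Per SNP: 1 - 2pq * 2n/(2n-1), summed over the individual's non-missing
    SNPs; SNPs with fewer than 2 genotyped individuals are excluded.
    """
    k = gm.individuals.index(individual)
    calls = gm.calls
    ok = calls != MISSING
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, calls, 0).sum(axis=0) / (2.0 * n)
        contrib = 1.0 - 2.0 * p * (1.0 - p) * (2.0 * n / (2.0 * n - 1.0))
    use = ok[k] & (n >= 2)
    return float(contrib[use].sum())


def inbreeding_table(
    gm: GenotypeMatrix,
    pedigree: Pedigree | None,
    roh_table: pd.DataFrame,
    genome_length: GenomeLength,
    pops: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-individual F_PED, F_HOM, F_ROH, F_ROH>5Mb and PCI_5G."""
    f_ped = pedigree_inbreeding(pedigree) if pedigree is not None else {}
    by_iid = dict(tuple(roh_table.groupby("IID"))) if len(roh_table) else {}
    rows = []
    for k, iid in enumerate(gm.individuals):
        calls = gm.calls[k]
        ok = calls != MISSING
        n_nonmiss = int(ok.sum())
        n_obs_hom = int(((calls == 0) | (calls == 2)).sum())
        exp = expected_hom(gm, iid)
        segs = by_iid.get(iid, pd.DataFrame(columns=["KB"]))
        fr = f_roh(segs, genome_length)
        fr5 = f_roh(segs, genome_length, min_segment_kb=5000.0)
        rows.append(
            (
                iid,
                pops.get(iid, "") if pops else "",
                f_ped.get(iid, np.nan) if pedigree is not None else np.nan,
                f_hom(n_obs_hom, exp, n_nonmiss),
                fr,
                fr5,
                pci_5g(pedigree, iid) if pedigree is not None and iid in pedigree.sire else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["iid", "pop", "F_PED", "F_HOM", "F_ROH", "F_ROH_gt5", "PCI5"]
    )


def roh_summaries(
    roh_table: pd.DataFrame, pops: Mapping[str, str], individuals: Sequence[str]
) -> dict[str, pd.DataFrame]:
    """Per-population ROH summary, length-class histogram, per-chromosome counts."""
    pop_order = list(dict.fromkeys(pops[i] for i in individuals))
    per_pop_rows, hist_rows, chrom_rows = [], [], []
    counts = roh_table.groupby("IID").size() if len(roh_table) else pd.Series(dtype=int)
    totals = (
        roh_table.groupby("IID")["KB"].sum() if len(roh_table) else pd.Series(dtype=float)
    )
    for pop in pop_order:
        members = [i for i in individuals if pops[i] == pop]
        with_roh = [i for i in members if i in counts.index]
        n_with = len(with_roh)
        seg = (
            roh_table[roh_table["IID"].isin(members)]
            if len(roh_table)
            else roh_table
        )
        cnt = counts.reindex(with_roh)
        tot_mb = totals.reindex(with_roh) / 1000.0
        per_pop_rows.append(
            (
                pop,
                len(members) - n_with,
                n_with,
                int(len(seg)),
                float(cnt.mean()) if n_with else 0.0,
                int(cnt.min()) if n_with else 0,
                int(cnt.max()) if n_with else 0,
                float(tot_mb.mean()) if n_with else 0.0,
                float(tot_mb.min()) if n_with else 0.0,
                float(tot_mb.max()) if n_with else 0.0,
            )
        )
        length_mb = seg["KB"].to_numpy(dtype=float) / 1000.0 if len(seg) else np.array([])
        hist = []
        for lo, hi in LENGTH_CLASSES_MB:
            hist.append(int(((length_mb >= lo) & (length_mb < hi)).sum()))
        hist_rows.append((pop, *hist))
        for c, sub in (seg.groupby("CHR") if len(seg) else []):
            chrom_rows.append((pop, int(c), len(sub)))
    per_pop = pd.DataFrame(
        per_pop_rows,
        columns=[
            "pop", "n_without_roh", "n_with_roh", "total_roh", "mean_count",
            "min_count", "max_count", "mean_total_mb", "min_total_mb", "max_total_mb",
        ],
    )
    class_labels = [
        f"[{lo}-{hi})Mb" if math.isfinite(hi) else f">={lo}Mb"
        for lo, hi in LENGTH_CLASSES_MB
    ]
    histogram = pd.DataFrame(hist_rows, columns=["pop", *class_labels])
    per_chrom = pd.DataFrame(chrom_rows, columns=["pop", "chrom", "n_roh"])
    return {"per_population": per_pop, "length_classes": histogram, "per_chromosome": per_chrom}


def roh_incidence(
    roh_table: pd.DataFrame,
    snp_map: SnpMap,
    pops: Mapping[str, str],
    individuals: Sequence[str],
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Per SNP and population: fraction of individuals whose ROH covers it.

    Coverage is inclusive of segment endpoints; fractions >= ``threshold``
    are flagged.
    """
    pop_order = list(dict.fromkeys(pops[i] for i in individuals))
    n_snps = len(snp_map)
    chrom = snp_map.chrom
    pos = snp_map.pos_bp
    frames = []
    for pop in pop_order:
        members = [i for i in individuals if pops[i] == pop]
        covered_counts = np.zeros(n_snps, dtype=np.int64)
        seg = roh_table[roh_table["IID"].isin(members)] if len(roh_table) else roh_table
        for iid, sub in (seg.groupby("IID") if len(seg) else []):
            cov = np.zeros(n_snps + 1, dtype=np.int64)
            for _, r in sub.iterrows():
                on_chrom = np.nonzero(chrom == r["CHR"])[0]
                if not len(on_chrom):
                    continue
                sub_pos = pos[on_chrom]
                first = np.searchsorted(sub_pos, r["POS1"], side="left")
                last = np.searchsorted(sub_pos, r["POS2"], side="right")
                if last <= first:
                    continue
                cov[on_chrom[first]] += 1
                cov[on_chrom[last - 1] + 1] -= 1
            covered_counts += (np.cumsum(cov[:-1]) > 0).astype(np.int64)
        frac = covered_counts / len(members) if members else np.zeros(n_snps)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": snp_map.snp_id,
                    "chrom": chrom,
                    "pos_bp": pos,
                    "pop": pop,
                    "fraction": frac,
                    "flagged": frac >= threshold,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def compare_inbreeding(
    records: pd.DataFrame, pci_min: float | None = None
) -> pd.DataFrame:
    """Pearson r and OLS fit of F_ROH and F_HOM against F_PED."""
    df = records
    if pci_min is not None:
        df = df[df["PCI5"] >= pci_min]
    if len(df) < 3:
        raise ValueError("need at least 3 records after filtering")
    out = []
    x = df["F_PED"].to_numpy(dtype=float)
    for col in ("F_ROH", "F_HOM"):
        y = df[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero variance comparing F_PED with {col}")
        r, _ = stats.pearsonr(x, y)
        fit = stats.linregress(x, y)
        out.append((col, float(r), fit.slope, fit.intercept, fit.rvalue**2, len(df)))
    return pd.DataFrame(
        out, columns=["measure", "pearson_r", "slope", "intercept", "r_squared", "n"]
    )
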