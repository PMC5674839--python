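"""Reading/writing PLINK-dialect text genotype files and three-stage SNP QC.

Genotypes are held as an individuals x SNPs matrix of minor-allele counts
(0/1/2) with ``MISSING`` (-1) for no-calls.  QC follows the usual array
workflow: panel intersection, a call-rate filter over the merged sample,
then per-population MAF and exact Hardy-Weinberg filters, a SNP surviving
only if it passes in every population.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "N_AUTOSOMES",
    "SnpMap",
    "GenotypeMatrix",
    "QcReport",
    "read_plink_text",
    "write_plink_text",
    "intersect_panels",
    "filter_call_rate",
    "hwe_exact_test",
    "per_population_filter",
    "run_qc",
]

MISSING: int = -1
N_AUTOSOMES: int = 29


class PlinkParseError(ValueError):
    """Raised for malformed PED/MAP input."""


@dataclass(frozen=True)
class SnpMap:
    """Per-SNP chromosome / position / allele table.

    ``allele_a`` is the major and ``allele_b`` the minor allele; genotype
    calls count copies of ``allele_b``.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        for name in ("chrom", "pos_bp", "allele_a", "allele_b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SnpMap column {name!r} has wrong length")
        if len(set(self.snp_id.tolist())) != n:
            raise ValueError("SNP ids are not unique")
        if n and (self.chrom.min() < 1 or self.chrom.max() > N_AUTOSOMES):
            raise ValueError(f"chromosome outside 1..{N_AUTOSOMES}")
        if n and np.any(self.pos_bp < 1):
            raise ValueError("positions must be >= 1")
        for c in np.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions on chromosome {c} not strictly increasing"
                )

    def __len__(self) -> int:
        return len(self.snp_id)

    def subset(self, index: np.ndarray) -> "SnpMap":
        return SnpMap(
            self.snp_id[index],
            self.chrom[index],
            self.pos_bp[index],
            self.allele_a[index],
            self.allele_b[index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )

    @classmethod
    def from_arrays(
        cls,
        snp_id: Sequence[str],
        chrom: Sequence[int],
        pos_bp: Sequence[int],
        allele_a: Sequence[str] | None = None,
        allele_b: Sequence[str] | None = None,
    ) -> "SnpMap":
        n = len(snp_id)
        return cls(
            np.asarray(snp_id, dtype=object),
            np.asarray(chrom, dtype=np.int64),
            np.asarray(pos_bp, dtype=np.int64),
            np.asarray(allele_a if allele_a is not None else ["A"] * n, dtype=object),
            np.asarray(allele_b if allele_b is not None else ["B"] * n, dtype=object),
        )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele-count matrix."""

    individuals: list[str]
    snps: SnpMap
    calls: np.ndarray  # int8, MISSING = -1

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        bad = (self.calls != MISSING) & ((self.calls < 0) | (self.calls > 2))
        if bad.any():
            raise ValueError("non-missing calls must be in {0,1,2}")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids are not unique")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.snps.subset(index), self.calls[:, index])

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {iid: k for k, iid in enumerate(self.individuals)}
        idx = np.array([pos[i] for i in ids], dtype=np.intp)
        return GenotypeMatrix(list(ids), self.snps, self.calls[idx])


@dataclass
class QcReport:
    n_input_snps: int
    n_after_callrate: int
    n_after_per_population: int
    fate: pd.DataFrame = field(repr=False)  # snp_id, stage, status, reason

    def __post_init__(self) -> None:
        if not (
            self.n_input_snps >= self.n_after_callrate >= self.n_after_per_population
        ):
            raise ValueError("QC stage counts must be non-increasing")
        if len(self.fate) != self.n_input_snps:
            raise ValueError("fate table must cover every input SNP exactly once")

    def to_tsv(self, dest) -> None:
        self.fate.to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED/MAP parsing


def _open(source, mode="r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def _read_map_rows(map_source) -> list[tuple[str, str, int]]:
    """Return (chrom_code, snp_id, bp) for every MAP line, autosomes or not."""
    fh, close = _open(map_source)
    rows = []
    try:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PlinkParseError(
                    f"MAP line {lineno}: expected 4 columns, got {len(parts)}"
                )
            rows.append((parts[0], parts[1], int(parts[3])))
    finally:
        if close:
            fh.close()
    return rows


def read_plink_text(
    ped_source, map_source
) -> tuple[GenotypeMatrix, SnpMap, dict[str, str]]:
    """Read whitespace-separated PED/MAP files.

    Returns the coded genotype matrix, its SNP map and a population
    assignment taken from the PED family column.  Alleles are re-coded per
    SNP as (major, minor) by frequency in the merged sample, ties broken
    lexicographically (the smaller label becomes the major allele); calls
    count minor-allele copies.  Non-autosomal MAP records are skipped with
    a warning; a half-missing genotype becomes a fully missing call.
    """
    map_rows = _read_map_rows(map_source)
    keep: list[int] = []
    for k, (chrom_code, _, _) in enumerate(map_rows):
        try:
            c = int(chrom_code)
        except ValueError:
            c = -1
        if 1 <= c <= N_AUTOSOMES:
            keep.append(k)
        else:
            warnings.warn(
                f"skipping non-autosomal SNP {map_rows[k][1]!r} "
                f"(chromosome code {chrom_code!r})",
                stacklevel=2,
            )
    n_all = len(map_rows)
    n_kept = len(keep)

    fh, close = _open(ped_source)
    individuals: list[str] = []
    pops: dict[str, str] = {}
    a1_rows: list[list[str]] = []
    a2_rows: list[list[str]] = []
    try:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_all:
                raise PlinkParseError(
                    f"PED line {lineno}: expected {6 + 2 * n_all} fields "
                    f"for {n_all} SNPs, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            individuals.append(iid)
            pops[iid] = fid
            alleles = parts[6:]
            a1_rows.append([alleles[2 * k] for k in keep])
            a2_rows.append([alleles[2 * k + 1] for k in keep])
    finally:
        if close:
            fh.close()

    n_ind = len(individuals)
    a1 = np.asarray(a1_rows, dtype=object).reshape(n_ind, n_kept)
    a2 = np.asarray(a2_rows, dtype=object).reshape(n_ind, n_kept)

    snp_id = np.empty(n_kept, dtype=object)
    chrom = np.empty(n_kept, dtype=np.int64)
    pos = np.empty(n_kept, dtype=np.int64)
    for j, k in enumerate(keep):
        chrom[j] = int(map_rows[k][0])
        snp_id[j] = map_rows[k][1]
        pos[j] = map_rows[k][2]

    allele_a = np.empty(n_kept, dtype=object)
    allele_b = np.empty(n_kept, dtype=object)
    calls = np.full((n_ind, n_kept), MISSING, dtype=np.int8)
    for j in range(n_kept):
        c1, c2 = a1[:, j], a2[:, j]
        counts: dict[str, int] = {}
        for arr in (c1, c2):
            for al in arr:
                if al != "0":
                    counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise PlinkParseError(
                f"SNP {snp_id[j]!r} has more than two alleles: {sorted(counts)}"
            )
        # major first; ties broken toward the lexicographically smaller label
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        maj = ordered[0][0] if ordered else "0"
        mnr = ordered[1][0] if len(ordered) > 1 else "0"
        allele_a[j], allele_b[j] = maj, mnr
        ok = (c1 != "0") & (c2 != "0")
        calls[ok, j] = (c1[ok] == mnr).astype(np.int8) + (c2[ok] == mnr).astype(np.int8)

    order = np.lexsort((pos, chrom))
    snp_map = SnpMap(snp_id[order], chrom[order], pos[order], allele_a[order], allele_b[order])
    gm = GenotypeMatrix(individuals, snp_map, calls[:, order])
    return gm, snp_map, pops


def write_plink_text(
    gm: GenotypeMatrix,
    snp_map: SnpMap,
    pops: Mapping[str, str],
    ped_dest,
    map_dest,
) -> None:
    """Write a GenotypeMatrix back to PLINK text PED/MAP."""
    fh, close = _open(map_dest, "w")
    try:
        for j in range(len(snp_map)):
            fh.write(
                f"{snp_map.chrom[j]}\t{snp_map.snp_id[j]}\t0\t{snp_map.pos_bp[j]}\n"
            )
    finally:
        if close:
            fh.close()

    # genotype call -> allele pair strings, one lookup table per SNP
    fh, close = _open(ped_dest, "w")
    try:
        for i, iid in enumerate(gm.individuals):
            fam = pops.get(iid, "POP")
            fields = [fam, iid, "0", "0", "0", "-9"]
            row = gm.calls[i]
            for j in range(len(snp_map)):
                g = row[j]
                a, b = snp_map.allele_a[j], snp_map.allele_b[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a, a]
                elif g == 1:
                    fields += [a, b]
                else:
                    fields += [b, b]
            fh.write(" ".join(fields) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# QC operations


def intersect_panels(maps: Sequence[SnpMap]) -> SnpMap:
    """SNPs present (by id, with matching chrom/pos) in every input map.

    Order follows the first map.  Conflicting positions for a shared id
    raise with the full conflict list.
    """
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    lookup = [
        {m.snp_id[j]: (m.chrom[j], m.pos_bp[j]) for j in range(len(m))} for m in maps
    ]
    conflicts = []
    keep = np.zeros(len(first), dtype=bool)
    for j in range(len(first)):
        sid = first.snp_id[j]
        key = (first.chrom[j], first.pos_bp[j])
        present = True
        for table in lookup[1:]:
            if sid not in table:
                present = False
                break
            if table[sid] != key:
                conflicts.append((sid, key, table[sid]))
                present = False
        keep[j] = present
    if conflicts:
        msg = "; ".join(
            f"{sid}: {a[0]}:{a[1]} vs {b[0]}:{b[1]}" for sid, a, b in conflicts
        )
        raise ValueError(f"conflicting positions for shared SNP ids: {msg}")
    return first.subset(np.nonzero(keep)[0])


def filter_call_rate(gm: GenotypeMatrix, max_missing_rate: float = 0.1) -> np.ndarray:
    """Boolean keep-mask: SNP kept iff missing fraction <= ``max_missing_rate``."""
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    miss = (gm.calls == MISSING).mean(axis=0)
    return miss <= max_missing_rate


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on the heterozygote count.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote configurations no more probable than the observed one
    (no mid-p adjustment).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no data: all genotype counts are zero")
    n_rare = 2 * n_bb + n_ab if n_bb <= n_aa else 2 * n_aa + n_ab
    # feasible het counts share the parity of the rare-allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized probabilities via the symmetric recurrence around mid
    probs = np.zeros(len(het_values))
    mid_idx = len(het_values) // 2
    probs[mid_idx] = 1.0
    for k in range(mid_idx, 0, -1):  # downward: het h -> h - 2
        h = het_values[k]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[k - 1] = probs[k] * h * (h - 1) / (4.0 * (rare_hom + 1) * (common_hom + 1))
    for k in range(mid_idx, len(het_values) - 1):  # upward: het h -> h + 2
        h = het_values[k]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[k + 1] = probs[k] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(het_values, n_ab)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_conditional_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """(het_values, probabilities) of the conditional HWE distribution."""
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    probs = np.zeros(len(het_values))
    probs[0] = 1.0
    for k in range(len(het_values) - 1):
        h = het_values[k]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[k + 1] = probs[k] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    return het_values, probs


def per_population_filter(
    gm: GenotypeMatrix,
    pops: Mapping[str, str],
    maf_min: float = 0.01,
    hwe_alpha: float = 0.0001,
    callrate_keep: np.ndarray | None = None,
) -> tuple[np.ndarray, QcReport]:
    """Per-population MAF / HWE filter applied after the call-rate stage.

    A SNP survives only if, within *every* population, the minor-allele
    frequency over non-missing alleles is >= ``maf_min`` and the exact HWE
    p-value is >= ``hwe_alpha``.  Returns the final keep-mask and a QcReport
    whose fate table names the first failing population per dropped SNP.
    """
    labels = [pops[i] for i in gm.individuals]
    pop_order = list(dict.fromkeys(labels))
    masks = {p: np.array([l == p for l in labels]) for p in pop_order}
    for p, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")

    if callrate_keep is None:
        callrate_keep = np.ones(gm.n_snps, dtype=bool)

    status = np.full(gm.n_snps, "kept", dtype=object)
    stage = np.full(gm.n_snps, "final", dtype=object)
    reason = np.full(gm.n_snps, "", dtype=object)

    status[~callrate_keep] = "dropped"
    stage[~callrate_keep] = "callrate"
    reason[~callrate_keep] = "missing rate above threshold"

    keep = callrate_keep.copy()
    calls = gm.calls
    for p in pop_order:
        sub = calls[masks[p]]
        nonmiss = sub != MISSING
        n_bb = (sub == 2).sum(axis=0)
        n_ab = (sub == 1).sum(axis=0)
        n_aa = (sub == 0).sum(axis=0)
        n_tot = nonmiss.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_b = (2 * n_bb + n_ab) / (2.0 * n_tot)
        maf = np.minimum(freq_b, 1.0 - freq_b)
        for j in np.nonzero(keep)[0]:
            if n_tot[j] == 0:
                keep[j] = False
                status[j], stage[j] = "dropped", "per_population"
                reason[j] = f"no data in population {p}"
            elif maf[j] < maf_min:
                keep[j] = False
                status[j], stage[j] = "dropped", "per_population"
                reason[j] = f"maf {maf[j]:.4g} < {maf_min} in population {p}"
            elif hwe_exact_test(int(n_aa[j]), int(n_ab[j]), int(n_bb[j])) < hwe_alpha:
                keep[j] = False
                status[j], stage[j] = "dropped", "per_population"
                reason[j] = f"HWE deviation in population {p}"

    fate = pd.DataFrame(
        {"snp_id": gm.snps.snp_id, "stage": stage, "status": status, "reason": reason}
    )
    report = QcReport(
        n_input_snps=gm.n_snps,
        n_after_callrate=int(callrate_keep.sum()),
        n_after_per_population=int(keep.sum()),
        fate=fate,
    )
    return keep, report


def run_qc(
    gm: GenotypeMatrix,
    pops: Mapping[str, str],
    max_missing_rate: float = 0.1,
    maf_min: float = 0.01,
    hwe_alpha: float = 0.0001,
) -> tuple[GenotypeMatrix, QcReport]:
    """Call-rate filter followed by the per-population MAF/HWE filter."""
    cr_keep = filter_call_rate(gm, max_missing_rate)
    keep, report = per_population_filter(
        gm, pops, maf_min=maf_min, hwe_alpha=hwe_alpha, callrate_keep=cr_keep
    )
    return gm.subset_snps(np.nonzero(keep)[0]), report
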