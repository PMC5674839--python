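"""Synthetic multi-population genotype panels with recoverable ground truth.

Population allele frequencies follow the Balding-Nichols model around a
shared ancestral frequency; genotypes for pedigreed individuals are
produced by gene-dropping founder haplotypes through the pedigree with
Haldane (no-interference) recombination.  Founder alleles carry unique
labels, so true autozygous tracts — stretches where the two haplotypes
descend from the same founder allele copy — are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SnpMap
from .pedigree import Pedigree, pedigree_inbreeding

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "balding_nichols_freqs",
    "random_snp_map",
    "gene_drop",
    "make_cross",
    "make_looped_pedigree",
    "simulate_panel",
]


@dataclass
class SimulationConfig:
    """Knobs for a full synthetic panel; every run is fixed by ``seed``."""

    n_chromosomes: int = 29
    chrom_length_bp: int = 100_000_000
    n_snps_per_chrom: int = 1_100  # ~90 kb spacing on a 100-Mb chromosome
    populations: list[tuple[str, float, int]] = field(
        default_factory=lambda: [("P1", 0.05, 30), ("P2", 0.05, 30)]
    )  # (label, divergence_F, n_founders)
    crosses: list[tuple[str, str, str, float]] = field(default_factory=list)
    pedigree_depth: int = 0
    mating_scheme: str = "random"  # random | full_sib_loop | half_sib_loop
    recomb_rate: float = 1.0  # cM per Mb
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_snps_per_chrom) <= 0:
            raise ValueError("counts must be positive")
        for label, f, n in self.populations:
            if not 0.0 <= f < 1.0:
                raise ValueError(f"divergence F for {label} must be in [0, 1)")
            if n <= 0:
                raise ValueError(f"founder count for {label} must be positive")
        for label, a, b, prop in self.crosses:
            if not 0.0 <= prop < 1.0 or (prop != 0.0 and prop <= 0.0):
                raise ValueError(f"cross proportion for {label} must be in [0, 1)")
        if self.mating_scheme not in ("random", "full_sib_loop", "half_sib_loop"):
            raise ValueError(f"unknown mating scheme {self.mating_scheme!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "populations" in d:
            d["populations"] = [tuple(p) for p in d["populations"]]
        if "crosses" in d:
            d["crosses"] = [tuple(c) for c in d["crosses"]]
        return cls(**d)


@dataclass
class TruthSet:
    """Ground truth emitted alongside simulated genotypes."""

    ancestral_freqs: np.ndarray  # (n_snps,)
    population_freqs: dict[str, np.ndarray]
    # individual -> list of (chrom, start_bp, end_bp) IBD-of-both-haplotypes tracts
    true_autozygous_tracts: dict[str, list[tuple[int, int, int]]]
    true_f_ped: dict[str, float]

    def tracts_frame(self) -> pd.DataFrame:
        rows = [
            (iid, c, s, e)
            for iid, tracts in self.true_autozygous_tracts.items()
            for c, s, e in tracts
        ]
        return pd.DataFrame(rows, columns=["individual", "chrom", "start_bp", "end_bp"])

    def autozygous_fraction(self, individual: str, snp_map: SnpMap) -> float:
        """Summed tract length over the SNP-spanned genome length."""
        l_auto = 0.0
        for c in np.unique(snp_map.chrom):
            p = snp_map.pos_bp[snp_map.chrom == c]
            l_auto += float(p.max() - p.min())
        total = sum(e - s for _, s, e in self.true_autozygous_tracts[individual])
        return total / l_auto


def balding_nichols_freqs(
    n_snps: int, divergence_F: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral ~ Uniform(0.05, 0.95); population freq Beta-drifted around it."""
    if not 0.0 <= divergence_F < 1.0:
        raise ValueError("divergence_F must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_snps)
    if divergence_F == 0.0:
        return p, p.copy()
    scale = (1.0 - divergence_F) / divergence_F
    pop = rng.beta(p * scale, (1.0 - p) * scale)
    return p, pop


def random_snp_map(
    n_chromosomes: int,
    chrom_length_bp: int,
    n_snps_per_chrom: int,
    seed: int | np.random.Generator,
    prefix: str = "snp",
) -> SnpMap:
    """Uniform random SNP positions, distinct within each chromosome."""
    rng = np.random.default_rng(seed)
    chroms, positions, ids = [], [], []
    for c in range(1, n_chromosomes + 1):
        pos = np.sort(
            rng.choice(
                np.arange(1, chrom_length_bp + 1), size=n_snps_per_chrom, replace=False
            )
            if chrom_length_bp <= 10 * n_snps_per_chrom
            else _distinct_sorted(rng, chrom_length_bp, n_snps_per_chrom)
        )
        chroms.append(np.full(n_snps_per_chrom, c))
        positions.append(pos)
        ids.extend(f"{prefix}_{c}_{k}" for k in range(n_snps_per_chrom))
    return SnpMap.from_arrays(
        ids, np.concatenate(chroms), np.concatenate(positions)
    )


def _distinct_sorted(rng, length_bp: int, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length_bp + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length_bp + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n]


# ---------------------------------------------------------------------------
# gene dropping


def _meiosis(
    hap_alleles: np.ndarray,  # (2, n_snps) for one chromosome
    hap_origins: np.ndarray,
    positions: np.ndarray,
    chrom_length_bp: float,
    recomb_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete: Poisson crossover count, uniform positions."""
    length_mb = chrom_length_bp / 1e6
    n_xo = rng.poisson(recomb_rate * length_mb / 100.0)
    start = rng.integers(2)
    if n_xo == 0:
        return hap_alleles[start].copy(), hap_origins[start].copy()
    xo = np.sort(rng.uniform(1, chrom_length_bp, size=n_xo))
    # which haplotype each SNP comes from: flip at every crossover
    seg = (start + np.searchsorted(xo, positions)) % 2
    idx = np.arange(len(positions))
    return hap_alleles[seg, idx], hap_origins[seg, idx]


def gene_drop(
    pedigree: Pedigree,
    snp_map: SnpMap,
    founder_freqs: np.ndarray | Mapping[str, np.ndarray],
    recomb_rate: float = 1.0,
    seed: int | np.random.Generator = None,
    founder_pop: Mapping[str, str] | None = None,
    chrom_length_bp: int | None = None,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Drop founder haplotypes through a pedigree, tracking allele origins.

    ``founder_freqs`` is either one per-SNP frequency vector for all
    founders or a mapping population -> vector combined with
    ``founder_pop`` (founder id -> population).  Every pedigree member must
    have both parents known or neither.
    """
    rng = np.random.default_rng(seed)
    n_snps = len(snp_map)
    chrom_ids = np.unique(snp_map.chrom)
    chrom_slices = {c: np.nonzero(snp_map.chrom == c)[0] for c in chrom_ids}
    if chrom_length_bp is None:
        lengths = {c: int(snp_map.pos_bp[chrom_slices[c]].max()) for c in chrom_ids}
    else:
        lengths = {c: chrom_length_bp for c in chrom_ids}

    def freqs_for(iid: str) -> np.ndarray:
        if isinstance(founder_freqs, Mapping):
            if founder_pop is None:
                raise ValueError("founder_pop required with per-population freqs")
            return np.asarray(founder_freqs[founder_pop[iid]])
        return np.asarray(founder_freqs)

    alleles: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {}
    founder_counter = 0
    for iid in pedigree.order:
        s, d = pedigree.parents(iid)
        if (s is None) != (d is None):
            raise ValueError(f"individual {iid!r} has exactly one known parent")
        if s is None:
            f = freqs_for(iid)
            if len(f) != n_snps:
                raise ValueError("founder_freqs length mismatch with SNP map")
            a = (rng.random((2, n_snps)) < f).astype(np.int8)
            o = np.empty((2, n_snps), dtype=np.int64)
            o[0] = 2 * founder_counter
            o[1] = 2 * founder_counter + 1
            founder_counter += 1
        else:
            a = np.empty((2, n_snps), dtype=np.int8)
            o = np.empty((2, n_snps), dtype=np.int64)
            for h, parent in enumerate((s, d)):
                pa, po = alleles[parent], origins[parent]
                for c in chrom_ids:
                    sl = chrom_slices[c]
                    ga, go = _meiosis(
                        pa[:, sl], po[:, sl], snp_map.pos_bp[sl],
                        lengths[c], recomb_rate, rng,
                    )
                    a[h, sl] = ga
                    o[h, sl] = go
        alleles[iid] = a
        origins[iid] = o

    individuals = list(pedigree.order)
    calls = np.empty((len(individuals), n_snps), dtype=np.int8)
    tracts: dict[str, list[tuple[int, int, int]]] = {}
    for k, iid in enumerate(individuals):
        calls[k] = alleles[iid].sum(axis=0)
        tracts[iid] = _autozygous_tracts(origins[iid], snp_map, chrom_slices)

    f_ped = pedigree_inbreeding(pedigree)
    truth = TruthSet(
        ancestral_freqs=np.asarray(
            founder_freqs if not isinstance(founder_freqs, Mapping) else np.nan
        ),
        population_freqs={},
        true_autozygous_tracts=tracts,
        true_f_ped=f_ped,
    )
    gm = GenotypeMatrix(individuals, snp_map, calls)
    return gm, truth


def _autozygous_tracts(
    origins: np.ndarray, snp_map: SnpMap, chrom_slices
) -> list[tuple[int, int, int]]:
    out = []
    ibd = origins[0] == origins[1]
    for c, sl in chrom_slices.items():
        mask = ibd[sl]
        pos = snp_map.pos_bp[sl]
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        for s_idx, e_idx in zip(edges[::2], edges[1::2]):
            start, end = int(pos[s_idx]), int(pos[e_idx - 1])
            if end > start:  # single-SNP tracts carry no length
                out.append((int(c), start, end))
    return out


# ---------------------------------------------------------------------------
# crosses and pedigree builders


def make_cross(
    gm: GenotypeMatrix,
    pops: Mapping[str, str],
    label: str,
    parent_a: str,
    parent_b: str,
    proportion: float,
    seed: int | np.random.Generator = None,
    n_offspring: int | None = None,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """F1 individuals from two parent populations' gene pools.

    Each offspring receives one gamete sampled from a random individual of
    each parent population (allele drawn per SNP from the parent's
    genotype).  ``n_offspring`` defaults to
    ``round(proportion * (n_a + n_b))``.  Returns the extended matrix and
    population assignment.
    """
    rng = np.random.default_rng(seed)
    ids_a = [i for i in gm.individuals if pops[i] == parent_a]
    ids_b = [i for i in gm.individuals if pops[i] == parent_b]
    if not ids_a:
        raise ValueError(f"unknown or empty parent population {parent_a!r}")
    if not ids_b:
        raise ValueError(f"unknown or empty parent population {parent_b!r}")
    if n_offspring is None:
        n_offspring = int(round(proportion * (len(ids_a) + len(ids_b))))
    pos = {iid: k for k, iid in enumerate(gm.individuals)}
    new_calls = np.empty((n_offspring, gm.n_snps), dtype=np.int8)
    for k in range(n_offspring):
        g = np.zeros(gm.n_snps, dtype=np.int8)
        miss = np.zeros(gm.n_snps, dtype=bool)
        for ids in (ids_a, ids_b):
            parent = gm.calls[pos[ids[rng.integers(len(ids))]]]
            m = parent == MISSING
            gam = (rng.random(gm.n_snps) < parent / 2.0).astype(np.int8)
            g += np.where(m, 0, gam)
            miss |= m
        new_calls[k] = np.where(miss, MISSING, g)
    new_ids = [f"{label}_{k}" for k in range(n_offspring)]
    all_calls = np.vstack([gm.calls, new_calls])
    out_gm = GenotypeMatrix(gm.individuals + new_ids, gm.snps, all_calls)
    out_pops = dict(pops)
    out_pops.update({i: label for i in new_ids})
    return out_gm, out_pops


def make_looped_pedigree(
    label: str,
    n_founders: int,
    n_generations: int,
    scheme: str,
    rng: np.random.Generator,
    n_per_generation: int | None = None,
) -> Pedigree:
    """Multi-generation pedigree whose loops create autozygosity.

    ``random`` mates random pairs each generation; ``full_sib_loop`` and
    ``half_sib_loop`` additionally force a share of full-/half-sib matings
    so inbreeding coefficients vary across the final generation.
    """
    if n_per_generation is None:
        n_per_generation = n_founders
    records: list[tuple[str, str | None, str | None]] = []
    founders = [f"{label}_F{k}" for k in range(n_founders)]
    records += [(f, None, None) for f in founders]
    prev = founders
    sibs: dict[str, tuple[str, str]] = {}
    for g in range(1, n_generations + 1):
        cur = []
        new_sibs = {}
        for k in range(n_per_generation):
            iid = f"{label}_G{g}_{k}"
            u = rng.random()
            s = d = None
            if scheme == "full_sib_loop" and u < 0.35:
                pairs = {}
                for child, par in sibs.items():
                    pairs.setdefault(par, []).append(child)
                full = [v for v in pairs.values() if len(v) >= 2]
                if full:
                    fam = full[rng.integers(len(full))]
                    s, d = fam[0], fam[1]
            elif scheme == "half_sib_loop" and u < 0.35:
                by_sire = {}
                for child, (cs, _) in sibs.items():
                    by_sire.setdefault(cs, []).append(child)
                half = [v for v in by_sire.values() if len(v) >= 2]
                if half:
                    fam = half[rng.integers(len(half))]
                    s, d = fam[0], fam[1]
            if s is None:
                i, j = rng.choice(len(prev), size=2, replace=False)
                s, d = prev[i], prev[j]
            records.append((iid, s, d))
            new_sibs[iid] = (s, d)
            cur.append(iid)
        # keep full sibs around so the sib-loop schemes can find them
        if scheme == "full_sib_loop":
            # force some shared parent pairs
            for k in range(0, n_per_generation - 1, 2):
                new_sibs[cur[k + 1]] = new_sibs[cur[k]]
                records[-n_per_generation + k + 1] = (
                    cur[k + 1], new_sibs[cur[k]][0], new_sibs[cur[k]][1]
                )
        prev, sibs = cur, new_sibs
    return Pedigree.from_records(records)


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SnpMap, dict[str, str], Pedigree, TruthSet]:
    """Full synthetic panel: map, diverged populations, pedigrees, crosses."""
    rng = np.random.default_rng(config.seed)
    snp_map = random_snp_map(
        config.n_chromosomes,
        config.chrom_length_bp,
        config.n_snps_per_chrom,
        rng,
    )
    n_snps = len(snp_map)
    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    pop_freqs: dict[str, np.ndarray] = {}
    matrices: list[GenotypeMatrix] = []
    pops: dict[str, str] = {}
    ped_records: list[tuple[str, str | None, str | None]] = []
    all_tracts: dict[str, list[tuple[int, int, int]]] = {}
    f_ped: dict[str, float] = {}

    for label, div_f, n_founders in config.populations:
        if div_f > 0:
            scale = (1.0 - div_f) / div_f
            freqs = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)
        else:
            freqs = ancestral.copy()
        pop_freqs[label] = freqs
        if config.pedigree_depth > 0:
            ped = make_looped_pedigree(
                label, n_founders, config.pedigree_depth, config.mating_scheme, rng
            )
        else:
            ped = Pedigree.from_records(
                [(f"{label}_F{k}", None, None) for k in range(n_founders)]
            )
        gm_pop, truth_pop = gene_drop(
            ped, snp_map, freqs, config.recomb_rate, rng,
            chrom_length_bp=config.chrom_length_bp,
        )
        matrices.append(gm_pop)
        pops.update({i: label for i in gm_pop.individuals})
        ped_records += [
            (i, *(p or "0" for p in ped.parents(i))) for i in ped.order
        ]
        all_tracts.update(truth_pop.true_autozygous_tracts)
        f_ped.update(truth_pop.true_f_ped)

    gm = GenotypeMatrix(
        [i for m in matrices for i in m.individuals],
        snp_map,
        np.vstack([m.calls for m in matrices]),
    )
    for label, pa, pb, prop in config.crosses:
        gm, pops = make_cross(gm, pops, label, pa, pb, prop, rng)

    pedigree = Pedigree.from_records(
        ped_records
        + [(i, None, None) for i in gm.individuals if i not in {r[0] for r in ped_records}]
    )
    truth = TruthSet(
        ancestral_freqs=ancestral,
        population_freqs=pop_freqs,
        true_autozygous_tracts=all_tracts,
        true_f_ped=f_ped,
    )
    return gm, snp_map, pops, pedigree, truth
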