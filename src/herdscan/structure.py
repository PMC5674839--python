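"""Population-structure statistics.

Observed heterozygosity, 1-IBS distances, method-of-moments IBD sharing
(PI_HAT), Torgerson classical MDS, Weir-Cockerham pairwise F_ST with a
percentile bootstrap CI, and Saitou-Nei neighbor joining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "NjTree",
    "observed_heterozygosity",
    "ibs_distance",
    "ibd_moments",
    "classical_mds",
    "wc_components",
    "pairwise_fst",
    "fst_matrix",
    "bootstrap_fst_ci",
    "neighbor_joining",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape inconsistent with labels")
        if np.max(np.abs(v - v.T), initial=0.0) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def observed_heterozygosity(individual_calls: np.ndarray) -> float:
    """1 - observed homozygous / non-missing loci."""
    calls = np.asarray(individual_calls)
    ok = calls != MISSING
    if not ok.any():
        raise ValueError("all calls missing: heterozygosity undefined")
    return float((calls[ok] == 1).mean())


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - average IBS similarity over jointly non-missing SNPs."""
    if gm.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    calls = gm.calls.astype(np.float64)
    n = gm.n_individuals
    dist = np.zeros((n, n))
    ok = gm.calls != MISSING
    for i in range(n):
        joint = ok[i] & ok[i + 1:]
        diff = np.abs(calls[i] - calls[i + 1:])
        n_joint = joint.sum(axis=1)
        zero = np.nonzero(n_joint == 0)[0]
        if len(zero):
            j = i + 1 + zero[0]
            raise ValueError(
                f"pair ({gm.individuals[i]}, {gm.individuals[j]}) shares "
                "no non-missing SNPs"
            )
        ibs = np.where(joint, 2.0 - diff, 0.0).sum(axis=1)
        d = 1.0 - ibs / (2.0 * n_joint)
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
    return DistanceMatrix(tuple(gm.individuals), dist)


def _ibs_expectations(gm: GenotypeMatrix) -> tuple[np.ndarray, ...]:
    """Per-SNP expected IBS-state probabilities given IBD state.

    Finite-sample corrected expectations based on allele counts in the
    merged sample (the same correction family PLINK applies for --genome).
    """
    calls = gm.calls
    ok = calls != MISSING
    cb = np.where(ok, calls, 0).sum(axis=0).astype(float)  # minor-allele count
    tot = 2.0 * ok.sum(axis=0)
    ca = tot - cb
    usable = (ca >= 2) & (cb >= 2) & (tot >= 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ca / tot
        q = cb / tot
        T = tot
        c3 = T / (T - 1) * T / (T - 2) * T / (T - 3)
        c2 = T / (T - 1) * T / (T - 2)
        aA = (ca - 1) / ca
        aA2 = (ca - 2) / ca
        aA3 = (ca - 3) / ca
        aB = (cb - 1) / cb
        aB2 = (cb - 2) / cb
        aB3 = (cb - 3) / cb
        e00 = 2 * p**2 * q**2 * aA * aB * c3
        e10 = 4 * p**3 * q * aA * aA2 * c3 + 4 * p * q**3 * aB * aB2 * c3
        e20 = (
            p**4 * aA * aA2 * aA3 * c3
            + q**4 * aB * aB2 * aB3 * c3
            + 4 * p**2 * q**2 * aA * aB * c3
        )
        e11 = 2 * p**2 * q * aA * c2 + 2 * p * q**2 * aB * c2
        e21 = (
            p**3 * aA * aA2 * c2
            + q**3 * aB * aB2 * c2
            + p**2 * q * aA * c2
            + p * q**2 * aB * c2
        )
    for e in (e00, e10, e20, e11, e21):
        e[~usable] = np.nan
    return e00, e10, e20, e11, e21, usable


def ibd_moments(
    gm: GenotypeMatrix, pairs: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Method-of-moments IBD-state probabilities and PI_HAT per pair.

    Allele frequencies come from the merged sample.  Z estimates are
    constrained to the probability simplex; ``pi_hat = Z1/2 + Z2``.
    """
    e00, e10, e20, e11, e21, usable = _ibs_expectations(gm)
    if not usable.any():
        raise ValueError("no polymorphic SNPs: IBD expectations undefined")
    calls = gm.calls
    ok = (calls != MISSING) & usable
    index = {iid: k for k, iid in enumerate(gm.individuals)}
    if pairs is None:
        ids = gm.individuals
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    rows = []
    for id1, id2 in pairs:
        i, j = index[id1], index[id2]
        joint = ok[i] & ok[j]
        diff = np.abs(calls[i].astype(int) - calls[j].astype(int))
        ibs0 = joint & (diff == 2)
        ibs1 = joint & (diff == 1)
        ibs2 = joint & (diff == 0)
        N0, N1, N2 = ibs0.sum(), ibs1.sum(), ibs2.sum()
        E00 = np.nansum(np.where(joint, e00, 0.0))
        E10 = np.nansum(np.where(joint, e10, 0.0))
        E20 = np.nansum(np.where(joint, e20, 0.0))
        E11 = np.nansum(np.where(joint, e11, 0.0))
        E21 = np.nansum(np.where(joint, e21, 0.0))
        n_joint = joint.sum()
        z0 = N0 / E00 if E00 > 0 else 0.0
        z1 = (N1 - z0 * E10) / E11 if E11 > 0 else 0.0
        z2 = (N2 - z0 * E20 - z1 * E21) / n_joint
        z = np.clip([z0, z1, z2], 0.0, None)
        s = z.sum()
        z = z / s if s > 0 else np.array([1.0, 0.0, 0.0])
        pi_hat = z[1] / 2.0 + z[2]
        rows.append((id1, id2, z[0], z[1], z[2], pi_hat))
    return pd.DataFrame(rows, columns=["id1", "id2", "Z0", "Z1", "Z2", "PI_HAT"])


def classical_mds(dist: DistanceMatrix, n_dims: int = 2) -> np.ndarray:
    """Torgerson scaling: double-center D^2, top non-negative eigenpairs."""
    n = len(dist.labels)
    if n_dims >= n:
        raise ValueError("n_dims must be smaller than the number of points")
    d2 = dist.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, n_dims))
    n_pos = 0
    for k in range(n_dims):
        if evals[k] > 0:
            coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
            n_pos += 1
    if n_pos < n_dims:
        warnings.warn(
            f"only {n_pos} non-negative eigenvalues; trailing dimensions are zero",
            stacklevel=2,
        )
    return coords


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def wc_components(
    gm: GenotypeMatrix, pops: Mapping[str, str], pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Weir-Cockerham variance components for a population pair.

    Returns ``(a, abc)`` where ``abc = a + b + c``; both are NaN where the
    components are undefined (a population with no data, or a single
    non-missing individual on average).
    """
    mask_a = np.array([pops[i] == pop_a for i in gm.individuals])
    mask_b = np.array([pops[i] == pop_b for i in gm.individuals])
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("both populations need at least 2 individuals")
    r = 2
    n_i = np.empty((2, gm.n_snps))
    p_i = np.empty((2, gm.n_snps))
    h_i = np.empty((2, gm.n_snps))
    for k, mask in enumerate((mask_a, mask_b)):
        sub = gm.calls[mask]
        ok = sub != MISSING
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, sub, 0).sum(axis=0) / (2.0 * n)
            h = ((sub == 1) & ok).sum(axis=0) / n
        n_i[k], p_i[k], h_i[k] = n, p, h
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    abc = a + b + c
    bad = (n_i.min(axis=0) < 1) | (nbar <= 1) | ~np.isfinite(abc)
    a = np.where(bad, np.nan, a)
    abc = np.where(bad, np.nan, abc)
    return a, abc


def pairwise_fst(
    gm: GenotypeMatrix, pops: Mapping[str, str], pop_a: str, pop_b: str
) -> float:
    """Multi-SNP Weir-Cockerham estimate: ratio of sums over defined SNPs."""
    a, abc = wc_components(gm, pops, pop_a, pop_b)
    defined = np.isfinite(abc) & (abc != 0.0)
    if not defined.any():
        raise ValueError("no SNP with defined variance components")
    return float(a[defined].sum() / abc[defined].sum())


def fst_matrix(
    gm: GenotypeMatrix,
    pops: Mapping[str, str],
    labels: Sequence[str] | None = None,
    clamp_negative: bool = False,
) -> DistanceMatrix:
    """Pairwise F_ST over all population pairs, optionally clamped at 0."""
    if labels is None:
        labels = list(dict.fromkeys(pops[i] for i in gm.individuals))
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            f = pairwise_fst(gm, pops, labels[i], labels[j])
            if clamp_negative:
                f = max(f, 0.0)
            m[i, j] = m[j, i] = f
    return DistanceMatrix(tuple(labels), m)


def bootstrap_fst_ci(
    gm: GenotypeMatrix,
    pops: Mapping[str, str],
    pair: tuple[str, str],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for pairwise F_ST, resampling SNP columns."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    a, abc = wc_components(gm, pops, pair[0], pair[1])
    defined = np.isfinite(abc)
    a, abc = a[defined], abc[defined]
    if len(a) == 0:
        raise ValueError("no SNP with defined variance components")
    point = a.sum() / abc.sum()
    reps = np.empty(n_boot)
    n = len(a)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        denom = abc[idx].sum()
        reps[k] = a[idx].sum() / denom if denom != 0 else 0.0
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    # degenerate resampling can exclude the point estimate; widen to include it
    return float(min(lo, point)), float(max(hi, point))


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class NjTree:
    """Unrooted tree: adjacency of node -> [(neighbor, branch_length)]."""

    leaves: tuple[str, ...]
    adjacency: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def to_newick(self) -> str:
        # root the traversal at the last internal node (or a leaf for n<=2)
        internal = [n for n in self.adjacency if n not in self.leaves]
        root = internal[-1] if internal else self.leaves[0]

        def sub(node: str, parent: str | None) -> str:
            children = [(n, l) for n, l in self.adjacency[node] if n != parent]
            if not children:
                return node
            inner = ",".join(f"{sub(n, node)}:{l:.10g}" for n, l in children)
            return f"({inner}){node if node in self.leaves else ''}"

        return sub(root, None) + ";"

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (smaller side), for topology checks."""
        out = set()
        all_leaves = set(self.leaves)
        for node, nbrs in self.adjacency.items():
            for other, _ in nbrs:
                if node < other:
                    side = self._leaves_beyond(other, node)
                    if 1 < len(side) < len(self.leaves) - 1:
                        comp = all_leaves - side
                        canon = min(side, comp, key=lambda s: (len(s), sorted(s)))
                        out.add(frozenset(canon))
        return out

    def _leaves_beyond(self, node: str, parent: str) -> set[str]:
        found = set()
        stack = [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if cur in self.leaves:
                found.add(cur)
            for n, _ in self.adjacency[cur]:
                if n != par:
                    stack.append((n, cur))
        return found

    def path_length(self, a: str, b: str) -> float:
        dist = {a: 0.0}
        stack = [a]
        while stack:
            cur = stack.pop()
            for n, l in self.adjacency[cur]:
                if n not in dist:
                    dist[n] = dist[cur] + l
                    stack.append(n)
        return dist[b]


def neighbor_joining(dist: DistanceMatrix) -> NjTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties on the Q criterion go to the lexicographically smallest label
    pair.  Negative branch lengths are clamped to zero with the deficit
    moved onto the sister branch.
    """
    labels = list(dist.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    tree = NjTree(leaves=tuple(labels), adjacency={l: [] for l in labels})

    def connect(a: str, b: str, length: float) -> None:
        tree.adjacency[a].append((b, length))
        tree.adjacency[b].append((a, length))

    if n == 2:
        connect(labels[0], labels[1], float(dist.values[0, 1]))
        return tree

    d = dist.values.astype(float).copy()
    active = list(labels)
    next_internal = 0
    while len(active) > 3:
        m = len(active)
        row = d.sum(axis=1)
        q = (m - 2) * d - row[:, None] - row[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                key = (q[i, j], *sorted((active[i], active[j])))
                if best is None or key < best[0:3]:
                    best = (q[i, j], *sorted((active[i], active[j])), i, j)
        i, j = best[3], best[4]
        li, lj = active[i], active[j]
        bi = 0.5 * d[i, j] + (row[i] - row[j]) / (2.0 * (m - 2))
        bj = d[i, j] - bi
        # clamp negatives, moving the deficit to the sister branch
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bj = max(bj, 0.0)
        node = f"_nj{next_internal}"
        next_internal += 1
        tree.adjacency[node] = []
        connect(node, li, bi)
        connect(node, lj, bj)
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [node]

    # final three nodes: three-point formulas
    a, b, c = active
    ia, ib, ic = 0, 1, 2
    la = 0.5 * (d[ia, ib] + d[ia, ic] - d[ib, ic])
    lb = 0.5 * (d[ia, ib] + d[ib, ic] - d[ia, ic])
    lc = 0.5 * (d[ia, ic] + d[ib, ic] - d[ia, ib])
    node = f"_nj{next_internal}"
    tree.adjacency[node] = []
    for leaf, length in ((a, la), (b, lb), (c, lc)):
        connect(node, leaf, max(length, 0.0))
    return tree
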