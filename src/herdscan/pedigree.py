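"""Pedigree graph, recursive kinship, Wright's inbreeding and completeness."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["Pedigree", "pedigree_inbreeding", "pci_5g"]

UNKNOWN = "0"


@dataclass
class Pedigree:
    """Individual -> (sire, dam) graph; ``"0"``/None denotes an unknown parent."""

    sire: dict[str, str | None]
    dam: dict[str, str | None]
    order: list[str] = field(default_factory=list)  # topological, parents first

    def __post_init__(self) -> None:
        def norm(p):
            return None if p in (None, UNKNOWN, "") else str(p)

        self.sire = {str(k): norm(v) for k, v in self.sire.items()}
        self.dam = {str(k): norm(v) for k, v in self.dam.items()}
        # parents referenced but without their own record are founders
        for table in (self.sire, self.dam):
            for p in list(table.values()):
                if p is not None and p not in self.sire:
                    self.sire[p] = None
                    self.dam[p] = None
        self.order = self._toposort()
        self._depth = {iid: k for k, iid in enumerate(self.order)}
        self._kinship_cache: dict[tuple[str, str], float] = {}

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        sire, dam = {}, {}
        for iid, s, d in records:
            sire[iid], dam[iid] = s, d
        return cls(sire, dam)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = list(df.columns[:3])
        return cls.from_records(
            (str(r[cols[0]]), str(r[cols[1]]), str(r[cols[2]]))
            for _, r in df.iterrows()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.order,
                "sire": [self.sire[i] or UNKNOWN for i in self.order],
                "dam": [self.dam[i] or UNKNOWN for i in self.order],
            }
        )

    @property
    def individuals(self) -> list[str]:
        return list(self.order)

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        return self.sire[iid], self.dam[iid]

    def is_founder(self, iid: str) -> bool:
        return self.sire[iid] is None and self.dam[iid] is None

    def _toposort(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done
        for root in self.sire:
            if root in state:
                continue
            stack = [(root, False)]
            path = []
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    path.pop()
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    cyc = path[path.index(node):] + [node]
                    raise ValueError(f"pedigree cycle: {' -> '.join(cyc)}")
                state[node] = 0
                path.append(node)
                stack.append((node, True))
                for p in (self.sire[node], self.dam[node]):
                    if p is not None and state.get(p) != 1:
                        stack.append((p, False))
        return order

    # -- kinship ---------------------------------------------------------

    def kinship(self, a: str | None, b: str | None) -> float:
        """Coefficient of kinship; unknown individuals contribute 0."""
        if a is None or b is None:
            return 0.0
        if self._depth[a] > self._depth[b]:
            a, b = b, a
        key = (a, b)
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached
        # iterative post-order on the standard recursion to avoid deep stacks
        stack = [key]
        while stack:
            x, y = stack[-1]
            if (x, y) in self._kinship_cache:
                stack.pop()
                continue
            if x == y:
                s, d = self.sire[x], self.dam[x]
                dep = self._norm_pair(s, d)
                if dep is not None and dep not in self._kinship_cache:
                    stack.append(dep)
                    continue
                fsd = self._kinship_cache[dep] if dep is not None else 0.0
                self._kinship_cache[(x, y)] = 0.5 * (1.0 + fsd)
                stack.pop()
                continue
            # recurse through the later-born individual's parents
            s, d = self.sire[y], self.dam[y]
            deps = []
            for p in (s, d):
                dep = self._norm_pair(x, p)
                if dep is not None and dep not in self._kinship_cache:
                    deps.append(dep)
            if deps:
                stack.extend(deps)
                continue
            v = 0.0
            for p in (s, d):
                dep = self._norm_pair(x, p)
                v += 0.5 * (self._kinship_cache[dep] if dep is not None else 0.0)
            self._kinship_cache[(x, y)] = v
            stack.pop()
        return self._kinship_cache[key]

    def _norm_pair(self, a: str | None, b: str | None):
        if a is None or b is None:
            return None
        if self._depth[a] > self._depth[b]:
            a, b = b, a
        return (a, b)

    def inbreeding(self, iid: str) -> float:
        """Wright's F: kinship of the parents (0 for founders)."""
        return self.kinship(self.sire[iid], self.dam[iid])


def pedigree_inbreeding(pedigree: Pedigree) -> dict[str, float]:
    """Wright's inbreeding coefficient for every individual in the pedigree."""
    return {iid: pedigree.inbreeding(iid) for iid in pedigree.order}


def pci_5g(pedigree: Pedigree, individual: str, depth: int = 5) -> float:
    """Fraction of ancestor slots known over ``depth`` generations.

    There are sum(2**k, k=1..depth) slots (62 for depth 5); a slot counts
    as known only if every link on the path to it is recorded.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")

    def known_slots(iid: str | None, d: int) -> int:
        if d == 0 or iid is None:
            return 0
        total = 0
        for p in pedigree.parents(iid):
            if p is not None:
                total += 1 + known_slots(p, d - 1)
        return total

    n_slots = 2 ** (depth + 1) - 2
    return known_slots(individual, depth) / n_slots
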