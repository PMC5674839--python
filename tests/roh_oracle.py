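"""Independent brute-force ROH enumerator used as a test oracle.

Tests every (i, j) sub-run against all constraints directly and keeps
runs not properly contained in another qualifying run.  Deliberately
separate from the package implementation.
"""

import numpy as np

from herdscan.genotype_io import MISSING


def brute_force_roh(calls, positions, params):
    n = len(calls)
    het = np.cumsum(np.concatenate([[0], np.asarray(calls) == 1]))
    mis = np.cumsum(np.concatenate([[0], np.asarray(calls) == MISSING]))
    gaps = np.diff(positions) / 1000.0
    # furthest index reachable from i without an oversized gap
    far = np.empty(n, dtype=int)
    far[-1] = n - 1
    for i in range(n - 2, -1, -1):
        far[i] = i if gaps[i] > params.max_gap_kb else far[i + 1]
    best_j = {}  # i -> largest qualifying j
    for i in range(n):
        for j in range(i + params.min_snps - 1, far[i] + 1):
            # het/missing counts grow with j: once over budget, no longer j works
            if het[j + 1] - het[i] > params.max_het:
                break
            if mis[j + 1] - mis[i] > params.max_missing:
                break
            span_kb = (positions[j] - positions[i]) / 1000.0
            n_snps = j - i + 1
            if (
                span_kb >= params.min_length_kb
                and span_kb / n_snps <= params.min_density_kb_per_snp
            ):
                best_j[i] = j
    # (i, j) is maximal iff j is the largest qualifying end for i and no
    # earlier start reaches j or beyond
    maximal = []
    prefix_max = -1
    for i in sorted(best_j):
        if best_j[i] > prefix_max:
            maximal.append((i, best_j[i]))
        prefix_max = max(prefix_max, best_j[i])
    return {
        (int(positions[i]), int(positions[j]), j - i + 1) for i, j in maximal
    }


def random_roh_instance(rng, n=300, span_bp=25_000_000, p_het=0.05, p_miss=0.03):
    positions = np.sort(rng.choice(np.arange(1, span_bp), size=n, replace=False))
    p_hom = (1.0 - p_het - p_miss) / 2.0
    calls = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8),
        size=n,
        p=[p_hom, p_het, p_hom, p_miss],
    )
    return calls, positions
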