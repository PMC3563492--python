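"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: the Fst oracle
enumerates categories with plain Python floats, the pairing oracle assigns
bases one by one, and the BH oracle is the textbook sort/compare/cummin
step-up.
"""

from __future__ import annotations

import numpy as np


def fst_brute_force(x: np.ndarray, y: np.ndarray, nx: int, ny: int):
    """Plain-Python Ht/Hs/Fst over categories."""
    t = [(xi * nx + yi * ny) / (nx + ny) for xi, yi in zip(x, y)]
    Ht = 1.0 - sum(ti * ti for ti in t)
    Hs = ((1.0 - sum(xi * xi for xi in x)) * nx
          + (1.0 - sum(yi * yi for yi in y)) * ny) / (nx + ny)
    f = 0.0 if Ht == 0 else (Ht - Hs) / Ht
    return Ht, Hs, f


def base_assignment(areas: list[tuple[str, int, int]],
                    chrom_len: int) -> np.ndarray:
    """Per-base gene-area index (-1 for uncovered bases)."""
    arr = np.full(chrom_len, -1, dtype=np.int64)
    for idx, (_, s, e) in enumerate(areas):
        arr[s:e] = idx
    return arr


def pair_brute_force(cnv_start: int, cnv_end: int,
                     areas: list[tuple[str, int, int]],
                     assignment: np.ndarray) -> set[str]:
    """Base-by-base pairing oracle for one CNV on one chromosome.

    Counts, for every area, the CNV bases assigned to it, then applies:
    pair any area whose every base lies inside the CNV; pair the single
    containing area; pair the area holding strictly more than half of the
    CNV's in-area bases, or the lower-coordinate one on an exact half split.
    """
    slice_ = assignment[cnv_start:cnv_end]
    covered = slice_[slice_ >= 0]
    counts = np.bincount(covered, minlength=len(areas))
    per_area = {i: int(c) for i, c in enumerate(counts) if c > 0}
    total = sum(per_area.values())
    paired: set[int] = set()
    for i in per_area:
        _, s, e = areas[i]
        if per_area[i] == e - s:  # every base of the area is inside the CNV
            paired.add(i)
    if len(per_area) == 1:
        paired.add(next(iter(per_area)))
    elif per_area:
        best = max(per_area.values())
        winners = sorted(i for i, n in per_area.items() if n == best)
        if 2 * best > total:
            paired.add(winners[0])
        elif 2 * best == total:
            paired.add(min(winners, key=lambda i: areas[i][1]))
    return {areas[i][0] for i in paired}


def bh_step_up(pvals: np.ndarray, q: float):
    """Textbook Benjamini-Hochberg: sort, compare to q*i/m, cummin back."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    qvals_sorted = ranked * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(qvals_sorted[::-1])[::-1]
    qvals_sorted = np.minimum(qvals_sorted, 1.0)
    qvals = np.empty(m)
    qvals[order] = qvals_sorted
    thresh = q * np.arange(1, m + 1) / m
    below = ranked <= thresh
    k = np.nonzero(below)[0].max() + 1 if below.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return qvals, reject


def hypergeom_enumerate(M: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(M, n) draws."""
    from itertools import combinations

    universe = list(range(M))
    special = set(range(K))
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total
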