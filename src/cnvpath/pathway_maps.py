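"""Per-pathway CNV-gene frequency maps and pathway-level differentiation.

A frequency map has one row per CNV-gene pair and one column per population
(YRI, CEU, ASN) holding the CNV's polymorphism frequency; rows are ordered
by complete-linkage hierarchical clustering on Euclidean distances, the
ordering used for the heatmap display.  A pathway is called differentiated
at a level (5% or 1%) when at least one of its CNV-gene pairs has an Fst at
or above the empirical cutoff of any population pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .gene_areas import CnvGenePair

MAP_COLUMNS = ("YRI", "CEU", "ASN")
LEVELS = ("p05", "p01")
_LEVEL_TAIL = {"p05": 0.05, "p01": 0.01}


@dataclass
class PathwayDifferentiation:
    pathway: str
    level: str  # none | p05 | p01
    differentiated_pairs: list[tuple[str, str, str, float]]  # cnv, gene, pop-pair, fst
    fraction_differentiated: float
    n_pairs: int


def pathway_pairs(pathway_genes: set[str],
                  pairs: Sequence[CnvGenePair]) -> list[CnvGenePair]:
    return [p for p in pairs if p.gene_id in pathway_genes]


def frequency_map(pathway_name: str, pathway_genes: set[str],
                  pairs: Sequence[CnvGenePair],
                  freq_table: pd.DataFrame) -> pd.DataFrame:
    """Rows ``cnv_id|gene_id``, columns YRI/CEU/ASN, values polymorphism
    frequency of the pair's CNV.  Pathways with no pairs give an empty map."""
    rows, labels = [], []
    for p in pathway_pairs(pathway_genes, pairs):
        if p.cnv_id not in freq_table.index:
            continue
        f = freq_table.loc[p.cnv_id]
        rows.append([f[c] for c in MAP_COLUMNS])
        labels.append(f"{p.cnv_id}|{p.gene_id}")
    df = pd.DataFrame(rows, index=labels, columns=list(MAP_COLUMNS),
                      dtype=float)
    df.index.name = pathway_name
    return df


def cluster_rows(fmap: pd.DataFrame) -> np.ndarray:
    """Leaf order of complete-linkage clustering on Euclidean row distances.

    Fewer than two rows gives the identity order.  scipy's linkage is
    deterministic for a given input, ties resolved by input order of the
    condensed distance matrix.
    """
    n = len(fmap)
    if n < 2:
        return np.arange(n)
    d = pdist(fmap.to_numpy(dtype=float), metric="euclidean")
    Z = hierarchy.linkage(d, method="complete")
    return np.asarray(hierarchy.leaves_list(Z))


def pathway_differentiation(pathway_name: str, pathway_genes: set[str],
                            pairs: Sequence[CnvGenePair],
                            fst_df: pd.DataFrame,
                            cutoffs: Mapping[tuple[str, float], float]
                            ) -> PathwayDifferentiation:
    """Differentiation call for one pathway.

    ``cutoffs`` maps (population-pair string like "CEU_YRI", tail) to the
    empirical Fst cutoff.  A pair counts as differentiated at a level when
    its CNV's Fst is >= the cutoff for any population pair (closed
    boundary); the pathway's level is the strongest attained by any pair.
    """
    ppairs = pathway_pairs(pathway_genes, pairs)
    diff: list[tuple[str, str, str, float]] = []
    best = "none"
    n_diff = 0
    for p in ppairs:
        if p.cnv_id not in fst_df.index:
            continue
        pair_level = "none"
        for col in fst_df.columns:
            pop_pair = col.removeprefix("fst_")
            val = fst_df.loc[p.cnv_id, col]
            if np.isnan(val):
                continue
            for level in LEVELS:
                cut = cutoffs.get((pop_pair, _LEVEL_TAIL[level]))
                if cut is not None and val >= cut and _stronger(level, pair_level):
                    pair_level = level
            cut05 = cutoffs.get((pop_pair, 0.05))
            if cut05 is not None and val >= cut05:
                diff.append((p.cnv_id, p.gene_id, pop_pair, float(val)))
        if pair_level != "none":
            n_diff += 1
            if _stronger(pair_level, best):
                best = pair_level
    frac = n_diff / len(ppairs) if ppairs else 0.0
    return PathwayDifferentiation(pathway_name, best, diff, frac, len(ppairs))


def _stronger(a: str, b: str) -> bool:
    order = {"none": 0, "p05": 1, "p01": 2}
    return order[a] > order[b]


def differentiation_summary(pathways: Mapping[str, set[str]],
                            pairs: Sequence[CnvGenePair],
                            fst_df: pd.DataFrame,
                            cutoffs: Mapping[tuple[str, float], float]
                            ) -> pd.DataFrame:
    rows = []
    for name, genes in pathways.items():
        d = pathway_differentiation(name, genes, pairs, fst_df, cutoffs)
        rows.append((name, d.level, d.n_pairs, d.fraction_differentiated))
    return pd.DataFrame(rows, columns=["pathway", "level", "n_pairs",
                                       "fraction_differentiated"])


def venn_partition(flags: Mapping[str, set[str]]) -> dict[str, int]:
    """Seven-region partition of items by the population pairs flagging them.

    ``flags`` maps an item (pathway or gene) to the set of population-pair
    strings in which it is differentiated; items with an empty set are
    ignored.  Region keys are sorted '&'-joined pair names.
    """
    pair_names = sorted({p for s in flags.values() for p in s})
    if len(pair_names) > 3:
        raise ValueError("expected at most three population pairs")
    regions: dict[str, int] = {}
    from itertools import combinations

    for r in (1, 2, 3):
        for combo in combinations(pair_names, r):
            regions["&".join(combo)] = 0
    for item, s in flags.items():
        if not s:
            continue
        key = "&".join(sorted(s))
        regions[key] = regions.get(key, 0) + 1
    return regions


def per_pair_flags(items: Mapping[str, set[str]],
                   pairs: Sequence[CnvGenePair],
                   fst_df: pd.DataFrame,
                   cutoffs: Mapping[tuple[str, float], float],
                   tail: float = 0.05) -> dict[str, set[str]]:
    """For each pathway, the population pairs with >= 1 differentiated
    CNV-gene pair at ``tail``; input to ``venn_partition``."""
    out: dict[str, set[str]] = {}
    for name, genes in items.items():
        hit: set[str] = set()
        for p in pathway_pairs(genes, pairs):
            if p.cnv_id not in fst_df.index:
                continue
            for col in fst_df.columns:
                pop_pair = col.removeprefix("fst_")
                cut = cutoffs.get((pop_pair, tail))
                val = fst_df.loc[p.cnv_id, col]
                if cut is not None and not np.isnan(val) and val >= cut:
                    hit.add(pop_pair)
        out[name] = hit
    return out


def render_heatmap(fmap: pd.DataFrame, path: str, order=None) -> None:
    """Optional thin rendering layer; requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if order is None:
        order = cluster_rows(fmap)
    data = fmap.to_numpy(dtype=float)[order]
    fig, ax = plt.subplots(figsize=(4, max(2, 0.25 * len(fmap))))
    im = ax.imshow(data, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(fmap.columns)), fmap.columns)
    ax.set_yticks(range(len(fmap)), [fmap.index[i] for i in order])
    fig.colorbar(im, ax=ax, label="polymorphism frequency")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
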