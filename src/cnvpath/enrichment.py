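"""Size-dependent permutation test of pathway enrichment for CNV-gene overlap.

The observed statistic for a pathway is the number of distinct pathway genes
paired with at least one CNV.  The null is built by permuting the truncated
CNVs on the pseudo-transcriptome, keeping the number and the size of CNVs
per chromosome, and re-pairing every replicate under the same rules R1-R3.
Gene and CNV sizes therefore enter the null directly: a long gene is hit by
a uniformly placed CNV more often than a short one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CnvRecord, PathwayCollection
from .gene_areas import (CnvGenePair, PseudoTranscriptome, TruncatedCnv,
                         pair_placements, pair_truncated)
from .mechanisms import proportion_test


@dataclass
class EnrichmentResult:
    pathway: str
    n_genes_total: int
    n_genes_cnv: int
    null_counts: np.ndarray
    p_enrich: float
    p_deplete: float


def observed_statistic(pairs: Sequence[CnvGenePair],
                       pathway_genes: set[str],
                       annotated_genes: set[str] | None = None) -> int:
    """Distinct pathway genes appearing in at least one CNV-gene pair.

    Pathway genes absent from the annotation (when given) are dropped from
    the count and a warning is issued; ``effective_pathway`` returns the
    corresponding reduced gene set.
    """
    genes = effective_pathway(pathway_genes, annotated_genes)
    hit = {p.gene_id for p in pairs}
    return len(genes & hit)


def effective_pathway(pathway_genes: set[str],
                      annotated_genes: set[str] | None) -> set[str]:
    if annotated_genes is None:
        return set(pathway_genes)
    dropped = pathway_genes - annotated_genes
    if dropped:
        warnings.warn(f"{len(dropped)} pathway gene(s) absent from the "
                      "annotation; dropped from the test", stacklevel=3)
    return pathway_genes & annotated_genes


def _chrom_rng(seed: int, replicate: int, chrom_index: int) -> np.random.Generator:
    # counter-based substream: placements do not depend on iteration order
    return np.random.Generator(np.random.Philox(
        key=np.uint64(seed), counter=[0, 0, replicate, chrom_index]))


def permute_cnvs(truncated: Sequence[TruncatedCnv], pt: PseudoTranscriptome,
                 seed: int, replicate: int = 0) -> dict[str, tuple[list[str], np.ndarray, np.ndarray]]:
    """One permutation replicate: uniform placement on the concatenated axis.

    Each truncated CNV is placed as one contiguous block of its total size,
    independently and uniformly on [0, L - size] of its own chromosome.
    Returns per chromosome (cnv_ids, starts, sizes).
    """
    by_chrom: dict[str, list[TruncatedCnv]] = {}
    for t in truncated:
        by_chrom.setdefault(t.chrom, []).append(t)
    chrom_order = {c: i for i, c in enumerate(pt.chroms)}
    out = {}
    for chrom, ts in by_chrom.items():
        L = pt.length(chrom)
        too_big = [t.cnv_id for t in ts if t.total_size > L]
        if too_big:
            raise ValueError(
                f"CNV size exceeds pseudo-transcriptome length on {chrom}: "
                f"{too_big[:5]}")
        sizes = np.array([t.total_size for t in ts], dtype=np.int64)
        rng = _chrom_rng(seed, replicate, chrom_order[chrom])
        starts = rng.integers(0, L - sizes + 1)
        out[chrom] = ([t.cnv_id for t in ts], starts.astype(np.int64), sizes)
    return out


def _genes_hit(placement, pt: PseudoTranscriptome) -> set[str]:
    hit: set[str] = set()
    for chrom, (ids, starts, sizes) in placement.items():
        for p in pair_placements(ids, chrom, starts, sizes, pt):
            hit.add(p.gene_id)
    return hit


def enrichment_test(pathways: PathwayCollection | Mapping[str, set[str]],
                    truncated: Sequence[TruncatedCnv],
                    pt: PseudoTranscriptome,
                    n_perm: int = 1000, seed: int = 0,
                    flank_used: int = 0) -> list[EnrichmentResult]:
    """Score every pathway against one shared stream of permutation replicates.

    p_enrich = (1 + #{null >= observed}) / (n_perm + 1), and p_deplete the
    analogue with <=; the pseudo-count keeps p-values strictly positive.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sets = pathways.pathways if isinstance(pathways, PathwayCollection) else dict(pathways)
    annotated = set(pt.all_gene_ids())
    gene_index = {g: i for i, g in enumerate(sorted(annotated))}
    n_genes = len(gene_index)

    members: dict[str, np.ndarray] = {}
    observed: dict[str, int] = {}
    obs_pairs = pair_truncated(truncated, pt, flank_used)
    obs_hit = {p.gene_id for p in obs_pairs}
    for name, genes in sets.items():
        eff = effective_pathway(genes, annotated)
        idx = np.array(sorted(gene_index[g] for g in eff), dtype=np.int64)
        members[name] = idx
        observed[name] = len(eff & obs_hit)

    null = np.zeros((n_perm, len(sets)), dtype=np.int32)
    names = list(sets)
    mask = np.zeros(n_genes, dtype=bool)
    for r in range(n_perm):
        placement = permute_cnvs(truncated, pt, seed, replicate=r)
        mask[:] = False
        for g in _genes_hit(placement, pt):
            mask[gene_index[g]] = True
        for j, name in enumerate(names):
            null[r, j] = int(mask[members[name]].sum())

    results = []
    for j, name in enumerate(names):
        obs = observed[name]
        nc = null[:, j]
        p_enr = (1 + int((nc >= obs).sum())) / (n_perm + 1)
        p_dep = (1 + int((nc <= obs).sum())) / (n_perm + 1)
        results.append(EnrichmentResult(name, len(members[name]), obs,
                                        nc.copy(), p_enr, p_dep))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pathway, r.n_genes_cnv, r.n_genes_total, r.p_enrich, r.p_deplete)
         for r in results],
        columns=["pathway", "gene_cnv", "gene_total", "p_enrich", "p_deplete"])


def class_composition(results: Sequence[EnrichmentResult],
                      pathways: PathwayCollection, alpha: float,
                      tail: str = "enrich") -> pd.DataFrame:
    """Source/category composition of significant pathways vs the baseline.

    Mirrors the bar-chart comparison of database class composition among
    enriched (or depleted) pathways against all pathways.
    """
    if tail not in ("enrich", "deplete"):
        raise ValueError("tail must be 'enrich' or 'deplete'")
    pick = [r.pathway for r in results
            if (r.p_enrich if tail == "enrich" else r.p_deplete) < alpha]
    rows = []
    all_names = list(pathways.pathways)
    for names, which in ((pick, "significant"), (all_names, "baseline")):
        counts: dict[tuple[str, str], int] = {}
        for n in names:
            key = (pathways.source.get(n, "unknown"),
                   pathways.category.get(n, ""))
            counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        for (src, cat), k in sorted(counts.items()):
            rows.append((which, src, cat, k, k / total if total else np.nan))
    return pd.DataFrame(rows, columns=["set", "source", "category",
                                       "count", "fraction"])


def subset_proportion_shift(subset: Sequence[CnvRecord],
                            reference: Sequence[CnvRecord],
                            attribute: str = "mechanism") -> pd.DataFrame:
    """Per-class fold change and z-test of a CNV subset vs all CNVs.

    ``attribute`` is ``mechanism`` (VNTR/NAHR/TEI/NHR) or ``cnv_type``
    (gain/loss; CNVs labelled both or unknown are excluded from the
    gain/loss comparison).
    """
    if attribute not in ("mechanism", "cnv_type"):
        raise ValueError(f"unknown attribute {attribute!r}")
    exclude = {"unknown"} | ({"both"} if attribute == "cnv_type" else set())

    def labels(recs):
        return [getattr(c, attribute) for c in recs
                if getattr(c, attribute) not in exclude]

    sub, ref = labels(subset), labels(reference)
    classes = sorted(set(ref) | set(sub))
    rows = []
    for cls in classes:
        k1, n1 = sub.count(cls), len(sub)
        k2, n2 = ref.count(cls), len(ref)
        if n1 == 0 or n2 == 0:
            rows.append((cls, k1, n1, k2, n2, np.nan, np.nan, np.nan))
            continue
        cmp = proportion_test(k1, n1, k2, n2)
        rows.append((cls, k1, n1, k2, n2, cmp.fold, cmp.z, cmp.p))
    return pd.DataFrame(rows, columns=["class", "k_subset", "n_subset",
                                       "k_all", "n_all", "fold", "z", "p"])
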