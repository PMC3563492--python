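"""CNV-expression association and functional CNV-gene pairs.

For every CNV-gene pair linked at a 1 Mb flank, two tests relate a gene's
expression to the CNV's copy-number states within one population:

* dosage effect — simple linear regression of expression on numeric CN,
  two-sided t-test of the slope;
* allelic effect — one-way ANOVA (or Kruskal-Wallis) with the CN state as
  a categorical factor, which can detect non-monotone patterns the linear
  slope misses.

P-values are corrected per population and per test family with the
Benjamini-Hochberg step-up; a pair is *functional* when either corrected
test passes the FDR threshold (configurable).  Functional genes are then
scored for pathway over-representation with an upper-tail hypergeometric
test, and intersected with the population-differentiation calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix, GenotypeMatrix
from .gene_areas import CnvGenePair


@dataclass
class TestOutcome:
    p: float | None
    sign: int = 0  # slope sign for the dosage test
    n: int = 0
    reason: str = ""  # non-empty when the test was skipped


def dosage_test(expr: np.ndarray, cn: np.ndarray) -> TestOutcome:
    """Linear regression of expression on copy number; two-sided slope p."""
    expr = np.asarray(expr, dtype=float)
    cn = np.asarray(cn, dtype=float)
    n = expr.size
    if n < 3:
        return TestOutcome(None, 0, n, "fewer than 3 samples")
    if np.unique(cn).size < 2:
        return TestOutcome(None, 0, n, "constant copy number")
    if np.allclose(expr, expr[0]):
        return TestOutcome(1.0, 0, n)
    res = stats.linregress(cn, expr)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    sign = 0 if res.slope == 0 else (1 if res.slope > 0 else -1)
    return TestOutcome(p, sign, n)


def allelic_test(expr: np.ndarray, cn: np.ndarray, min_per_state: int = 3,
                 method: str = "anova") -> TestOutcome:
    """Categorical test of expression across CN states.

    States with fewer than ``min_per_state`` samples are dropped; at least
    two eligible states are required.
    """
    expr = np.asarray(expr, dtype=float)
    cn = np.asarray(cn)
    groups = [expr[cn == s] for s in np.unique(cn)]
    groups = [g for g in groups if g.size >= min_per_state]
    if len(groups) < 2:
        return TestOutcome(None, 0, int(expr.size),
                           "fewer than 2 CN states with enough samples")
    n = int(sum(g.size for g in groups))
    if all(np.allclose(g, groups[0][0]) for g in groups):
        return TestOutcome(1.0, 0, n)
    if method == "anova":
        stat = stats.f_oneway(*groups)
    elif method == "kruskal":
        stat = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(stat.pvalue)
    if np.isnan(p):
        p = 1.0
    return TestOutcome(p, 0, n)


def bh_fdr(pvals: Sequence[float] | np.ndarray,
           q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (monotone q-values, reject mask)."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def associate(expr: ExpressionMatrix, genotypes: GenotypeMatrix,
              pairs: Sequence[CnvGenePair], population: str,
              q: float = 0.05, min_per_state: int = 3,
              allelic_method: str = "anova",
              combine: str = "min") -> pd.DataFrame:
    """Run both tests for every testable pair in one population.

    Returns one row per pair with p_dosage, p_allelic, the per-family BH
    q-values, and the functional flag under the chosen combination rule
    (``min``: either test passes its own family's FDR; ``dosage_only`` /
    ``allelic_only``).
    """
    if combine not in ("min", "dosage_only", "allelic_only"):
        raise ValueError(f"unknown combine rule {combine!r}")
    samples = [s for s in expr.samples_of(population)
               if s in genotypes.cn.columns]
    expr_mat = expr.values[samples].to_numpy(dtype=float)
    geno_mat = genotypes.cn[samples].astype(float).to_numpy()
    gene_row = {g: i for i, g in enumerate(expr.values.index)}
    cnv_row = {c: i for i, c in enumerate(genotypes.cn.index)}
    rows = []
    for pr in pairs:
        gi, ci = gene_row.get(pr.gene_id), cnv_row.get(pr.cnv_id)
        if gi is None or ci is None:
            continue
        g = geno_mat[ci]
        ok = ~np.isnan(g)
        ev = expr_mat[gi][ok]
        gv = g[ok].astype(int)
        dos = dosage_test(ev, gv)
        alle = allelic_test(ev, gv, min_per_state=min_per_state,
                            method=allelic_method)
        rows.append({"cnv_id": pr.cnv_id, "gene_id": pr.gene_id,
                     "population": population, "n_used": int(ok.sum()),
                     "p_dosage": dos.p, "slope_sign": dos.sign,
                     "dosage_skip": dos.reason,
                     "p_allelic": alle.p, "allelic_skip": alle.reason})
    df = pd.DataFrame(rows)
    if df.empty:
        for col in ("q_dosage", "q_allelic", "functional"):
            df[col] = []
        return df
    for test in ("dosage", "allelic"):
        pcol, qcol, rcol = f"p_{test}", f"q_{test}", f"reject_{test}"
        tested = df[pcol].notna()
        df[qcol] = np.nan
        df[rcol] = False
        if tested.any():
            qv, rej = bh_fdr(df.loc[tested, pcol].to_numpy(), q)
            df.loc[tested, qcol] = qv
            df.loc[tested, rcol] = rej
    if combine == "min":
        df["functional"] = df["reject_dosage"] | df["reject_allelic"]
    elif combine == "dosage_only":
        df["functional"] = df["reject_dosage"]
    else:
        df["functional"] = df["reject_allelic"]
    return df


def functional_pairs(assoc: pd.DataFrame) -> set[tuple[str, str]]:
    """(cnv_id, gene_id) pairs flagged functional in an association table."""
    if assoc.empty:
        return set()
    sel = assoc[assoc["functional"]]
    return set(zip(sel["cnv_id"], sel["gene_id"]))


def hypergeometric_pathway_enrichment(functional_genes: set[str],
                                      pathway_genes: set[str],
                                      universe: set[str]) -> float:
    """Upper-tail hypergeometric P(X >= k) of functional genes in a pathway.

    universe = all pathway-annotated genes with >= 1 tested pair; K =
    functional genes in the universe; n = pathway genes in the universe;
    k = functional genes in the pathway.
    """
    if not universe:
        raise ValueError("empty universe")
    if not pathway_genes <= universe:
        pathway_genes = pathway_genes & universe
    M = len(universe)
    K = len(functional_genes & universe)
    n = len(pathway_genes)
    k = len(functional_genes & pathway_genes)
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def pathway_enrichment_table(functional_genes: set[str],
                             pathways: Mapping[str, set[str]],
                             universe: set[str]) -> pd.DataFrame:
    rows = []
    for name, genes in pathways.items():
        g = genes & universe
        if not g:
            continue
        k = len(functional_genes & g)
        p = hypergeometric_pathway_enrichment(functional_genes, g, universe)
        rows.append((name, len(g), k, p))
    return pd.DataFrame(rows, columns=["pathway", "n_genes_universe",
                                       "n_functional", "p_hypergeom"])


def functional_differentiation_overlap(
        functional: set[tuple[str, str]], fst_df: pd.DataFrame,
        cutoffs: Mapping[tuple[str, float], float],
        pathways: Mapping[str, set[str]] | None = None) -> pd.DataFrame:
    """Cross functional pairs with the population-differentiation calls.

    One row per functional pair: the maximal Fst over population pairs, the
    significance level attained (none/p05/p01, closed boundary) and the
    pathways containing the gene.
    """
    rows = []
    for cnv_id, gene_id in sorted(functional):
        max_fst, level = np.nan, "none"
        if cnv_id in fst_df.index:
            for col in fst_df.columns:
                pop_pair = col.removeprefix("fst_")
                val = fst_df.loc[cnv_id, col]
                if np.isnan(val):
                    continue
                if np.isnan(max_fst) or val > max_fst:
                    max_fst = float(val)
                for tail, name in ((0.01, "p01"), (0.05, "p05")):
                    cut = cutoffs.get((pop_pair, tail))
                    if cut is not None and val >= cut:
                        if name == "p01" or level == "none":
                            level = name
        memberships = []
        if pathways:
            memberships = sorted(n for n, g in pathways.items()
                                 if gene_id in g)
        rows.append((cnv_id, gene_id, max_fst, level, ";".join(memberships)))
    df = pd.DataFrame(rows, columns=["cnv_id", "gene_id", "max_fst",
                                     "level", "pathways"])
    return df
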