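"""Synthetic genomes, pathways, CNVs, genotypes and expression.

The generator emulates the statistical structure the analysis assumes —
gene models on several chromosomes, pathway memberships, CNVs with a
realistic size distribution, population-stratified copy-number genotypes
and expression with dosage effects — and records every planted signal in a
ground-truth object so that recovery can be checked.

Population differentiation follows a Balding-Nichols-style model applied
directly to CN-genotype categories: each CNV has an ancestral category
frequency vector p; a population with divergence F draws its own vector
from Dirichlet(p * (1 - F) / F), and individuals are sampled i.i.d. from
that population's categorical distribution.  F = 0 means all populations
share the ancestral frequencies exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .data_io import (CnvRecord, ExpressionMatrix, GeneModel, GenotypeMatrix,
                      PathwayCollection)
from .gene_areas import (CnvGenePair, build_gene_areas,
                         build_pseudo_transcriptome, pair_by_flank)

# stage identifiers for the per-stage RNG substreams
_S_ANNOT, _S_CNV, _S_GENO, _S_EXPR = 1, 2, 3, 4

_MECHANISMS = ("VNTR", "NAHR", "TEI", "NHR")
_MECH_PROBS = (0.10, 0.25, 0.20, 0.45)
_TYPES = ("gain", "loss", "both")
_TYPE_PROBS = (0.35, 0.55, 0.10)

# ancestral CN-category weights, centred on the diploid state
_ANCESTRAL_ALPHA = np.array([0.3, 1.2, 9.0, 2.7, 1.0, 0.45])


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Sample sizes mirror the HapMap panels used by the analysis (180 CEU,
    180 YRI, 45 JPT + 45 CHB = 90 ASN; expression for 60 CEU and 69 YRI).
    The default scale (2 chromosomes x 5 Mb, 200 genes, 50 pathways,
    300 CNVs) keeps every test suite comfortably within minutes on one CPU
    while leaving tens of genes per pathway-free null comparison.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    gene_length_mu: float = 9.0   # log-normal log-bp, median ~8.1 kb
    gene_length_sigma: float = 0.6
    n_pathways: int = 50
    pathway_size_min: int = 5
    pathway_size_max: int = 25
    n_cnvs: int = 300
    cnv_length_mu: float = 8.0    # log-normal log-bp, median ~3 kb
    cnv_length_sigma: float = 0.8
    cnv_placement: str = "genome"  # or "transcriptome"
    flank: int = 10_000            # gene-area flank for transcriptome placement
    # planted signals
    n_enriched_pathways: int = 0
    enrichment_multiplier: float = 3.0   # rho
    n_differentiated_cnvs: int = 0
    baseline_f: float = 0.05
    planted_f: float = 0.4
    n_functional_pairs: int = 0
    dosage_beta: float = 1.0
    expr_noise: float = 0.5       # sigma_e for planted pairs
    # populations
    pop_sizes: dict = field(default_factory=lambda: {
        "CEU": 180, "YRI": 180, "ASN": 90})
    expr_pop_sizes: dict = field(default_factory=lambda: {
        "CEU": 60, "YRI": 69})
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.enrichment_multiplier < 1:
            raise ValueError("enrichment_multiplier must be >= 1")
        for f in (self.baseline_f, self.planted_f):
            if not 0 <= f < 1:
                raise ValueError("F must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class GroundTruth:
    enriched_pathways: dict[str, float] = field(default_factory=dict)
    differentiated_cnvs: dict[str, float] = field(default_factory=dict)
    functional_pairs: dict[str, float] = field(default_factory=dict)  # "cnv|gene" -> beta

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stage]))


def simulate_annotation(cfg: SimConfig) -> tuple[list[GeneModel], PathwayCollection]:
    """Non-overlapping genes with random gaps, plus random pathways."""
    rng = _rng(cfg, _S_ANNOT)
    genes: list[GeneModel] = []
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    gid = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        k = int(per_chrom[ci])
        if k == 0:
            continue
        lengths = np.maximum(200, rng.lognormal(
            cfg.gene_length_mu, cfg.gene_length_sigma, size=k)).astype(np.int64)
        slack = cfg.chrom_length - int(lengths.sum())
        if slack < k + 1:
            raise ValueError(
                f"cannot pack {k} genes of total {int(lengths.sum())} bp into "
                f"{cfg.chrom_length} bp on {chrom}; reduce n_genes or "
                "gene_length_mu, or increase chrom_length")
        gaps = rng.multinomial(slack - (k + 1), np.full(k + 1, 1 / (k + 1))) + 1
        pos = 0
        for j in range(k):
            pos += int(gaps[j])
            start, end = pos, pos + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"G{gid:04d}", chrom, start, end, strand))
            gid += 1
            pos = end
    coll = PathwayCollection()
    gene_ids = [g.gene_id for g in genes]
    sources = ("KEGG", "BIOCARTA")
    categories = ("Metabolism", "Signaling", "Cell Process", "Disease")
    for pi in range(cfg.n_pathways):
        size = int(rng.integers(cfg.pathway_size_min,
                                min(cfg.pathway_size_max, len(gene_ids)) + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        name = f"PW{pi:03d}"
        coll.pathways[name] = {gene_ids[i] for i in members}
        coll.source[name] = sources[int(rng.integers(0, 2))]
        coll.category[name] = categories[int(rng.integers(0, len(categories)))]
    return genes, coll


def simulate_cnvs(cfg: SimConfig, genes: list[GeneModel],
                  pathways: PathwayCollection,
                  truth: GroundTruth) -> list[CnvRecord]:
    """Baseline CNVs placed uniformly, plus planted pathway enrichment.

    With ``cnv_placement = "transcriptome"`` baseline CNVs are placed
    uniformly on the concatenated gene areas (the exchangeable null of the
    permutation test); with ``"genome"`` they are uniform on the genome.
    For each planted pathway the expected per-base CNV density on its gene
    bodies is raised to rho x baseline by adding extra CNVs centred inside
    the pathway's genes.
    """
    rng = _rng(cfg, _S_CNV)
    chroms = [f"chr{ci + 1}" for ci in range(cfg.n_chromosomes)]
    cnvs: list[CnvRecord] = []
    cid = 0

    def new_cnv(chrom: str, start: int, end: int) -> None:
        nonlocal cid
        mech = str(rng.choice(_MECHANISMS, p=_MECH_PROBS))
        ctype = str(rng.choice(_TYPES, p=_TYPE_PROBS))
        cnvs.append(CnvRecord(f"CNV{cid:05d}", chrom, start, end, ctype, mech))
        cid += 1

    sizes = np.maximum(100, rng.lognormal(
        cfg.cnv_length_mu, cfg.cnv_length_sigma, size=cfg.n_cnvs)).astype(np.int64)
    if cfg.cnv_placement == "transcriptome":
        pt = build_pseudo_transcriptome(build_gene_areas(genes, cfg.flank))
        Ls = np.array([pt.length(c) for c in chroms], dtype=float)
        probs = Ls / Ls.sum()
        for s in sizes:
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            L = pt.length(chrom)
            s = min(int(s), L)
            cstart = int(rng.integers(0, L - s + 1))
            gstart = pt.to_genomic(chrom, cstart)
            # project back to genomic space; may span area gaps, which the
            # truncation step removes again without changing transcriptome mass
            gend = pt.to_genomic(chrom, cstart + s - 1) + 1
            new_cnv(chrom, gstart, max(gend, gstart + 1))
    elif cfg.cnv_placement == "genome":
        for s in sizes:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            s = min(int(s), cfg.chrom_length)
            start = int(rng.integers(0, cfg.chrom_length - s + 1))
            new_cnv(chrom, start, start + int(s))
    else:
        raise ValueError(f"unknown cnv_placement {cfg.cnv_placement!r}")

    if cfg.n_enriched_pathways > 0:
        rho = cfg.enrichment_multiplier
        # plant in the largest gene sets: a density multiplier on a handful
        # of genes cannot rise above the null's hit-rate ceiling, so the
        # planted signal is only identifiable in sets of adequate size
        names = sorted(pathways.pathways,
                       key=lambda n: (-len(pathways.pathways[n]), n))
        chosen = names[: cfg.n_enriched_pathways]
        by_id = {g.gene_id: g for g in genes}
        genome_bp = cfg.n_chromosomes * cfg.chrom_length
        for name in chosen:
            truth.enriched_pathways[name] = rho
            members = [by_id[g] for g in sorted(pathways.pathways[name])
                       if g in by_id]
            if not members:
                continue
            # area footprint (body + both flanks) is what the test sees
            area_bp = np.array([g.length + 2 * cfg.flank for g in members],
                               dtype=float)
            n_extra = int(round((rho - 1) * cfg.n_cnvs
                                * area_bp.sum() / genome_bp))
            weights = area_bp / area_bp.sum()
            extra_sizes = np.maximum(100, rng.lognormal(
                cfg.cnv_length_mu, cfg.cnv_length_sigma,
                size=n_extra)).astype(np.int64)
            for s in extra_sizes:
                g = members[int(rng.choice(len(members), p=weights))]
                a_start = max(0, g.start - cfg.flank)
                a_end = min(cfg.chrom_length, g.end + cfg.flank)
                s = min(int(s), a_end - a_start)
                start = int(rng.integers(a_start, a_end - s + 1))
                new_cnv(g.chrom, start, start + s)
    return cnvs


def simulate_genotypes(cfg: SimConfig, cnvs: list[CnvRecord],
                       truth: GroundTruth) -> GenotypeMatrix:
    """Balding-Nichols-style CN-category genotypes for three populations."""
    rng = _rng(cfg, _S_GENO)
    samples, pops = [], []
    for pop, n in cfg.pop_sizes.items():
        for i in range(n):
            samples.append(f"{pop}{i:03d}")
            pops.append(pop)
    population = pd.Series(pops, index=samples, name="population")

    if cfg.n_differentiated_cnvs > 0:
        idx = rng.choice(len(cnvs), size=min(cfg.n_differentiated_cnvs,
                                             len(cnvs)), replace=False)
        for i in idx:
            truth.differentiated_cnvs[cnvs[int(i)].cnv_id] = cfg.planted_f

    data = np.zeros((len(cnvs), len(samples)), dtype=np.int64)
    miss = np.zeros_like(data, dtype=bool)
    for r, c in enumerate(cnvs):
        ancestral = rng.dirichlet(_ANCESTRAL_ALPHA)
        F = truth.differentiated_cnvs.get(c.cnv_id, cfg.baseline_f)
        col = 0
        for pop, n in cfg.pop_sizes.items():
            if F > 0:
                conc = (1 - F) / F
                p = rng.dirichlet(np.maximum(ancestral * conc, 1e-9))
            else:
                p = ancestral
            states = rng.choice(len(p), size=n, p=p)
            data[r, col:col + n] = states
            col += n
        if cfg.missing_rate > 0:
            miss[r] = rng.random(len(samples)) < cfg.missing_rate
    cn = pd.DataFrame(data, index=[c.cnv_id for c in cnvs],
                      columns=samples).astype("Int64")
    cn = cn.mask(pd.DataFrame(miss, index=cn.index, columns=cn.columns))
    return GenotypeMatrix(cn, population)


def simulate_expression(cfg: SimConfig, genotypes: GenotypeMatrix,
                        pairs: list[CnvGenePair], genes: list[GeneModel],
                        truth: GroundTruth) -> ExpressionMatrix:
    """Expression matrices for CEU and YRI with planted dosage effects.

    Planted pair: expr = mu_g + beta * CN + Normal(0, sigma_e); all other
    genes: expr = mu_g + Normal(0, 1), independent of copy number.
    """
    rng = _rng(cfg, _S_EXPR)
    expr_samples, expr_pops = [], []
    for pop, n in cfg.expr_pop_sizes.items():
        pool = genotypes.samples_of(pop)
        if n > len(pool):
            raise ValueError(f"{pop}: requested {n} expression samples but "
                             f"only {len(pool)} genotyped individuals")
        expr_samples.extend(pool[:n])
        expr_pops.extend([pop] * n)
    population = pd.Series(expr_pops, index=expr_samples, name="population")

    if cfg.n_functional_pairs > 0 and pairs:
        uniq = sorted({(p.cnv_id, p.gene_id) for p in pairs})
        idx = rng.choice(len(uniq), size=min(cfg.n_functional_pairs,
                                             len(uniq)), replace=False)
        for i in idx:
            cnv_id, gene_id = uniq[int(i)]
            truth.functional_pairs[f"{cnv_id}|{gene_id}"] = cfg.dosage_beta

    planted_by_gene: dict[str, str] = {}
    for key in truth.functional_pairs:
        cnv_id, gene_id = key.split("|")
        planted_by_gene[gene_id] = cnv_id

    gene_ids = [g.gene_id for g in genes]
    mu = rng.normal(8.0, 2.0, size=len(gene_ids))
    vals = np.empty((len(gene_ids), len(expr_samples)))
    cn_matrix = genotypes.cn[expr_samples]
    for gi, gid in enumerate(gene_ids):
        cnv_id = planted_by_gene.get(gid)
        if cnv_id is not None:
            beta = truth.functional_pairs[f"{cnv_id}|{gid}"]
            cn = cn_matrix.loc[cnv_id].to_numpy(dtype=object)
            cn = np.array([2 if pd.isna(v) else int(v) for v in cn], dtype=float)
            vals[gi] = (mu[gi] + beta * cn
                        + rng.normal(0, cfg.expr_noise, size=len(expr_samples)))
        else:
            vals[gi] = mu[gi] + rng.normal(0, 1.0, size=len(expr_samples))
    values = pd.DataFrame(vals, index=gene_ids, columns=expr_samples)
    return ExpressionMatrix(values, population)


@dataclass
class SimData:
    config: SimConfig
    genes: list[GeneModel]
    pathways: PathwayCollection
    cnvs: list[CnvRecord]
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    pairs_1mb: list[CnvGenePair]
    truth: GroundTruth


def simulate_all(cfg: SimConfig, assoc_flank: int = 1_000_000) -> SimData:
    truth = GroundTruth()
    genes, pathways = simulate_annotation(cfg)
    cnvs = simulate_cnvs(cfg, genes, pathways, truth)
    genotypes = simulate_genotypes(cfg, cnvs, truth)
    pairs = pair_by_flank(cnvs, genes, assoc_flank)
    expression = simulate_expression(cfg, genotypes, pairs, genes, truth)
    return SimData(cfg, genes, pathways, cnvs, genotypes, expression,
                   pairs, truth)


def write_dataset(sim: SimData, out_dir: str | Path) -> dict[str, str]:
    """Emit the full dataset as the pipeline's input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.refflat",
        "cnvs": out / "cnvs.bed",
        "pathways": out / "pathways.gmt",
        "genotypes": out / "genotypes.tsv",
        "expression": out / "expression.tsv",
        "popmap": out / "popmap.tsv",
        "truth": out / "truth.json",
    }
    data_io.write_genes(sim.genes, paths["genes"])
    data_io.write_cnvs(sim.cnvs, paths["cnvs"])
    data_io.write_gmt(sim.pathways, paths["pathways"])
    data_io.write_matrix(sim.genotypes, paths["genotypes"])
    data_io.write_matrix(sim.expression, paths["expression"])
    pop = pd.concat([sim.genotypes.population,
                     sim.expression.population]).groupby(level=0).first()
    data_io.write_pop_map(pop, paths["popmap"])
    sim.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
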