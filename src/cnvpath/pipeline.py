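"""End-to-end orchestration of the analysis stages.

``run_all`` executes: (optional) simulate -> enrichment -> Fst and
polymorphism frequencies -> pathway frequency maps -> expression
association -> functional/differentiation overlap -> mechanism composition,
writing per-stage TSV outputs and a JSON manifest with input checksums so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import data_io, enrichment, expression, mechanisms, pathway_maps, popdiff
from .gene_areas import (build_gene_areas, build_pseudo_transcriptome,
                         pair_by_flank, pairs_to_frame, truncate_cnvs)
from .simulate import SimConfig, simulate_all, write_dataset

log = logging.getLogger("cnvpath")


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    # inputs (ignored when simulate is set)
    genes: str | None = None
    gene_dialect: str = "refflat"
    cnvs: str | None = None
    pathways: str | None = None
    genotypes: str | None = None
    expr: str | None = None
    popmap: str | None = None
    # parameters
    flank_enrichment: int = 10_000
    flank_association: int = 1_000_000
    n_perm: int = 1000
    tails: tuple[float, float] = (0.05, 0.01)
    fdr_q: float = 0.05
    alpha_enrich: float = 0.05
    # optional simulation stage
    simulate: dict | None = field(default=None)

    def __post_init__(self) -> None:
        if self.flank_enrichment < 0 or self.flank_association < 0:
            raise ValueError("flanks must be >= 0")
        for t in (*self.tails, self.fdr_q):
            if not 0 < t < 1:
                raise ValueError("tails and fdr_q must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tails" in raw:
            raw["tails"] = tuple(raw["tails"])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    def __init__(self, manifest: dict, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self.t0 = time.monotonic()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.monotonic() - self.t0
        if exc_type is not None:
            self.manifest["stages"].append(
                {"name": self.name, "status": "failed", "error": str(exc),
                 "seconds": round(dt, 2)})
            log.error("stage %s failed after %.1fs: %s", self.name, dt, exc)
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        self.manifest["stages"].append(
            {"name": self.name, "status": "ok", "seconds": round(dt, 2)})
        log.info("stage %s: done in %.1fs", self.name, dt)
        return False


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "inputs": {},
                      "outputs": {}}

    def emit(name: str, df: pd.DataFrame, index=False) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        manifest["outputs"][name] = {"path": str(path),
                                     "sha256": _sha256(path)}

    if config.simulate is not None:
        with _Stage(manifest, "simulate"):
            sim_cfg = SimConfig(**{"seed": config.seed, **config.simulate})
            sim = simulate_all(sim_cfg, assoc_flank=config.flank_association)
            paths = write_dataset(sim, out / "data")
            config.genes = paths["genes"]
            config.cnvs = paths["cnvs"]
            config.pathways = paths["pathways"]
            config.genotypes = paths["genotypes"]
            config.expr = paths["expression"]
            config.popmap = paths["popmap"]

    with _Stage(manifest, "load"):
        for key in ("genes", "cnvs", "pathways", "genotypes", "expr",
                    "popmap"):
            path = getattr(config, key)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"input {key!r}: {path}")
            manifest["inputs"][key] = {"path": str(path),
                                       "sha256": _sha256(path)}
        genes = data_io.read_genes(config.genes, config.gene_dialect)
        cnvs = data_io.read_cnvs(config.cnvs)
        pathways = data_io.read_gmt(config.pathways)
        genotypes = data_io.read_matrix(config.genotypes, "genotype",
                                        config.popmap)
        expr = data_io.read_matrix(config.expr, "expression", config.popmap)

    with _Stage(manifest, "enrich"):
        areas = build_gene_areas(genes, config.flank_enrichment)
        pt = build_pseudo_transcriptome(areas)
        truncated = truncate_cnvs(cnvs, pt)
        results = enrichment.enrichment_test(
            pathways, truncated, pt, n_perm=config.n_perm, seed=config.seed,
            flank_used=config.flank_enrichment)
        emit("enrichment", enrichment.results_to_frame(results))
        enriched = {r.pathway for r in results
                    if r.p_enrich < config.alpha_enrich}
        pairs_10kb = pair_by_flank(cnvs, genes, config.flank_enrichment)
        emit("pairs_10kb", pairs_to_frame(pairs_10kb))
        enriched_genes = set().union(*(pathways.pathways[n]
                                       for n in enriched)) if enriched else set()
        hit_ids = {p.cnv_id for p in pairs_10kb
                   if p.gene_id in enriched_genes}
        cnvs_in_enriched = [c for c in cnvs if c.cnv_id in hit_ids]
        for attr in ("mechanism", "cnv_type"):
            emit(f"enriched_shift_{attr}",
                 enrichment.subset_proportion_shift(cnvs_in_enriched, cnvs,
                                                    attr))

    with _Stage(manifest, "fst"):
        fst_df = popdiff.fst_table(genotypes)
        cutoffs = popdiff.empirical_cutoffs(fst_df, tails=config.tails)
        freq_df = popdiff.frequency_table(genotypes)
        emit("fst", fst_df.join(freq_df, how="left",
                                rsuffix="_freq"), index=True)
        cut_rows = [(pair, tail, raw, round(raw, 2))
                    for (pair, tail), raw in sorted(cutoffs.items())]
        emit("fst_cutoffs", pd.DataFrame(
            cut_rows, columns=["pair", "tail", "cutoff", "cutoff_2dp"]))

    with _Stage(manifest, "freqmap"):
        summary = pathway_maps.differentiation_summary(
            pathways.pathways, pairs_10kb, fst_df, cutoffs)
        emit("pathway_differentiation", summary)
        flags = pathway_maps.per_pair_flags(pathways.pathways, pairs_10kb,
                                            fst_df, cutoffs,
                                            tail=config.tails[0])
        venn = pathway_maps.venn_partition(flags)
        emit("venn_pathways", pd.DataFrame(
            sorted(venn.items()), columns=["region", "count"]))
        map_dir = out / "freqmaps"
        map_dir.mkdir(exist_ok=True)
        for name in sorted(pathways.pathways):
            fmap = pathway_maps.frequency_map(
                name, pathways.pathways[name], pairs_10kb, freq_df)
            if fmap.empty:
                continue
            order = pathway_maps.cluster_rows(fmap)
            fmap.iloc[order].to_csv(map_dir / f"{name}.tsv", sep="\t")

    with _Stage(manifest, "assoc"):
        pairs_1mb = pair_by_flank(cnvs, genes, config.flank_association)
        emit("pairs_1mb", pairs_to_frame(pairs_1mb))
        tables = []
        functional: set[tuple[str, str]] = set()
        for pop in ("CEU", "YRI"):
            if not expr.samples_of(pop):
                continue
            t = expression.associate(expr, genotypes, pairs_1mb, pop,
                                     q=config.fdr_q)
            tables.append(t)
            functional |= expression.functional_pairs(t)
        assoc = pd.concat(tables) if tables else pd.DataFrame()
        emit("association", assoc)
        universe = {p.gene_id for p in pairs_1mb} & set().union(
            *pathways.pathways.values())
        func_genes = {g for _, g in functional}
        if universe:
            emit("functional_pathway_enrichment",
                 expression.pathway_enrichment_table(
                     func_genes, pathways.pathways, universe))

    with _Stage(manifest, "overlap"):
        emit("functional_differentiation",
             expression.functional_differentiation_overlap(
                 functional, fst_df, cutoffs, pathways.pathways))

    with _Stage(manifest, "mechanisms"):
        diff_ids = set()
        for col in fst_df.columns:
            pair = col.removeprefix("fst_")
            cut = cutoffs.get((pair, config.tails[0]))
            if cut is None:
                continue
            diff_ids |= set(fst_df.index[fst_df[col] >= cut])
        diff_cnvs = [c for c in cnvs if c.cnv_id in diff_ids]
        emit("mechanisms_differentiated",
             mechanisms.compare_composition(diff_cnvs, cnvs, "mechanism"))

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("manifest written to %s", manifest_path)
    return manifest
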