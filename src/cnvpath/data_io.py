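"""Readers and writers for the external formats the pipeline consumes.

All genomic intervals are stored 0-based half-open, matching BED and the
UCSC refFlat file layout.  Population labels are normalised at load time:
JPT and CHB samples are merged into a single ASN panel.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_CNV_TYPES = {"gain", "loss", "both", "unknown"}
VALID_MECHANISMS = {"VNTR", "NAHR", "TEI", "NHR", "unknown"}
POPULATIONS = ("CEU", "YRI", "ASN")
_POP_ALIASES = {"JPT": "ASN", "CHB": "ASN", "JPT+CHB": "ASN",
                "CEU": "CEU", "YRI": "YRI", "ASN": "ASN"}


@dataclass(frozen=True)
class GeneModel:
    """One gene's widest-isoform genomic span."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvRecord:
    """A copy-number variant interval with optional annotation."""

    cnv_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str = "unknown"
    mechanism: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"CNV {self.cnv_id}: start {self.start} >= end {self.end}")
        if self.cnv_type not in VALID_CNV_TYPES:
            raise ValueError(f"CNV {self.cnv_id}: bad type {self.cnv_type!r}")
        if self.mechanism not in VALID_MECHANISMS:
            raise ValueError(
                f"CNV {self.cnv_id}: bad mechanism {self.mechanism!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PathwayCollection:
    """Named gene sets with their database source and category label."""

    pathways: dict[str, set[str]] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def genes(self, name: str) -> set[str]:
        return self.pathways[name]


@dataclass
class GenotypeMatrix:
    """Integer copy-number state per (CNV, sample), with population labels.

    ``cn`` is a CNV x sample DataFrame with nullable-integer dtype; missing
    genotypes are pd.NA.  ``population`` maps every sample to CEU/YRI/ASN.
    """

    cn: pd.DataFrame
    population: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.cn.columns if s not in self.population.index]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}")
        self.population = self.population.loc[list(self.cn.columns)]
        bad = set(self.population.unique()) - set(POPULATIONS)
        if bad:
            raise ValueError(f"unknown population labels: {sorted(bad)}")

    @property
    def cnv_ids(self) -> list[str]:
        return list(self.cn.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cn.columns)

    def samples_of(self, population: str) -> list[str]:
        return list(self.population.index[self.population == population])


@dataclass
class ExpressionMatrix:
    """Normalised expression per (gene, sample), with population labels."""

    values: pd.DataFrame
    population: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns
                   if s not in self.population.index]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}")
        self.population = self.population.loc[list(self.values.columns)]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, population: str) -> list[str]:
        return list(self.population.index[self.population == population])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_genes(path: str | Path, dialect: str = "refflat") -> list[GeneModel]:
    """Read gene models, collapsing multiple isoforms to the widest span.

    ``refflat``: geneName, name, chrom, strand, txStart, txEnd, ...
    ``bed``: chrom, start, end, name[, score[, strand]].
    """
    if dialect not in ("refflat", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    spans: dict[str, list] = {}
    for lineno, fields in _data_lines(path):
        try:
            if dialect == "refflat":
                if len(fields) < 6:
                    raise ValueError("expected >= 6 columns")
                gid, _, chrom, strand = fields[0], fields[1], fields[2], fields[3]
                start, end = int(fields[4]), int(fields[5])
            else:
                if len(fields) < 4:
                    raise ValueError("expected >= 4 columns")
                chrom, gid = fields[0], fields[3]
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5] if len(fields) >= 6 else "+"
            if start >= end:
                raise ValueError(f"start {start} >= end {end}")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
        rec = spans.get(gid)
        if rec is None:
            spans[gid] = [chrom, start, end, strand]
        else:
            if rec[0] != chrom:
                raise ValueError(
                    f"{path}:{lineno}: gene {gid} appears on {rec[0]} and {chrom}")
            rec[1] = min(rec[1], start)
            rec[2] = max(rec[2], end)
    return [GeneModel(gid, c, s, e, st) for gid, (c, s, e, st) in spans.items()]


def read_cnvs(path: str | Path) -> list[CnvRecord]:
    """Read a BED-like CNV table: chrom, start, end, id[, type[, mechanism]]."""
    out: list[CnvRecord] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
        chrom, cid = fields[0], fields[3]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
        if cid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate cnv_id {cid!r}")
        seen.add(cid)
        ctype = fields[4] if len(fields) >= 5 and fields[4] else "unknown"
        mech = fields[5] if len(fields) >= 6 and fields[5] else "unknown"
        try:
            out.append(CnvRecord(cid, chrom, start, end, ctype, mech))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


_DESC_RE = re.compile(r"^(KEGG|BIOCARTA)\|(.*)$", re.IGNORECASE)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read gene sets in GMT format (name, description, genes...).

    A description of the form ``SOURCE|category`` populates the source and
    category maps; anything else leaves source = unknown.  Pathways with no
    genes are skipped with a warning.
    """
    coll = PathwayCollection()
    for lineno, fields in _data_lines(path):
        name = fields[0]
        genes = {g for g in fields[2:] if g}
        if not genes:
            warnings.warn(f"{path}:{lineno}: pathway {name!r} has no genes; "
                          "skipped", stacklevel=2)
            continue
        desc = fields[1] if len(fields) > 1 else ""
        m = _DESC_RE.match(desc)
        coll.pathways[name] = genes
        coll.source[name] = m.group(1).upper() if m else "unknown"
        coll.category[name] = m.group(2) if m else desc
    return coll


def read_pop_map(path: str | Path) -> pd.Series:
    """Two-column TSV sample -> population; JPT/CHB are merged into ASN."""
    labels: dict[str, str] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        sample, pop = fields[0], fields[1]
        if pop not in _POP_ALIASES:
            raise ValueError(f"{path}:{lineno}: unknown population {pop!r}")
        labels[sample] = _POP_ALIASES[pop]
    return pd.Series(labels, name="population")


def read_matrix(path: str | Path, kind: str,
                pop_map_path: str | Path) -> GenotypeMatrix | ExpressionMatrix:
    """Read a genotype or expression TSV (rows = ids, columns = samples)."""
    if kind not in ("genotype", "expression"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    pop = read_pop_map(pop_map_path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     na_values=["NA"], keep_default_na=False)
    df.index.name = None
    unlabeled = [s for s in df.columns if s not in pop.index]
    if unlabeled:
        raise ValueError(f"samples without population label: {unlabeled[:5]}")
    if kind == "expression":
        vals = df.astype(float)
        return ExpressionMatrix(vals, pop)
    cn = pd.DataFrame(index=df.index, columns=df.columns, dtype="Int64")
    for col in df.columns:
        converted = []
        for v in df[col]:
            if v is np.nan or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
                converted.append(pd.NA)
                continue
            try:
                iv = int(v)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer genotype {v!r} in column {col}") from exc
            if iv < 0:
                raise ValueError(f"{path}: negative genotype {v!r}")
            converted.append(iv)
        cn[col] = pd.array(converted, dtype="Int64")
    return GenotypeMatrix(cn, pop)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------

def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.gene_id}.1\t{g.chrom}\t{g.strand}"
                     f"\t{g.start}\t{g.end}\n")


def write_cnvs(cnvs: Iterable[CnvRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cnvs:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cnv_id}"
                     f"\t{c.cnv_type}\t{c.mechanism}\n")


def write_gmt(coll: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.pathways.items():
            desc = f"{coll.source.get(name, 'unknown')}|{coll.category.get(name, '')}"
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def write_pop_map(pop: pd.Series | Mapping[str, str], path: str | Path) -> None:
    items = pop.items() if isinstance(pop, pd.Series) else pop.items()
    with open(path, "w") as fh:
        for sample, label in items:
            fh.write(f"{sample}\t{label}\n")


def write_matrix(mat: GenotypeMatrix | ExpressionMatrix,
                 path: str | Path) -> None:
    df = mat.cn if isinstance(mat, GenotypeMatrix) else mat.values
    out = df.astype(object).where(df.notna(), "NA")
    out.to_csv(path, sep="\t", index_label="id")
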