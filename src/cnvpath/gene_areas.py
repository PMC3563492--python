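"""Gene areas, the pseudo-transcriptome, CNV truncation and CNV-gene pairing.

A *gene area* is a gene's widest-isoform span extended by an upstream and a
downstream flank.  Per chromosome the (disjoint) areas are concatenated into
a *pseudo-transcriptome*: a single coordinate axis on which truncated CNVs
can be permuted while respecting gene and CNV sizes.  Pairing of a CNV with
genes follows three rules:

  R1  every gene area entirely inside the CNV is paired;
  R2  a CNV contained in exactly one area is paired with that gene;
  R3  a CNV straddling an area boundary is paired with the gene whose area
      holds strictly more than half of the CNV's length; an exact 50/50
      split goes to the lower-coordinate area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data_io import CnvRecord, GeneModel


@dataclass(frozen=True)
class GeneArea:
    gene_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruncatedCnv:
    """A CNV clipped to the union of gene areas on its chromosome."""

    cnv_id: str
    chrom: str
    segments: tuple[tuple[int, int], ...]
    total_size: int


@dataclass(frozen=True)
class CnvGenePair:
    cnv_id: str
    gene_id: str
    overlap_bp: int
    flank_used: int


def build_gene_areas(genes: Sequence[GeneModel], flank: int) -> list[GeneArea]:
    """Extend each gene by ``flank`` on both sides and disjointify.

    Where two flanked areas overlap, the contested bases are assigned to the
    gene whose body is nearer: the boundary is the midpoint between the left
    gene's body end and the right gene's body start (also the midpoint of
    the body overlap when the bodies themselves overlap).  Areas are clipped
    at the chromosome origin; the result is sorted and pairwise disjoint per
    chromosome.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneArea] = []
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        starts = [max(0, g.start - flank) for g in gs]
        ends = [g.end + flank for g in gs]
        for i in range(len(gs) - 1):
            if ends[i] > starts[i + 1]:
                m = (gs[i].end + gs[i + 1].start) // 2
                m = max(starts[i + 1], min(m, ends[i]))
                m = max(m, starts[i])  # never extend left area backwards
                ends[i] = m
                starts[i + 1] = max(starts[i + 1], m)
        for g, s, e in zip(gs, starts, ends):
            if s >= e:
                warnings.warn(f"gene {g.gene_id}: area emptied by neighbouring "
                              "gene bodies; dropped", stacklevel=2)
                continue
            out.append(GeneArea(g.gene_id, chrom, s, e))
    return out


@dataclass
class PseudoTranscriptome:
    """Per-chromosome concatenation of disjoint gene areas.

    Provides a bijection between genomic positions covered by areas and the
    concatenated coordinate [0, L) of each chromosome.
    """

    areas: dict[str, list[GeneArea]] = field(default_factory=dict)
    _starts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _ends: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _offsets: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.areas)

    def length(self, chrom: str) -> int:
        off = self._offsets.get(chrom)
        return 0 if off is None else int(off[-1])

    def area_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated [start, end) of every area on ``chrom``."""
        off = self._offsets[chrom]
        return off[:-1], off[1:]

    def gene_ids(self, chrom: str) -> list[str]:
        return [a.gene_id for a in self.areas[chrom]]

    def all_gene_ids(self) -> list[str]:
        return [a.gene_id for c in self.chroms for a in self.areas[c]]

    def to_concat(self, chrom: str, pos: int) -> int:
        """Map a genomic base covered by some area to its concatenated index."""
        starts, ends, off = self._starts[chrom], self._ends[chrom], self._offsets[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            raise ValueError(f"{chrom}:{pos} is not covered by any gene area")
        return int(off[i] + (pos - starts[i]))

    def to_genomic(self, chrom: str, cpos: int) -> int:
        off, starts = self._offsets[chrom], self._starts[chrom]
        if cpos < 0 or cpos >= off[-1]:
            raise ValueError(f"concatenated position {cpos} out of range")
        i = int(np.searchsorted(off, cpos, side="right")) - 1
        return int(starts[i] + (cpos - off[i]))


def build_pseudo_transcriptome(areas: Iterable[GeneArea]) -> PseudoTranscriptome:
    pt = PseudoTranscriptome()
    for a in areas:
        pt.areas.setdefault(a.chrom, []).append(a)
    for chrom, lst in pt.areas.items():
        lst.sort(key=lambda a: a.start)
        starts = np.array([a.start for a in lst], dtype=np.int64)
        ends = np.array([a.end for a in lst], dtype=np.int64)
        if np.any(ends[:-1] > starts[1:]):
            raise ValueError(f"overlapping gene areas on {chrom}")
        lengths = ends - starts
        off = np.zeros(len(lst) + 1, dtype=np.int64)
        np.cumsum(lengths, out=off[1:])
        pt._starts[chrom] = starts
        pt._ends[chrom] = ends
        pt._offsets[chrom] = off
    return pt


def truncate_cnvs(cnvs: Sequence[CnvRecord],
                  pt: PseudoTranscriptome) -> list[TruncatedCnv]:
    """Clip CNVs to gene areas; CNVs outside every area are dropped."""
    out: list[TruncatedCnv] = []
    for c in cnvs:
        if c.chrom not in pt.areas:
            continue
        starts, ends = pt._starts[c.chrom], pt._ends[c.chrom]
        lo = int(np.searchsorted(ends, c.start, side="right"))
        hi = int(np.searchsorted(starts, c.end, side="left"))
        segs = []
        for i in range(lo, hi):
            s, e = max(c.start, int(starts[i])), min(c.end, int(ends[i]))
            if s < e:
                segs.append((s, e))
        if segs:
            total = sum(e - s for s, e in segs)
            out.append(TruncatedCnv(c.cnv_id, c.chrom, tuple(segs), total))
    return out


def _pairs_from_area_overlaps(cnv_id: str, chrom: str, total: int,
                              overlaps: dict[int, int],
                              pt: PseudoTranscriptome,
                              flank_used: int) -> list[CnvGenePair]:
    """Apply rules R1-R3 given per-area overlap lengths for one CNV."""
    gene_ids = pt.gene_ids(chrom)
    area_len = pt._ends[chrom] - pt._starts[chrom]
    paired: dict[int, int] = {}
    for i, ov in overlaps.items():
        if ov == area_len[i]:  # R1: area entirely inside the CNV
            paired[i] = ov
    if len(overlaps) == 1:  # R2
        (i, ov), = overlaps.items()
        paired[i] = ov
    else:  # R3 on the straddling CNV
        best = max(overlaps.values())
        if 2 * best > total:
            i = next(i for i in sorted(overlaps) if overlaps[i] == best)
            paired[i] = overlaps[i]
        elif 2 * best == total:
            i = min(i for i in overlaps if overlaps[i] == best)
            paired[i] = overlaps[i]
    return [CnvGenePair(cnv_id, gene_ids[i], int(ov), flank_used)
            for i, ov in sorted(paired.items())]


def pair_truncated(truncated: Sequence[TruncatedCnv],
                   pt: PseudoTranscriptome,
                   flank_used: int = 0) -> list[CnvGenePair]:
    """Pair truncated CNVs (genomic segments) with genes under R1-R3."""
    pairs: list[CnvGenePair] = []
    for t in truncated:
        starts, ends = pt._starts[t.chrom], pt._ends[t.chrom]
        overlaps: dict[int, int] = {}
        for s, e in t.segments:
            lo = int(np.searchsorted(ends, s, side="right"))
            hi = int(np.searchsorted(starts, e, side="left"))
            for i in range(lo, hi):
                ov = min(e, int(ends[i])) - max(s, int(starts[i]))
                if ov > 0:
                    overlaps[i] = overlaps.get(i, 0) + ov
        if overlaps:
            pairs.extend(_pairs_from_area_overlaps(
                t.cnv_id, t.chrom, t.total_size, overlaps, pt, flank_used))
    return pairs


def pair_placements(cnv_ids: Sequence[str], chrom: str,
                    starts: np.ndarray, sizes: np.ndarray,
                    pt: PseudoTranscriptome,
                    flank_used: int = 0) -> list[CnvGenePair]:
    """Pair CNVs placed on the concatenated axis (one contiguous block each)."""
    off = pt._offsets[chrom]
    pairs: list[CnvGenePair] = []
    s = np.asarray(starts, dtype=np.int64)
    e = s + np.asarray(sizes, dtype=np.int64)
    i0 = np.searchsorted(off, s, side="right") - 1
    i1 = np.searchsorted(off, e - 1, side="right") - 1
    gene_ids = pt.gene_ids(chrom)
    for k in range(len(s)):
        if i0[k] == i1[k]:  # R2: single area
            pairs.append(CnvGenePair(cnv_ids[k], gene_ids[i0[k]],
                                     int(e[k] - s[k]), flank_used))
            continue
        overlaps = {}
        for i in range(int(i0[k]), int(i1[k]) + 1):
            ov = min(int(e[k]), int(off[i + 1])) - max(int(s[k]), int(off[i]))
            if ov > 0:
                overlaps[i] = ov
        pairs.extend(_pairs_from_area_overlaps(
            cnv_ids[k], chrom, int(e[k] - s[k]), overlaps, pt, flank_used))
    return pairs


def pair_overlaps(cnvs: Sequence[CnvRecord], pt: PseudoTranscriptome,
                  flank_used: int = 0) -> list[CnvGenePair]:
    """Truncate genomic CNVs to gene areas and pair them under R1-R3."""
    return pair_truncated(truncate_cnvs(cnvs, pt), pt, flank_used)


def pair_by_flank(cnvs: Sequence[CnvRecord], genes: Sequence[GeneModel],
                  flank: int) -> list[CnvGenePair]:
    """Plain interval intersection of CNVs with flanked gene spans.

    No 50% rule: every gene whose flanked span intersects the CNV is paired.
    Used for the frequency maps (10 kb) and expression association (1 Mb).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
        arrays[chrom] = (np.array([max(0, g.start - flank) for g in gs]),
                         np.array([g.end + flank for g in gs]), gs)
    pairs: list[CnvGenePair] = []
    for c in cnvs:
        if c.chrom not in arrays:
            continue
        fs, fe, gs = arrays[c.chrom]
        hit = np.nonzero((fs < c.end) & (fe > c.start))[0]
        for i in hit:
            ov = min(c.end, int(fe[i])) - max(c.start, int(fs[i]))
            pairs.append(CnvGenePair(c.cnv_id, gs[i].gene_id, int(ov), flank))
    return pairs


def pairs_to_frame(pairs: Sequence[CnvGenePair]):
    import pandas as pd

    return pd.DataFrame(
        [(p.cnv_id, p.gene_id, p.overlap_bp, p.flank_used) for p in pairs],
        columns=["cnv_id", "gene_id", "overlap_bp", "flank_used"])
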