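"""Population differentiation of CNVs from multi-state copy-number genotypes.

Each diploid copy-number call is treated as an allele-like category
(A0, A1, A2, A3, A4 and >A4, with CN >= 5 binned), ignoring haplotype
phase.  For a pair of populations X, Y with category frequencies x_i, y_i
and sizes N_x, N_y:

    t_i = (x_i N_x + y_i N_y) / (N_x + N_y)
    H_t = 1 - sum t_i^2
    H_s = [(1 - sum x_i^2) N_x + (1 - sum y_i^2) N_y] / (N_x + N_y)
    Fst = (H_t - H_s) / H_t        (0 when H_t = 0)

Fst is 0 for identical frequency vectors and 1 when the two populations
are fixed for different states.  Empirical significance cutoffs are the
upper 5% / 1% tail ranks of the per-population-pair Fst distributions.

The *polymorphism frequency* of a CNV in a population is 1 minus that
population's frequency of the CNV's major state in the reference (CEU)
population; it feeds the pathway frequency heatmaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, POPULATIONS

CN_CATEGORIES = ("A0", "A1", "A2", "A3", "A4", ">A4")
N_CATEGORIES = len(CN_CATEGORIES)
POPULATION_PAIRS = (("CEU", "YRI"), ("YRI", "ASN"), ("CEU", "ASN"))


def cn_category(cn: int) -> int:
    """Map an integer CN state to its category index (CN >= 5 binned)."""
    if cn < 0:
        raise ValueError(f"negative copy number {cn}")
    return min(cn, N_CATEGORIES - 1)


@dataclass
class StateFrequencies:
    population: str
    counts: np.ndarray  # length 6, per CN category
    N: int

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.N

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CN_CATEGORIES, self.freqs))


@dataclass
class FstResult:
    cnv_id: str
    pair: tuple[str, str]
    fst: float
    Ht: float
    Hs: float


@dataclass
class CnvFrequency:
    cnv_id: str
    population: str
    freq: float
    major_state: str


def state_frequencies(genotypes: GenotypeMatrix, cnv_id: str,
                      population: str) -> StateFrequencies:
    """Category counts/frequencies for one CNV in one population.

    Missing genotypes are excluded from N; an all-missing combination is an
    error because no frequency vector exists for it.
    """
    samples = genotypes.samples_of(population)
    row = genotypes.cn.loc[cnv_id, samples]
    vals = row.dropna().astype(int).to_numpy()
    if vals.size == 0:
        raise ValueError(f"no genotypes for {cnv_id} in {population}")
    counts = np.zeros(N_CATEGORIES, dtype=np.int64)
    for v in vals:
        counts[cn_category(int(v))] += 1
    return StateFrequencies(population, counts, int(vals.size))


def fst(fx: StateFrequencies, fy: StateFrequencies,
        cnv_id: str = "") -> FstResult:
    """Category-based fixation index between two populations."""
    if fx.N <= 0 or fy.N <= 0:
        raise ValueError("both populations need N > 0")
    x, y = fx.freqs, fy.freqs
    nx, ny = fx.N, fy.N
    t = (x * nx + y * ny) / (nx + ny)
    Ht = 1.0 - float(np.sum(t * t))
    Hs = ((1.0 - float(np.sum(x * x))) * nx
          + (1.0 - float(np.sum(y * y))) * ny) / (nx + ny)
    val = 0.0 if Ht == 0.0 else (Ht - Hs) / Ht
    # guard against float round-off at the boundaries
    val = min(1.0, max(0.0, val))
    return FstResult(cnv_id, (fx.population, fy.population), val, Ht, Hs)


def fst_table(genotypes: GenotypeMatrix,
              pairs: Sequence[tuple[str, str]] = POPULATION_PAIRS,
              diallelic_only: bool = False) -> pd.DataFrame:
    """Per-CNV Fst for each population pair (columns ``fst_CEU_YRI`` etc.).

    CNVs with no genotypes in a population get NaN for pairs involving it.
    With ``diallelic_only``, CNVs observed in more than two CN categories
    across all populations are dropped.
    """
    rows = {}
    for cnv_id in genotypes.cnv_ids:
        freqs = {}
        for pop in POPULATIONS:
            try:
                freqs[pop] = state_frequencies(genotypes, cnv_id, pop)
            except ValueError:
                freqs[pop] = None
        if diallelic_only:
            total = np.zeros(N_CATEGORIES, dtype=np.int64)
            for f in freqs.values():
                if f is not None:
                    total += f.counts
            if int((total > 0).sum()) > 2:
                continue
        row = {}
        for a, b in pairs:
            key = f"fst_{a}_{b}"
            if freqs[a] is None or freqs[b] is None:
                row[key] = np.nan
            else:
                row[key] = fst(freqs[a], freqs[b], cnv_id).fst
        rows[cnv_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cnv_id"
    return df


def empirical_cutoff(values: Sequence[float] | np.ndarray,
                     tail: float) -> tuple[float, float]:
    """Upper-tail rank cutoff of an empirical Fst distribution.

    Returns (raw, rounded-to-2-decimals).  The cutoff is the smallest value
    v in the sample such that at most ``tail`` of the values are >= v: with
    the values sorted ascending this is index ceil((1 - tail) * n).
    """
    if not 0 < tail < 1:
        raise ValueError("tail must be in (0, 1)")
    vals = np.sort(np.asarray(values, dtype=float))
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no values")
    idx = min(math.ceil((1 - tail) * vals.size), vals.size - 1)
    raw = float(vals[idx])
    return raw, round(raw, 2)


def empirical_cutoffs(fst_df: pd.DataFrame,
                      tails: Sequence[float] = (0.05, 0.01)
                      ) -> dict[tuple[str, float], float]:
    """Cutoff per (population-pair column, tail), raw values."""
    out = {}
    for col in fst_df.columns:
        pair = col.removeprefix("fst_")
        for tail in tails:
            out[(pair, tail)] = empirical_cutoff(fst_df[col].to_numpy(), tail)[0]
    return out


def polymorphism_frequency(genotypes: GenotypeMatrix, cnv_id: str,
                           reference_population: str = "CEU"
                           ) -> list[CnvFrequency]:
    """Per-population polymorphism frequency relative to the reference
    population's major CN state (ties broken toward the lower CN state)."""
    ref = state_frequencies(genotypes, cnv_id, reference_population)
    major = int(np.argmax(ref.freqs))  # argmax takes the first (lowest) tie
    out = []
    for pop in POPULATIONS:
        try:
            f = state_frequencies(genotypes, cnv_id, pop)
        except ValueError:
            out.append(CnvFrequency(cnv_id, pop, float("nan"),
                                    CN_CATEGORIES[major]))
            continue
        out.append(CnvFrequency(cnv_id, pop, float(1.0 - f.freqs[major]),
                                CN_CATEGORIES[major]))
    return out


def frequency_table(genotypes: GenotypeMatrix,
                    reference_population: str = "CEU") -> pd.DataFrame:
    """Polymorphism frequencies for all CNVs, one column per population."""
    rows = {}
    for cnv_id in genotypes.cnv_ids:
        try:
            freqs = polymorphism_frequency(genotypes, cnv_id,
                                           reference_population)
        except ValueError:
            continue  # no reference genotypes for this CNV
        rows[cnv_id] = {f.population: f.freq for f in freqs}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cnv_id"
    return df[list(POPULATIONS)]
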