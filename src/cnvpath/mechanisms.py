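"""Two-sample tests of proportions for CNV composition comparisons.

Used to ask whether a CNV subset (e.g. CNVs in enriched pathways, or CNVs
differentiated between populations) is shifted in its formation-mechanism
classes (VNTR, NAHR, TEI, NHR) or in its gain/loss composition relative to
a reference set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .data_io import CnvRecord


@dataclass
class ProportionComparison:
    class_label: str
    k1: int
    n1: int
    k2: int
    n2: int
    fold: float
    z: float
    p: float


def proportion_test(k1: int, n1: int, k2: int, n2: int,
                    class_label: str = "") -> ProportionComparison:
    """Pooled two-sample z-test of proportions, two-sided, no continuity
    correction.

    fold = (k1/n1)/(k2/n2); undefined (NaN) when k2 = 0.  The degenerate
    case of a pooled proportion of 0 or 1 yields z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    z = 0.0 if denom == 0 else (p1 - p2) / math.sqrt(denom)
    p = 2 * stats.norm.sf(abs(z))
    fold = p1 / p2 if k2 > 0 else float("nan")
    return ProportionComparison(class_label, k1, n1, k2, n2, fold, z, p)


def compare_composition(subset: Sequence[CnvRecord],
                        reference: Sequence[CnvRecord],
                        attribute: str = "mechanism",
                        use_complement: bool = False) -> pd.DataFrame:
    """One-vs-rest proportion test for every class of ``attribute``.

    By default the reference group is the full CNV set; with
    ``use_complement`` the subset is removed from the reference first.
    """
    if use_complement:
        ids = {c.cnv_id for c in subset}
        reference = [c for c in reference if c.cnv_id not in ids]
    exclude = {"unknown"} | ({"both"} if attribute == "cnv_type" else set())
    sub = [getattr(c, attribute) for c in subset
           if getattr(c, attribute) not in exclude]
    ref = [getattr(c, attribute) for c in reference
           if getattr(c, attribute) not in exclude]
    rows = []
    for cls in sorted(set(sub) | set(ref)):
        if not sub or not ref:
            rows.append((cls, sub.count(cls), len(sub), ref.count(cls),
                         len(ref), float("nan"), float("nan"), float("nan")))
            continue
        cmp = proportion_test(sub.count(cls), len(sub),
                              ref.count(cls), len(ref), class_label=cls)
        rows.append((cls, cmp.k1, cmp.n1, cmp.k2, cmp.n2,
                     cmp.fold, cmp.z, cmp.p))
    return pd.DataFrame(rows, columns=["class", "k_subset", "n_subset",
                                       "k_reference", "n_reference",
                                       "fold", "z", "p"])
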