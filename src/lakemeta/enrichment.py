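"""Compartment-enrichment statistics for protein families.

For every (protein family, lake compartment) pair a 2x2 occurrence
table is built — genomes inside the compartment with/without the
family versus genomes outside — and tested with a two-sided Fisher
exact test.  The degree of enrichment is the ratio of in-compartment to
outside occurrence frequencies; a family absent outside is labeled
"exclusive" and gets no ratio.  P-values are pooled across all pairs
and corrected by Benjamini-Hochberg FDR.  A pair counts as enriched
when adjusted p <= 0.05 and the ratio is >= 3 (or the family is
exclusive).

The Fisher p-value is computed by the point-probability convention —
summing the hypergeometric probabilities of all tables with fixed
margins that are no more likely than the observed one — using exact
integer arithmetic, so ties between equiprobable tables are decided
exactly rather than to floating-point tolerance.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections.abc import Iterable, Mapping
from functools import lru_cache
from itertools import accumulate
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .records import FamilyMembership

logger = logging.getLogger("lakemeta")

#: families need more than this many member proteins to be tested
MIN_FAMILY_PROTEINS = 6

DEFAULT_RATIO_MIN = 3.0
DEFAULT_ALPHA = 0.05


@lru_cache(maxsize=1 << 16)
def _margin_family(row1: int, row2: int, col1: int):
    """Exact hypergeometric numerators for all tables with these margins.

    Returns (numerator per a-value, sorted numerators, their prefix
    sums); the common denominator is C(row1 + row2, col1).
    """
    kmin = max(0, col1 - row2)
    kmax = min(row1, col1)
    nums = {k: comb(row1, k) * comb(row2, col1 - k) for k in range(kmin, kmax + 1)}
    ordered = sorted(nums.values())
    prefix = list(accumulate(ordered))
    return nums, ordered, prefix


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    With margins fixed, p is the total hypergeometric probability of
    every table whose point probability does not exceed the observed
    table's.  Arithmetic is exact (integer numerators over a common
    binomial denominator) with one final correctly-rounded float
    division, so results agree with exhaustive rational enumeration.
    Degenerate margins (an empty row or column) admit a single table
    and give p = 1.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
    row1, row2, col1 = a + b, c + d, a + c
    nums, ordered, prefix = _margin_family(row1, row2, col1)
    observed = nums[a]
    idx = bisect_right(ordered, observed)
    p_num = prefix[idx - 1]
    denom = comb(row1 + row2, col1)
    return min(1.0, p_num / denom)


def enrichment_ratio(a: int, b: int, c: int, d: int) -> tuple[float | None, bool]:
    """Occurrence-frequency ratio (in-compartment over outside).

    Returns (ratio, exclusive).  When no genome outside the compartment
    carries the family (c = 0) but some inside do, the family is
    exclusive and no ratio is computed; a family absent inside (a = 0)
    has ratio 0.
    """
    if a + b <= 0 or c + d <= 0:
        raise ValueError("both the compartment and the outside group must be non-empty")
    if a == 0:
        return 0.0, False
    if c == 0:
        return None, True
    return (a / (a + b)) / (c / (c + d)), False


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_occurrence(
    families: Iterable[FamilyMembership],
    genome_compartments: Mapping[str, Iterable[str]],
    min_family_size: int = MIN_FAMILY_PROTEINS,
) -> pd.DataFrame:
    """2x2 occurrence counts per (family, compartment).

    ``genome_compartments`` maps each genome to the compartments where
    it is detected (from the breadth rule, or supplied directly).  A
    genome detected in several compartments counts as "inside" each of
    them and "outside" only where undetected.  Families with fewer than
    ``min_family_size`` member proteins are dropped.  Genomes with an
    empty compartment set are excluded with a warning.

    Returns a frame with columns family_id, compartment, a, b, c, d
    where a + b is the compartment genome count and c + d the outside
    count.
    """
    members = list(families)
    comp_of: dict[str, frozenset[str]] = {}
    for genome, comps in genome_compartments.items():
        comps = frozenset(comps)
        if not comps:
            logger.warning("genome %s has no compartment assignment; excluded", genome)
            continue
        comp_of[genome] = comps

    protein_count: dict[str, int] = {}
    family_genomes: dict[str, set[str]] = {}
    for m in members:
        protein_count[m.family_id] = protein_count.get(m.family_id, 0) + 1
        if m.genome_id in comp_of:
            family_genomes.setdefault(m.family_id, set()).add(m.genome_id)

    kept = sorted(f for f, n in protein_count.items() if n >= min_family_size)
    compartments = sorted(set().union(*comp_of.values())) if comp_of else []
    n_by_comp = {
        comp: sum(1 for comps in comp_of.values() if comp in comps)
        for comp in compartments
    }
    n_total = len(comp_of)

    rows = []
    for fam in kept:
        carriers = family_genomes.get(fam, set())
        for comp in compartments:
            a = sum(1 for g in carriers if comp in comp_of[g])
            b = n_by_comp[comp] - a
            c = len(carriers) - a
            d = (n_total - n_by_comp[comp]) - c
            rows.append((fam, comp, a, b, c, d))
    return pd.DataFrame(rows, columns=["family_id", "compartment", "a", "b", "c", "d"])


def classify_enriched(
    results: pd.DataFrame,
    ratio_min: float = DEFAULT_RATIO_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Add the boolean ``enriched`` column: adjusted p <= alpha and
    (ratio >= ratio_min or exclusive)."""
    out = results.copy()
    ratio_ok = out["exclusive"] | (
        pd.to_numeric(out["ratio"], errors="coerce").fillna(0.0) >= ratio_min
    )
    out["enriched"] = (out["p_adj"] <= alpha) & ratio_ok
    return out


def run_enrichment(
    families: Iterable[FamilyMembership],
    genome_compartments: Mapping[str, Iterable[str]],
    min_family_size: int = MIN_FAMILY_PROTEINS,
    ratio_min: float = DEFAULT_RATIO_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Full enrichment analysis: occurrence tables, ratios/exclusivity,
    two-sided Fisher tests, pooled BH correction, enrichment flags.

    The FDR family is every (family x compartment) comparison of the
    run, pooled.  Returns one row per comparison with columns a, b, c,
    d, ratio, exclusive, p_raw, p_adj, enriched.
    """
    occ = build_occurrence(families, genome_compartments, min_family_size)
    if occ.empty:
        return occ.assign(
            ratio=pd.Series(dtype=float),
            exclusive=pd.Series(dtype=bool),
            p_raw=pd.Series(dtype=float),
            p_adj=pd.Series(dtype=float),
            enriched=pd.Series(dtype=bool),
        )
    ratios, exclusives, p_raw = [], [], []
    for row in occ.itertuples(index=False):
        ratio, exclusive = enrichment_ratio(row.a, row.b, row.c, row.d)
        ratios.append(ratio)
        exclusives.append(exclusive)
        p_raw.append(fisher_two_sided(row.a, row.b, row.c, row.d))
    occ = occ.assign(
        ratio=pd.array(ratios, dtype="Float64").astype(float),
        exclusive=exclusives,
        p_raw=p_raw,
        p_adj=bh_adjust(p_raw),
    )
    return classify_enriched(occ, ratio_min=ratio_min, alpha=alpha)
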