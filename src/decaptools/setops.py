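"""Gene-set combinatorics: ESR filtering, Venn arithmetic, overlap
enrichment, and redundancy/epistasis classification from a
single/single/double mutant panel."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass(frozen=True)
class VennCounts3:
    """Region counts of a three-set Venn diagram."""

    totals: tuple[int, int, int]
    exclusive: tuple[int, int, int]
    pairwise_only: tuple[int, int, int]  # (ab, ac, bc), triple excluded
    triple: int

    def __post_init__(self) -> None:
        nA, nB, nC = self.totals
        a, b, c = self.exclusive
        ab, ac, bc = self.pairwise_only
        for v in (*self.totals, *self.exclusive, *self.pairwise_only, self.triple):
            if v < 0:
                raise ValueError("Venn region counts must be non-negative")
        checks = (
            nA == a + ab + ac + self.triple,
            nB == b + ab + bc + self.triple,
            nC == c + ac + bc + self.triple,
        )
        if not all(checks):
            raise ValueError("Venn region counts inconsistent with set totals")


def venn3(A: GeneSet, B: GeneSet, C: GeneSet) -> VennCounts3:
    """Exact three-set region counts by set algebra."""
    a, b, c = A.members, B.members, C.members
    abc = a & b & c
    ab = (a & b) - abc
    ac = (a & c) - abc
    bc = (b & c) - abc
    return VennCounts3(
        totals=(len(a), len(b), len(c)),
        exclusive=(
            len(a - b - c),
            len(b - a - c),
            len(c - a - b),
        ),
        pairwise_only=(len(ab), len(ac), len(bc)),
        triple=len(abc),
    )


def solve_venn3_from_totals(
    totals: tuple[int, int, int],
    exclusives: tuple[int, int, int],
    triple: int,
) -> VennCounts3:
    """Reconstruct the pairwise-only overlaps from published totals,
    exclusive counts and the triple overlap.

    Each total satisfies nA = a_only + ab + ac + abc (cyclically), which is
    a linear system with the closed form ab = (x + y - z)/2 where
    x = nA - a_only - abc, etc.
    """
    x = totals[0] - exclusives[0] - triple
    y = totals[1] - exclusives[1] - triple
    z = totals[2] - exclusives[2] - triple
    ab2, ac2, bc2 = x + y - z, x + z - y, y + z - x
    if min(ab2, ac2, bc2) < 0 or any(v % 2 for v in (ab2, ac2, bc2)):
        raise ValueError(
            "inconsistent Venn specification: no non-negative integer solution"
        )
    return VennCounts3(
        totals=totals,
        exclusive=exclusives,
        pairwise_only=(ab2 // 2, ac2 // 2, bc2 // 2),
        triple=triple,
    )


_SET_INDEX = {"A": 0, "B": 1, "C": 2}
_PAIR_INDEX = {frozenset("AB"): 0, frozenset("AC"): 1, frozenset("BC"): 2}


def shared_fraction(venn: VennCounts3, focal: str, partner: str) -> tuple[float, int]:
    """Percent of the focal set shared with the partner (pairwise + triple).

    Returns (raw percentage, whole-percent rounding for reporting).
    """
    if focal == partner or focal not in _SET_INDEX or partner not in _SET_INDEX:
        raise ValueError("focal and partner must be distinct members of {A,B,C}")
    total = venn.totals[_SET_INDEX[focal]]
    if total == 0:
        raise ValueError("focal set is empty")
    shared = venn.pairwise_only[_PAIR_INDEX[frozenset(focal + partner)]] + venn.triple
    pct = 100.0 * shared / total
    return pct, int(round(pct))


def hypergeometric_overlap(k: int, nA: int, nB: int, N: int) -> tuple[float, float]:
    """Fold enrichment and upper-tail hypergeometric p-value of an overlap.

    fold = (k/nA) / (nB/N); p = P(X >= k) for X ~ Hypergeom(N, nA, nB).
    """
    if not (0 <= k <= min(nA, nB) <= N) or nA < 0:
        raise ValueError("require 0 <= k <= min(nA, nB) <= N")
    if nA == 0 or nB == 0:
        raise ValueError("fold enrichment undefined for empty sets")
    fold = (k / nA) / (nB / N)
    p = float(stats.hypergeom.sf(k - 1, N, nA, nB))
    return fold, p


def exclude_esr(
    gene_set: GeneSet,
    esr_annotation: pd.Series | dict[str, str],
    direction: str,
) -> tuple[GeneSet, float]:
    """Drop environmental-stress-response genes from a regulated set.

    Up-regulated sets lose iESR members (induced by stress, hence
    confounded with indirect slow-growth effects); down-regulated sets
    lose rESR members.  Genes absent from the annotation are kept.
    Returns the filtered set and the retained percentage.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if isinstance(esr_annotation, pd.Series):
        esr_annotation = esr_annotation.to_dict()
    drop_class = "iESR" if direction == "up" else "rESR"
    kept = frozenset(
        g for g in gene_set.members if esr_annotation.get(g, "none") != drop_class
    )
    retained = 100.0 * len(kept) / len(gene_set) if len(gene_set) else 0.0
    filtered = GeneSet(
        label=f"non-{drop_class}_{gene_set.label}",
        members=kept,
        provenance=f"{gene_set.provenance}; {drop_class} excluded",
    )
    return filtered, retained


def esr_signature(
    log2fc: pd.Series,
    iesr: set[str] | frozenset[str],
    resr: set[str] | frozenset[str],
) -> tuple[float, float]:
    """Median log2 fold change of the iESR and rESR gene sets."""
    i_vals = log2fc.reindex(list(iesr)).dropna()
    r_vals = log2fc.reindex(list(resr)).dropna()
    if i_vals.empty or r_vals.empty:
        raise ValueError("ESR sets do not intersect the measured genes")
    return float(i_vals.median()), float(r_vals.median())


REDUNDANCY_CALLS = (
    "redundant_double_only",
    "single_shared",
    "single_exclusive",
    "opposite_in_other_single",
    "unclassified",
)


@dataclass(frozen=True)
class RedundancyCall:
    gene_id: str
    pattern: tuple[str, str, str]  # status in (scd6, edc3, double): up/down/ns
    call: str


def _classify_pattern(s6: str, e3: str, double: str) -> str:
    """Pure epistasis-sector mapping from per-contrast significance calls.

    Sector logic (direction-aware): significant only in the double mutant
    means the two factors are redundant for this gene; one single plus the
    double means that factor suffices; one single alone is an exclusive
    target; opposite directions in the two singles flag antagonism.
    """
    singles = (s6, e3)
    n_sig_singles = sum(s != "ns" for s in singles)
    if n_sig_singles == 2 and "up" in singles and "down" in singles:
        return "opposite_in_other_single"
    if double != "ns":
        if n_sig_singles == 0:
            return "redundant_double_only"
        if n_sig_singles == 1:
            return "single_shared"
        return "unclassified"  # both singles + double: not a redundancy sector
    if n_sig_singles == 1:
        return "single_exclusive"
    return "unclassified"


def classify_redundancy(
    patterns: pd.DataFrame,
) -> list[RedundancyCall]:
    """Classify genes into epistasis sectors from a pattern table.

    `patterns` needs columns scd6, edc3, double with values in
    {up, down, ns}; one row per gene (index = gene_id).
    """
    missing = {"scd6", "edc3", "double"} - set(patterns.columns)
    if missing:
        raise ValueError(f"pattern table missing contrasts: {missing}")
    calls = []
    for gene, row in patterns.iterrows():
        pat = (row["scd6"], row["edc3"], row["double"])
        if any(v not in ("up", "down", "ns") for v in pat):
            raise ValueError(f"invalid status in pattern for {gene}: {pat}")
        calls.append(RedundancyCall(gene_id=str(gene), pattern=pat, call=_classify_pattern(*pat)))
    return calls


def patterns_from_sets(
    genes: list[str],
    up_sets: dict[str, GeneSet],
    down_sets: dict[str, GeneSet],
) -> pd.DataFrame:
    """Build the significance-pattern table from thresholded gene sets.

    `up_sets`/`down_sets` map contrast keys (scd6, edc3, double) to the
    called sets; a gene is 'up'/'down' if it is a member, else 'ns'.
    """
    data = {}
    for key in ("scd6", "edc3", "double"):
        up = up_sets[key].members
        dn = down_sets[key].members if key in down_sets else frozenset()
        data[key] = ["up" if g in up else "down" if g in dn else "ns" for g in genes]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
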