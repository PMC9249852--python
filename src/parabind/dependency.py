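"""Cofactor-dependency ordering of paralog-specific loci.

Loci are ordered by the wild-type vs cofactor-interaction-mutant contrast:
loci with higher wild-type occupancy (log2fc > 0) come first, sorted by FDR
ascending (most confidently reduced in the mutant first); loci with higher
mutant occupancy follow, sorted by FDR descending. High-confidence
dependent / independent labels are then assigned by overlap with two
reference locus classes: the last ordered locus overlapping the
significantly-reduced (dependent) class closes the dependent prefix, and
the first locus overlapping the unchanged (independent) class opens the
independent suffix; everything between is ambiguous.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .types import ConsensusLocus, Interval

logger = logging.getLogger(__name__)


@dataclass
class DependencyOrdering:
    """FDR-ordering of loci by cofactor dependency, with confidence labels."""

    locus_ids: list[str]
    sign: dict[str, str]  # locus id -> {"WT_gt_mut", "WT_lt_mut"}
    fdr: dict[str, float]
    labels: dict[str, str] = field(default_factory=dict)
    boundary_dependent: int | None = None  # 1-based index of last dependent locus
    boundary_independent: int | None = None  # 1-based index of first independent locus
    conflict: bool = False


def dependency_sort(loci: list[ConsensusLocus],
                    wt_vs_mut: pd.DataFrame) -> DependencyOrdering:
    """Order loci by the WT-vs-mutant contrast.

    Positive log2fc (WT > mutant) loci sorted by FDR ascending, then
    negative-log2fc loci by FDR descending, concatenated positive-first.
    Ties broken by (contig, start). A log2fc of exactly 0 joins the
    positive class (logged).
    """
    by_id = {lo.locus_id: lo for lo in loci}
    missing = [lid for lid in by_id if lid not in wt_vs_mut.index]
    if missing:
        raise ValueError(f"loci without WT-vs-mutant statistics: {missing[:5]}")
    pos, neg = [], []
    sign, fdr = {}, {}
    for lo in loci:
        row = wt_vs_mut.loc[lo.locus_id]
        lfc, q = float(row["log2fc"]), float(row["fdr"])
        fdr[lo.locus_id] = q
        key = (q, lo.interval.contig, lo.interval.start)
        if lfc > 0:
            sign[lo.locus_id] = "WT_gt_mut"
            pos.append((key, lo.locus_id))
        elif lfc < 0:
            sign[lo.locus_id] = "WT_lt_mut"
            neg.append((key, lo.locus_id))
        else:
            logger.info("locus %s has log2fc == 0; assigned to WT>mut class",
                        lo.locus_id)
            sign[lo.locus_id] = "WT_gt_mut"
            pos.append((key, lo.locus_id))
    pos.sort(key=lambda t: t[0])
    # descending FDR, ties still by coordinates ascending
    neg.sort(key=lambda t: (-t[0][0], t[0][1], t[0][2]))
    ordered = [lid for _, lid in pos] + [lid for _, lid in neg]
    return DependencyOrdering(locus_ids=ordered, sign=sign, fdr=fdr)


def _overlaps_any(iv: Interval, refs: list[Interval]) -> bool:
    return any(iv.overlaps(r) for r in refs)


def confidence_boundaries(
    ordering: DependencyOrdering,
    loci: list[ConsensusLocus],
    dependent_class: list[Interval],
    independent_class: list[Interval],
) -> DependencyOrdering:
    """Assign dependent / ambiguous / independent labels along the ordering.

    i_dep is the 1-based rank of the LAST ordered locus overlapping (>= 1 bp)
    the dependent reference class; i_ind the rank of the FIRST locus
    overlapping the independent class. Ranks [1, i_dep] are dependent,
    [i_ind, end] independent, the rest ambiguous. If i_dep >= i_ind the loci
    between the two indices are flagged as conflicts and the run continues
    with a warning.
    """
    by_id = {lo.locus_id: lo for lo in loci}
    n = len(ordering.locus_ids)
    i_dep, i_ind = 0, n + 1
    for rank, lid in enumerate(ordering.locus_ids, start=1):
        iv = by_id[lid].interval
        if _overlaps_any(iv, dependent_class):
            i_dep = rank
        if i_ind > n and _overlaps_any(iv, independent_class):
            i_ind = rank
    ordering.boundary_dependent = i_dep
    ordering.boundary_independent = i_ind
    if i_dep >= i_ind:
        ordering.conflict = True
        logger.warning("dependency boundaries conflict: i_dep=%d >= i_ind=%d",
                       i_dep, i_ind)
    for rank, lid in enumerate(ordering.locus_ids, start=1):
        if ordering.conflict and min(i_ind, i_dep) <= rank <= max(i_ind, i_dep):
            ordering.labels[lid] = "conflict"
        elif rank <= i_dep:
            ordering.labels[lid] = "dependent"
        elif rank >= i_ind:
            ordering.labels[lid] = "independent"
        else:
            ordering.labels[lid] = "ambiguous"
    return ordering


def ordering_table(ordering: DependencyOrdering) -> pd.DataFrame:
    rows = []
    for rank, lid in enumerate(ordering.locus_ids, start=1):
        rows.append(dict(rank=rank, locus_id=lid, sign=ordering.sign[lid],
                         fdr=ordering.fdr[lid],
                         label=ordering.labels.get(lid, "")))
    return pd.DataFrame(rows)
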