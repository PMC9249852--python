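"""Consensus loci, per-locus signal quantification, and peak-centered matrices.

Loci are built by re-centering each peak on its summit (summit +/- 250 bp,
501 bp total), merging overlapping re-centered windows across replicate peak
sets, and keeping loci supported by at least ``min_overlap`` of the input
sets. Per-locus signal is the sum of per-base coverage over the 100-bp
window [center-50, center+50); sample-to-sample scaling equalizes mean
signal over a shared reference locus set.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConsensusLocus, CoverageTrack, Interval, PeakSet

logger = logging.getLogger(__name__)


def consensus_loci(
    peak_sets: list[PeakSet],
    min_overlap: int = 2,
    summit_halfwidth: int = 250,
) -> list[ConsensusLocus]:
    """Merge summit-re-centered peaks across peak sets into consensus loci.

    Each peak is re-centered to [summit - hw, summit + hw + 1); peaks whose
    re-centered windows overlap (>= 1 bp, any pair, single linkage) are merged
    into one locus whose center is the floor of the mean of contributing
    summits. A locus is retained iff peaks from at least ``min_overlap``
    distinct input sets contributed. Output is sorted by (contig, start).
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least 2 peak sets")
    hw = summit_halfwidth
    recentered = []  # (contig, start, end, summit, set_index)
    for si, ps in enumerate(peak_sets):
        for p in ps:
            if p.summit is None:
                logger.info("peak %s:%d-%d has no summit; using midpoint",
                            p.contig, p.start, p.end)
            c = p.center
            recentered.append((p.contig, max(0, c - hw), c + hw + 1, c, si))
    recentered.sort()
    loci = []
    cluster: list[tuple] = []

    def _flush(cluster):
        members = tuple(
            any(r[4] == si for r in cluster) for si in range(len(peak_sets))
        )
        center = int(np.floor(np.mean([r[3] for r in cluster])))
        iv = Interval(cluster[0][0], max(0, center - hw), center + hw + 1,
                      summit=center)
        return ConsensusLocus(interval=iv, center=center, membership=members)

    cur_contig, cur_end = None, -1
    for rec in recentered:
        contig, start, end = rec[0], rec[1], rec[2]
        if cluster and (contig != cur_contig or start >= cur_end):
            loci.append(_flush(cluster))
            cluster = []
        cluster.append(rec)
        if contig != cur_contig:
            cur_contig, cur_end = contig, end
        else:
            cur_end = max(cur_end, end)
    if cluster:
        loci.append(_flush(cluster))
    loci = [lo for lo in loci if lo.n_members >= min_overlap]
    loci.sort(key=lambda lo: (lo.interval.contig, lo.interval.start))
    for i, lo in enumerate(loci):
        lo.locus_id = f"locus_{i:05d}"
    return loci


def union_loci(peak_sets: list[PeakSet], min_overlap: int = 2,
               summit_halfwidth: int = 250) -> list[ConsensusLocus]:
    """Union ("and/or") locus universe: same membership machinery as
    consensus_loci, without any downstream significance filtering. Mixed
    ChIP and accessibility peak sets are accepted."""
    return consensus_loci(peak_sets, min_overlap=min_overlap,
                          summit_halfwidth=summit_halfwidth)


def locus_score(track: CoverageTrack, contig: str, center: int,
                flank: int = 50) -> float:
    """Sum of per-base signal over [center - flank, center + flank).

    With the default flank of 50 this is exactly 100 bases. Windows that
    run off the contig are truncated with a warning; a center outside the
    contig is an error.
    """
    vec = track[contig]
    if not (0 <= center < len(vec)):
        raise ValueError(f"center {center} outside contig {contig!r}")
    lo, hi = center - flank, center + flank
    if lo < 0 or hi > len(vec):
        warnings.warn(f"locus window [{lo},{hi}) truncated to contig {contig!r}")
        lo, hi = max(0, lo), min(len(vec), hi)
    return float(vec[lo:hi].sum())


def scaling_factor(scores_a: pd.Series, scores_b: pd.Series,
                   shared_locus_ids) -> float:
    """mean(a)/mean(b) over the shared loci; multiplying sample b's scores
    by the factor makes the two shared-set means equal exactly."""
    ids = list(shared_locus_ids)
    if not ids:
        raise ValueError("empty shared locus set")
    ma = float(pd.Series(scores_a).loc[ids].mean())
    mb = float(pd.Series(scores_b).loc[ids].mean())
    if mb <= 0:
        raise ValueError("shared-set mean of sample b is not positive")
    return ma / mb


def signal_matrix(
    loci: list[ConsensusLocus],
    track: CoverageTrack,
    halfwidth: int = 1000,
    binsize: int = 20,
) -> np.ndarray:
    """Peak-centered loci x bins matrix of mean per-base signal.

    Each locus window [center - halfwidth, center + halfwidth) is split into
    2*halfwidth/binsize bins (100 with the defaults); each bin holds the mean
    per-base signal. Bins partially off the contig average the available
    bases; loci fully off a contig yield zero rows (logged).
    """
    if (2 * halfwidth) % binsize != 0:
        raise ValueError("binsize must divide 2*halfwidth")
    n_bins = 2 * halfwidth // binsize
    out = np.zeros((len(loci), n_bins))
    for li, lo in enumerate(loci):
        contig = lo.interval.contig
        if contig not in track:
            logger.warning("locus %s on unknown contig %s -> zero row",
                           lo.locus_id, contig)
            continue
        vec = track[contig]
        w0 = lo.center - halfwidth
        if w0 + 2 * halfwidth <= 0 or w0 >= len(vec):
            logger.warning("locus %s window fully off contig -> zero row",
                           lo.locus_id)
            continue
        for b in range(n_bins):
            s, e = w0 + b * binsize, w0 + (b + 1) * binsize
            s2, e2 = max(0, s), min(len(vec), e)
            if e2 > s2:
                out[li, b] = vec[s2:e2].mean()
    return out


def annotate_locus(center: int, contig: str, gene_table: pd.DataFrame) -> str:
    """Classify a locus center as TSS / TTS / exon / intron / intergenic.

    Precedence TSS > TTS > exon > intron. The TSS (promoter) region is the
    strand-aware window from 1 kb upstream to 100 bp downstream of the
    transcription start, inclusive; the TTS window mirrors it (100 bp
    upstream to 1 kb downstream of the transcription end).
    """
    sub = gene_table[gene_table.contig == contig]
    in_tss = in_tts = in_exon = in_gene = False
    for _, g in sub.iterrows():
        if g.strand == "+":
            tss_lo, tss_hi = g.tss - 1000, g.tss + 100
            tts_lo, tts_hi = g.tts - 100, g.tts + 1000
        else:
            tss_lo, tss_hi = g.tss - 100, g.tss + 1000
            tts_lo, tts_hi = g.tts - 1000, g.tts + 100
        if tss_lo <= center <= tss_hi:
            in_tss = True
        if tts_lo <= center <= tts_hi:
            in_tts = True
        if g.start <= center < g.end:
            in_gene = True
            if any(s <= center < e for s, e in g.exons):
                in_exon = True
    if in_tss:
        return "TSS"
    if in_tts:
        return "TTS"
    if in_exon:
        return "exon"
    if in_gene:
        return "intron"
    return "intergenic"


def pearson(x, y) -> float:
    """Product-moment correlation; zero variance is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


def loci_to_frame(loci: list[ConsensusLocus]) -> pd.DataFrame:
    """Consensus loci as a BED6-plus-membership table."""
    rows = []
    for lo in loci:
        rows.append(
            dict(contig=lo.interval.contig, start=lo.interval.start,
                 end=lo.interval.end, name=lo.locus_id, score=lo.n_members,
                 strand=".", center=lo.center,
                 **{f"member_{i}": int(m) for i, m in enumerate(lo.membership)})
        )
    return pd.DataFrame(rows)
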