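"""Count-based differential occupancy testing and locus classification.

The test is a self-contained negative-binomial Wald test on median-of-ratios
normalized counts: per-locus dispersion is estimated by method of moments and
shrunk halfway toward a trimmed-mean common value, and the log fold change of
condition means is tested with the delta-method variance (mu + alpha*mu^2)/n
per condition. Classification follows the two-threshold scheme used for
replicated ChIP comparisons: a locus is differential when supported by peaks
in >= 2 of the 4 experiments and FDR < 0.05, and common when supported by
>= 3 of 4 and raw p > 0.1; differentially accessible loci additionally
require |log2 fold| > 1 after the FDR cut.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """loci x samples integer counts with per-sample condition/replicate tags."""

    counts: pd.DataFrame  # index: locus ids; columns: sample names
    condition: dict[str, str]  # sample -> condition label
    is_input: dict[str, bool] | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.condition)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns
                if self.condition[s] == condition
                and not (self.is_input or {}).get(s, False)]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample size factors, renormalized to geometric mean 1.

    The reference is the per-locus geometric mean over all-positive loci;
    when no locus is all-positive the factors fall back to relative totals
    (logged).
    """
    mat = counts.values.astype(float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        ref = np.exp(np.log(mat[positive]).mean(axis=1))
        sf = np.median(mat[positive] / ref[:, None], axis=0)
    else:
        logger.warning("no all-positive locus; using total-count size factors")
        totals = mat.sum(axis=0)
        sf = totals / totals.mean()
    sf = sf / np.exp(np.log(sf).mean())  # geometric mean 1
    return pd.Series(sf, index=counts.columns)


def estimate_dispersion(cm: CountMatrix, sf: pd.Series | None = None,
                        shrink: float = 0.5, trim: float = 0.0) -> pd.Series:
    """Per-locus NB dispersion alpha, method of moments with shrinkage.

    On size-factor-normalized counts, alpha_hat = max(0, (s^2 - m) / m^2)
    within each condition, averaged across conditions; the common dispersion
    is the mean across loci (untrimmed by default: the per-locus estimates
    are zero-truncated and right-skewed, so trimming the upper tail biases
    the pooled value low) and each locus is shrunk ``shrink``-weighted
    toward it. The pooled value is stored in ``.attrs["common_dispersion"]``.
    """
    if sf is None:
        sf = size_factors(cm.counts)
    norm = cm.counts / sf
    conds = sorted({c for s, c in cm.condition.items()
                    if not (cm.is_input or {}).get(s, False)})
    per_locus = np.zeros(len(norm))
    n_conds = 0
    for cond in conds:
        cols = cm.samples_of(cond)
        if len(cols) < 2:
            continue
        sub = norm[cols].values
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        per_locus += np.maximum(a, 0.0)
        n_conds += 1
    if n_conds == 0:
        raise ValueError("need >= 2 replicates in at least one condition")
    per_locus /= n_conds
    common = float(stats.trim_mean(per_locus, trim))
    shrunk = shrink * common + (1 - shrink) * per_locus
    out = pd.Series(shrunk, index=cm.counts.index)
    out.attrs["common_dispersion"] = common
    return out


def nb_test(cm: CountMatrix, sf: pd.Series, dispersion: pd.Series | float,
            condition_a: str, condition_b: str,
            pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-locus Wald test of condition A vs B on normalized counts.

    log2fc = log2((mean_A + 0.5) / (mean_B + 0.5)); the Wald statistic uses
    Var(ln mean) ~= (mu + alpha*mu^2) / (n * mu^2) per condition with the
    pseudocounted mean plugged in; p is two-sided normal.
    """
    disp = np.asarray(dispersion if np.ndim(dispersion) else
                      np.full(len(cm.counts), dispersion), dtype=float)
    if (disp < 0).any():
        raise ValueError("dispersion must be >= 0")
    cols_a, cols_b = cm.samples_of(condition_a), cm.samples_of(condition_b)
    if not cols_a or not cols_b:
        raise ValueError("both conditions need samples")
    norm = cm.counts / sf
    ma = norm[cols_a].values.mean(axis=1) + pseudocount
    mb = norm[cols_b].values.mean(axis=1) + pseudocount
    log2fc = np.log2(ma / mb)
    na, nb = len(cols_a), len(cols_b)
    var_ln_a = (ma + disp * ma**2) / (na * ma**2)
    var_ln_b = (mb + disp * mb**2) / (nb * mb**2)
    se = np.sqrt(var_ln_a + var_ln_b)
    z = (np.log(ma) - np.log(mb)) / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p}, index=cm.counts.index
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(cm: CountMatrix, condition_a: str, condition_b: str,
                       dispersion: pd.Series | float | None = None,
                       sf: pd.Series | None = None) -> pd.DataFrame:
    """Full differential pipeline: size factors, dispersion, test, BH FDR.

    The Wald test uses the pooled common dispersion: with two replicates
    per condition the per-locus moment estimates carry almost no
    information, and plugging them into the test breaks type-I calibration.

    ``sf`` lets the caller supply externally estimated size factors, e.g.
    median-of-ratios over background bins: when a large fraction of loci is
    genuinely differential, factors estimated from the locus counts
    themselves are composition-biased.
    """
    if sf is None:
        sf = size_factors(cm.counts)
    if dispersion is None:
        dispersion = estimate_dispersion(cm, sf).attrs["common_dispersion"]
    res = nb_test(cm, sf, dispersion, condition_a, condition_b)
    res["fdr"] = bh_adjust(res["p"].values)
    return res


def classify_paralog_loci(
    diff: pd.DataFrame,
    membership_counts: pd.Series,
    fdr_lt: float = 0.05,
    p_gt: float = 0.1,
    m_diff: int = 2,
    m_common: int = 3,
) -> pd.Series:
    """Differential / common / unclassified labels for a paralog contrast.

    differential: peak support in >= m_diff of the experiments AND
    FDR < fdr_lt (split by sign of log2fc into A>B and A<B); common:
    support in >= m_common AND raw p > p_gt. A locus meeting both rules is
    differential. Everything else is unclassified.
    """
    mem = membership_counts.reindex(diff.index)
    labels = pd.Series("unclassified", index=diff.index)
    common = (mem >= m_common) & (diff["p"] > p_gt)
    labels[common] = "common"
    is_diff = (mem >= m_diff) & (diff["fdr"] < fdr_lt)
    labels[is_diff & (diff["log2fc"] > 0)] = "differential_A_gt_B"
    labels[is_diff & (diff["log2fc"] <= 0)] = "differential_A_lt_B"
    return labels


def classify_accessibility(diff: pd.DataFrame, fdr_lt: float = 0.05,
                           lfc_gt: float = 1.0) -> pd.Series:
    """Two-step differential-accessibility flag: FDR < 0.05 first, then
    |log2 fold| > 1 among the step-1 survivors."""
    step1 = diff["fdr"] < fdr_lt
    logger.info("accessibility step 1: %d of %d loci at FDR < %g",
                int(step1.sum()), len(diff), fdr_lt)
    return step1 & (diff["log2fc"].abs() > lfc_gt)
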