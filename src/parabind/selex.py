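"""k-mer enrichment and single-mode PSAM fitting from one-round SELEX reads.

A read's predicted occupancy weight is the sum of relative affinities over
all offsets and both strands, w(s) = sum_j a+(j) + a-(j). Under a linear
(low-occupancy) selection model, the probability that a library read is
selected is proportional to w(s), so the log-likelihood of the selected
round R1 given the unselected round R0 is

    L(beta) = sum_{s in R1} log w(s) - |R1| * log( mean_{s' in R0} w(s') )

with the R0 sample serving as a Monte-Carlo estimate of the partition
function. L is maximized over mononucleotide parameters by full-batch
gradient ascent with backtracking step halving; the per-position max-0
normalization is re-applied after every step (a pure shift, likelihood
neutral).
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psam import PSAM, encode, scan_sequence
from .types import revcomp

logger = logging.getLogger(__name__)


@dataclass
class SelexReadSet:
    """Reads from one SELEX round, all with the same variable-region length."""

    round: str  # "R0" or "R1"
    reads: list[str]
    variable_length: int
    fixed_5p: str = ""
    fixed_3p: str = ""

    def __post_init__(self):
        if self.round not in ("R0", "R1"):
            raise ValueError("round must be 'R0' or 'R1'")
        for r in self.reads[:100]:
            if len(r) != self.variable_length:
                raise ValueError(
                    f"read length {len(r)} != variable_length {self.variable_length}")

    def __len__(self):
        return len(self.reads)


def read_selex_fasta(path, round: str, variable_length: int) -> SelexReadSet:
    from Bio import SeqIO

    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    reads = [str(r.seq).upper() for r in SeqIO.parse(str(path), fmt)]
    return SelexReadSet(round=round, reads=reads, variable_length=variable_length)


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_enrichment(r0: SelexReadSet, r1: SelexReadSet, k: int) -> pd.DataFrame:
    """Canonical k-mer frequencies in both rounds and their ratio.

    Frequencies are over all read offsets; enrichment uses a pseudo-
    frequency of one window, (f1 + 1/W1) / (f0 + 1/W0). Sorted by
    enrichment descending.
    """
    if k > min(r0.variable_length, r1.variable_length):
        raise ValueError(f"k={k} exceeds the variable-region length")

    def _freqs(rs: SelexReadSet) -> tuple[Counter, int]:
        c: Counter = Counter()
        n_win = 0
        for read in rs.reads:
            for j in range(len(read) - k + 1):
                c[canonical(read[j : j + k])] += 1
                n_win += 1
        return c, n_win

    c0, w0 = _freqs(r0)
    c1, w1 = _freqs(r1)
    kmers = sorted(set(c0) | set(c1))
    f0 = np.array([c0[m] / w0 for m in kmers])
    f1 = np.array([c1[m] / w1 for m in kmers])
    enr = (f1 + 1 / w1) / (f0 + 1 / w0)
    out = pd.DataFrame({"kmer": kmers, "freq_R0": f0, "freq_R1": f1,
                        "enrichment": enr})
    return out.sort_values("enrichment", ascending=False,
                           kind="mergesort").reset_index(drop=True)


def predicted_read_weight(seq: str, psam: PSAM) -> float:
    """Additive occupancy weight of a read: sum of strand-summed affinities
    over all offsets (equals scan_sequence(seq).sum(), exactly)."""
    return float(scan_sequence(seq, psam).sum())


def seed_psam(enrichment: pd.DataFrame, k: int, top: int = 100,
              floor: float = -6.0) -> PSAM:
    """Initialize a PSAM from the enrichment table.

    The top-enriched k-mer becomes the consensus (beta 0); each non-consensus
    base gets log of its column frequency among the ``top`` most enriched
    k-mers (oriented to the consensus by best ungapped match), floored.
    """
    if enrichment.empty:
        raise ValueError("empty enrichment table")
    cons = enrichment.iloc[0]["kmer"]
    if len(cons) != k:
        raise ValueError(f"table k-mers have length {len(cons)}, expected {k}")
    top_kmers = enrichment["kmer"].head(top).tolist()
    counts = np.zeros((k, 4))
    cons_codes = encode(cons)
    for m in top_kmers:
        fwd, rc = m, revcomp(m)
        m_use = fwd if _matches(fwd, cons) >= _matches(rc, cons) else rc
        codes = encode(m_use)
        for i, b in enumerate(codes):
            counts[i, b] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        beta = np.maximum(np.log(freqs), floor)
    beta[np.arange(k), cons_codes] = 0.0
    return PSAM(PSAM.normalize_mono(beta), mode_id="seed")


def _matches(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# fitting


def _windows_from_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """(n_reads, n_offsets*2, k) window codes from an (n, L) code matrix:
    forward windows then the reverse complement of each window, so every
    row scores forward."""
    n_off = codes.shape[1] - k + 1
    idx = np.arange(n_off)[:, None] + np.arange(k)[None, :]  # (n_off, k)
    fwd = codes[:, idx]  # (n, n_off, k)
    rev = (3 - fwd)[:, :, ::-1]  # revcomp of each window
    return np.concatenate([fwd, rev], axis=1)


def _encode_windows(reads: list[str], k: int) -> np.ndarray:
    return _windows_from_codes(np.stack([encode(r) for r in reads]), k)


def read_weights_from_codes(codes: np.ndarray, psam: PSAM) -> np.ndarray:
    """Vectorized w(s) for a batch of equal-length reads given as base codes
    (no N allowed). Mononucleotide parameters only."""
    if psam.beta_di is not None:
        raise ValueError("vectorized weights support mononucleotide models only")
    win = _windows_from_codes(codes, psam.k)
    return _window_scores(win, psam.beta_mono).sum(axis=1)


def _window_scores(win: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """exp of summed mono energies; win: (n, W, k), beta: (k, 4)."""
    k = beta.shape[0]
    e = np.zeros(win.shape[:2])
    for i in range(k):
        e += beta[i, win[:, :, i]]
    return np.exp(e)


@dataclass
class FitResult:
    psam: PSAM
    log_likelihood: float
    n_iterations: int
    converged: bool
    history: list[float] = field(default_factory=list)


def fit_psam(r0: SelexReadSet, r1: SelexReadSet, k: int,
             seed_model: PSAM, max_iter: int = 500,
             tol: float = 1e-6, step0: float = 1.0,
             l2: float = 1e-2) -> FitResult:
    """Penalized-maximum-likelihood mononucleotide PSAM from one SELEX round.

    Full-batch gradient ascent on the mean per-read log-likelihood
    (so step sizes and the convergence tolerance are independent of read
    count) with backtracking step halving; parameters are renormalized to
    per-position max 0 after every accepted step (likelihood-neutral: a
    per-position shift rescales every read weight by the same factor).
    Stops when the per-read objective gain drops below ``tol`` or after
    ``max_iter`` iterations. The reported log-likelihood is the total over
    R1 reads, without the penalty term.

    The ``l2`` ridge penalty acts on per-position mean-centered parameters
    (so it is invariant under the gauge shifts the normalization removes).
    Near a flat model the additive-over-offsets weight depends on the
    parameters only through per-base column sums to first order, leaving
    within-column contrasts almost unidentified; without the penalty an
    unselected (null) library drives the fit to pure-noise optima with
    parameter magnitudes of several tenths. The default 1e-2 per read sits
    an order of magnitude above the null noise curvature (about 1e-3 per
    unit beta^2, matching the chi-square overfitting expectation) and far
    below the per-read information of a genuine selection signal.
    """
    if not r0.reads or not r1.reads:
        raise ValueError("R0 and R1 must be non-empty")
    if seed_model.k != k:
        raise ValueError("seed model k mismatch")
    w1 = _encode_windows(r1.reads, k)
    w0 = _encode_windows(r0.reads, k)
    beta = seed_model.beta_mono.copy()
    n1 = len(r1.reads)

    def ll_and_grad(beta):
        a1 = _window_scores(w1, beta)  # (n1, W)
        a0 = _window_scores(w0, beta)
        s1 = a1.sum(axis=1)  # per-read weights
        s0 = a0.sum(axis=1)
        ll = np.log(s1).mean() - np.log(s0.mean())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood during fit")
        # d ll / d beta[i,b] = mean_r sum_w (a1/s1_r) x_w - sum a0 x_w / sum s0
        grad = np.zeros((k, 4))
        wt1 = a1 / (n1 * s1[:, None])
        wt0 = a0 / s0.sum()
        for i in range(k):
            np.add.at(grad, (i, w1[:, :, i].ravel()), wt1.ravel())
            np.subtract.at(grad, (i, w0[:, :, i].ravel()), wt0.ravel())
        centered = beta - beta.mean(axis=1, keepdims=True)
        obj = ll - l2 * (centered**2).sum()
        return obj, ll, grad - 2 * l2 * centered

    obj, ll, grad = ll_and_grad(beta)
    history = [obj]
    step = step0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() == 0:
            converged = True
            break
        accepted = False
        for _ in range(40):
            cand = PSAM.normalize_mono(beta + step * grad)
            try:
                cobj, cll, cgrad = ll_and_grad(cand)
            except FloatingPointError:
                step /= 2
                continue
            if cobj > obj:
                accepted = True
                break
            step /= 2
        if not accepted:
            converged = True
            break
        gain = cobj - obj
        beta, obj, ll, grad = cand, cobj, cll, cgrad
        history.append(obj)
        step = min(step * 2, 1e4)
        if gain < tol:
            converged = True
            break
    psam = PSAM(PSAM.normalize_mono(beta), mode_id="fit")
    return FitResult(psam=psam, log_likelihood=float(ll * n1), n_iterations=it,
                     converged=converged, history=history)
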