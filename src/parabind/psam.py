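"""Position-specific affinity models (PSAMs) and genome affinity tracks.

A PSAM assigns every k-bp window a relative binding affinity
``exp(sum_i beta_mono[i, b_i] + sum_i beta_di[i, (b_i, b_{i+1})])`` with the
mononucleotide parameters normalized so the per-position maximum is 0; the
mono-consensus sequence then scores exactly 1 (when no dinucleotide terms are
present). Genome tracks are built by summing affinities across both strands
at every offset, normalizing to the genomic maximum, discarding values below
a threshold (default 1e-4), and taking a windowed maximum of length k to
smooth out local position-specific variation.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import GenomeSequence, revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = -1
DINUCS = [a + b for a in BASES for b in BASES]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0,C=1,G=2,T=3,N=-1."""
    table = np.full(128, -2, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes == -2):
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return codes


@dataclass
class PSAM:
    """Free-energy-like binding model of length k.

    beta_mono: (k, 4) array, natural-log scale, per-position max = 0.
    beta_di: optional (k-1, 16) array of adjacent-dinucleotide corrections,
    indexed by 4*b1 + b2.
    """

    beta_mono: np.ndarray
    beta_di: Optional[np.ndarray] = None
    mode_id: str = "mode0"

    def __post_init__(self):
        self.beta_mono = np.asarray(self.beta_mono, dtype=float)
        if self.beta_mono.ndim != 2 or self.beta_mono.shape[1] != 4:
            raise ValueError("beta_mono must have shape (k, 4)")
        if self.beta_di is not None:
            self.beta_di = np.asarray(self.beta_di, dtype=float)
            if self.beta_di.shape != (self.k - 1, 16):
                raise ValueError("beta_di must have shape (k-1, 16)")
        if not np.allclose(self.beta_mono.max(axis=1), 0.0, atol=1e-9):
            raise ValueError("beta_mono must satisfy per-position max = 0")

    @property
    def k(self) -> int:
        return self.beta_mono.shape[0]

    @property
    def consensus(self) -> str:
        """Mono-consensus: the per-position argmax base (ties -> first in ACGT)."""
        return "".join(BASES[i] for i in self.beta_mono.argmax(axis=1))

    def reverse_complement(self) -> "PSAM":
        """The model that scores a window as this model scores its revcomp."""
        mono = self.beta_mono[::-1, ::-1].copy()
        di = None
        if self.beta_di is not None:
            di = np.empty_like(self.beta_di)
            for i in range(self.k - 1):
                for b1 in range(4):
                    for b2 in range(4):
                        di[i, 4 * b1 + b2] = self.beta_di[
                            self.k - 2 - i, 4 * (3 - b2) + (3 - b1)
                        ]
        return PSAM(mono, di, mode_id=self.mode_id)

    @staticmethod
    def normalize_mono(beta_mono: np.ndarray) -> np.ndarray:
        """Shift each position so its maximum is 0 (affinity-scale invariant)."""
        beta_mono = np.asarray(beta_mono, dtype=float)
        return beta_mono - beta_mono.max(axis=1, keepdims=True)


@dataclass
class AffinityTrack:
    """Normalized, thresholded, windowed-max relative affinities per contig."""

    data: dict[str, np.ndarray]
    k: int
    threshold: float
    raw_max: float  # genomic maximum of the strand-summed affinity before normalization
    anchor: str = "left"
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.data[contig]


@dataclass(frozen=True)
class MotifHit:
    """One scored binding-site window."""

    contig: str
    offset: int
    strand: str
    relative_affinity: float


# ---------------------------------------------------------------------------
# scoring


def relative_affinity(window: str, psam: PSAM, strand: str = "+") -> float:
    """Relative affinity of one k-bp window; N anywhere -> 0."""
    if len(window) != psam.k:
        raise ValueError(f"window length {len(window)} != k={psam.k}")
    if strand == "-":
        window = revcomp(window)
    codes = encode(window)
    if np.any(codes < 0):
        return 0.0
    e = psam.beta_mono[np.arange(psam.k), codes].sum()
    if psam.beta_di is not None:
        di_idx = 4 * codes[:-1] + codes[1:]
        e += psam.beta_di[np.arange(psam.k - 1), di_idx].sum()
    return float(np.exp(e))


def _scan_one_strand(codes: np.ndarray, psam: PSAM) -> np.ndarray:
    """Per-offset affinities on the encoded forward sequence; N windows -> 0."""
    n, k = codes.size, psam.k
    n_off = n - k + 1
    safe = np.where(codes < 0, 0, codes)
    energy = np.zeros(n_off)
    for i in range(k):
        energy += psam.beta_mono[i, safe[i : i + n_off]]
    if psam.beta_di is not None:
        # dinucleotide energies accumulate separately (mono-sum + di-sum)
        di_idx = 4 * safe[:-1] + safe[1:]
        di_energy = np.zeros(n_off)
        for i in range(k - 1):
            di_energy += psam.beta_di[i, di_idx[i : i + n_off]]
        energy = energy + di_energy
    aff = np.exp(energy)
    has_n = codes < 0
    if has_n.any():
        # window j contains an N iff any of codes[j..j+k-1] is N
        bad = np.convolve(has_n.astype(int), np.ones(k, dtype=int), mode="valid") > 0
        aff[bad] = 0.0
    return aff


def _scan_reverse_strand(codes: np.ndarray, psam: PSAM) -> np.ndarray:
    """Per-offset affinities of each window's reverse complement.

    Energies accumulate in the same position order as scoring the revcomp
    window directly, so results match a per-window oracle bit-for-bit.
    """
    n, k = codes.size, psam.k
    n_off = n - k + 1
    comp = np.where(codes < 0, 0, 3 - codes)
    energy = np.zeros(n_off)
    for m in range(k):
        # position m of the revcomp window is forward position j + k-1-m
        energy += psam.beta_mono[m, comp[k - 1 - m : k - 1 - m + n_off]]
    if psam.beta_di is not None:
        di_energy = np.zeros(n_off)
        for m in range(k - 1):
            b1 = comp[k - 1 - m : k - 1 - m + n_off]
            b2 = comp[k - 2 - m : k - 2 - m + n_off]
            di_energy += psam.beta_di[m, 4 * b1 + b2]
        energy = energy + di_energy
    aff = np.exp(energy)
    has_n = codes < 0
    if has_n.any():
        bad = np.convolve(has_n.astype(int), np.ones(k, dtype=int), mode="valid") > 0
        aff[bad] = 0.0
    return aff


def scan_sequence(seq, psam: PSAM) -> np.ndarray:
    """Strand-summed raw relative affinities at every offset of a sequence.

    Entry j is the affinity of window [j, j+k) on the forward strand plus the
    affinity of its reverse complement. Length is len(seq) - k + 1.
    """
    s = seq.sequence if isinstance(seq, GenomeSequence) else seq
    name = seq.name if isinstance(seq, GenomeSequence) else "<sequence>"
    if len(s) < psam.k:
        raise ValueError(f"contig {name!r} shorter than k={psam.k}")
    codes = encode(s)
    fwd = _scan_one_strand(codes, psam)
    rev = _scan_reverse_strand(codes, psam)
    return fwd + rev


def windowed_max(values: np.ndarray, k: int, anchor: str = "left") -> np.ndarray:
    """Left-anchored sliding maximum: out[i] = max(values[i : min(i+k, n)]).

    Windows are truncated at the right edge so the output length equals the
    input length.
    """
    if k < 1:
        raise ValueError("window length k must be >= 1")
    if anchor != "left":
        raise ValueError(f"unsupported anchor {anchor!r}")
    values = np.asarray(values, dtype=float)
    if k == 1:
        return values.copy()
    padded = np.concatenate([values, np.full(k - 1, -np.inf)])
    return np.lib.stride_tricks.sliding_window_view(padded, k).max(axis=1)


def build_affinity_track(
    genome: Sequence[GenomeSequence],
    psam: PSAM | Sequence[PSAM],
    threshold: float = 1e-4,
    anchor: str = "left",
) -> AffinityTrack:
    """Genome-wide normalized affinity track.

    Steps, in this fixed order: (1) sum affinities across both strands at
    every offset (summing across modes when several PSAMs are given);
    (2) divide by the global maximum across all contigs; (3) zero values
    below ``threshold``; (4) windowed maximum of length k. Per-offset
    vectors are padded with zeros to contig length so track coordinates
    match genome coordinates.
    """
    psams = [psam] if isinstance(psam, PSAM) else list(psam)
    if not psams:
        raise ValueError("need at least one PSAM")
    k = psams[0].k
    if any(p.k != k for p in psams):
        raise ValueError("all modes must share the same k")
    if not genome:
        raise ValueError("empty genome")
    raw: dict[str, np.ndarray] = {}
    for contig in genome:
        vec = np.zeros(len(contig))
        per_offset = sum(_scan_sum_modes(contig, p) for p in psams)
        vec[: len(contig) - k + 1] = per_offset
        raw[contig.name] = vec
    raw_max = max(v.max() for v in raw.values())
    if raw_max <= 0:
        raise ValueError("no scorable window (all affinities are 0)")
    data = {}
    for name, vec in raw.items():
        norm = vec / raw_max
        norm[norm < threshold] = 0.0
        data[name] = windowed_max(norm, k, anchor=anchor)
    return AffinityTrack(
        data=data, k=k, threshold=threshold, raw_max=float(raw_max), anchor=anchor,
        metadata={"modes": [p.mode_id for p in psams]},
    )


def _scan_sum_modes(contig: GenomeSequence, psam: PSAM) -> np.ndarray:
    if len(contig) < psam.k:
        raise ValueError(f"contig {contig.name!r} shorter than k={psam.k}")
    return scan_sequence(contig, psam)


def top_motifs(
    seq, psam: PSAM, n: int = 10, genomic_max: Optional[float] = None
) -> list[MotifHit]:
    """The n strongest binding-site windows of a sequence, per strand.

    Every offset is scored on each strand separately (so each hit has a
    defined strand), normalized to ``genomic_max`` when given (the raw_max
    of a companion AffinityTrack), else to the sequence maximum. Sorted by
    affinity descending; ties broken by (offset, + before -).
    """
    s = seq.sequence if isinstance(seq, GenomeSequence) else seq
    name = seq.name if isinstance(seq, GenomeSequence) else "seq"
    if len(s) < psam.k:
        raise ValueError(f"sequence shorter than k={psam.k}")
    codes = encode(s)
    fwd = _scan_one_strand(codes, psam)
    rev = _scan_reverse_strand(codes, psam)
    denom = genomic_max if genomic_max is not None else max(fwd.max(), rev.max())
    if denom <= 0:
        return []
    hits = []
    for off in range(len(fwd)):
        if fwd[off] > 0:
            hits.append(MotifHit(name, off, "+", float(fwd[off] / denom)))
        if rev[off] > 0:
            hits.append(MotifHit(name, off, "-", float(rev[off] / denom)))
    hits.sort(key=lambda h: (-h.relative_affinity, h.offset, h.strand))
    return hits[:n]


# ---------------------------------------------------------------------------
# PSAM text format
#
#   #PSAM k=<k> mode_id=<id> dinuc=<0|1>
#   #mono A C G T
#   <k rows of 4 floats>
#   [#di AA AC ... TT
#    <k-1 rows of 16 floats>]


def write_psam(psam: PSAM, path) -> None:
    with open(path, "w") as fh:
        dinuc = 0 if psam.beta_di is None else 1
        fh.write(f"#PSAM k={psam.k} mode_id={psam.mode_id} dinuc={dinuc}\n")
        fh.write("#mono " + " ".join(BASES) + "\n")
        for row in psam.beta_mono:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
        if psam.beta_di is not None:
            fh.write("#di " + " ".join(DINUCS) + "\n")
            for row in psam.beta_di:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_psam(path) -> PSAM:
    """Read the PSAM text format; mono parameters are renormalized on read
    so the per-position maximum is 0 (a pure shift; window affinities are
    unchanged up to the global track normalization)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    m = re.match(r"#PSAM k=(\d+) mode_id=(\S+) dinuc=([01])", lines[0])
    if not m:
        raise ValueError(f"{path}: bad PSAM header {lines[0]!r}")
    k, mode_id, dinuc = int(m.group(1)), m.group(2), int(m.group(3))
    body = [ln for ln in lines[1:] if not ln.startswith("#")]
    if len(body) != k + (k - 1 if dinuc else 0):
        raise ValueError(f"{path}: expected {k} mono rows"
                         + (f" and {k-1} di rows" if dinuc else ""))
    mono = []
    for i, ln in enumerate(body[:k]):
        vals = ln.split()
        if len(vals) != 4:
            raise ValueError(f"{path}: mono row {i} has {len(vals)} columns, need 4")
        mono.append([float(v) for v in vals])
    mono = PSAM.normalize_mono(np.array(mono))
    di = None
    if dinuc:
        di = []
        for i, ln in enumerate(body[k:]):
            vals = ln.split()
            if len(vals) != 16:
                raise ValueError(f"{path}: di row {i} has {len(vals)} columns, need 16")
            di.append([float(v) for v in vals])
        di = np.array(di)
    return PSAM(mono, di, mode_id=mode_id)


def write_affinity_bedgraph(track: AffinityTrack, path) -> None:
    """Export an affinity track as bedGraph (4 decimals, equal runs merged)."""
    from .io import write_bedgraph
    from .types import CoverageTrack

    write_bedgraph(CoverageTrack(track.data), path, decimals=4)


def motif_table(hits: list[MotifHit]):
    import pandas as pd

    return pd.DataFrame(
        [(h.contig, h.offset, h.strand, h.relative_affinity) for h in hits],
        columns=["contig", "offset", "strand", "relative_affinity"],
    )
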