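"""Core domain containers shared across the pipeline.

Coordinates are 0-based half-open everywhere (BED convention). GTF input is
converted on read; no other module performs 1-based arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: an uppercase DNA sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"contig {self.name!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.name!r}: invalid characters {sorted(bad)!r} "
                "(alphabet is A,C,G,T,N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Interval:
    """Genomic interval, 0-based half-open, with optional summit and score."""

    contig: str
    start: int
    end: int
    strand: str = "."
    summit: Optional[int] = None
    score: Optional[float] = None
    name: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.contig}:{self.start}-{self.end}"
            )

    @property
    def center(self) -> int:
        """Summit when present, else interval midpoint (floor)."""
        if self.summit is not None:
            return self.summit
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        """True iff the two intervals share >= 1 bp on the same contig."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class CoverageTrack:
    """Dense per-base non-negative signal, one float vector per contig."""

    def __init__(self, data: dict[str, np.ndarray]):
        self.data = {}
        for contig, vec in data.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"contig {contig!r}: coverage must be 1-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"contig {contig!r}: coverage must be finite and >= 0")
            self.data[contig] = arr

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.data[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.data

    def contigs(self) -> list[str]:
        return list(self.data)


@dataclass
class ConsensusLocus:
    """A summit-re-centered locus supported by one or more peak sets.

    membership[i] is True iff input peak set i contributed a peak.
    """

    interval: Interval
    center: int
    membership: tuple[bool, ...]
    locus_id: str = ""

    def __post_init__(self):
        if not (self.interval.start <= self.center < self.interval.end):
            raise ValueError("locus center outside its interval")

    @property
    def n_members(self) -> int:
        return sum(self.membership)


@dataclass
class PeakSet:
    """A named collection of peaks from one experiment."""

    name: str
    peaks: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self):
        return len(self.peaks)
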