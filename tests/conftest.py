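import numpy as np
import pytest

from parabind.psam import PSAM
from parabind.types import GenomeSequence


@pytest.fixture
def two_base_psam():
    """k=2 model: pos0 {A:0,C:-1,G:-2,T:-3}, pos1 {T:0,A:-1,C:-1,G:-1}.

    Mono-consensus 'AT' scores 1; 'CT' scores e^-1.
    """
    return PSAM(np.array([[0.0, -1.0, -2.0, -3.0],
                          [-1.0, -1.0, -1.0, 0.0]]))


@pytest.fixture
def identity_psam():
    """All-zero parameters: every N-free window scores 1."""
    return PSAM(np.zeros((2, 4)))


@pytest.fixture
def random_genome():
    rng = np.random.default_rng(1234)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=200)])
    return GenomeSequence("chrT", seq)


def naive_affinity(window: str, psam: PSAM) -> float:
    """Brute-force single-window score, independent of the scanning code."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    if "N" in window:
        return 0.0
    e = sum(psam.beta_mono[i][idx[b]] for i, b in enumerate(window))
    if psam.beta_di is not None:
        e += sum(psam.beta_di[i][4 * idx[window[i]] + idx[window[i + 1]]]
                 for i in range(len(window) - 1))
    return float(np.exp(e))


def naive_revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(s))


def naive_track(genome, psam, threshold=1e-4):
    """Independent enumeration oracle for build_affinity_track: scores every
    window on both strands per contig, pads, normalizes, thresholds, and
    takes a naive O(n k) left-anchored sliding max."""
    raw = {}
    k = psam.k
    for contig in genome:
        s = contig.sequence
        vec = np.zeros(len(s))
        for j in range(len(s) - k + 1):
            w = s[j : j + k]
            vec[j] = naive_affinity(w, psam) + naive_affinity(naive_revcomp(w), psam)
        raw[contig.name] = vec
    m = max(v.max() for v in raw.values())
    out = {}
    for name, vec in raw.items():
        norm = vec / m
        norm[norm < threshold] = 0.0
        n = len(norm)
        out[name] = np.array([norm[i : min(i + k, n)].max() for i in range(n)])
    return out, m
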