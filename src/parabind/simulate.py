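"""Synthetic genomes, motif models, ChIP-style data and SELEX reads with
planted ground truth.

The generator emulates a two-condition (paralog A vs paralog B), two-
replicate ChIP design with matched inputs, plus a cofactor-interaction-
mutant condition, over a random genome carrying planted motif instances of
four locus classes:

- shared: a monomer consensus, bound equally in both conditions;
- specific_cofactor_dependent: a composite-dimer site bound preferentially
  in condition A, whose occupancy collapses in the interaction mutant;
- specific_cofactor_independent: a spaced-dimer site (monomer site plus an
  adjacent partner half-site) bound preferentially in A, preserved in the
  mutant;
- specific_other: a monomer-only site bound preferentially in A with
  neither dimer signature.

Counts are negative binomial; per-sample coverage is a triangular kernel of
half-width 250 bp scaled so that the kernel height is count/250 (hence the
100-bp locus score equals count * 90/250 exactly); per-replicate peak
calling is emulated with a logistic detection probability on the count, so
membership-based consensus rules are genuinely exercised.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psam import PSAM, scan_sequence
from .selex import SelexReadSet
from .types import CoverageTrack, GenomeSequence, Interval, PeakSet, revcomp

BASES = "ACGT"

PEAK_HALFWIDTH = 250  # coverage-kernel and planted-peak half-width, bp


@dataclass
class SimulationPlan:
    """Study conditions for one synthetic experiment."""

    genome_length: int = 500_000
    gc: float = 0.41
    n_shared: int = 100
    n_dependent: int = 40
    n_independent: int = 40
    n_other: int = 20
    effect_log2fc: float = 2.0   # planted log2 fold change, condition A over B
    mean_depth: float = 200.0    # expected ChIP count at a fully bound locus
    dispersion: float = 0.1      # NB alpha
    input_depth: float = 5.0     # expected background count
    peak_detect_slope: float = 0.5  # logistic steepness of peak-call emulation
    track_background: float = 0.0   # flat per-base coverage baseline
    n_background_bins: int = 400    # non-peak bins emitted for normalization
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.gc < 1):
            raise ValueError("gc must lie in (0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if min(self.n_shared, self.n_dependent, self.n_independent,
               self.n_other) < 0:
            raise ValueError("locus counts must be >= 0")

    @property
    def n_loci(self) -> int:
        return self.n_shared + self.n_dependent + self.n_independent + self.n_other


def make_genome(length: int, gc: float, seed: int,
                name: str = "chrS") -> GenomeSequence:
    """Random i.i.d. genome with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 < gc < 1):
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])
    return GenomeSequence(name, seq)


def make_psam_set(seed: int) -> dict[str, PSAM]:
    """Deterministic monomer / composite-dimer / spaced-dimer model triple.

    monomer: 7-bp AT-rich consensus, off-consensus penalties in [-3.5, -1.5];
    composite: 12-bp model whose two 7-bp half-sites overlap by 2 bp, the
    first half-site being the monomer consensus; spaced: two 6-bp half-site
    blocks around a 4-bp near-neutral spacer (spacer betas >= -0.2).
    """
    rng = np.random.default_rng(seed)

    def _penalized(consensus: str, lo=-3.5, hi=-1.5) -> np.ndarray:
        k = len(consensus)
        beta = rng.uniform(lo, hi, size=(k, 4))
        for i, b in enumerate(consensus):
            beta[i, BASES.index(b)] = 0.0
        return PSAM.normalize_mono(beta)

    mono_cons = "".join(rng.choice(list("AT"), size=7))
    # ensure it is not a homopolymer (keeps half-sites distinguishable)
    mono_cons = mono_cons[:3] + ("A" if mono_cons[3] == "T" else "T") + mono_cons[4:]
    partner = mono_cons[-2:] + "".join(rng.choice(list("ACGT"), size=5,
                                                  p=[.35, .15, .15, .35]))
    composite_cons = mono_cons + partner[2:]  # 7 + 7 with 2 bp shared
    half_a = mono_cons[:6]
    half_b = "".join(rng.choice(list("ACGT"), size=6, p=[.35, .15, .15, .35]))
    spacer = "".join(rng.choice(list("ACGT"), size=4))
    spaced_cons = half_a + spacer + half_b

    monomer = PSAM(_penalized(mono_cons), mode_id="monomer")
    composite = PSAM(_penalized(composite_cons), mode_id="composite_dimer")
    beta_sp = _penalized(spaced_cons, lo=-3.0, hi=-1.5)
    for i in range(6, 10):  # near-neutral spacer positions
        row = rng.uniform(-0.2, 0.0, size=4)
        row[BASES.index(spaced_cons[i])] = 0.0
        beta_sp[i] = row
    spaced = PSAM(PSAM.normalize_mono(beta_sp), mode_id="spaced_dimer")
    return {"monomer": monomer, "composite_dimer": composite,
            "spaced_dimer": spaced}


_CLASS_MOTIF = {
    "shared": "monomer",
    "specific_cofactor_dependent": "composite_dimer",
    "specific_cofactor_independent": "spaced_dimer",
    "specific_other": "monomer",
}


def plant_sites(genome: GenomeSequence, psams: dict[str, PSAM],
                plan: SimulationPlan):
    """Overwrite the genome with one motif instance per planned locus.

    Returns (genome', truth_table, loci). Locus centers are laid out with at
    least 2 kb spacing; classes are shuffled across positions. Planted
    occupancies (expected count = input_depth + occ * mean_depth): shared
    loci are bound equally in both conditions (occ 1); the three specific
    classes are bound 2**effect_log2fc-fold more in condition A than B
    (occ_A = 2**effect, occ_B = 1); the interaction mutant preserves
    condition-A occupancy everywhere except cofactor-dependent loci, where
    binding collapses to background (occ 0).
    """
    rng = np.random.default_rng(plan.seed)
    n = plan.n_loci
    if n == 0:
        return genome, _empty_truth(), []
    margin = 1000
    spacing = (plan.genome_length - 2 * margin) // max(n, 1)
    if spacing < 2000:
        need = 2 * margin + 2000 * n
        raise ValueError(
            f"genome too short for {n} loci at 2 kb spacing; need >= {need} bp")
    classes = (["shared"] * plan.n_shared
               + ["specific_cofactor_dependent"] * plan.n_dependent
               + ["specific_cofactor_independent"] * plan.n_independent
               + ["specific_other"] * plan.n_other)
    rng.shuffle(classes)
    occ_a_specific = 2.0 ** plan.effect_log2fc
    seq = list(genome.sequence)
    rows, loci = [], []
    for i, cls in enumerate(classes):
        center = margin + i * spacing + spacing // 2
        motif_name = _CLASS_MOTIF[cls]
        site = psams[motif_name].consensus
        strand = rng.choice(["+", "-"])
        planted = site if strand == "+" else revcomp(site)
        off = center - len(site) // 2
        seq[off : off + len(site)] = planted
        occ_a = 1.0 if cls == "shared" else occ_a_specific
        occ_b = 1.0
        occ_mut = 0.0 if cls == "specific_cofactor_dependent" else occ_a
        lid = f"locus_{i:05d}"
        rows.append(dict(
            locus_id=lid, truth_class=cls, contig=genome.name, center=center,
            site_offset=off, strand=strand, motif_type=motif_name,
            rel_affinity=1.0, occ_A=occ_a, occ_B=occ_b, occ_mut=occ_mut,
        ))
        loci.append(Interval(genome.name, center - PEAK_HALFWIDTH,
                             center + PEAK_HALFWIDTH + 1, summit=center,
                             name=lid))
    truth = pd.DataFrame(rows).set_index("locus_id")
    return GenomeSequence(genome.name, "".join(seq)), truth, loci


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["truth_class", "contig", "center", "site_offset", "strand",
                 "motif_type", "rel_affinity", "occ_A", "occ_B", "occ_mut"]
    ).rename_axis("locus_id")


def _nb_draw(rng, mean, alpha, size=None):
    """NB draws with Var = mu + alpha*mu^2; alpha=0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


#: ChIP sample layout: (name, condition, occupancy column, is_input)
CHIP_SAMPLES = [
    ("A_rep1", "A", "occ_A", False), ("A_rep2", "A", "occ_A", False),
    ("B_rep1", "B", "occ_B", False), ("B_rep2", "B", "occ_B", False),
    ("mut_rep1", "mut", "occ_mut", False), ("mut_rep2", "mut", "occ_mut", False),
    ("input_rep1", "input", None, True), ("input_rep2", "input", None, True),
]


def simulate_chip(truth: pd.DataFrame, genome_length: int,
                  plan: SimulationPlan, make_tracks: bool = True):
    """NB counts, coverage tracks and emulated per-replicate peak sets.

    Per locus and ChIP sample: count ~ NB(input_depth + occ * mean_depth,
    alpha); matched inputs ~ NB(input_depth, alpha). A sample's peak set
    contains a locus with probability logistic(slope * (count - 3 *
    input_depth)); called summits are jittered by up to +/-20 bp around the
    planted center. Besides the locus counts, ``n_background_bins``
    non-peak background bins are drawn per sample at the input depth and
    returned as a second count table: they carry each sample's sequencing
    depth free of binding signal, the information background normalization
    relies on when many loci are genuinely differential.

    Returns (counts, background_counts, condition_map, is_input_map,
    tracks, peak_sets).
    """
    rng = np.random.default_rng(plan.seed + 1)
    counts = {}
    bg = {}
    for name, _cond, occ_col, is_input in CHIP_SAMPLES:
        if is_input:
            mean = np.full(len(truth), plan.input_depth)
        else:
            mean = plan.input_depth + truth[occ_col].values * plan.mean_depth
        counts[name] = _nb_draw(rng, mean, plan.dispersion)
        bg[name] = _nb_draw(rng, np.full(plan.n_background_bins,
                                         plan.input_depth), plan.dispersion)
    count_df = pd.DataFrame(counts, index=truth.index)
    bg_df = pd.DataFrame(
        bg, index=[f"bg_{i:05d}" for i in range(plan.n_background_bins)])

    peak_sets = {}
    for name, _cond, _occ, is_input in CHIP_SAMPLES:
        if is_input:
            continue
        c = count_df[name].values.astype(float)
        p_call = 1.0 / (1.0 + np.exp(-plan.peak_detect_slope
                                     * (c - 3 * plan.input_depth)))
        called = rng.random(len(c)) < p_call
        jitter = rng.integers(-20, 21, size=len(c))
        peaks = []
        for (lid, row), ok, j in zip(truth.iterrows(), called, jitter):
            if not ok:
                continue
            s = int(row.center + j)
            peaks.append(Interval(row.contig, s - PEAK_HALFWIDTH,
                                  s + PEAK_HALFWIDTH + 1, summit=s, name=lid))
        peak_sets[name] = PeakSet(name=name, peaks=peaks)

    tracks = {}
    if make_tracks:
        d = np.arange(-PEAK_HALFWIDTH + 1, PEAK_HALFWIDTH)
        kernel = 1.0 - np.abs(d) / PEAK_HALFWIDTH  # height 1 at the center
        for name, _cond, _occ, is_input in CHIP_SAMPLES:
            vec = np.full(genome_length, plan.track_background, dtype=float)
            for (lid, row), c in zip(truth.iterrows(), count_df[name].values):
                h = c / PEAK_HALFWIDTH
                lo = int(row.center) - PEAK_HALFWIDTH + 1
                vec[lo : lo + kernel.size] += h * kernel
            tracks[name] = CoverageTrack({truth.contig.iloc[0] if len(truth)
                                          else "chrS": vec})
    meta = {name: cond for name, cond, _o, _i in CHIP_SAMPLES}
    is_input = {name: inp for name, _c, _o, inp in CHIP_SAMPLES}
    return count_df, bg_df, meta, is_input, tracks, peak_sets


def expected_locus_score(count: float, flank: int = 50,
                         background: float = 0.0) -> float:
    """Closed-form 100-bp locus score of the triangular kernel.

    sum_{d=-flank}^{flank-1} (count/250) * (1 - |d|/250) + 2*flank*background.
    """
    d = np.arange(-flank, flank)
    return float((count / PEAK_HALFWIDTH)
                 * (1 - np.abs(d) / PEAK_HALFWIDTH).sum()
                 + 2 * flank * background)


def simulate_selex(psam: PSAM, n_reads: int, variable_length: int, seed: int,
                   calibration_size: int = 10_000):
    """One-round SELEX read pair (R0, R1) under linear selection.

    R0 reads are uniform; R1 reads are rejection-sampled with acceptance
    probability w(s)/w_max, where w(s) is the additive occupancy weight and
    w_max the maximum weight in a seeded calibration sample (probabilities
    capped at 1).
    """
    import warnings

    if variable_length < psam.k:
        raise ValueError("variable_length must be >= k")
    if n_reads < 1000:
        warnings.warn("fewer than 1000 reads: downstream fits will be unstable")
    from .selex import read_weights_from_codes

    rng = np.random.default_rng(seed)
    base_arr = np.array(list(BASES))

    def _uniform_codes(n):
        return rng.integers(0, 4, size=(n, variable_length), dtype=np.int8)

    def _to_strings(codes):
        return ["".join(row) for row in base_arr[codes]]

    if psam.beta_di is None:
        _weights = lambda codes: read_weights_from_codes(codes, psam)
    else:
        _weights = lambda codes: np.array(
            [scan_sequence(s, psam).sum() for s in _to_strings(codes)])

    w_max = _weights(_uniform_codes(calibration_size)).max()
    r0_reads = _to_strings(_uniform_codes(n_reads))
    accepted: list[np.ndarray] = []
    n_acc = 0
    batch_size = max(4 * n_reads, 10_000)
    while n_acc < n_reads:
        batch = _uniform_codes(batch_size)
        w = _weights(batch)
        keep = rng.random(len(batch)) < np.minimum(w / w_max, 1.0)
        accepted.append(batch[keep])
        n_acc += int(keep.sum())
    r1_reads = _to_strings(np.concatenate(accepted)[:n_reads])
    r0 = SelexReadSet(round="R0", reads=r0_reads, variable_length=variable_length)
    r1 = SelexReadSet(round="R1", reads=r1_reads, variable_length=variable_length)
    return r0, r1
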