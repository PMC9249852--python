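# parabind

Tools for dissecting **paralog-specific transcription-factor binding**:
when two paralogous factors (for example two Hox proteins expressed in
serially homologous tissues) share nearly identical monomer DNA-binding
preferences, which genomic loci do they nonetheless occupy differently,
and how much of that difference is explained by heterodimerization with a
cofactor? `parabind` implements the genomics side of that question as a
reusable, fully tested pipeline:

- **PSAM affinity tracks** — position-specific affinity models
  (`a(s) = exp(Σ_i β_i(b_i) + Σ_i β_i(b_i, b_{i+1}))`, consensus = 1)
  scanned over a genome, strand-summed, normalized to the genomic maximum,
  thresholded at 10⁻⁴ and smoothed with a windowed maximum of length k.
- **Consensus loci and occupancy scores** — summit ± 250 bp re-centering,
  replicate merging with membership tracking, 100-bp locus scores,
  between-sample scaling factors, and ±1 kb / 20-bp peak-centered matrices.
- **Differential occupancy** — a negative-binomial Wald test on
  median-of-ratios normalized counts with BH FDR, and the two-rule
  classification: *differential* (peak support ≥ 2/4, FDR < 0.05, sign
  splits A>B from A<B) vs *common* (support ≥ 3/4, raw p > 0.1); plus the
  two-step differential-accessibility rule (FDR < 0.05 then |log2FC| > 1).
- **Cofactor-dependency ordering** — A-specific loci sorted by the
  wild-type vs interaction-mutant contrast (WT>mut by FDR ascending, then
  WT<mut by FDR descending) with high-confidence dependent / independent
  boundaries from overlap with reference classes.
- **SELEX model fitting** — k-mer enrichment between an unselected (R0)
  and one selected (R1) round, and a single-mode mononucleotide PSAM fit
  by penalized maximum likelihood under linear selection,
  `L(β) = Σ_{R1} log w(s) − |R1| log( mean_{R0} w )`, where `w(s)` sums
  window affinities over offsets and strands.
- **Synthetic data with planted truth** — genomes, monomer /
  composite-dimer / spaced-dimer motif models, NB ChIP counts, coverage
  tracks, emulated per-replicate peak calling and one-round SELEX reads,
  so every stage is testable end-to-end without any external download.

See `docs/methods.md` for the models, parameter defaults, and the design
decisions behind the statistics.

## Worked example

Run the self-contained synthetic analysis (200 planted loci: 100 shared,
40 cofactor-dependent, 40 cofactor-independent, 20 other A-specific;
2×2 design at depth 200, NB dispersion 0.1, 4-fold planted effect):

```python
import tempfile
from parabind import RunConfig
from parabind.pipeline import run_pipeline, recovery_metrics

cfg = RunConfig(rng_seed=1)
with tempfile.TemporaryDirectory() as out:
    res = run_pipeline(cfg, out, stages=["simulate", "quantify",
                                         "classify", "dependency"])
    print(res["classify"]["table"].head(3).round(4))
    print(recovery_metrics(res))
```

which prints (seed 1):

```
             log2fc       p     fdr          class_label
locus_00000  0.2346  0.6227  0.7687               common
locus_00001  2.8032  0.0000  0.0000  differential_A_gt_B
locus_00002 -0.4660  0.3273  0.5112               common
{'sensitivity': 0.97, 'n_specific': 100, 'fpr': 0.0, 'n_shared': 100,
 'dependent_placed': 1.0, 'n_dep': 38,
 'independent_placed': 0.974, 'n_ind': 39, 'i_dep': 40, 'i_ind': 41}
```

Reading: 97 of the 100 planted A-specific loci are recovered as
`differential_A_gt_B` at FDR < 0.05 (sensitivity 0.97) with no shared
locus mislabeled (fpr 0.0); in the dependency ordering, all ranked
cofactor-dependent loci fall at or before the dependent boundary
(i_dep = 40) and 97% of ranked independent loci at or after the
independent boundary (i_ind = 41).

The same stages are exposed on the command line:

```sh
parabind --seed 1 --out-dir out dependency   # runs simulate..dependency
parabind show-config                          # all defaults
```

writing `genome.fa`, `truth.tsv`, `counts.tsv`, `consensus_loci.tsv`,
`differential.tsv`, `dependency.tsv` and the PSAM/bedGraph exports.

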