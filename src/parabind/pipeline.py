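"""End-to-end orchestration: simulate -> scan -> quantify -> classify ->
dependency -> selex-fit, with every stage logging its parameters and writing
deterministic tabular outputs."""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff_mod
from . import io as pio
from . import occupancy as occ_mod
from . import psam as psam_mod
from . import selex as selex_mod
from . import simulate as sim_mod
from .config import RunConfig
from .dependency import confidence_boundaries, dependency_sort, ordering_table
from .types import Interval

logger = logging.getLogger(__name__)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def match_loci_to_truth(loci, truth: pd.DataFrame, max_dist: int = 250):
    """Map consensus loci to planted truth rows by nearest center within
    ``max_dist`` bp on the same contig. Returns {locus_id: truth_id}."""
    mapping = {}
    by_contig = {c: sub for c, sub in truth.groupby("contig")}
    for lo in loci:
        sub = by_contig.get(lo.interval.contig)
        if sub is None:
            continue
        d = (sub.center - lo.center).abs()
        if d.min() <= max_dist:
            mapping[lo.locus_id] = d.idxmin()
    return mapping


def run_pipeline(config: RunConfig, out_dir, stages=None) -> dict:
    """Execute the configured stages and write all outputs under out_dir.

    With no external inputs configured, the run starts from the synthetic
    generator (the default, fully self-contained mode). Identical config
    and seed produce byte-identical outputs. Returns a dict of result
    objects keyed by stage.
    """
    stages = list(stages or ["simulate", "scan", "quantify", "classify",
                             "dependency", "selex-fit"])
    _validate_stages(config, stages)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run parameters: %s", vars(config))
    results: dict = {}
    seed = config.rng_seed

    if "simulate" in stages:
        plan = sim_mod.SimulationPlan(seed=seed)
        psams = sim_mod.make_psam_set(seed)
        genome0 = sim_mod.make_genome(plan.genome_length, plan.gc, seed)
        genome, truth, planted = sim_mod.plant_sites(genome0, psams, plan)
        counts, bg_counts, cond, is_inp, tracks, peak_sets = sim_mod.simulate_chip(
            truth, plan.genome_length, plan, make_tracks=True)
        pio.write_fasta([genome], out / "genome.fa")
        truth.to_csv(out / "truth.tsv", sep="\t")
        counts.to_csv(out / "counts.tsv", sep="\t")
        bg_counts.to_csv(out / "background_counts.tsv", sep="\t")
        for name, ps in peak_sets.items():
            pio.write_intervals(ps, out / f"peaks_{name}.narrowPeak",
                                dialect="narrowPeak")
        for name, mdl in psams.items():
            psam_mod.write_psam(mdl, out / f"psam_{name}.txt")
        results["simulate"] = dict(plan=plan, psams=psams, genome=genome,
                                   truth=truth, planted=planted, counts=counts,
                                   background_counts=bg_counts,
                                   condition=cond, is_input=is_inp,
                                   tracks=tracks, peak_sets=peak_sets)
        logger.info("simulate: genome %s (%s)", "genome.fa",
                    _digest(out / "genome.fa"))

    if "scan" in stages:
        sim = results.get("simulate")
        if sim is not None:
            genome_seqs, psams = [sim["genome"]], sim["psams"]
        else:
            genome_seqs = pio.read_fasta(config.genome_fasta)
            psams = {Path(p).stem: psam_mod.read_psam(p)
                     for p in config.psam_files}
        tracks = {}
        for name, mdl in psams.items():
            tr = psam_mod.build_affinity_track(
                genome_seqs, mdl, threshold=config.affinity_threshold)
            psam_mod.write_affinity_bedgraph(tr, out / f"affinity_{name}.bedgraph")
            tracks[name] = tr
        results["scan"] = tracks

    if "quantify" in stages:
        sim = results["simulate"]
        chip_sets = [sim["peak_sets"][s] for s in
                     ("A_rep1", "A_rep2", "B_rep1", "B_rep2")]
        loci = occ_mod.consensus_loci(chip_sets,
                                      min_overlap=config.min_overlap_differential,
                                      summit_halfwidth=config.summit_halfwidth)
        scores = {}
        for name, track in sim["tracks"].items():
            scores[name] = [occ_mod.locus_score(track, lo.interval.contig,
                                                lo.center, flank=config.flank)
                            for lo in loci]
        score_df = pd.DataFrame(scores, index=[lo.locus_id for lo in loci])
        pio.write_tsv(occ_mod.loci_to_frame(loci), out / "consensus_loci.tsv")
        score_df.to_csv(out / "locus_scores.tsv", sep="\t")
        results["quantify"] = dict(loci=loci, scores=score_df)

    if "classify" in stages:
        sim = results["simulate"]
        q = results["quantify"]
        loci = q["loci"]
        mapping = match_loci_to_truth(loci, sim["truth"])
        matched = [lo for lo in loci if lo.locus_id in mapping]
        cm = diff_mod.CountMatrix(
            counts=sim["counts"].loc[[mapping[lo.locus_id] for lo in matched]]
            .set_axis([lo.locus_id for lo in matched]),
            condition=sim["condition"], is_input=sim["is_input"])
        # background normalization: factors from non-peak bins, immune to
        # the composition shift a large differential fraction induces
        bg_sf = diff_mod.size_factors(sim["background_counts"])
        table = diff_mod.differential_table(cm, "A", "B", sf=bg_sf)
        membership = pd.Series({lo.locus_id: lo.n_members for lo in matched})
        table["class_label"] = diff_mod.classify_paralog_loci(
            table, membership, fdr_lt=config.fdr_differential,
            p_gt=config.p_common, m_diff=config.min_overlap_differential,
            m_common=config.min_overlap_common)
        table.to_csv(out / "differential.tsv", sep="\t")
        results["classify"] = dict(table=table, count_matrix=cm,
                                   loci=matched, mapping=mapping)

    if "dependency" in stages:
        sim = results["simulate"]
        cl = results["classify"]
        cm, table = cl["count_matrix"], cl["table"]
        bg_sf = diff_mod.size_factors(sim["background_counts"])
        wt_mut = diff_mod.differential_table(cm, "A", "mut", sf=bg_sf)
        # membership for the WT-vs-mutant contrast comes from its own four
        # experiments (WT and mutant replicates), not the paralog peak sets
        mapping = cl["mapping"]
        wm_sets = [sim["peak_sets"][s] for s in
                   ("A_rep1", "A_rep2", "mut_rep1", "mut_rep2")]
        called = [{p.name for p in ps} for ps in wm_sets]
        membership = pd.Series(
            {lo.locus_id: sum(mapping[lo.locus_id] in c for c in called)
             for lo in cl["loci"]})
        wt_mut_label = diff_mod.classify_paralog_loci(
            wt_mut, membership, fdr_lt=config.fdr_differential,
            p_gt=config.p_common, m_diff=config.min_overlap_differential,
            m_common=config.min_overlap_common)
        spec_ids = set(table.index[table.class_label == "differential_A_gt_B"])
        ordered_loci = [lo for lo in cl["loci"] if lo.locus_id in spec_ids]
        dep_refs = [lo.interval for lo in cl["loci"]
                    if wt_mut_label[lo.locus_id] == "differential_A_gt_B"]
        ind_refs = [lo.interval for lo in cl["loci"]
                    if wt_mut_label[lo.locus_id] == "common"]
        ordering = dependency_sort(ordered_loci, wt_mut)
        ordering = confidence_boundaries(ordering, ordered_loci,
                                         dep_refs, ind_refs)
        pio.write_tsv(ordering_table(ordering), out / "dependency.tsv")
        results["dependency"] = dict(ordering=ordering, wt_vs_mut=wt_mut)

    if "selex-fit" in stages:
        sim = results.get("simulate")
        if sim is not None:
            mono = sim["psams"]["monomer"]
            r0, r1 = sim_mod.simulate_selex(mono, config.selex_reads, 16,
                                            seed + 2)
        else:
            k = config.selex_k
            r0 = selex_mod.read_selex_fasta(config.selex_r0, "R0", 16)
            r1 = selex_mod.read_selex_fasta(config.selex_r1, "R1", 16)
            mono = None
        enr = selex_mod.kmer_enrichment(r0, r1, config.selex_k)
        seed_model = selex_mod.seed_psam(enr, config.selex_k)
        fit = selex_mod.fit_psam(r0, r1, config.selex_k, seed_model)
        pio.write_tsv(enr.head(1000), out / "kmer_enrichment.tsv")
        psam_mod.write_psam(fit.psam, out / "psam_fitted.txt")
        diag = dict(log_likelihood=fit.log_likelihood,
                    n_iterations=fit.n_iterations, converged=fit.converged,
                    model_scope="single mode, mononucleotide, one round")
        (out / "selex_fit.json").write_text(json.dumps(diag, indent=2))
        results["selex-fit"] = dict(fit=fit, enrichment=enr, true_model=mono)

    return results


def recovery_metrics(results: dict) -> dict:
    """Planted-truth recovery of a simulate->classify->dependency run.

    sensitivity: fraction of planted condition-A-specific loci labeled
    differential with the correct sign; fpr: fraction of planted shared
    loci labeled differential either way; dependent_placed /
    independent_placed: fraction of planted cofactor-dependent
    (independent) loci, among those present in the dependency ordering,
    ranked at or before i_dep (at or after i_ind).
    """
    truth = results["simulate"]["truth"]
    table = results["classify"]["table"]
    mapping = results["classify"]["mapping"]
    inv = {v: k for k, v in mapping.items()}
    tc = truth.truth_class
    lab = table.class_label

    def label_of(truth_id):
        return lab.get(inv.get(truth_id), "missing")

    spec_ids = truth.index[tc != "shared"]
    shared_ids = truth.index[tc == "shared"]
    sens = float(np.mean([label_of(t) == "differential_A_gt_B"
                          for t in spec_ids]))
    fpr = float(np.mean([label_of(t) in ("differential_A_gt_B",
                                         "differential_A_lt_B")
                         for t in shared_ids]))
    ordering = results["dependency"]["ordering"]
    rank = {lid: r for r, lid in enumerate(ordering.locus_ids, start=1)}

    def placed(cls, keep):
        ranks = [rank[inv[t]] for t in truth.index[tc == cls]
                 if inv.get(t) in rank]
        return (float(np.mean([keep(r) for r in ranks])), len(ranks))

    dep, n_dep = placed("specific_cofactor_dependent",
                        lambda r: r <= ordering.boundary_dependent)
    ind, n_ind = placed("specific_cofactor_independent",
                        lambda r: r >= ordering.boundary_independent)
    return dict(sensitivity=sens, n_specific=len(spec_ids), fpr=fpr,
                n_shared=len(shared_ids), dependent_placed=dep, n_dep=n_dep,
                independent_placed=ind, n_ind=n_ind,
                i_dep=ordering.boundary_dependent,
                i_ind=ordering.boundary_independent)


def _validate_stages(config: RunConfig, stages) -> None:
    """Fail before any computation when a requested stage lacks its inputs."""
    known = {"simulate", "scan", "quantify", "classify", "dependency",
             "selex-fit", "report"}
    bad = set(stages) - known
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    simulated = "simulate" in stages
    if "scan" in stages and not simulated and not (
            config.genome_fasta and config.psam_files):
        raise ValueError("scan stage needs genome_fasta and psam_files, "
                         "or the simulate stage")
    for st in ("quantify", "classify", "dependency"):
        if st in stages and not simulated:
            raise ValueError(f"{st} stage requires the simulate stage "
                             "(external count input not configured)")
    if "selex-fit" in stages and not simulated and not (
            config.selex_r0 and config.selex_r1):
        raise ValueError("selex-fit stage needs selex_r0 and selex_r1 reads, "
                         "or the simulate stage")
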