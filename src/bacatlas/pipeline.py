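"""End-to-end pipeline driver.

Stages run in the order simulate -> classify -> annotate -> synteny ->
landscape -> saturate -> stats. Each stage records its outputs and
parameters in a JSON manifest; a stage whose inputs were provided
externally consumes them unchanged (their checksums go into the manifest).
A stage whose upstream data is missing fails with an error naming it.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import annotation as ann
from . import arm_classifier as armc
from . import landscape as lsc
from . import metrics as met
from . import saturation as sat
from . import synteny as syn
from . import synthetic as sim
from .config import PipelineConfig
from .errors import DataError
from .io import config_hash, read_fasta, write_fasta, write_table

log = logging.getLogger("bacatlas")

ALL_STAGES = ["simulate", "classify", "annotate", "synteny", "landscape", "saturate", "stats"]


def default_synthetic_config(seed: int = 0, outdir: str = "bacatlas_out") -> PipelineConfig:
    """Pipeline configuration for a self-contained synthetic run.

    The genome plants one interior gene-dense island inside chromosome 2's
    recombination-suppressed zone, so the landscape stage has a deviant
    region to find. The landscape window/step are scaled to the toy
    chromosome length keeping the production 16:1 window:step ratio.
    """
    cfg = PipelineConfig(seed=seed, outdir=outdir)
    spec = dataclasses.replace(cfg.genome, seed=seed)
    chrom_len = sum(spec.arm_pairs()[1]) - spec.centromere_overlap_len
    island_half = int(0.12 * chrom_len)
    centre = chrom_len // 2
    cfg.genome = dataclasses.replace(
        spec,
        interior_islands=((1, centre - island_half, centre + island_half, 120),),
    )
    # assembled targets are single-copy: the rare-k-mer filter (meant to scrub
    # sequencing errors out of read-based targets) must not apply
    cfg.classifier = dataclasses.replace(cfg.classifier, min_kmer_count=1)
    cfg.landscape = dataclasses.replace(cfg.landscape, window=400_000, step=25_000)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineState:
    """In-memory objects handed between stages."""

    def __init__(self):
        self.genome: sim.SimulatedGenome | None = None
        self.library: sim.BacLibrary | None = None
        self.matrix = None
        self.gene_bearing: set | None = None
        self.hit_table: pd.DataFrame | None = None
        self.bacs: dict[str, dict[str, str]] | None = None  # bac -> nodes
        self.targets: dict[str, str] | None = None
        self.assignments: pd.DataFrame | None = None
        self.retained_hits: pd.DataFrame | None = None
        self.gene_counts: dict | None = None


def _require(value, stage: str, what: str):
    if value is None:
        raise DataError(f"stage {stage!r}: missing upstream input ({what})")
    return value


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the pipeline and return the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stages = stages or ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise DataError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    # the hash identifies the scientific configuration; where the run writes
    # and how chattily it logs are not part of it
    cfg_dict.pop("outdir", None)
    cfg_dict.pop("log_level", None)
    state = PipelineState()
    manifest: dict = {
        "tool": "bacatlas",
        "version": __version__,
        "config_hash": config_hash(cfg_dict),
        "seed": config.seed,
        "stages": {},
    }

    # external inputs pre-load (skip-simulate path)
    ext = config.inputs
    inputs_note = {}
    if ext.targets_fasta:
        state.targets = read_fasta(ext.targets_fasta)
        inputs_note["targets_fasta"] = {"path": ext.targets_fasta, "sha256": _sha256(Path(ext.targets_fasta))}
    if ext.bacs_fasta:
        recs = read_fasta(ext.bacs_fasta)
        bacs: dict[str, dict[str, str]] = {}
        for node_id, seq in recs.items():
            bac_id = node_id.rsplit("_n", 1)[0] if "_n" in node_id else node_id
            bacs.setdefault(bac_id, {})[node_id] = seq
        state.bacs = bacs
        inputs_note["bacs_fasta"] = {"path": ext.bacs_fasta, "sha256": _sha256(Path(ext.bacs_fasta))}
    if ext.hits_tsv:
        state.hit_table = pd.read_csv(ext.hits_tsv, sep="\t", comment="#")
        inputs_note["hits_tsv"] = {"path": ext.hits_tsv, "sha256": _sha256(Path(ext.hits_tsv))}
    if inputs_note:
        manifest["external_inputs"] = inputs_note

    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        log.info("stage %s", stage)
        outputs = _STAGE_FN[stage](config, state, outdir, cfg_dict)
        manifest["stages"][stage] = outputs

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, state: PipelineState, outdir: Path, cfg_dict) -> dict:
    genome = sim.simulate_genome(config.genome)
    lib = sim.simulate_bac_library(
        genome,
        n_clones=config.library.n_clones,
        insert_mean=config.library.insert_mean,
        insert_sd=config.library.insert_sd,
        node_split=config.library.node_split,
        seed=config.seed + 1,
    )
    matrix, screening_truth = sim.simulate_probe_screening(
        genome,
        lib,
        n_pools=config.screening.n_pools,
        detect_prob=config.screening.detect_prob,
        fp_rate=config.screening.fp_rate,
        seed=config.seed + 2,
    )
    hit_table = sim.simulate_hit_table(lib, genome, noise=config.synteny.noise, seed=config.seed + 3)

    d = outdir / "simulate"
    write_fasta(d / "arm_targets.fasta", genome.arm_targets)
    write_fasta(
        d / "bacs.fasta",
        ((nid, s) for bac in lib.clones for nid, s in bac.nodes.items()),
    )
    gene_seqs = {
        row.gene_id: genome.sequences[row.chrom][row.start : row.end]
        for row in genome.genes.itertuples()
    }
    write_fasta(d / "gene_models.fasta", gene_seqs)
    write_table(
        genome.genes.rename(columns={"gene_id": "model_id"})[["model_id", "confidence_class"]],
        d / "gene_classes.tsv",
        cfg_dict,
    )
    write_table(lib.truth, d / "bac_truth.tsv", cfg_dict)
    write_table(genome.map_samples(), d / "genetic_map.tsv", cfg_dict)
    mat_out = matrix.reset_index()
    write_table(mat_out, d / "detection_matrix.tsv", cfg_dict)
    write_table(hit_table, d / "synteny_hits.tsv", cfg_dict)

    state.genome = genome
    state.library = lib
    state.matrix = matrix
    state.gene_bearing = screening_truth.gene_bearing
    state.hit_table = hit_table
    state.targets = genome.arm_targets
    state.bacs = {b.bac_id: b.nodes for b in lib.clones}
    return {
        "outputs": sorted(str(p) for p in d.iterdir()),
        "n_clones": len(lib),
        "n_genes": int(len(genome.genes)),
    }


def _stage_classify(config: PipelineConfig, state: PipelineState, outdir: Path, cfg_dict) -> dict:
    targets = _require(state.targets, "classify", "arm target sequences")
    bacs = _require(state.bacs, "classify", "BAC assemblies")
    index = armc.build_index(targets, config.classifier)
    clones = [sim.BacAssembly(bac_id=b, nodes=nodes) for b, nodes in bacs.items()]
    assignments, summary = armc.classify_library(index, clones, config.classifier)
    frame = armc.assignments_frame(assignments)

    d = outdir / "classify"
    d.mkdir(parents=True, exist_ok=True)
    index.save(d / "kmer_index.bin")
    write_table(frame, d / "assignments.tsv", cfg_dict)
    state.assignments = frame
    return {
        "outputs": [str(d / "kmer_index.bin"), str(d / "assignments.tsv")],
        "summary": summary,
        "n_index_kmers": len(index),
    }


def _stage_annotate(config: PipelineConfig, state: PipelineState, outdir: Path, cfg_dict) -> dict:
    bacs = _require(state.bacs, "annotate", "BAC assemblies")
    genome = _require(state.genome, "annotate", "gene model sequences")
    assignments = _require(state.assignments, "annotate", "assignments from classify")
    gene_seqs = {
        row.gene_id: genome.sequences[row.chrom][row.start : row.end]
        for row in genome.genes.itertuples()
    }
    nodes_flat = {nid: s for nodes in bacs.values() for nid, s in nodes.items()}
    raw = ann.match_genes_builtin(nodes_flat, gene_seqs)
    node_index = pd.DataFrame(
        [
            {"node_id": nid, "bac_id": b, "length": len(s)}
            for b, nodes in bacs.items()
            for nid, s in nodes.items()
        ]
    )
    filtered = ann.filter_hits(raw, node_index, config.annotation)
    excluded, retained = ann.flag_frequent_models(filtered, config.annotation)
    classes = genome.genes.rename(columns={"gene_id": "model_id"})[["model_id", "confidence_class"]]
    counts = ann.count_genes(retained, assignments, classes)

    d = outdir / "annotate"
    write_table(retained, d / "gene_hits.tsv", cfg_dict)
    write_table(pd.DataFrame({"model_id": excluded}), d / "excluded_models.tsv", cfg_dict)
    write_table(counts["per_bac"], d / "per_bac_genes.tsv", cfg_dict)
    write_table(counts["per_label"], d / "per_label_genes.tsv", cfg_dict)
    state.retained_hits = retained
    state.gene_counts = counts
    return {
        "outputs": sorted(str(p) for p in d.iterdir()),
        "summary": counts["summary"],
        "n_excluded_models": len(excluded),
    }


def _stage_synteny(config: PipelineConfig, state: PipelineState, outdir: Path, cfg_dict) -> dict:
    hits = _require(state.hit_table, "synteny", "cross-species hit table")
    votes = syn.vote_table(hits, evalue_cutoff=config.synteny.evalue_cutoff)
    d = outdir / "synteny"
    write_table(votes, d / "votes.tsv", cfg_dict)
    outputs = [str(d / "votes.tsv")]

    if state.library is not None:
        contigs = sim.contig_assignments(state.library)
        vmap = {
            r.bac_id: syn.SyntenyVote(
                bac_id=r.bac_id,
                status=r.status,
                chrom=None if pd.isna(r.chrom) else r.chrom,
                position=None if pd.isna(r.position) else r.position,
            )
            for r in votes.itertuples()
        }
        rows = []
        for cid, sub in contigs.groupby("contig_id", sort=True):
            members = [vmap[b] for b in sub["bac_id"] if b in vmap]
            if not members:
                continue
            v = syn.vote_contig(members, contig_id=str(cid))
            rows.append(
                {"contig_id": v.bac_id, "status": v.status, "chrom": v.chrom, "position": v.position}
            )
        write_table(pd.DataFrame(rows), d / "contig_votes.tsv", cfg_dict)
        outputs.append(str(d / "contig_votes.tsv"))
    return {"outputs": outputs, "n_placed": int((votes["status"] == "placed").sum())}


def _stage_landscape(config: PipelineConfig, state: PipelineState, outdir: Path, cfg_dict) -> dict:
    genome = _require(state.genome, "landscape", "genome truth for anchoring")
    lib = _require(state.library, "landscape", "library truth")
    hits = _require(state.retained_hits, "landscape", "retained gene hits from annotate")
    truth = lib.truth
    mid = ((truth["start"] + truth["end"]) // 2).to_numpy()
    cm = np.array(
        [genome.map_cm(c, m) for c, m in zip(truth["chrom"], mid)], dtype=float
    )
    hc_ids = set(
        genome.genes.loc[genome.genes["confidence_class"] == "HC", "gene_id"]
    )
    hc_by_bac = (
        hits[hits["gene_model_id"].isin(hc_ids)]
        .groupby("bac_id")["gene_model_id"]
        .agg(lambda s: ";".join(sorted(set(s))))
    )
    anchored = pd.DataFrame(
        {
            "bac_id": truth["bac_id"],
            "chrom": truth["chrom"],
            "bp": mid,
            "cM": np.round(cm, 6),
            "hc_models": hc_by_bac.reindex(truth["bac_id"]).fillna("").to_numpy(),
        }
    )
    lengths = {c: genome.chrom_length(c) for c in genome.chrom_names}
    stats = lsc.window_stats(anchored, config.landscape, chrom_lengths=lengths)
    regions = lsc.detect_deviant_regions(stats, config.landscape)
    track = lsc.bac_density_track(anchored, config.landscape, chrom_lengths=lengths)

    d = outdir / "landscape"
    write_table(anchored, d / "anchored_bacs.tsv", cfg_dict)
    write_table(stats, d / "windows.tsv", cfg_dict)
    write_table(regions, d / "deviant_regions.tsv", cfg_dict)
    write_table(track, d / "bac_density.tsv", cfg_dict)
    return {
        "outputs": sorted(str(p) for p in d.iterdir()),
        "n_windows": int(len(stats)),
        "n_deviant_regions": int(len(regions)),
    }


def _stage_saturate(config: PipelineConfig, state: PipelineState, outdir: Path, cfg_dict) -> dict:
    matrix = _require(state.matrix, "saturate", "detection matrix")
    curve = sat.accumulation_curve(
        matrix, n_permutations=config.saturation.n_permutations, seed=config.seed + 4
    )
    estimate = sat.fit_asymptote(curve, model=config.saturation.model)
    d = outdir / "saturate"
    write_table(curve.frame(), d / "accumulation_curve.tsv", cfg_dict)
    est = {
        "asymptote": estimate.asymptote,
        "model": estimate.model_name,
        "params": estimate.params,
        "residual_rms": estimate.residual_rms,
        "observed_unique": float(curve.mean_unique[-1]),
    }
    if state.gene_bearing is not None:
        est["true_gene_bearing"] = len(state.gene_bearing)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "estimate.json", "w") as fh:
        json.dump(est, fh, indent=2)
    return {"outputs": [str(d / "accumulation_curve.tsv"), str(d / "estimate.json")], "estimate": est}


def _alt_platform_assembly(genome, row, rng) -> sim.BacAssembly:
    """Re-fragment a clone's true insert with an independent cut pattern,
    emulating the same clone assembled from another sequencing platform."""
    seq = genome.sequences[row.chrom][row.start : row.end]
    n_cuts = int(rng.integers(1, 5))
    cuts = np.sort(rng.integers(1, max(2, len(seq) - 1), size=n_cuts))
    bounds = np.concatenate(([0], cuts, [len(seq)]))
    nodes = {}
    for j in range(len(bounds) - 1):
        frag = seq[int(bounds[j]) : int(bounds[j + 1])]
        if len(frag) >= 200:
            nodes[f"{row.bac_id}_alt{j}"] = frag
    if not nodes:
        nodes[f"{row.bac_id}_alt0"] = seq
    return sim.BacAssembly(bac_id=row.bac_id, nodes=nodes)


def _stage_stats(config: PipelineConfig, state: PipelineState, outdir: Path, cfg_dict) -> dict:
    bacs = _require(state.bacs, "stats", "BAC assemblies")
    assignments = _require(state.assignments, "stats", "assignments from classify")
    clones = [sim.BacAssembly(bac_id=b, nodes=nodes) for b, nodes in bacs.items()]
    stats = met.stats_frame(clones, min_node_len=config.stats.min_node_len)
    per_label = state.gene_counts["per_label"] if state.gene_counts else None
    table = met.aggregate_table(stats, assignments, per_label_genes=per_label)

    d = outdir / "stats"
    write_table(stats, d / "per_bac_stats.tsv", cfg_dict)
    write_table(table, d / "group_table.tsv", cfg_dict)
    outputs = [str(d / "per_bac_stats.tsv"), str(d / "group_table.tsv")]
    out = {"outputs": outputs, "n_bacs": int(len(stats))}

    # cross-platform concordance on a clone subset (needs simulation truth)
    if state.genome is not None and state.library is not None:
        rng = np.random.default_rng(config.seed + 5)
        truth = state.library.truth
        subset = truth.sample(n=min(40, len(truth)), random_state=config.seed + 5)
        cov_rows = []
        clone_map = {b.bac_id: b for b in state.library.clones}
        for row in subset.itertuples():
            alt = _alt_platform_assembly(state.genome, row, rng)
            cov_ab, cov_ba = met.pairwise_coverage(
                clone_map[row.bac_id], alt, min_match=config.stats.min_match
            )
            cov_rows.append({"bac_id": row.bac_id, "cov_ab": cov_ab, "cov_ba": cov_ba})
        coverage = pd.DataFrame(cov_rows)
        kept, removed = met.filter_discordant_pairs(
            coverage, threshold=config.stats.discordance_threshold
        )
        write_table(coverage, d / "platform_coverage.tsv", cfg_dict)
        outputs.append(str(d / "platform_coverage.tsv"))
        out["validation"] = {
            "n_pairs": int(len(coverage)),
            "n_removed_discordant": int(len(removed)),
            "mean_coverage_pct": round(float(kept["cov_ab"].mean()), 2) if len(kept) else None,
        }
    return out


_STAGE_FN = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "annotate": _stage_annotate,
    "synteny": _stage_synteny,
    "landscape": _stage_landscape,
    "saturate": _stage_saturate,
    "stats": _stage_stats,
}
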