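import dataclasses

import pytest

from bacatlas import synthetic as sim
from bacatlas.pipeline import default_synthetic_config


@pytest.fixture(scope="session")
def small_spec():
    """Compact 3-chromosome genome for fast unit tests."""
    return sim.GenomeSpec(
        n_chromosomes=3,
        arm_lengths=(300_000, 400_000),
        centromere_overlap_len=60_000,
        gene_count=80,
        distal_enrichment=4.0,
        repeat_families=(2, 1_500),
        repeat_copies_per_family=8,
        map_suppression_width=200_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return sim.simulate_genome(small_spec)


@pytest.fixture(scope="session")
def small_library(small_genome):
    return sim.simulate_bac_library(
        small_genome, n_clones=120, insert_mean=40_000, insert_sd=4_000,
        node_split=4, seed=77,
    )


@pytest.fixture(scope="session")
def clean_genome():
    """Repeat-free genome: every k-mer is single-copy, matches are exact."""
    spec = sim.GenomeSpec(
        n_chromosomes=3,
        arm_lengths=(300_000, 400_000),
        centromere_overlap_len=60_000,
        gene_count=80,
        repeat_families=(0, 1_000),
        map_suppression_width=200_000,
        seed=5,
    )
    return sim.simulate_genome(spec)


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic study conditions, built once per session:
    genome with the planted island, 500-clone library, discriminative index,
    assignments, annotation and screening."""
    from bacatlas import annotation as ann
    from bacatlas import arm_classifier as armc
    import pandas as pd

    cfg = default_synthetic_config(seed=11)
    genome = sim.simulate_genome(cfg.genome)
    library = sim.simulate_bac_library(
        genome,
        n_clones=cfg.library.n_clones,
        insert_mean=cfg.library.insert_mean,
        insert_sd=cfg.library.insert_sd,
        node_split=cfg.library.node_split,
        seed=cfg.seed + 1,
    )
    index = armc.build_index(genome.arm_targets, cfg.classifier)
    assignments, summary = armc.classify_library(index, library, cfg.classifier)

    gene_seqs = {
        row.gene_id: genome.sequences[row.chrom][row.start : row.end]
        for row in genome.genes.itertuples()
    }
    nodes_flat = {nid: s for b in library.clones for nid, s in b.nodes.items()}
    raw = ann.match_genes_builtin(nodes_flat, gene_seqs)
    node_index = pd.DataFrame(
        [
            {"node_id": nid, "bac_id": b.bac_id, "length": len(s)}
            for b in library.clones
            for nid, s in b.nodes.items()
        ]
    )
    filtered = ann.filter_hits(raw, node_index, cfg.annotation)
    excluded, retained = ann.flag_frequent_models(filtered, cfg.annotation)

    matrix, screening_truth = sim.simulate_probe_screening(
        genome,
        library,
        n_pools=cfg.screening.n_pools,
        detect_prob=cfg.screening.detect_prob,
        fp_rate=cfg.screening.fp_rate,
        seed=cfg.seed + 2,
    )
    return {
        "config": cfg,
        "genome": genome,
        "library": library,
        "index": index,
        "assignments": assignments,
        "summary": summary,
        "retained_hits": retained,
        "excluded_models": excluded,
        "matrix": matrix,
        "screening_truth": screening_truth,
    }
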