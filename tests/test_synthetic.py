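"""Synthetic-data generator: determinism, structure and ground-truth checks."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bacatlas import synthetic as sim
from bacatlas.errors import ConfigurationError


def test_invalid_spec_names_field():
    with pytest.raises(ConfigurationError, match="centromere_overlap_len"):
        sim.GenomeSpec(arm_lengths=(10_000, 20_000), centromere_overlap_len=15_000).validate()
    with pytest.raises(ConfigurationError, match="distal_enrichment"):
        sim.GenomeSpec(distal_enrichment=0.5).validate()


def test_same_spec_and_seed_give_identical_genomes(small_spec):
    g1 = sim.simulate_genome(small_spec)
    g2 = sim.simulate_genome(small_spec)
    assert g1.sequences == g2.sequences
    assert g1.arm_targets == g2.arm_targets
    pd.testing.assert_frame_equal(g1.genes, g2.genes)


def test_arms_share_exactly_the_centromeric_overlap(small_genome, small_spec):
    # chromosome 1 is a whole-chromosome target; 2H/3H are split into arms
    s_len, overlap = small_genome.arm_boundaries["2H"]
    short, long = small_genome.arm_targets["2HS"], small_genome.arm_targets["2HL"]
    assert short[-overlap:] == long[:overlap]
    assert len(short) + len(long) - overlap == small_genome.chrom_length("2H")


def test_gene_conservation_per_chromosome(small_genome, small_spec):
    counts = small_genome.genes.groupby("chrom").size()
    for chrom, expected in zip(small_genome.chrom_names, small_spec.gene_counts()):
        assert counts[chrom] == expected


def test_uniform_density_is_uniform():
    spec = sim.GenomeSpec(
        n_chromosomes=1, arm_lengths=(500_000, 500_000), centromere_overlap_len=50_000,
        gene_count=2_000, distal_enrichment=1.0, repeat_families=(0, 1000), seed=3,
    )
    genome = sim.simulate_genome(spec)
    length = genome.chrom_length("1H")
    starts = genome.genes["start"].to_numpy()
    observed, _ = np.histogram(starts, bins=10, range=(0, length))
    p = sps.chisquare(observed).pvalue
    assert p > 0.001


def test_interior_island_triples_local_gene_count():
    base = sim.GenomeSpec(n_chromosomes=3, seed=9, repeat_families=(0, 1000))
    base.validate()
    length = sum(base.arm_pairs()[1]) - base.centromere_overlap_len
    span = int(0.05 * length)
    start = length // 2 - span // 2
    spec = sim.GenomeSpec(
        n_chromosomes=3, seed=9, repeat_families=(0, 1000),
        interior_islands=((1, start, start + span, 50),),
    )
    genome = sim.simulate_genome(spec)
    g2 = genome.genes[genome.genes["chrom"] == "2H"]
    mids = ((g2["start"] + g2["end"]) // 2).to_numpy()
    in_span = ((mids >= start) & (mids < start + span)).sum()
    left = ((mids >= start - span) & (mids < start)).sum()
    right = ((mids >= start + span) & (mids < start + 2 * span)).sum()
    assert in_span >= 3 * max((left + right) / 2, 1)


def test_genetic_map_is_weakly_monotone(small_genome):
    for chrom in small_genome.chrom_names:
        bp, cm = small_genome.map_grid[chrom]
        assert (np.diff(cm) >= 0).all()
        assert cm[0] == 0.0
        assert cm[-1] == pytest.approx(small_genome.spec.total_cm)


def test_map_is_suppressed_at_the_centromere(small_genome):
    chrom = "2H"
    length = small_genome.chrom_length(chrom)
    centre_rate = (
        small_genome.map_cm(chrom, length / 2 + 25_000) - small_genome.map_cm(chrom, length / 2 - 25_000)
    )
    distal_rate = small_genome.map_cm(chrom, 50_000) - small_genome.map_cm(chrom, 0)
    assert centre_rate < 0.2 * distal_rate


class TestLibrary:
    def test_single_node_split_keeps_insert_verbatim(self, small_genome):
        lib = sim.simulate_bac_library(small_genome, n_clones=5, insert_mean=30_000,
                                       insert_sd=1_000, node_split=1, seed=1)
        for clone, row in zip(lib.clones, lib.truth.itertuples()):
            assert len(clone.nodes) == 1
            (seq,) = clone.nodes.values()
            assert seq == small_genome.sequences[row.chrom][row.start : row.end]

    def test_empty_library(self, small_genome):
        lib = sim.simulate_bac_library(small_genome, n_clones=0, insert_mean=30_000, seed=1)
        assert len(lib) == 0 and lib.truth.empty

    def test_oversized_insert_rejected(self, small_genome):
        with pytest.raises(ConfigurationError, match="insert_mean"):
            sim.simulate_bac_library(small_genome, n_clones=1, insert_mean=10**9, seed=1)

    def test_coverage_recovery_five_x(self):
        spec = sim.GenomeSpec(
            n_chromosomes=2, arm_lengths=(2_400_000, 2_600_000),
            centromere_overlap_len=100_000, gene_count=50,
            repeat_families=(0, 1000), seed=4,
        )
        genome = sim.simulate_genome(spec)
        genome_bp = sum(len(s) for s in genome.sequences.values())
        lib = sim.simulate_bac_library(
            genome, n_clones=500, insert_mean=100_000, insert_sd=10_000,
            node_split=1, seed=44,
        )
        total = sum(c.total_length for c in lib.clones)
        assert total / genome_bp == pytest.approx(5.0, abs=0.5)

    def test_every_insert_lies_within_one_chromosome(self, small_library, small_genome):
        for row in small_library.truth.itertuples():
            assert 0 <= row.start < row.end <= small_genome.chrom_length(row.chrom)

    def test_nodes_meet_min_length_and_sit_inside_insert(self, small_library):
        for clone in small_library.clones:
            assert all(len(s) >= 200 for s in clone.nodes.values())


class TestScreening:
    def test_perfect_detection_recovers_gene_bearing_set(self, small_genome, small_library):
        matrix, truth = sim.simulate_probe_screening(
            small_genome, small_library, n_pools=8, detect_prob=1.0, fp_rate=0.0, seed=2
        )
        detected = set(matrix.columns[(matrix.to_numpy().sum(axis=0) > 0)])
        assert detected == truth.gene_bearing

    def test_zero_detection_gives_empty_matrix(self, small_genome, small_library):
        matrix, _ = sim.simulate_probe_screening(
            small_genome, small_library, n_pools=4, detect_prob=0.0, fp_rate=0.0, seed=2
        )
        assert matrix.to_numpy().sum() == 0

    def test_detection_counts_match_binomial_mean(self, small_genome, small_library):
        p = 0.6
        matrix, truth = sim.simulate_probe_screening(
            small_genome, small_library, n_pools=8, detect_prob=p, fp_rate=0.0, seed=6
        )
        overlaps = sim.true_overlaps(small_genome, small_library)
        overlaps = overlaps.assign(pool=[truth.pool_of_gene[g] for g in overlaps["gene_id"]])
        n_trials = len(overlaps[["pool", "bac_id"]].drop_duplicates())
        total = matrix.to_numpy().sum()
        sd = np.sqrt(n_trials * p * (1 - p))
        assert abs(total - n_trials * p) <= 3 * sd

    def test_bad_pool_count_rejected(self, small_genome, small_library):
        with pytest.raises(ConfigurationError):
            sim.simulate_probe_screening(small_genome, small_library, n_pools=0, seed=1)


class TestHitTable:
    def test_noise_free_hits_point_at_orthologous_chromosome(self, small_genome, small_library):
        hits = sim.simulate_hit_table(small_library, small_genome, noise=0.0, seed=3)
        idx = {c: f"Os{i + 1}" for i, c in enumerate(small_genome.chrom_names)}
        origin = small_library.truth.set_index("bac_id")["chrom"]
        for bac_id, sub in hits.groupby("query_id"):
            assert set(sub["subject_chrom"]) == {idx[origin[bac_id]]}

    def test_hit_count_equals_true_overlap_count(self, small_genome, small_library):
        hits = sim.simulate_hit_table(small_library, small_genome, noise=0.0, seed=3)
        overlaps = sim.true_overlaps(small_genome, small_library)
        assert len(hits) == len(overlaps)

    def test_records_sorted_by_query_then_evalue(self, small_genome, small_library):
        hits = sim.simulate_hit_table(small_library, small_genome, noise=1.0, seed=3)
        resorted = hits.sort_values(["query_id", "evalue"], kind="stable").reset_index(drop=True)
        pd.testing.assert_frame_equal(hits, resorted)
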