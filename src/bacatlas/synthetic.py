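"""Synthetic genomes, BAC libraries, probe screenings and cross-species hit
tables with the statistical structure of a gene-bearing BAC clone resource.

The generator emulates a large-genome cereal setup: several chromosomes each
split into a short (S) and long (L) flow-sorted arm target that share a
centromeric overlap segment, telomere-biased gene density with optional
interior gene-dense islands, shared repeat families, and a genetic map whose
recombination intensity is suppressed around the centromere ("bathtub"
shape). Every stochastic draw flows from the seed carried by the spec (or
passed to the operation), so identical inputs give byte-identical outputs.

Ground truth (gene coordinates, each clone's true origin, the map function)
is retained alongside the sequences so downstream stages can be scored.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# specification


@dataclass
class GenomeSpec:
    """Parameters of one synthetic genome.

    arm_lengths is either one (short_bp, long_bp) pair applied to every
    chromosome or a per-chromosome sequence of pairs. The first chromosome is
    modelled as a single whole-chromosome target (no S/L split) when
    ``whole_chromosome_first`` is set, mirroring resources where one
    chromosome could not be arm-sorted.
    """

    n_chromosomes: int = 7
    arm_lengths: Sequence = (1_600_000, 2_000_000)
    centromere_overlap_len: int = 120_000
    gene_count: int | Sequence[int] = 300
    distal_enrichment: float = 4.0
    interior_islands: Sequence[tuple] = ()  # (chrom_idx, start_bp, end_bp, extra_genes)
    repeat_families: tuple[int, int] = (5, 3_000)  # (n_families, unit_len)
    repeat_copies_per_family: int = 30
    map_suppression_width: int = 1_000_000
    total_cm: float = 150.0
    gc: float = 0.445
    gene_length: int = 2_000
    hc_fraction: float = 0.45
    whole_chromosome_first: bool = True
    seed: int = 0

    def arm_pairs(self) -> list[tuple[int, int]]:
        arms = self.arm_lengths
        if len(arms) == 2 and isinstance(arms[0], (int, np.integer)):
            return [tuple(arms)] * self.n_chromosomes
        if len(arms) != self.n_chromosomes:
            raise ConfigurationError(
                "arm_lengths: need one (S, L) pair or one per chromosome"
            )
        return [tuple(a) for a in arms]

    def gene_counts(self) -> list[int]:
        g = self.gene_count
        if isinstance(g, (int, np.integer)):
            return [int(g)] * self.n_chromosomes
        if len(g) != self.n_chromosomes:
            raise ConfigurationError("gene_count: need a scalar or one per chromosome")
        return [int(x) for x in g]

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        pairs = self.arm_pairs()
        for s, l in pairs:
            if s <= 0 or l <= 0:
                raise ConfigurationError("arm_lengths: all lengths must be > 0")
            if self.centromere_overlap_len >= min(s, l):
                raise ConfigurationError(
                    "centromere_overlap_len must be smaller than the shortest arm"
                )
        if self.centromere_overlap_len < 0:
            raise ConfigurationError("centromere_overlap_len must be >= 0")
        if any(c < 0 for c in self.gene_counts()):
            raise ConfigurationError("gene_count must be >= 0")
        if self.distal_enrichment < 1:
            raise ConfigurationError("distal_enrichment must be >= 1")
        if not 0 < self.gc < 1:
            raise ConfigurationError("gc must be in (0, 1)")
        if self.gene_length < 1:
            raise ConfigurationError("gene_length must be >= 1")
        if self.map_suppression_width < 0:
            raise ConfigurationError("map_suppression_width must be >= 0")
        if self.total_cm <= 0:
            raise ConfigurationError("total_cm must be > 0")
        if not 0 <= self.hc_fraction <= 1:
            raise ConfigurationError("hc_fraction must be in [0, 1]")
        for isl in self.interior_islands:
            ci, a, b, n = isl
            if not 0 <= ci < self.n_chromosomes:
                raise ConfigurationError(f"interior_islands: chromosome index {ci} out of range")
            if not (0 <= a < b):
                raise ConfigurationError("interior_islands: need 0 <= start < end")
            if n < 0:
                raise ConfigurationError("interior_islands: extra gene count must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arm_lengths"] = [list(p) for p in self.arm_pairs()]
        d["interior_islands"] = [list(i) for i in self.interior_islands]
        return d


# ---------------------------------------------------------------------------
# containers


@dataclass
class BacAssembly:
    """One BAC clone's set of assembled node sequences."""

    bac_id: str
    nodes: dict[str, str]

    @property
    def node_lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.nodes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.nodes.values())


@dataclass
class SimulatedGenome:
    """Sequences plus ground truth for one synthetic genome."""

    spec: GenomeSpec
    chrom_names: list[str]
    sequences: dict[str, str]           # full chromosome sequences
    arm_targets: dict[str, str]         # label -> target sequence (arms overlap)
    arm_boundaries: dict[str, tuple[int, int]]  # chrom -> (S length, overlap)
    genes: pd.DataFrame                 # gene_id, chrom, start, end, confidence_class
    map_grid: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (bp, cM)

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def map_cm(self, chrom: str, bp) -> np.ndarray:
        """Genetic position (cM) at physical position(s) bp, by interpolation."""
        grid_bp, grid_cm = self.map_grid[chrom]
        return np.interp(np.asarray(bp, dtype=float), grid_bp, grid_cm)

    def map_samples(self, step: int = 50_000) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_names:
            bps = np.arange(0, self.chrom_length(chrom) + 1, step)
            cms = self.map_cm(chrom, bps)
            rows.append(pd.DataFrame({"chrom": chrom, "bp": bps, "cM": np.round(cms, 6)}))
        return pd.concat(rows, ignore_index=True)

    def true_arm_label(self, chrom: str, start: int, end: int) -> str:
        """Arm-target label a clone insert [start, end) truly belongs to:
        the region (S-unique, centromeric overlap, L-unique) holding the
        majority of the insert's bases."""
        s_len, overlap = self.arm_boundaries[chrom]
        if overlap == 0 and s_len == self.chrom_length(chrom):
            return chrom  # whole-chromosome target
        ov_lo, ov_hi = s_len - overlap, s_len
        n = end - start
        in_ov = max(0, min(end, ov_hi) - max(start, ov_lo))
        if in_ov > n / 2:
            return chrom + "C"
        in_s = max(0, min(end, ov_lo) - start)
        in_l = max(0, end - max(start, ov_hi))
        return chrom + ("S" if in_s >= in_l else "L")

    def ortholog_catalog(self, prefix: str = "Os") -> pd.DataFrame:
        """Collinear foreign gene set: each gene mapped 1:1 to a foreign
        chromosome named after its own, at its own midpoint coordinate."""
        g = self.genes
        idx = {c: i + 1 for i, c in enumerate(self.chrom_names)}
        return pd.DataFrame(
            {
                "subject_id": [f"{prefix}_{gid}" for gid in g["gene_id"]],
                "subject_chrom": [f"{prefix}{idx[c]}" for c in g["chrom"]],
                "subject_pos": ((g["start"] + g["end"]) // 2).to_numpy(),
                "gene_id": g["gene_id"].to_numpy(),
            }
        )


@dataclass
class BacLibrary:
    """Simulated clone library with per-clone ground truth."""

    clones: list[BacAssembly]
    truth: pd.DataFrame  # bac_id, chrom, start, end, true_label, insert_len

    def __len__(self) -> int:
        return len(self.clones)

    def node_index(self) -> pd.DataFrame:
        rows = [
            {"node_id": nid, "bac_id": bac.bac_id, "length": len(seq)}
            for bac in self.clones
            for nid, seq in bac.nodes.items()
        ]
        return pd.DataFrame(rows, columns=["node_id", "bac_id", "length"])


# ---------------------------------------------------------------------------
# operations


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def _gene_density(x: np.ndarray, length: int, enrichment: float) -> np.ndarray:
    """Piecewise-linear density: 1 at the chromosome midpoint (centromere
    proxy) ramping to ``enrichment`` at both telomeres."""
    c = length / 2
    d = np.abs(x - c) / c  # 0 at centromere, 1 at ends
    return 1.0 + (enrichment - 1.0) * d


def simulate_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Generate chromosome sequences, arm targets, genes and a genetic map.

    Both arms of a chromosome are slices of the same underlying sequence and
    share exactly the ``centromere_overlap_len`` middle segment. Genes are
    placed by thinning a uniform proposal against the telomere-ramp density;
    interior islands add a uniform block of extra genes. Repeat-family copies
    are pasted genome-wide before gene placement so that some gene models can
    legitimately overlap repeats.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pairs = spec.arm_pairs()
    counts = spec.gene_counts()

    chrom_names = [f"{i + 1}H" for i in range(spec.n_chromosomes)]
    seq_arrays: dict[str, np.ndarray] = {}
    arm_boundaries: dict[str, tuple[int, int]] = {}
    for name, (s_len, l_len) in zip(chrom_names, pairs):
        total = s_len + l_len - spec.centromere_overlap_len
        seq_arrays[name] = _random_sequence(rng, total, spec.gc)
        arm_boundaries[name] = (s_len, spec.centromere_overlap_len)

    # shared repeat families: identical units pasted across chromosomes
    n_fam, unit_len = spec.repeat_families
    lengths = np.array([seq_arrays[c].size for c in chrom_names], dtype=float)
    for _ in range(n_fam):
        unit = _random_sequence(rng, unit_len, spec.gc)
        for _ in range(spec.repeat_copies_per_family):
            ci = rng.choice(len(chrom_names), p=lengths / lengths.sum())
            chrom = chrom_names[ci]
            arr = seq_arrays[chrom]
            if arr.size <= unit_len:
                continue
            pos = int(rng.integers(0, arr.size - unit_len))
            arr[pos : pos + unit_len] = unit

    # gene placement by rejection sampling against the density ramp
    gene_rows = []
    islands_by_chrom: dict[int, list] = {}
    for isl in spec.interior_islands:
        islands_by_chrom.setdefault(int(isl[0]), []).append(isl)
    gid = 0
    for ci, (name, n_genes) in enumerate(zip(chrom_names, counts)):
        length = seq_arrays[name].size
        fmax = spec.distal_enrichment
        placed = 0
        while placed < n_genes:
            draw = max(16, 2 * (n_genes - placed))
            xs = rng.uniform(0, length - spec.gene_length, size=draw)
            keep = rng.uniform(0, fmax, size=draw) < _gene_density(xs, length, spec.distal_enrichment)
            for x in xs[keep]:
                if placed >= n_genes:
                    break
                start = int(x)
                gene_rows.append((f"G{gid:05d}", name, start, start + spec.gene_length))
                gid += 1
                placed += 1
        for _, a, b, n_extra in islands_by_chrom.get(ci, []):
            b = min(int(b), length)
            hi = max(int(a) + 1, b - spec.gene_length)
            xs = rng.integers(int(a), hi, size=int(n_extra))
            for x in xs:
                gene_rows.append((f"G{gid:05d}", name, int(x), int(x) + spec.gene_length))
                gid += 1

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    genes["confidence_class"] = np.where(
        rng.uniform(size=len(genes)) < spec.hc_fraction, "HC", "LC"
    )

    # genetic map: cumulative integral of a bathtub-shaped intensity
    map_grid: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grid_step = 2_000
    eps = 0.02
    for name in chrom_names:
        length = seq_arrays[name].size
        bp = np.arange(0, length + grid_step, grid_step, dtype=float)
        bp[-1] = length
        c = length / 2
        half_w = spec.map_suppression_width / 2
        dist = np.abs(bp - c)
        ramp = np.clip((dist - half_w) / np.maximum(c - half_w, 1.0), 0.0, 1.0)
        intensity = eps + (1 - eps) * ramp
        cm = np.concatenate(([0.0], np.cumsum(0.5 * (intensity[1:] + intensity[:-1]) * np.diff(bp))))
        cm *= spec.total_cm / cm[-1]
        map_grid[name] = (bp, cm)

    sequences = {c: seq_arrays[c].tobytes().decode("ascii") for c in chrom_names}
    arm_targets: dict[str, str] = {}
    for ci, name in enumerate(chrom_names):
        s_len, overlap = arm_boundaries[name]
        if ci == 0 and spec.whole_chromosome_first:
            arm_targets[name] = sequences[name]
            arm_boundaries[name] = (len(sequences[name]), 0)
        else:
            arm_targets[name + "S"] = sequences[name][:s_len]
            arm_targets[name + "L"] = sequences[name][s_len - overlap :]

    return SimulatedGenome(
        spec=spec,
        chrom_names=chrom_names,
        sequences=sequences,
        arm_targets=arm_targets,
        arm_boundaries=arm_boundaries,
        genes=genes,
        map_grid=map_grid,
    )


def simulate_bac_library(
    genome: SimulatedGenome,
    n_clones: int = 500,
    insert_mean: int = 100_000,
    insert_sd: int = 10_000,
    node_split: float = 19.7,
    min_node_len: int = 200,
    junction_loss: int = 60,
    seed: int | None = None,
) -> BacLibrary:
    """Draw clone inserts from the genome and fragment each into nodes.

    Inserts come from a chromosome chosen proportionally to its length, with
    Gaussian lengths. Each insert is cut into roughly ``node_split`` nodes on
    average (1 + Poisson(node_split - 1)); a small deletion of
    ``junction_loss`` bp at each internal junction emulates assembly gaps.
    Nodes shorter than ``min_node_len`` after cutting are dropped. With
    ``node_split == 1`` the single node equals the insert verbatim.
    """
    if insert_mean <= 0:
        raise ConfigurationError("insert_mean must be > 0")
    if n_clones < 0:
        raise ConfigurationError("n_clones must be >= 0")
    shortest = min(len(s) for s in genome.sequences.values())
    if insert_mean > shortest:
        raise ConfigurationError(
            f"insert_mean ({insert_mean}) exceeds the shortest chromosome ({shortest})"
        )
    if node_split < 1:
        raise ConfigurationError("node_split must be >= 1")
    rng = np.random.default_rng(genome.spec.seed + 1 if seed is None else seed)

    names = genome.chrom_names
    lengths = np.array([len(genome.sequences[c]) for c in names], dtype=float)
    p = lengths / lengths.sum()

    clones: list[BacAssembly] = []
    truth_rows = []
    for i in range(n_clones):
        bac_id = f"BAC{i:05d}"
        ci = rng.choice(len(names), p=p)
        chrom = names[ci]
        clen = len(genome.sequences[chrom])
        ins = int(np.clip(rng.normal(insert_mean, insert_sd), min_node_len + 1, clen))
        start = int(rng.integers(0, clen - ins + 1))
        insert_seq = genome.sequences[chrom][start : start + ins]

        if node_split == 1:
            segs = [insert_seq]
        else:
            n_nodes = 1 + rng.poisson(node_split - 1)
            cuts = np.sort(rng.integers(0, ins, size=n_nodes - 1)) if n_nodes > 1 else np.empty(0, int)
            bounds = np.concatenate(([0], cuts, [ins]))
            segs = []
            for j in range(len(bounds) - 1):
                a, b = int(bounds[j]), int(bounds[j + 1])
                if j > 0:
                    a += junction_loss  # internal deletion at the junction
                if b - a >= min_node_len:
                    segs.append(insert_seq[a:b])
            if not segs:  # degenerate cutting: keep the longest raw segment
                j = int(np.argmax(np.diff(bounds)))
                segs = [insert_seq[int(bounds[j]) : int(bounds[j + 1])]]

        nodes = {f"{bac_id}_n{j}": s for j, s in enumerate(segs)}
        clones.append(BacAssembly(bac_id=bac_id, nodes=nodes))
        truth_rows.append(
            {
                "bac_id": bac_id,
                "chrom": chrom,
                "start": start,
                "end": start + ins,
                "true_label": genome.true_arm_label(chrom, start, start + ins),
                "insert_len": ins,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["bac_id", "chrom", "start", "end", "true_label", "insert_len"]
    )
    return BacLibrary(clones=clones, truth=truth)


def true_overlaps(
    genome: SimulatedGenome, library: BacLibrary, min_overlap: int = 1
) -> pd.DataFrame:
    """(bac_id, gene_id) pairs where the true clone insert overlaps the gene
    by at least ``min_overlap`` bp — the ground-truth oracle for annotation
    and screening."""
    rows = []
    genes = genome.genes
    for chrom, sub in library.truth.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        gs, ge = g["start"].to_numpy(), g["end"].to_numpy()
        for bac_id, bs, be in zip(sub["bac_id"], sub["start"], sub["end"]):
            ov = np.minimum(ge, be) - np.maximum(gs, bs)
            for gid in g["gene_id"].to_numpy()[ov >= min_overlap]:
                rows.append((bac_id, gid))
    return pd.DataFrame(rows, columns=["bac_id", "gene_id"])


@dataclass
class ScreeningTruth:
    """Ground truth behind a simulated screening."""

    gene_bearing: set           # clone ids truly overlapping >= 1 gene
    pool_of_gene: dict          # gene_id -> pool index (the probe partition)


def simulate_probe_screening(
    genome: SimulatedGenome,
    library: BacLibrary,
    n_pools: int = 30,
    detect_prob: float = 0.6,
    fp_rate: float = 0.001,
    seed: int | None = None,
):
    """Binary pools x clones detection matrix from probe-pool hybridization.

    Genes are partitioned uniformly at random among pools. A pool containing
    at least one gene truly carried by a clone detects that clone with
    probability ``detect_prob``; every (pool, clone) cell additionally turns
    positive with probability ``fp_rate`` (false positives).

    Returns (matrix, truth) where matrix is a pools x clones 0/1 DataFrame
    and truth is a ScreeningTruth (genuinely gene-bearing clone ids plus the
    gene -> pool partition).
    """
    if n_pools < 1:
        raise ConfigurationError("n_pools must be >= 1")
    for nm, v in (("detect_prob", detect_prob), ("fp_rate", fp_rate)):
        if not 0 <= v <= 1:
            raise ConfigurationError(f"{nm} must be in [0, 1]")
    rng = np.random.default_rng(genome.spec.seed + 2 if seed is None else seed)

    pool_of_gene = {
        gid: int(pool)
        for gid, pool in zip(
            genome.genes["gene_id"], rng.integers(0, n_pools, size=len(genome.genes))
        )
    }
    overlaps = true_overlaps(genome, library)
    clone_ids = [b.bac_id for b in library.clones]
    clone_idx = {b: i for i, b in enumerate(clone_ids)}
    mat = np.zeros((n_pools, len(clone_ids)), dtype=np.int8)

    # true signal: per (pool, clone) Bernoulli where the pool holds >=1 of the
    # clone's genes
    pairs = {
        (pool_of_gene[g], clone_idx[b])
        for b, g in zip(overlaps["bac_id"], overlaps["gene_id"])
    }
    for p_i, c_i in sorted(pairs):
        if rng.uniform() < detect_prob:
            mat[p_i, c_i] = 1
    if fp_rate > 0:
        mat |= (rng.uniform(size=mat.shape) < fp_rate).astype(np.int8)

    matrix = pd.DataFrame(mat, index=[f"pool{p:03d}" for p in range(n_pools)], columns=clone_ids)
    matrix.index.name = "pool_id"
    truth = ScreeningTruth(
        gene_bearing=set(overlaps["bac_id"].unique()), pool_of_gene=pool_of_gene
    )
    return matrix, truth


def simulate_hit_table(
    library: BacLibrary,
    genome: SimulatedGenome,
    foreign: pd.DataFrame | None = None,
    noise: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cross-species alignment hit records for synteny voting.

    One record per (BAC, foreign gene) pair whose ortholog the clone truly
    overlaps (e-value 1e-30), plus Poisson(``noise``) off-target records per
    clone pointing at a random foreign chromosome/position (e-value 1e-21,
    i.e. still passing a 1e-20 cutoff — voting must out-shout them). Records
    are sorted by query id then e-value.
    """
    if noise < 0:
        raise ConfigurationError("noise must be >= 0")
    rng = np.random.default_rng(genome.spec.seed + 3 if seed is None else seed)
    if foreign is None:
        foreign = genome.ortholog_catalog()
    fg = foreign.set_index("gene_id")

    overlaps = true_overlaps(genome, library)
    rows = []
    for b, g in zip(overlaps["bac_id"], overlaps["gene_id"]):
        if g not in fg.index:
            continue
        rec = fg.loc[g]
        rows.append((b, rec["subject_id"], rec["subject_chrom"], int(rec["subject_pos"]), 1e-30))
    chroms = foreign["subject_chrom"].unique()
    max_pos = int(foreign["subject_pos"].max()) if len(foreign) else 1
    if noise > 0:
        for bac in library.clones:
            for j in range(rng.poisson(noise)):
                rows.append(
                    (
                        bac.bac_id,
                        f"offtarget_{bac.bac_id}_{j}",
                        str(rng.choice(chroms)),
                        int(rng.integers(0, max_pos + 1)),
                        1e-21,
                    )
                )
    hits = pd.DataFrame(
        rows, columns=["query_id", "subject_id", "subject_chrom", "subject_pos", "evalue"]
    )
    return hits.sort_values(["query_id", "evalue"], kind="stable").reset_index(drop=True)


def contig_assignments(library: BacLibrary, max_gap: int = 0) -> pd.DataFrame:
    """Group clones into physical-map 'contigs' by true interval overlap
    (connected runs along each chromosome). Returns bac_id -> contig_id."""
    rows = []
    cid = 0
    for chrom, sub in library.truth.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        reach = None
        for bac_id, s, e in zip(sub["bac_id"], sub["start"], sub["end"]):
            if reach is None or s > reach + max_gap:
                cid += 1
                reach = e
            else:
                reach = max(reach, e)
            rows.append({"bac_id": bac_id, "contig_id": f"ctg{cid:04d}"})
    return pd.DataFrame(rows, columns=["bac_id", "contig_id"])
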