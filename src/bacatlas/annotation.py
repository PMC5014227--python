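"""Gene-model annotation of BAC assemblies.

Hits arrive as 12-column tabular alignment records (BLAST outfmt-6 layout)
or from the built-in exact-seed matcher. Filtering applies the resource's
annotation rules: nodes shorter than 200 bp are ignored, hits worse than
e-value 1e-20 are dropped, and gene models hitting ten or more distinct BACs
(mostly transposon-related) are excluded from gene counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kmers import kmer_positions, revcomp
from .errors import ConfigurationError, DataError

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class AnnotationConfig:
    min_node_len: int = 200
    evalue_cutoff: float = 1e-20
    frequent_bac_threshold: int = 10

    def validate(self) -> None:
        if self.min_node_len < 1:
            raise ConfigurationError("min_node_len must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ConfigurationError("evalue_cutoff must be > 0")
        if self.frequent_bac_threshold < 2:
            raise ConfigurationError("frequent_bac_threshold must be >= 2")


def filter_hits(
    raw_hits: pd.DataFrame,
    nodes: pd.DataFrame,
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Apply node-length and e-value cutoffs to raw alignment hits.

    ``raw_hits`` must carry at least (qseqid, sseqid, evalue) — qseqid is a
    node id. ``nodes`` maps node_id -> (bac_id, length). Hits referencing
    unknown nodes raise a DataError naming the offenders. Output columns:
    bac_id, gene_model_id, node_id, evalue (plus any alignment columns
    present), sorted by (bac_id, gene_model_id, evalue).
    """
    config = config or AnnotationConfig()
    config.validate()
    node_info = nodes.set_index("node_id")
    unknown = sorted(set(raw_hits["qseqid"]) - set(node_info.index))
    if unknown:
        shown = ", ".join(unknown[:10])
        raise DataError(f"hits reference {len(unknown)} unknown node(s): {shown}")

    hits = raw_hits.copy()
    hits["bac_id"] = node_info["bac_id"].reindex(hits["qseqid"]).to_numpy()
    hits["node_len"] = node_info["length"].reindex(hits["qseqid"]).to_numpy()
    keep = (hits["node_len"] >= config.min_node_len) & (hits["evalue"] <= config.evalue_cutoff)
    hits = hits[keep].drop(columns=["node_len"])
    hits = hits.rename(columns={"qseqid": "node_id", "sseqid": "gene_model_id"})
    lead = ["bac_id", "gene_model_id", "node_id", "evalue"]
    hits = hits[lead + [c for c in hits.columns if c not in lead]]
    return hits.sort_values(
        ["bac_id", "gene_model_id", "evalue"], kind="stable"
    ).reset_index(drop=True)


def flag_frequent_models(
    hits: pd.DataFrame, config: AnnotationConfig | None = None
):
    """Exclude gene models hitting >= frequent_bac_threshold distinct BACs.

    Returns (excluded model ids as a sorted list, retained hits).
    """
    config = config or AnnotationConfig()
    config.validate()
    if hits.empty:
        return [], hits.copy()
    per_model = hits.groupby("gene_model_id")["bac_id"].nunique()
    excluded = sorted(per_model.index[per_model >= config.frequent_bac_threshold])
    retained = hits[~hits["gene_model_id"].isin(excluded)].reset_index(drop=True)
    return excluded, retained


def count_genes(
    hits: pd.DataFrame,
    assignments: pd.DataFrame,
    gene_classes: pd.DataFrame,
) -> dict:
    """Distinct-model gene counts per BAC, per arm label, and genome-wide.

    A model hitting several nodes of one BAC counts once for that BAC.
    Per-label uniqueness is computed within the label; overall uniqueness
    across all BACs (so the overall count can be below the column sum when
    models are shared between labels). ``assignments`` maps bac_id -> label
    (UNASSIGNED allowed); ``gene_classes`` maps model_id -> HC|LC.

    Returns dict with 'per_bac', 'per_label' DataFrames and a 'summary' dict.
    """
    amap = assignments.set_index("bac_id")["label"]
    missing = sorted(set(hits["bac_id"]) - set(amap.index)) if not hits.empty else []
    if missing:
        raise DataError(f"hits reference BACs without assignments: {missing[:10]}")
    cmap = gene_classes.set_index("model_id")["confidence_class"]

    pairs = hits[["bac_id", "gene_model_id"]].drop_duplicates()
    pairs = pairs.assign(
        confidence_class=cmap.reindex(pairs["gene_model_id"]).fillna("LC").to_numpy(),
        label=amap.reindex(pairs["bac_id"]).to_numpy(),
    )

    all_bacs = assignments["bac_id"]
    per_bac = (
        pairs.pivot_table(
            index="bac_id", columns="confidence_class", values="gene_model_id",
            aggfunc="nunique", fill_value=0,
        )
        .reindex(all_bacs, fill_value=0)
        .reset_index()
    )
    for col in ("HC", "LC"):
        if col not in per_bac.columns:
            per_bac[col] = 0
    per_bac = per_bac.rename(columns={"HC": "n_hc", "LC": "n_lc"})[
        ["bac_id", "n_hc", "n_lc"]
    ]

    label_rows = []
    for label, sub in pairs.groupby("label", sort=True):
        label_rows.append(
            {
                "label": label,
                "n_bacs": int(assignments["label"].eq(label).sum()),
                "unique_hc": int(sub.loc[sub["confidence_class"] == "HC", "gene_model_id"].nunique()),
                "unique_lc": int(sub.loc[sub["confidence_class"] == "LC", "gene_model_id"].nunique()),
            }
        )
    per_label = pd.DataFrame(label_rows, columns=["label", "n_bacs", "unique_hc", "unique_lc"])

    n_with = int((per_bac[["n_hc", "n_lc"]].sum(axis=1) > 0).sum())
    n_total = len(all_bacs)
    summary = {
        "unique_hc_total": int(pairs.loc[pairs["confidence_class"] == "HC", "gene_model_id"].nunique()),
        "unique_lc_total": int(pairs.loc[pairs["confidence_class"] == "LC", "gene_model_id"].nunique()),
        "n_bacs": n_total,
        "n_bacs_with_gene": n_with,
        "n_bacs_zero_genes": n_total - n_with,
        "pct_bacs_with_gene": round(100.0 * n_with / n_total, 1) if n_total else 0.0,
    }
    return {"per_bac": per_bac, "per_label": per_label, "summary": summary}


def gc_content(sequences) -> float:
    """(G+C)/(A+C+G+T) over all nodes; non-ACGT letters excluded entirely.

    Returns NaN when no ACGT letters are present (e.g. an all-N assembly).
    """
    if hasattr(sequences, "nodes"):
        sequences = list(sequences.nodes.values())
    elif isinstance(sequences, str):
        sequences = [sequences]
    gc = total = 0
    for seq in sequences:
        s = seq.upper()
        a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
        gc += g + c
        total += a + c + g + t
    return gc / total if total else float("nan")


def match_genes_builtin(
    nodes: dict[str, str],
    gene_models: dict[str, str],
    seed_len: int = 31,
    min_identity: float = 0.95,
    min_match_len: int = 200,
) -> pd.DataFrame:
    """Exact-seed, ungapped-extension matcher for synthetic runs.

    Gene-model k-mers (``seed_len``, sampled at half-seed stride, both
    strands) anchor candidate diagonals in each node; each (node, gene,
    strand, diagonal) candidate is verified by direct comparison over the
    diagonal's overlap span. A match with identity >= ``min_identity`` over a
    span >= ``min_match_len`` emits one 12-column record with pseudo-e-value
    1e-30; the best span*identity record is kept per (node, gene).
    Deterministic; exists so pipelines on synthetic data need no external
    aligner.
    """
    stride = max(1, seed_len // 2)
    seed_map: dict[int, list[tuple[str, int, int]]] = {}
    gene_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for gid, seq in gene_models.items():
        fwd = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        rev = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
        gene_arrays[gid] = (fwd, rev)
        for strand, s in ((1, seq.upper()), (-1, revcomp(seq))):
            codes, positions = kmer_positions(s, seed_len, canonical=False)
            for p in range(0, len(positions), stride):
                seed_map.setdefault(int(codes[p]), []).append((gid, int(positions[p]), strand))

    seed_keys = np.array(sorted(seed_map), dtype=np.uint64)
    rows = []
    for node_id, nseq in nodes.items():
        narr = np.frombuffer(nseq.upper().encode(), dtype=np.uint8)
        codes, positions = kmer_positions(nseq, seed_len, canonical=False)
        if codes.size == 0 or seed_keys.size == 0:
            continue
        pos_in_keys = np.searchsorted(seed_keys, codes)
        clipped = np.minimum(pos_in_keys, seed_keys.size - 1)
        present = seed_keys[clipped] == codes
        diagonals: dict[tuple[str, int, int], None] = {}
        for code, npos in zip(codes[present], positions[present]):
            for gid, gpos, strand in seed_map[int(code)]:
                diagonals[(gid, strand, int(npos) - gpos)] = None
        best: dict[str, tuple[float, dict]] = {}
        for gid, strand, diag in diagonals:
            garr = gene_arrays[gid][0 if strand == 1 else 1]
            glen = garr.size
            n_lo, n_hi = max(0, diag), min(narr.size, diag + glen)
            span = n_hi - n_lo
            if span < min_match_len:
                continue
            a = narr[n_lo:n_hi]
            b = garr[n_lo - diag : n_hi - diag]
            matches = int((a == b).sum())
            identity = matches / span
            if identity < min_identity:
                continue
            g_lo, g_hi = n_lo - diag, n_hi - diag
            if strand == 1:
                sstart, send = g_lo + 1, g_hi
            else:  # report subject coordinates on the forward strand
                sstart, send = glen - g_lo, glen - g_hi + 1
            rec = {
                "qseqid": node_id,
                "sseqid": gid,
                "pident": round(100.0 * identity, 2),
                "length": span,
                "mismatch": span - matches,
                "gapopen": 0,
                "qstart": n_lo + 1,
                "qend": n_hi,
                "sstart": sstart,
                "send": send,
                "evalue": 1e-30,
                "bitscore": 2.0 * matches,
            }
            score = identity * span
            if gid not in best or score > best[gid][0]:
                best[gid] = (score, rec)
        rows.extend(rec for _, rec in best.values())
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits.sort_values(["qseqid", "sseqid"], kind="stable").reset_index(drop=True)
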