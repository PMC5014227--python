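"""Per-BAC and per-group assembly statistics, plus the pairwise-coverage
concordance check used to validate assemblies built from two platforms.

N50/L50 follow the asymmetric convention of the resource's summary table:
N50 is the length at which the descending prefix first reaches *at least*
half of the total; L50 is the minimal node count whose prefix *exceeds*
half. For [50, 50] this yields N50 = 50 (prefix 50 >= 50) but L50 = 2 (the
prefix must exceed 50). A strict mode applies the common ">= for both"
convention instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._kmers import revcomp
from .annotation import gc_content
from .errors import DataError
from .synthetic import BacAssembly


def n50_l50(lengths: Sequence[int], strict: bool = False) -> tuple[int, int]:
    """(N50, L50) of a node length set.

    Default mode: L50 = smallest descending-prefix count whose sum exceeds
    total/2; N50 = length of the node where the prefix first reaches
    total/2 (>=). ``strict`` uses >= for both (the common convention).
    """
    lengths = sorted((int(x) for x in lengths), reverse=True)
    if not lengths:
        raise DataError("n50_l50: empty length list")
    if lengths[-1] <= 0:
        raise DataError("n50_l50: lengths must be positive")
    total = sum(lengths)
    half = total / 2
    csum = np.cumsum(lengths)
    idx_ge = int(np.argmax(csum >= half))
    if strict:
        return lengths[idx_ge], idx_ge + 1
    idx_gt = int(np.argmax(csum > half))
    return lengths[idx_ge], idx_gt + 1


@dataclass
class BacStats:
    bac_id: str
    n_nodes: int
    total_len: int
    n50: int
    l50: int
    gc: float


def bac_stats(bac: BacAssembly, min_node_len: int = 200, strict_n50: bool = False) -> BacStats:
    """Assembly statistics of one BAC over nodes >= ``min_node_len``."""
    lengths = [len(s) for s in bac.nodes.values() if len(s) >= min_node_len]
    if not lengths:
        raise DataError(f"{bac.bac_id}: no nodes of length >= {min_node_len}")
    n50, l50 = n50_l50(lengths, strict=strict_n50)
    seqs = [s for s in bac.nodes.values() if len(s) >= min_node_len]
    return BacStats(
        bac_id=bac.bac_id,
        n_nodes=len(lengths),
        total_len=sum(lengths),
        n50=n50,
        l50=l50,
        gc=gc_content(seqs),
    )


def stats_frame(bacs: Iterable[BacAssembly], min_node_len: int = 200) -> pd.DataFrame:
    rows = [bac_stats(b, min_node_len) for b in bacs]
    return pd.DataFrame(
        [
            {
                "bac_id": s.bac_id,
                "n_nodes": s.n_nodes,
                "total_len": s.total_len,
                "n50": s.n50,
                "l50": s.l50,
                "gc": round(s.gc, 6),
            }
            for s in rows
        ]
    )


def aggregate_table(
    stats: pd.DataFrame,
    assignments: pd.DataFrame,
    per_label_genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group summary table: one row per assignment label plus an 'All' row.

    Group means are unweighted means over member BACs; the All row is
    recomputed from the pooled clone set, never from group means (so e.g.
    All avg length x All n_bacs reproduces All total length). Labels with
    zero BACs are omitted. ``per_label_genes`` (label, unique_hc, unique_lc)
    merges gene-count columns in when given.
    """
    merged = stats.merge(assignments[["bac_id", "label"]], on="bac_id", how="left")
    if merged["label"].isna().any():
        missing = merged.loc[merged["label"].isna(), "bac_id"].tolist()
        raise DataError(f"BACs without assignment label: {missing[:10]}")

    def summarize(sub: pd.DataFrame, label: str) -> dict:
        return {
            "label": label,
            "n_bacs": len(sub),
            "avg_nodes": sub["n_nodes"].mean(),
            "total_len": int(sub["total_len"].sum()),
            "avg_len": sub["total_len"].mean(),
            "avg_n50": sub["n50"].mean(),
            "avg_l50": sub["l50"].mean(),
        }

    rows = [summarize(sub, str(label)) for label, sub in merged.groupby("label", sort=True)]
    rows.append(summarize(merged, "All"))
    table = pd.DataFrame(rows)
    if per_label_genes is not None:
        table = table.merge(per_label_genes[["label", "unique_hc", "unique_lc"]], on="label", how="left")
    return table


def _covered_fraction(a_nodes: Mapping[str, str], b_nodes: Mapping[str, str], min_match: int) -> float:
    """Fraction of A's bases lying inside exact matches (>= min_match bp,
    either strand) to B; overlapping match windows are merged implicitly."""
    b_words: set[bytes] = set()
    for seq in b_nodes.values():
        for s in (seq, revcomp(seq)):
            enc = s.encode()
            b_words.update(enc[i : i + min_match] for i in range(len(enc) - min_match + 1))
    covered = 0
    total = 0
    for seq in a_nodes.values():
        enc = seq.encode()
        n = len(enc)
        total += n
        if n < min_match or not b_words:
            continue
        mask = np.zeros(n, dtype=bool)
        run_end = -1
        for i in range(n - min_match + 1):
            if enc[i : i + min_match] in b_words:
                lo = max(i, run_end)
                mask[lo : i + min_match] = True
                run_end = i + min_match
        covered += int(mask.sum())
    if total == 0:
        raise DataError("pairwise_coverage: empty assembly")
    return covered / total


def pairwise_coverage(
    a: BacAssembly | Mapping[str, str],
    b: BacAssembly | Mapping[str, str],
    min_match: int = 100,
) -> tuple[float, float]:
    """(percent of A covered by B, percent of B covered by A).

    Coverage counts bases inside maximal exact matches of at least
    ``min_match`` bp on either strand — a deliberate lower bound on what a
    gapped aligner would report.
    """
    a_nodes = a.nodes if isinstance(a, BacAssembly) else dict(a)
    b_nodes = b.nodes if isinstance(b, BacAssembly) else dict(b)
    if not a_nodes or not b_nodes:
        raise DataError("pairwise_coverage: empty assembly")
    return (
        round(100.0 * _covered_fraction(a_nodes, b_nodes, min_match), 4),
        round(100.0 * _covered_fraction(b_nodes, a_nodes, min_match), 4),
    )


def filter_discordant_pairs(
    coverage: pd.DataFrame, threshold: float = 33.0, both_directions: bool = True
):
    """Split assembly pairs into kept / removed by mutual coverage.

    A pair is removed iff its coverage is below ``threshold`` percent — in
    both directions by default (mirroring removal of pairs with <33%
    alignment *with each other*), or in either direction when
    ``both_directions`` is False. Expects columns cov_ab, cov_ba.
    """
    low_ab = coverage["cov_ab"] < threshold
    low_ba = coverage["cov_ba"] < threshold
    removed_mask = (low_ab & low_ba) if both_directions else (low_ab | low_ba)
    removed = coverage[removed_mask].reset_index(drop=True)
    kept = coverage[~removed_mask].reset_index(drop=True)
    return kept, removed
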