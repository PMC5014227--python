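"""Comparative placement of BACs on a reference genome by plurality voting,
two-map anchor joins, and rank-correlation inversion flagging.

A BAC's cross-species alignment hits (e-value <= 1e-20) vote for reference
chromosomes; the chromosome with a strict plurality wins and the BAC's
position is the mean of its hit coordinates on that chromosome. Contigs of
BACs vote the same way over their placed members. Two genetic maps are
joined through markers matched to sequenced BACs, restricted to orthologous
linkage-group pairs; inversions appear as runs of sliding windows with
negative Kendall rank correlation between the two maps' coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


@dataclass
class SyntenyVote:
    bac_id: str
    status: str                      # placed | tied | no_hits
    chrom: str | None = None
    position: float | None = None    # mean coordinate on the winning chromosome
    votes: dict[str, int] = field(default_factory=dict)


def vote_bac(hits: pd.DataFrame, bac_id: str | None = None, evalue_cutoff: float = 1e-20) -> SyntenyVote:
    """Plurality vote over one BAC's hits.

    ``hits`` columns: subject_chrom, subject_pos, evalue (query_id optional
    when ``bac_id`` is given). A strict plurality places the BAC; a tie for
    the top chromosome leaves it unplaced (status 'tied'). The position is
    the arithmetic mean of subject coordinates on the winning chromosome
    only. The result is invariant to hit order.
    """
    if bac_id is None:
        ids = hits["query_id"].unique()
        if len(ids) != 1:
            raise DataError(f"vote_bac expects hits of one BAC, got {len(ids)} query ids")
        bac_id = str(ids[0])
    kept = hits[hits["evalue"] <= evalue_cutoff]
    if kept.empty:
        return SyntenyVote(bac_id=bac_id, status="no_hits")
    counts = kept.groupby("subject_chrom").size().sort_index()
    votes = {str(c): int(n) for c, n in counts.items()}
    top = counts.max()
    winners = counts.index[counts == top]
    if len(winners) > 1:
        return SyntenyVote(bac_id=bac_id, status="tied", votes=votes)
    chrom = str(winners[0])
    pos = float(kept.loc[kept["subject_chrom"] == chrom, "subject_pos"].mean())
    return SyntenyVote(bac_id=bac_id, status="placed", chrom=chrom, position=pos, votes=votes)


def vote_table(hits: pd.DataFrame, evalue_cutoff: float = 1e-20) -> pd.DataFrame:
    """vote_bac over every query in a hit table -> one row per BAC."""
    rows = []
    for bac_id, sub in hits.groupby("query_id", sort=True):
        v = vote_bac(sub, bac_id=str(bac_id), evalue_cutoff=evalue_cutoff)
        rows.append(
            {
                "bac_id": v.bac_id,
                "status": v.status,
                "chrom": v.chrom,
                "position": v.position,
                "n_votes_winner": v.votes.get(v.chrom, 0) if v.chrom else 0,
                "n_hits": sum(v.votes.values()),
            }
        )
    return pd.DataFrame(
        rows, columns=["bac_id", "status", "chrom", "position", "n_votes_winner", "n_hits"]
    )


def vote_contig(member_votes: Sequence[SyntenyVote], contig_id: str = "") -> SyntenyVote:
    """Contig-level vote: each placed member BAC casts one vote for its
    chromosome; the contig position is the mean of member positions on the
    winning chromosome."""
    if not member_votes:
        raise DataError("vote_contig needs at least one member BAC")
    placed = [v for v in member_votes if v.status == "placed"]
    if not placed:
        return SyntenyVote(bac_id=contig_id, status="no_hits")
    counts: dict[str, int] = {}
    for v in placed:
        counts[v.chrom] = counts.get(v.chrom, 0) + 1
    top = max(counts.values())
    winners = sorted(c for c, n in counts.items() if n == top)
    if len(winners) > 1:
        return SyntenyVote(bac_id=contig_id, status="tied", votes=counts)
    chrom = winners[0]
    pos = float(np.mean([v.position for v in placed if v.chrom == chrom]))
    return SyntenyVote(bac_id=contig_id, status="placed", chrom=chrom, position=pos, votes=counts)


def anchor_join(
    markers_to_map_a: pd.DataFrame,   # marker_id, group, cm
    markers_to_bacs: pd.DataFrame,    # marker_id, bac_id
    bacs_to_map_b: pd.DataFrame,      # bac_id, group, cm
    orthology: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Cross-relate two genetic maps through markers and sequenced BACs.

    Inner join marker -> BAC -> map B; pairs whose (group_a, group_b) is not
    in the orthology table are dropped; duplicate (marker, bac) rows
    collapse to one. A marker mapped to two groups within map A (or a BAC
    within map B) raises a DataError.
    """
    for df, key, what in (
        (markers_to_map_a, "marker_id", "map A"),
        (bacs_to_map_b, "bac_id", "map B"),
    ):
        groups = df.groupby(key)["group"].nunique()
        bad = sorted(groups.index[groups > 1])
        if bad:
            raise DataError(f"{what}: {bad[:5]} mapped to more than one linkage group")

    a = markers_to_map_a.rename(columns={"group": "group_a", "cm": "cm_a"})
    b = bacs_to_map_b.rename(columns={"group": "group_b", "cm": "cm_b"})
    joined = markers_to_bacs.merge(a, on="marker_id").merge(b, on="bac_id")
    ortho = set(orthology)
    keep = [
        (ga, gb) in ortho
        for ga, gb in zip(joined["group_a"], joined["group_b"])
    ]
    joined = joined[keep].drop_duplicates(subset=["marker_id", "bac_id"])
    cols = ["marker_id", "bac_id", "group_a", "cm_a", "group_b", "cm_b"]
    return joined[cols].sort_values(["group_a", "cm_a"], kind="stable").reset_index(drop=True)


def detect_inversions(
    pairs: pd.DataFrame, window_size: int = 10, min_run: int = 2
) -> pd.DataFrame:
    """Flag inverted segments between two maps for one linkage-group pair.

    ``pairs`` must carry cm_a, cm_b and is processed in cm_a order. Kendall's
    tau is computed over every window of ``window_size`` consecutive pairs;
    maximal runs of >= ``min_run`` consecutive windows with tau < 0 are
    merged and reported with their cm_a extent. Reversing map B's
    orientation flips every window's correlation sign.
    """
    pairs = pairs.sort_values("cm_a", kind="stable").reset_index(drop=True)
    n = len(pairs)
    if n < window_size:
        warnings.warn(
            f"detect_inversions: {n} pairs < window_size {window_size}; no result",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["cm_a_start", "cm_a_end", "n_windows"])
    cm_a = pairs["cm_a"].to_numpy(float)
    cm_b = pairs["cm_b"].to_numpy(float)
    taus = np.empty(n - window_size + 1)
    for i in range(taus.size):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant windows give tau = nan
            taus[i] = stats.kendalltau(
                cm_a[i : i + window_size], cm_b[i : i + window_size]
            ).statistic
    neg = taus < 0

    regions = []
    i = 0
    while i < neg.size:
        if neg[i]:
            j = i
            while j + 1 < neg.size and neg[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                regions.append(
                    {
                        "cm_a_start": float(cm_a[i]),
                        "cm_a_end": float(cm_a[j + window_size - 1]),
                        "n_windows": j - i + 1,
                    }
                )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(regions, columns=["cm_a_start", "cm_a_end", "n_windows"])
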