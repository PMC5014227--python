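"""Chromosome-arm assignment of BAC assemblies by discriminative k-mers.

A k-mer index is built from chromosome-arm target sequences keeping only
k-mers specific to a single target; k-mers shared by exactly the short and
long arm of one chromosome (and by nothing else) define that chromosome's
centromeric pseudo-target (e.g. ``4HC``). Classification counts a BAC's
k-mer occurrences per target and accepts the top label when the confidence
h1/(h1+h2) — top hit count over top-two total — strictly exceeds the
threshold (default 0.75, exclusive).

Defaults follow the published procedure this mirrors: k = 19, within-target
k-mers seen only once discarded, confidence accepted only when > 0.75, and
strand-canonical k-mers since clone insert orientation is arbitrary.
"""
from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._kmers import kmer_codes
from .errors import ConfigurationError, DataError
from .synthetic import BacAssembly, BacLibrary

UNASSIGNED = "UNASSIGNED"

_MAGIC = b"BACATLAS-KMERIDX\n"
_VERSION = 1


@dataclass
class ClassifierConfig:
    k: int = 19
    min_kmer_count: int = 2
    confidence_threshold: float = 0.75
    canonical: bool = True
    distinct: bool = False  # count distinct BAC k-mers instead of occurrences

    def validate(self) -> None:
        if not 0 < self.k <= 31:
            raise ConfigurationError("k must be in 1..31")
        if self.min_kmer_count < 1:
            raise ConfigurationError("min_kmer_count must be >= 1")
        if not 0 <= self.confidence_threshold < 1:
            raise ConfigurationError("confidence_threshold must be in [0, 1)")


def _centromeric_label(label_a: str, label_b: str) -> str | None:
    """Centromeric label when two labels are the S/L arms of one chromosome."""
    if len(label_a) < 2 or len(label_b) < 2:
        return None
    if {label_a[-1], label_b[-1]} == {"S", "L"} and label_a[:-1] == label_b[:-1]:
        return label_a[:-1] + "C"
    return None


@dataclass
class KmerIndex:
    """Sorted discriminative k-mer table: code -> single target label."""

    k: int
    canonical: bool
    labels: list[str]               # arm labels first, then centromeric labels
    kmers: np.ndarray               # sorted uint64 codes
    label_codes: np.ndarray         # int16, parallel to kmers
    min_kmer_count: int = 2

    def __post_init__(self):
        self.kmers = np.asarray(self.kmers, dtype=np.uint64)
        self.label_codes = np.asarray(self.label_codes, dtype=np.int16)

    def __len__(self) -> int:
        return int(self.kmers.size)

    def label_counts(self) -> dict[str, int]:
        """Discriminative k-mers per target label."""
        counts = np.bincount(self.label_codes, minlength=len(self.labels))
        return {lab: int(c) for lab, c in zip(self.labels, counts)}

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Label code per query k-mer; -1 where not indexed."""
        if codes.size == 0:
            return np.empty(0, dtype=np.int16)
        pos = np.searchsorted(self.kmers, codes)
        pos_c = np.minimum(pos, self.kmers.size - 1)
        found = (self.kmers.size > 0) & (self.kmers[pos_c] == codes)
        out = np.full(codes.size, -1, dtype=np.int16)
        out[found] = self.label_codes[pos_c[found]]
        return out

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header = json.dumps(
            {
                "version": _VERSION,
                "k": self.k,
                "canonical": self.canonical,
                "labels": self.labels,
                "min_kmer_count": self.min_kmer_count,
                "n_kmers": int(self.kmers.size),
            }
        ).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<I", len(header)))
            fh.write(header)
            fh.write(self.kmers.tobytes())
            fh.write(self.label_codes.tobytes())

    @classmethod
    def load(cls, path) -> "KmerIndex":
        with open(path, "rb") as fh:
            magic = fh.read(len(_MAGIC))
            if magic != _MAGIC:
                raise DataError(f"{path}: not a bacatlas k-mer index (bad magic)")
            (hlen,) = struct.unpack("<I", fh.read(4))
            header = json.loads(fh.read(hlen))
            if header["version"] != _VERSION:
                raise DataError(f"{path}: unsupported index version {header['version']}")
            n = header["n_kmers"]
            kmers = np.frombuffer(fh.read(8 * n), dtype=np.uint64)
            codes = np.frombuffer(fh.read(2 * n), dtype=np.int16)
        return cls(
            k=header["k"],
            canonical=header["canonical"],
            labels=header["labels"],
            kmers=kmers.copy(),
            label_codes=codes.copy(),
            min_kmer_count=header["min_kmer_count"],
        )


@dataclass
class Assignment:
    bac_id: str
    label: str                      # arm label, centromeric label, or UNASSIGNED
    confidence: float
    h1: int
    h2: int
    hits: dict[str, int] = field(default_factory=dict)

    @property
    def total_hits(self) -> int:
        return sum(self.hits.values())


def build_index(
    targets: Mapping[str, Iterable[str] | str], config: ClassifierConfig | None = None
) -> KmerIndex:
    """Build the discriminative k-mer index from labelled target sequences.

    Keeps k-mers occurring (with total count >= min_kmer_count inside one
    target) in exactly one target under that target's label, and k-mers
    occurring in exactly the two arm targets of the same chromosome under the
    chromosome's centromeric label. Any k-mer seen in two unrelated targets,
    or in three or more, is discarded.
    """
    config = config or ClassifierConfig()
    config.validate()
    if len(targets) < 2:
        raise ConfigurationError("need at least 2 targets to build a discriminative index")

    labels = list(targets.keys())
    per_target: list[np.ndarray] = []
    for label in labels:
        seqs = targets[label]
        if isinstance(seqs, str):
            seqs = [seqs]
        seqs = list(seqs)
        if not seqs or all(len(s) == 0 for s in seqs):
            raise ConfigurationError(f"target {label!r} has no sequence")
        codes = (
            np.concatenate([kmer_codes(s, config.k, config.canonical) for s in seqs])
            if seqs
            else np.empty(0, np.uint64)
        )
        uniq, counts = np.unique(codes, return_counts=True)
        per_target.append(uniq[counts >= config.min_kmer_count])

    # centromeric pairs: (i, j) target indices that are S/L arms of one chromosome
    cent_label_of_pair: dict[tuple[int, int], str] = {}
    cent_labels: list[str] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            cl = _centromeric_label(labels[i], labels[j])
            if cl is not None:
                cent_label_of_pair[(i, j)] = cl
                cent_labels.append(cl)

    all_labels = labels + cent_labels
    label_idx = {lab: i for i, lab in enumerate(all_labels)}

    kmers_all = np.concatenate(per_target) if per_target else np.empty(0, np.uint64)
    owners = np.concatenate(
        [np.full(a.size, i, dtype=np.int16) for i, a in enumerate(per_target)]
    ) if per_target else np.empty(0, np.int16)
    order = np.argsort(kmers_all, kind="stable")
    kmers_all, owners = kmers_all[order], owners[order]

    uniq, start, counts = np.unique(kmers_all, return_index=True, return_counts=True)
    out_kmers = []
    out_codes = []
    single = counts == 1
    out_kmers.append(uniq[single])
    out_codes.append(owners[start[single]].astype(np.int16))
    # pairs: keep only S/L-of-same-chromosome pairs as centromeric
    two = np.flatnonzero(counts == 2)
    if two.size:
        a = owners[start[two]]
        b = owners[start[two] + 1]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        pair_kmers, pair_codes = [], []
        for (i, j), cl in cent_label_of_pair.items():
            sel = (lo == i) & (hi == j)
            if sel.any():
                pair_kmers.append(uniq[two[sel]])
                pair_codes.append(np.full(int(sel.sum()), label_idx[cl], dtype=np.int16))
        if pair_kmers:
            out_kmers.append(np.concatenate(pair_kmers))
            out_codes.append(np.concatenate(pair_codes))

    kmers = np.concatenate(out_kmers) if out_kmers else np.empty(0, np.uint64)
    codes = np.concatenate(out_codes) if out_codes else np.empty(0, np.int16)
    order = np.argsort(kmers, kind="stable")
    return KmerIndex(
        k=config.k,
        canonical=config.canonical,
        labels=all_labels,
        kmers=kmers[order],
        label_codes=codes[order],
        min_kmer_count=config.min_kmer_count,
    )


def classify(
    index: KmerIndex, bac: BacAssembly, config: ClassifierConfig | None = None
) -> Assignment:
    """Assign one BAC: count indexed k-mer occurrences per label, accept the
    plurality label iff h1/(h1+h2) strictly exceeds the threshold.

    Ties for the top label give UNASSIGNED. A BAC with no indexed k-mers is
    UNASSIGNED at confidence 0. Permuting the BAC's nodes cannot change the
    result (counting is order-free).
    """
    config = config or ClassifierConfig()
    config.validate()
    if config.k != index.k:
        raise DataError(f"k mismatch: index k={index.k}, config k={config.k}")
    if config.canonical != index.canonical:
        raise DataError("canonicalization mismatch between index and config")

    codes = [kmer_codes(seq, index.k, index.canonical) for seq in bac.nodes.values()]
    codes = np.concatenate(codes) if codes else np.empty(0, np.uint64)
    if config.distinct:
        codes = np.unique(codes)
    found = index.lookup(codes)
    counts = np.bincount(found[found >= 0], minlength=len(index.labels))
    hits = {lab: int(c) for lab, c in zip(index.labels, counts) if c > 0}

    if not hits:
        return Assignment(bac.bac_id, UNASSIGNED, 0.0, 0, 0, {})
    ordered = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    h1 = ordered[0][1]
    h2 = ordered[1][1] if len(ordered) > 1 else 0
    confidence = 1.0 if h2 == 0 else h1 / (h1 + h2)
    tied = len(ordered) > 1 and ordered[1][1] == h1
    if tied or not (confidence > config.confidence_threshold):
        return Assignment(bac.bac_id, UNASSIGNED, confidence, h1, h2, hits)
    return Assignment(bac.bac_id, ordered[0][0], confidence, h1, h2, hits)


def classify_library(
    index: KmerIndex,
    library: BacLibrary | Iterable[BacAssembly],
    config: ClassifierConfig | None = None,
):
    """Classify every clone; return (assignments, summary).

    summary has one row per label plus totals; the assignment rate is the
    percentage of clones not UNASSIGNED, reported to one decimal.
    """
    clones = library.clones if isinstance(library, BacLibrary) else list(library)
    assignments = [classify(index, bac, config) for bac in clones]
    n = len(assignments)
    per_label: dict[str, int] = {}
    for a in assignments:
        per_label[a.label] = per_label.get(a.label, 0) + 1
    n_assigned = sum(c for lab, c in per_label.items() if lab != UNASSIGNED)
    rate = round(100.0 * n_assigned / n, 1) if n else 0.0
    summary = {
        "n_bacs": n,
        "n_assigned": n_assigned,
        "assignment_rate_pct": rate,
        "per_label": dict(sorted(per_label.items())),
    }
    return assignments, summary


def assignments_frame(assignments: Iterable[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bac_id": a.bac_id,
                "label": a.label,
                "confidence": round(a.confidence, 6),
                "h1": a.h1,
                "h2": a.h2,
                "total_hits": a.total_hits,
            }
            for a in assignments
        ],
        columns=["bac_id", "label", "confidence", "h1", "h2", "total_hits"],
    )
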