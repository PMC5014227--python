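"""Readers and writers for the plain-text formats used across the pipeline.

All inter-stage data travels as FASTA and TSV. Every table written by the
package starts with a comment line recording the tool version and a hash of
the configuration that produced it, so downstream files are self-describing.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import DataError


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping.

    Multi-line records are supported; empty-sequence records and files whose
    first non-blank line is not a header are rejected with the line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise DataError(
                        f"{path}: malformed FASTA header at line {lineno}: "
                        f"expected '>', got {line[:30]!r}"
                    )
                break
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise DataError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in records:
            raise DataError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = seq
    return records


def write_fasta(path, records: Mapping[str, str] | Iterable[tuple[str, str]], width: int = 80) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def config_hash(config) -> str:
    """Short stable hash of any JSON-serializable configuration object."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config=None) -> None:
    """Write a TSV with a leading comment line (tool version + config hash)."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# bacatlas {__version__} config={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
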