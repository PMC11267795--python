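"""File-format helpers: FASTA, tabular hit tables, TSV matrices, run manifests."""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: column names of the 12-column tabular alignment format (BLAST/Diamond outfmt 6)
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Write ``{id: sequence}`` to a FASTA file wrapped at *width* columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False, columns=HIT_COLUMNS)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample matrix as TSV (rows = features)."""
    matrix.to_csv(path, sep="\t", index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_manifest(path: str | Path, params: Mapping) -> None:
    """Record generator/analysis parameters (seed included) for reproducibility."""
    payload = {"created": datetime.datetime.now().isoformat(timespec="seconds")}
    payload.update({k: (v.tolist() if hasattr(v, "tolist") else v) for k, v in params.items()})
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
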