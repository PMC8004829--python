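"""FASTA / TSV / Newick input-output helpers.

Thin wrappers over Biopython and pandas that add the error reporting and
header-comment conventions used throughout the pipeline.  Every tabular
output starts with ``#`` comment lines carrying the tool version, the RNG
seed and a hash of the configuration that produced it, so results remain
traceable after the fact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__


class FastaFormatError(ValueError):
    """Raised when a FASTA file has text before the first header."""


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly CRLF) FASTA file into a list of SeqRecords.

    Raises :class:`FastaFormatError` with the offending line number when
    non-blank text precedes the first ``>`` header.
    """
    path = Path(path)
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: text before first FASTA header"
                )
            break
    with open(path, "r", newline=None) as fh:
        return list(SeqIO.parse(fh, "fasta"))


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path) -> None:
    """Write records (SeqRecords or ``(id, sequence)`` pairs) as FASTA.

    Sequences are written on a single line each so that a write->read
    round trip is byte-stable.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rid, seq = rec
                fh.write(f">{rid}\n{seq}\n")
            else:
                desc = f" {rec.description}" if rec.description and rec.description != rec.id else ""
                fh.write(f">{rec.id}{desc}\n{str(rec.seq)}\n")


def config_hash(config: Mapping | object) -> str:
    """Short stable hash of a configuration mapping or dataclass-like object."""
    if hasattr(config, "__dict__") and not isinstance(config, Mapping):
        payload = {k: v for k, v in vars(config).items() if not k.startswith("_")}
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def output_header(seed: int | None = None, config: Mapping | object | None = None) -> str:
    parts = [f"mytipav v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config={config_hash(config)}")
    return "# " + " ".join(parts)


def write_tsv(
    table: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | object | None = None,
    index: bool = False,
) -> None:
    """Write a DataFrame as TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(output_header(seed=seed, config=config) + "\n")
        table.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_newick(tree, path: str | Path, seed: int | None = None) -> None:
    """Write an skbio TreeNode to a Newick file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(str(path), format="newick")


def as_records(pairs: Sequence[tuple[str, str]]) -> list[SeqRecord]:
    return [SeqRecord(Seq(s), id=i, description="") for i, s in pairs]
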