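"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO; depth tracks are
4-column bedGraph (0-based half-open) or 2-column TSV (1-based position,
depth).  Gzipped read files are handled transparently by suffix.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import MalformedReadError


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    raise MalformedReadError(f"cannot infer read format from file name: {path}")


def iter_reads(source) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from a file path or an in-memory collection.

    Accepts FASTA/FASTQ paths (optionally gzipped), iterables of
    ``(id, sequence)`` pairs, or objects with ``read_id``/``sequence``
    attributes (simulated reads).
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        fmt = _sniff_format(path)
        with _open_text(path) as handle:
            for i, rec in enumerate(SeqIO.parse(handle, fmt)):
                seq = str(rec.seq).upper()
                if not seq:
                    raise MalformedReadError(f"empty read record {rec.id}", record_index=i)
                yield rec.id, seq
        return
    for item in source:
        if hasattr(item, "read_id") and hasattr(item, "sequence"):
            yield item.read_id, item.sequence.upper()
        else:
            rid, seq = item
            yield rid, seq.upper()


def load_reads(source) -> list[tuple[str, str]]:
    return list(iter_reads(source))


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write ``(header, sequence)`` pairs, wrapping lines at 80 columns."""
    path = Path(path)
    with _open_text(path, "wt") as out:
        for header, seq in records:
            out.write(f">{header}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")


def write_fastq(reads, path) -> None:
    """Write simulated reads as FASTQ with their dummy qualities."""
    path = Path(path)
    with _open_text(path, "wt") as out:
        for read in reads:
            qual = getattr(read, "quality", None) or "I" * len(read.sequence)
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def read_single_fasta(path) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}")
    return records[0].id, str(records[0].seq).upper()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
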