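"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; intervals are written as 0-based half-open BED;
tables are tab-separated with a header line and ``#``-prefixed metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALLOWED = set("ACGTN")


@dataclasses.dataclass
class GenomeAssembly:
    """A named set of contigs with a species label and a role (base/donor)."""

    species: str
    contigs: dict[str, str]
    role: str = "donor"

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __len__(self) -> int:
        return len(self.contigs)


def read_fasta(path: str | Path, species: str | None = None, role: str = "donor") -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly`.

    Sequences are upper-cased; only A/C/G/T/N are accepted. Duplicate ids and
    empty records are errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record: {rec.id!r}")
        illegal = set(seq) - _ALLOWED
        if illegal:
            raise ValueError(f"illegal characters {sorted(illegal)} in record {rec.id!r}")
        contigs[rec.id] = seq
    if species is None:
        species = Path(path).stem
    return GenomeAssembly(species=species, contigs=contigs, role=role)


def write_fasta(assembly: GenomeAssembly | Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write contigs as FASTA with fixed-width line wrapping."""
    contigs = assembly.contigs if isinstance(assembly, GenomeAssembly) else assembly
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in contigs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: str = "I") -> None:
    """Write (name, sequence) pairs as FASTQ with a constant dummy quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ into (name, sequence) pairs; qualities are ignored."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name, ...]) tuples as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, str] | None = None,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
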