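"""Plain-text interchange formats.

All tables are tab-separated with no header row:

* homology table:   query <TAB> accession <TAB> identity_pct <TAB> evalue
* annotation index: accession <TAB> GO:NNNNNNN[,GO:NNNNNNN...]
* domain hits:      protein <TAB> domain_id <TAB> evalue
* benchmark:        protein_id <TAB> loc1;loc2;...
* index files:      one identifier per line, order = vector position

Sequences travel as FASTA (via Biopython, <= 80-character lines).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import LocativeDataset, ProteinRecord


class TableParseError(ValueError):
    """A malformed table row; the message names the file and line."""


def _rows(path: str | Path, n_fields: int) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != n_fields:
            raise TableParseError(
                f"{path}:{lineno}: expected {n_fields} tab-separated fields, "
                f"got {len(fields)}"
            )
        yield lineno, fields


def read_homology_table(path: str | Path) -> dict[str, list[tuple[str, float, float]]]:
    table: dict[str, list[tuple[str, float, float]]] = {}
    for lineno, (query, acc, ident, ev) in (
        (ln, f) for ln, f in _rows(path, 4)
    ):
        try:
            row = (acc, float(ident), float(ev))
        except ValueError:
            raise TableParseError(
                f"{path}:{lineno}: non-numeric identity/e-value"
            ) from None
        table.setdefault(query, []).append(row)
    return table


def write_homology_table(
    table: dict[str, list[tuple[str, float, float]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for query in table:
            for acc, ident, ev in table[query]:
                fh.write(f"{query}\t{acc}\t{ident:g}\t{ev:g}\n")


def read_annotation_index(path: str | Path) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for _, (acc, terms) in _rows(path, 2):
        index.setdefault(acc, set()).update(
            t for t in terms.split(",") if t
        )
    return index


def write_annotation_index(index: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc in index:
            fh.write(f"{acc}\t{','.join(sorted(index[acc]))}\n")


def read_domain_hits(path: str | Path) -> dict[str, list[tuple[str, float]]]:
    table: dict[str, list[tuple[str, float]]] = {}
    for lineno, (protein, domain, ev) in ((ln, f) for ln, f in _rows(path, 3)):
        try:
            row = (domain, float(ev))
        except ValueError:
            raise TableParseError(f"{path}:{lineno}: non-numeric e-value") from None
        table.setdefault(protein, []).append(row)
    return table


def write_domain_hits(table: dict[str, list[tuple[str, float]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for protein in table:
            for domain, ev in table[protein]:
                fh.write(f"{protein}\t{domain}\t{ev:g}\n")


def read_benchmark_labels(path: str | Path) -> list[tuple[str, frozenset[str]]]:
    """Read (protein id, label set) rows without frame validation."""
    out = []
    for lineno, (pid, labels) in ((ln, f) for ln, f in _rows(path, 2)):
        label_set = frozenset(l for l in labels.split(";") if l)
        if not label_set:
            raise TableParseError(f"{path}:{lineno}: protein {pid!r} has no labels")
        out.append((pid, label_set))
    return out


def read_benchmark(
    path: str | Path, locations: tuple[str, ...]
) -> LocativeDataset:
    """Read a labeled benchmark; sequences are attached separately if needed."""
    proteins = [
        ProteinRecord(pid, "X", labels) for pid, labels in read_benchmark_labels(path)
    ]
    return LocativeDataset(proteins, locations)


def write_benchmark(dataset: LocativeDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in dataset:
            fh.write(f"{rec.id}\t{';'.join(sorted(rec.labels))}\n")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise TableParseError(f"{path}: not FASTA (no '>' description line)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
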