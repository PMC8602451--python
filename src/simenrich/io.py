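"""Reading and writing of proteome FASTA files, protein lists and result tables.

FASTA handling follows the UniProt dialect: headers of the form
``>sp|ACC|NAME description`` (or ``tr|...``) are split into accession, entry
name and description; plain headers use the first whitespace-delimited token
as the accession.  Parsing and serialization go through :mod:`Bio.SeqIO`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "Proteome",
    "ProteinList",
    "read_fasta",
    "write_fasta",
    "read_protein_list",
    "write_table",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence keyed by its accession.

    The sequence is stored uppercase over A–Z; nonstandard residues
    (U, X, B, Z, O) are preserved — the motif scanner decides how to
    treat them.
    """

    accession: str
    sequence: str
    name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.accession!r}")
        if not self.sequence.isupper() or not self.sequence.isalpha():
            raise ValueError(
                f"sequence for {self.accession!r} must be uppercase A-Z"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class Proteome:
    """An ordered, accession-unique collection of :class:`ProteinRecord`.

    Iteration order equals insertion (file) order so that downstream
    random sampling is deterministic given a seed.
    """

    def __init__(self, records: Iterable[ProteinRecord], source_label: str = ""):
        self._records: list[ProteinRecord] = list(records)
        self.source_label = source_label
        self._index: dict[str, int] = {}
        for i, rec in enumerate(self._records):
            if rec.accession in self._index:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            self._index[rec.accession] = i

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def __getitem__(self, key: int | str) -> ProteinRecord:
        if isinstance(key, str):
            return self._records[self._index[key]]
        return self._records[key]

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self._records]

    def subset(self, accessions: Sequence[str], source_label: str = "") -> "Proteome":
        return Proteome(
            (self[a] for a in accessions),
            source_label=source_label or self.source_label,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Proteome({len(self)} records, source={self.source_label!r})"


@dataclass
class ProteinList:
    """A labelled protein list resolved against a proteome.

    ``members`` are resolved accessions (unique, in input order);
    ``unresolved`` keeps every input identifier that could not be matched
    so that nothing is silently dropped.
    """

    label: str
    members: list[str]
    unresolved: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def _parse_header(record: SeqRecord) -> tuple[str, str, str]:
    """Split a FASTA header into (accession, name, description)."""
    token = record.id
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr") and parts[1]:
        accession, name = parts[1], parts[2]
    else:
        accession, name = token, ""
    desc = record.description
    if desc.startswith(token):
        desc = desc[len(token):].strip()
    return accession, name, desc


def read_fasta(path: str | Path, source_label: str | None = None) -> Proteome:
    """Read a (UniProt-style) FASTA file into a :class:`Proteome`.

    Sequence lines are concatenated, whitespace-stripped and uppercased;
    parsing is insensitive to line-wrapping width.

    Raises
    ------
    ValueError
        If the file is empty / contains no records, does not start with
        ``>``, or contains duplicate accessions.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        while first and first.isspace():
            first = fh.read(1)
        if not first:
            raise ValueError(f"no records in {path}")
        if first != ">":
            raise ValueError(f"{path} is not FASTA (first character {first!r})")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, name, desc = _parse_header(rec)
        seq = "".join(str(rec.seq).split()).upper()
        records.append(
            ProteinRecord(accession=accession, sequence=seq, name=name, description=desc)
        )
    if not records:
        raise ValueError(f"no records in {path}")
    label = source_label if source_label is not None else path.name
    return Proteome(records, source_label=label)


def write_fasta(proteome: Proteome | Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, reconstructing UniProt-style headers.

    Records with an entry name round-trip as ``>sp|ACC|NAME desc``;
    records without one as ``>ACC desc``.
    """
    seq_records = []
    for rec in proteome:
        if rec.name:
            rid = f"sp|{rec.accession}|{rec.name}"
        else:
            rid = rec.accession
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rid, description=rec.description)
        )
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seq_records)


def read_protein_list(path: str | Path, proteome: Proteome,
                      label: str | None = None) -> ProteinList:
    """Read a one-identifier-per-line protein list and resolve it.

    Blank lines and ``#`` comments are ignored.  Identifiers are matched
    against accessions first, then entry names, case-sensitively and then
    case-insensitively.  Duplicates are collapsed with a warning;
    unmatched identifiers go to ``unresolved``.

    Raises
    ------
    ValueError
        If zero identifiers resolve (downstream statistics undefined).
    """
    path = Path(path)
    tokens = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens.append(line.split()[0])

    by_name = {r.name: r.accession for r in proteome if r.name}
    by_acc_ci = {r.accession.upper(): r.accession for r in proteome}
    by_name_ci = {r.name.upper(): r.accession for r in proteome if r.name}

    members: list[str] = []
    seen: set[str] = set()
    unresolved: list[str] = []
    n_dupes = 0
    for tok in tokens:
        acc = None
        if tok in proteome:
            acc = tok
        elif tok in by_name:
            acc = by_name[tok]
        elif tok.upper() in by_acc_ci:
            acc = by_acc_ci[tok.upper()]
        elif tok.upper() in by_name_ci:
            acc = by_name_ci[tok.upper()]
        if acc is None:
            unresolved.append(tok)
        elif acc in seen:
            n_dupes += 1
        else:
            seen.add(acc)
            members.append(acc)
    if n_dupes:
        warnings.warn(
            f"{path.name}: collapsed {n_dupes} duplicate identifier(s)",
            stacklevel=2,
        )
    if not members:
        raise ValueError(f"{path}: no identifiers resolved against the proteome")
    return ProteinList(label=label or path.stem, members=members,
                       unresolved=unresolved)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_table(rows: pd.DataFrame | Sequence[Mapping], path: str | Path,
                metadata: Mapping | None = None) -> None:
    """Write a tab-separated table plus a JSON metadata sidecar.

    Floats are serialized with 6 significant digits.  ``metadata``
    (seed, parameters, input checksums — whatever reproduces the run)
    lands in ``<path>.meta.json``.
    """
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(dict(metadata), indent=2, default=str) + "\n")
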