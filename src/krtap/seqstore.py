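"""Protein sequence records and FASTA I/O.

The I/O substrate for every pipeline stage.  Headers follow the NCBI/UniProt
convention: the first whitespace-delimited token is the accession (unique
within a store), the remainder is the free-text annotation, and a trailing
``[Genus species]`` bracket, when present, is parsed as the species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .scoring import PROTEIN_ALPHABET

_VALID_RESIDUES = frozenset(PROTEIN_ALPHABET)
_SPECIES_RE = re.compile(r"\[([^\[\]]+)\]\s*$")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its accession, species and annotation."""

    id: str
    residues: str
    annotation: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        residues = self.residues.upper().rstrip("*")
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        for pos, c in enumerate(residues, start=1):
            if c not in _VALID_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {c!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


class SequenceStore:
    """Ordered, id-indexed collection of :class:`SequenceRecord`.

    Iteration order equals insertion (file) order; ids are unique.
    """

    def __init__(self, records: list[SequenceRecord] | None = None):
        self._records: list[SequenceRecord] = []
        self._index: dict[str, SequenceRecord] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self._index:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        self._records.append(rec)
        self._index[rec.id] = rec

    def lookup(self, rec_id: str) -> SequenceRecord:
        try:
            return self._index[rec_id]
        except KeyError:
            raise KeyError(f"no record with id {rec_id!r}") from None

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    def subset(self, ids) -> "SequenceStore":
        wanted = set(ids)
        return SequenceStore([r for r in self._records if r.id in wanted])


def _parse_header(rec: _BioRecord) -> tuple[str, str, str]:
    annotation = rec.description[len(rec.id):].strip() if rec.description else ""
    species = ""
    m = _SPECIES_RE.search(annotation)
    if m:
        species = m.group(1).strip()
    return rec.id, annotation, species


def read_fasta(path: str | Path) -> SequenceStore:
    """Read a multi-record protein FASTA into a :class:`SequenceStore`.

    Residues are uppercased; a terminal '*' stop symbol is stripped.  An
    empty file, a duplicate id, or an illegal residue raise ValueError.
    """
    path = Path(path)
    store = SequenceStore()
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        rec_id, annotation, species = _parse_header(bio_rec)
        store.add(
            SequenceRecord(
                id=rec_id,
                residues=str(bio_rec.seq),
                annotation=annotation,
                species=species,
            )
        )
    if len(store) == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return store


def write_fasta(store: SequenceStore, path: str | Path) -> Path:
    """Write a store to FASTA with 60-column wrapping; round-trip lossless."""
    if len(store) == 0:
        raise ValueError("refusing to write an empty store")
    path = Path(path)
    bio_records = [
        _BioRecord(
            Seq(rec.residues),
            id=rec.id,
            description=rec.annotation,
        )
        for rec in store
    ]
    with open(path, "w") as handle:
        SeqIO.write(bio_records, handle, "fasta")
    return path


def filter_by_annotation(store: SequenceStore, pattern: str) -> SequenceStore:
    """Records whose annotation matches `pattern` (regex, case-insensitive).

    This is the KRTAP-annotated harvest selector: e.g. pattern
    ``"KRTAP|keratin[ -]associated"`` keeps KRTAP and KRTAP-like entries.
    Order is preserved; an empty result is allowed.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    rx = re.compile(pattern, re.IGNORECASE)
    return SequenceStore([r for r in store if rx.search(r.annotation)])
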