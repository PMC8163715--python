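"""Alignment and partition ingestion, validation and output.

An :class:`Alignment` is an ordered, equal-length, gapped nucleotide
matrix for a single marker (e.g. COI or 28S D1-D2).  A
:class:`Partition` maps sequence identifiers to species labels and is
what turns an alignment into query and reference groups.  All column
coordinates in the public API are 1-based, matching how diagnostic
positions are reported in taxonomic diagnoses.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
from Bio import SeqIO

from .iupac import ALPHABET, normalize_residues

Source = Union[str, Path, IO[str]]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped nucleotide sequences for one marker."""

    marker: str
    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise DataError("alignment has no records")
        if len(self.ids) != len(self.seqs):
            raise DataError("ids and seqs differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DataError(f"duplicate sequence id(s): {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise DataError(
                f"unequal sequence lengths {sorted(lengths)}: input is not aligned"
            )
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - ALPHABET
            if bad:
                raise DataError(f"record {sid!r}: non-IUPAC code(s) {sorted(bad)!r}")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.seqs[0])

    @property
    def n_records(self) -> int:
        return len(self.ids)

    @property
    def records(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.ids, self.seqs))

    def sequence(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(seq_id) from None

    def column(self, position: int) -> str:
        """Residues of a 1-based column, in record order."""
        if not 1 <= position <= self.length:
            raise IndexError(f"column {position} outside 1..{self.length}")
        j = position - 1
        return "".join(s[j] for s in self.seqs)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Restriction to the given ids, preserving record order."""
        keep = set(ids)
        pairs = [(i, s) for i, s in zip(self.ids, self.seqs) if i in keep]
        if not pairs:
            raise DataError("subset would leave no records")
        return Alignment(self.marker, tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))

    def to_array(self) -> np.ndarray:
        """(n_records, length) byte matrix view of the residues."""
        return np.frombuffer("".join(self.seqs).encode("ascii"), dtype="S1").reshape(
            self.n_records, self.length
        )


@dataclass(frozen=True)
class Partition:
    """Mapping of sequence id to species label (insertion-ordered)."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise DataError("partition is empty")

    @property
    def species(self) -> tuple[str, ...]:
        """Species labels in order of first appearance."""
        seen: dict[str, None] = {}
        for sp in self.assignments.values():
            seen.setdefault(sp, None)
        return tuple(seen)

    def members(self, species: str) -> tuple[str, ...]:
        ids = tuple(i for i, sp in self.assignments.items() if sp == species)
        if not ids:
            raise KeyError(f"unknown species {species!r}")
        return ids

    def species_of(self, seq_id: str) -> str:
        return self.assignments[seq_id]


@dataclass
class ValidationReport:
    """Findings from cross-checking an alignment against a partition."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _open(source: Source):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_alignment(source: Source, marker: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Residues are uppercased and ``U`` mapped to ``T``; record order is
    preserved.  Raises :class:`DataError` on an empty file, unequal
    lengths (unaligned input), duplicate ids, or non-IUPAC characters.
    """
    handle, close = _open(source)
    try:
        ids: list[str] = []
        seqs: list[str] = []
        for rec in SeqIO.parse(handle, "fasta"):
            ids.append(rec.id)
            try:
                seqs.append(normalize_residues(str(rec.seq)))
            except ValueError as exc:
                raise DataError(f"record {rec.id!r}: {exc}") from exc
    finally:
        if close:
            handle.close()
    if not ids:
        raise DataError("empty FASTA input")
    return Alignment(marker, tuple(ids), tuple(seqs))


def write_alignment(aln: Alignment, sink: Source) -> None:
    """Write an alignment as FASTA (60-column wrapped)."""
    handle, close = _open(sink) if not isinstance(sink, (str, Path)) else (open(sink, "w", encoding="utf-8"), True)
    try:
        for sid, seq in aln.records:
            handle.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")
    finally:
        if close:
            handle.close()


def read_partition(source: Source) -> Partition:
    """Read a tab-separated ``sequence_id<TAB>species[<TAB>marker]`` file.

    Blank lines and ``#``-prefixed comment lines are ignored; fields are
    whitespace-trimmed.  A sequence id listed twice with conflicting
    species labels is an error; an identical repeat is tolerated.
    """
    handle, close = _open(source)
    try:
        assignments: dict[str, str] = {}
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise DataError(f"line {lineno}: expected 'id<TAB>species[<TAB>marker]'")
            sid, species = parts[0], parts[1]
            if sid in assignments and assignments[sid] != species:
                raise DataError(
                    f"line {lineno}: {sid!r} assigned to both "
                    f"{assignments[sid]!r} and {species!r}"
                )
            assignments.setdefault(sid, species)
    finally:
        if close:
            handle.close()
    if not assignments:
        raise DataError("empty partition file")
    return Partition(assignments)


def write_partition(part: Partition, sink: Source) -> None:
    handle, close = _open(sink) if not isinstance(sink, (str, Path)) else (open(sink, "w", encoding="utf-8"), True)
    try:
        handle.write("#sequence_id\tspecies\n")
        for sid, sp in part.assignments.items():
            handle.write(f"{sid}\t{sp}\n")
    finally:
        if close:
            handle.close()


def validate(aln: Alignment, part: Partition, *, strict: bool = False) -> ValidationReport:
    """Cross-check an alignment against a partition without mutating either.

    Alignment ids absent from the partition are warnings by default
    (callers drop them) or errors under ``strict``.  Additional warnings:
    all-gap columns, and species represented by a single sequence (their
    within-group distance is undefined).
    """
    report = ValidationReport()
    missing = [i for i in aln.ids if i not in part.assignments]
    for sid in missing:
        finding = ("unassigned_sequence", "alignment id absent from partition", sid)
        (report.errors if strict else report.warnings).append(finding)

    arr = aln.to_array()
    gap_cols = np.flatnonzero((arr == b"-").all(axis=0))
    for j in gap_cols:
        report.warnings.append(("all_gap_column", "column consists only of gaps", str(j + 1)))

    present = [i for i in aln.ids if i in part.assignments]
    counts: dict[str, int] = {}
    for sid in present:
        counts[part.assignments[sid]] = counts.get(part.assignments[sid], 0) + 1
    for sp, n in counts.items():
        if n < 2:
            report.warnings.append(
                ("singleton_species", "within-group distance undefined (n<2)", sp)
            )
    return report


def restrict_to_partition(aln: Alignment, part: Partition) -> Alignment:
    """Drop alignment records whose ids are not assigned to any species."""
    keep = [i for i in aln.ids if i in part.assignments]
    if not keep:
        raise DataError("no alignment record is assigned in the partition")
    if len(keep) == aln.n_records:
        return aln
    return aln.subset(keep)


def alignment_from_string(text: str, marker: str) -> Alignment:
    """Convenience: parse FASTA text already in memory."""
    return read_alignment(_io.StringIO(text), marker)
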