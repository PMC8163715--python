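"""Single and combined diagnostic nucleotide characters.

A *single* diagnostic character for a species (the query group) is an
alignment column where every query sequence carries the same unambiguous
base and no sequence of the reference group (all remaining species by
default) can carry that base.  A *combined* character is a duo of
adjacent columns whose query dinucleotide occurs in no reference
sequence while neither member column is diagnostic on its own — the
character-based view of DNA barcoding used to diagnose cryptic species
that lack morphological characters.

Two ambiguity policies are provided.  Under ``conservative`` (default) a
reference IUPAC ambiguity code blocks a diagnosis whenever its expansion
contains the query state, so no reported character can be falsified by
resolving an ambiguity; under ``strict`` every code is compared literally
as its own symbol.  In both policies a query column containing any gap
or ambiguity code is ineligible and reported states are plain A/C/G/T;
a reference gap is a distinct symbol that never equals a base.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .io import Alignment, DataError, Partition, restrict_to_partition
from .iupac import BASES, expand, normalize_residues

POLICIES = ("conservative", "strict")


@dataclass(frozen=True, order=True)
class DiagnosticCharacter:
    """One or two adjacent 1-based alignment positions with fixed states."""

    positions: tuple[int, ...]
    states: str
    species: str
    marker: str

    def __post_init__(self) -> None:
        if len(self.positions) not in (1, 2):
            raise ValueError("a character spans one or two positions")
        if len(self.positions) == 2 and self.positions[1] != self.positions[0] + 1:
            raise ValueError("combined characters use adjacent positions only")
        if len(self.states) != len(self.positions):
            raise ValueError("one state per position required")
        if any(s not in BASES for s in self.states):
            raise ValueError("diagnostic states must be unambiguous bases")

    @property
    def kind(self) -> str:
        return "single" if len(self.positions) == 1 else "combined"


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the diagnostic search.

    ``k_window`` is the maximum span of a combined character; only the
    adjacent-duo window (2) is supported.  ``reference_scope`` limits the
    reference group to a subset of species (None = every other species
    in the dataset), exposing the reference-size trade-off: a larger
    reference makes characters rarer but more reliable.
    """

    k_window: int = 2
    ambiguity_policy: str = "conservative"
    reference_scope: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.k_window != 2:
            raise ValueError("only the adjacent-duo window (k_window=2) is supported")
        if self.ambiguity_policy not in POLICIES:
            raise ValueError(f"ambiguity_policy must be one of {POLICIES}")


class ColumnProfile(NamedTuple):
    """Per-column summary of a group of sequences."""

    query_state: str | None
    possible_states: frozenset[str]


@dataclass(frozen=True)
class MarkerDiagnosis:
    """Characters found for one species in one marker."""

    characters: tuple[DiagnosticCharacter, ...]
    n_sequences: int

    @property
    def singles(self) -> tuple[DiagnosticCharacter, ...]:
        return tuple(c for c in self.characters if c.kind == "single")

    @property
    def combined(self) -> tuple[DiagnosticCharacter, ...]:
        return tuple(c for c in self.characters if c.kind == "combined")


@dataclass(frozen=True)
class DiagnosisSet:
    """Diagnoses for every species over every supplied marker."""

    entries: dict[tuple[str, str], MarkerDiagnosis]
    marker_columns: dict[str, int]

    @property
    def species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for sp, _ in self.entries:
            seen.setdefault(sp, None)
        return tuple(seen)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.marker_columns)

    def for_species(self, species: str) -> dict[str, MarkerDiagnosis]:
        out = {m: d for (sp, m), d in self.entries.items() if sp == species}
        if not out:
            raise KeyError(f"unknown species {species!r}")
        return out

    def to_json(self) -> str:
        payload = {
            "marker_columns": self.marker_columns,
            "species": {},
        }
        for (sp, marker), entry in self.entries.items():
            block = payload["species"].setdefault(sp, {})
            block[marker] = {
                "n_sequences": entry.n_sequences,
                "characters": [
                    {"kind": c.kind, "positions": list(c.positions), "states": c.states}
                    for c in entry.characters
                ],
            }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DiagnosisSet":
        payload = json.loads(text)
        entries: dict[tuple[str, str], MarkerDiagnosis] = {}
        for sp, block in payload["species"].items():
            for marker, rec in block.items():
                chars = tuple(
                    DiagnosticCharacter(tuple(c["positions"]), c["states"], sp, marker)
                    for c in rec["characters"]
                )
                entries[(sp, marker)] = MarkerDiagnosis(chars, rec["n_sequences"])
        return cls(entries, {m: int(n) for m, n in payload["marker_columns"].items()})


@dataclass(frozen=True)
class ClassificationResult:
    """Per-species diagnostic match fractions for an unknown sequence."""

    scores: dict[str, float]
    verdict: str  # unique | ambiguous | no_call
    best: str | None


def _possible_states(symbols: Iterable[str], policy: str) -> frozenset[str]:
    if policy == "conservative":
        out: set[str] = set()
        for s in symbols:
            out |= expand(s)
        return frozenset(out)
    return frozenset(symbols)


def column_profile(
    aln: Alignment,
    position: int,
    group: Sequence[str],
    policy: str = "conservative",
) -> ColumnProfile:
    """Summarise one 1-based column over a group of sequence ids.

    ``query_state`` is the shared base if all group members carry the
    same unambiguous A/C/G/T, else None.  ``possible_states`` is the set
    of states the group may realise at the column: under the
    conservative policy the union of IUPAC expansions of observed codes
    (gap contributing the distinct symbol ``-``), under strict the
    literal symbols observed.
    """
    col = aln.column(position)
    index = {sid: i for i, sid in enumerate(aln.ids)}
    symbols = [col[index[sid]] for sid in group]
    uniq = set(symbols)
    state = symbols[0] if len(uniq) == 1 and symbols[0] in BASES else None
    return ColumnProfile(state, _possible_states(symbols, policy))


def _groups(
    aln: Alignment, part: Partition, species: str, config: AnalysisConfig
) -> tuple[list[int], list[int]]:
    """Row indices of the query and reference groups."""
    if species not in part.species:
        raise DataError(f"species {species!r} absent from partition")
    scope = config.reference_scope
    if scope is not None and species in scope:
        scope = tuple(sp for sp in scope if sp != species)
    query, reference = [], []
    for i, sid in enumerate(aln.ids):
        sp = part.assignments.get(sid)
        if sp is None:
            continue
        if sp == species:
            query.append(i)
        elif scope is None or sp in scope:
            reference.append(i)
    if not query:
        raise DataError(f"no sequences of {species!r} in the {aln.marker} alignment")
    return query, reference


def _query_states(columns: list[str], rows: list[int]) -> list[str | None]:
    """Uniform unambiguous query base per column (None where ineligible)."""
    out: list[str | None] = []
    for col in columns:
        symbols = {col[i] for i in rows}
        first = next(iter(symbols))
        out.append(first if len(symbols) == 1 and first in BASES else None)
    return out


def _single_positions(
    columns: list[str],
    query_rows: list[int],
    ref_rows: list[int],
    policy: str,
) -> tuple[list[str | None], set[int]]:
    qstates = _query_states(columns, query_rows)
    singles: set[int] = set()
    for j, s in enumerate(qstates):
        if s is None:
            continue
        ref = _possible_states((columns[j][i] for i in ref_rows), policy)
        if s not in ref:
            singles.add(j)
    return qstates, singles


def find_single_diagnostics(
    aln: Alignment,
    part: Partition,
    species: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[DiagnosticCharacter]:
    """Columns where the species is uniform for a base no reference can carry.

    Returned ascending by position.
    """
    query, reference = _groups(aln, part, species, config)
    columns = [aln.column(p) for p in range(1, aln.length + 1)]
    qstates, singles = _single_positions(columns, query, reference, config.ambiguity_policy)
    return [
        DiagnosticCharacter((j + 1,), qstates[j], species, aln.marker)
        for j in sorted(singles)
    ]


def find_combined_diagnostics(
    aln: Alignment,
    part: Partition,
    species: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[DiagnosticCharacter]:
    """Adjacent duos diagnostic as a pair but not through either member.

    A duo (i, i+1) qualifies when the query is uniform and unambiguous at
    both columns, no reference sequence can realise the query
    dinucleotide (under the conservative policy a reference row whose
    expansions jointly admit it disqualifies the duo), and neither
    member column is single-diagnostic.  Sorted ascending by first
    position.
    """
    policy = config.ambiguity_policy
    query, reference = _groups(aln, part, species, config)
    columns = [aln.column(p) for p in range(1, aln.length + 1)]
    qstates, singles = _single_positions(columns, query, reference, policy)
    out = []
    for j in range(aln.length - 1):
        if j in singles or (j + 1) in singles:
            continue
        s1, s2 = qstates[j], qstates[j + 1]
        if s1 is None or s2 is None:
            continue
        blocked = False
        for i in reference:
            a, b = columns[j][i], columns[j + 1][i]
            if policy == "conservative":
                if s1 in expand(a) and s2 in expand(b):
                    blocked = True
                    break
            elif a == s1 and b == s2:
                blocked = True
                break
        if not blocked:
            out.append(DiagnosticCharacter((j + 1, j + 2), s1 + s2, species, aln.marker))
    return out


def diagnose(
    alignments: dict[str, Alignment],
    part: Partition,
    config: AnalysisConfig = AnalysisConfig(),
) -> DiagnosisSet:
    """Full diagnosis: singles then combined duos per species and marker.

    Alignment records not assigned in the partition are dropped with a
    warning.  A species absent from a marker yields an empty entry with
    ``n_sequences = 0``.  Raises :class:`DataError` when fewer than two
    species are present overall (no reference group exists).
    """
    usable: dict[str, Alignment] = {}
    for marker, aln in alignments.items():
        dropped = [i for i in aln.ids if i not in part.assignments]
        if dropped:
            warnings.warn(
                f"{marker}: dropping {len(dropped)} unassigned sequence(s)",
                stacklevel=2,
            )
        usable[marker] = restrict_to_partition(aln, part)

    present_species: dict[str, None] = {}
    for aln in usable.values():
        for sid in aln.ids:
            present_species.setdefault(part.assignments[sid], None)
    if len(present_species) < 2:
        raise DataError("need at least two species to form a reference group")

    entries: dict[tuple[str, str], MarkerDiagnosis] = {}
    for species in part.species:
        if species not in present_species:
            continue
        for marker, aln in usable.items():
            n = sum(1 for sid in aln.ids if part.assignments[sid] == species)
            if n == 0:
                entries[(species, marker)] = MarkerDiagnosis((), 0)
                continue
            singles = find_single_diagnostics(aln, part, species, config)
            combined = find_combined_diagnostics(aln, part, species, config)
            entries[(species, marker)] = MarkerDiagnosis(tuple(singles + combined), n)
    return DiagnosisSet(entries, {m: a.length for m, a in usable.items()})


def classify_sequence(
    seq: str,
    diag: DiagnosisSet,
    marker: str,
    policy: str = "conservative",
) -> ClassificationResult:
    """Score an aligned unknown sequence against every species' diagnosis.

    For each species with at least one diagnostic in the marker, the
    score is the fraction of its characters matched by the sequence.  An
    ambiguity code in the sequence counts as a possible match under the
    conservative policy and as a mismatch under strict; a gap never
    matches.  Verdict is ``unique`` iff exactly one species scores 1.0.
    """
    if marker not in diag.marker_columns:
        raise DataError(f"no diagnosis recorded for marker {marker!r}")
    expected = diag.marker_columns[marker]
    residues = normalize_residues(seq)
    if len(residues) != expected:
        raise DataError(
            f"query length {len(residues)} != alignment length {expected}; "
            "the query must be pre-aligned to the reference coordinates"
        )

    def matches(char: DiagnosticCharacter) -> bool:
        for pos, state in zip(char.positions, char.states):
            symbol = residues[pos - 1]
            if policy == "conservative":
                if state not in expand(symbol):
                    return False
            elif symbol != state:
                return False
        return True

    scores: dict[str, float] = {}
    for species in diag.species:
        entry = diag.entries.get((species, marker))
        if entry is None or not entry.characters:
            warnings.warn(
                f"{species}: no {marker} diagnostics; excluded from classification",
                stacklevel=2,
            )
            continue
        hit = sum(1 for c in entry.characters if matches(c))
        scores[species] = hit / len(entry.characters)

    full = [sp for sp, f in scores.items() if f == 1.0]
    if len(full) == 1:
        return ClassificationResult(scores, "unique", full[0])
    if len(full) > 1:
        return ClassificationResult(scores, "ambiguous", None)
    return ClassificationResult(scores, "no_call", None)
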