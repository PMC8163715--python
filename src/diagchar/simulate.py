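"""Seeded synthetic alignments with planted diagnostic characters.

The generator emulates the structure of a multi-species barcode
alignment (a COI- or 28S-like marker): K species of unequal sample
sizes, small within-species and large between-species divergence,
occasional gaps and ambiguity codes, and — crucially for testing —
*planted* single and combined diagnostic characters whose columns are
locked against all further mutation and noise, so a correct finder must
recover them with recall 1.

Evolution follows a star phylogeny: a uniform random root sequence, one
ancestor per species obtained by mutating each unlocked site with
probability ``between_rate``, and individuals obtained from their
ancestor with per-site probability ``within_rate``.  A substitution
always changes the base, uniformly over the three alternatives, which
gives simple closed forms for the expected p-distances
(:func:`expected_within`, :func:`expected_between`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .diagnostics import AnalysisConfig, DiagnosticCharacter, column_profile
from .io import Alignment, Partition
from .iupac import BASES

_AMBIG_INJECT = "NRYSWKM"


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    n_species: int
    seqs_per_species: tuple[int, ...]
    length: int
    within_rate: float = 0.002
    between_rate: float = 0.11
    n_planted_single: int = 2
    n_planted_combined: int = 1
    gap_fraction: float = 0.01
    ambiguity_fraction: float = 0.002
    seed: int = 0
    marker: str = "COI"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seqs_per_species", tuple(self.seqs_per_species))
        if self.n_species < 1 or len(self.seqs_per_species) != self.n_species:
            raise ValueError("seqs_per_species must list one count per species")
        if any(n < 1 for n in self.seqs_per_species):
            raise ValueError("each species needs at least one sequence")
        for name in ("within_rate", "between_rate", "gap_fraction", "ambiguity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        demand = self.n_species * (self.n_planted_single + 2 * self.n_planted_combined)
        if demand > self.length:
            raise ValueError(f"planted columns ({demand}) exceed alignment length")

    @property
    def species_labels(self) -> tuple[str, ...]:
        return tuple(f"sp{k + 1:02d}" for k in range(self.n_species))


def default_spec(seed: int = 0) -> SimulationSpec:
    """Conditions emulating a real multi-species COI barcode dataset:
    13 species of 2-45 sequences, ~658 columns, within-species mean
    p-distance near 0.004 and between-species means near 0.2."""
    return SimulationSpec(
        n_species=13,
        seqs_per_species=(10, 8, 13, 10, 2, 45, 36, 2, 9, 3, 17, 2, 5),
        length=658,
        seed=seed,
    )


@dataclass(frozen=True)
class PlantedTruth:
    """Generator's record of what was planted, for recall checks."""

    planted: dict[str, tuple[DiagnosticCharacter, ...]]
    locked_columns: frozenset[int]  # 1-based
    spec: SimulationSpec = field(repr=False)

    def all_characters(self) -> tuple[DiagnosticCharacter, ...]:
        return tuple(c for chars in self.planted.values() for c in chars)

    def to_json(self) -> str:
        payload = {
            "locked_columns": sorted(self.locked_columns),
            "planted": {
                sp: [
                    {"kind": c.kind, "positions": list(c.positions), "states": c.states}
                    for c in chars
                ]
                for sp, chars in self.planted.items()
            },
            "parameters": {
                "n_species": self.spec.n_species,
                "seqs_per_species": list(self.spec.seqs_per_species),
                "length": self.spec.length,
                "within_rate": self.spec.within_rate,
                "between_rate": self.spec.between_rate,
                "gap_fraction": self.spec.gap_fraction,
                "ambiguity_fraction": self.spec.ambiguity_fraction,
                "seed": self.spec.seed,
                "marker": self.spec.marker,
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def expected_within(eps: float) -> float:
    """Expected p-distance between two individuals of one species.

    Each tip mutates a site with probability eps to one of the three
    other bases: P(differ) = 2*eps*(1-eps) + (2/3)*eps**2.
    """
    return 2.0 * eps * (1.0 - eps) + (2.0 / 3.0) * eps * eps


def expected_between(eps: float, delta: float) -> float:
    """Expected p-distance between individuals of two species.

    The tip-to-tip path root->ancestor->individual on both sides has per
    -edge substitution matrices M(p) = (1-4p/3)I + (p/3)J; composing the
    four edges (eps, delta, delta, eps) gives
    P(differ) = (3/4) * (1 - (1-4eps/3)^2 * (1-4delta/3)^2),
    the within formula being the delta=0 special case.
    """
    a = (1.0 - 4.0 * eps / 3.0) ** 2 * (1.0 - 4.0 * delta / 3.0) ** 2
    return 0.75 * (1.0 - a)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float, unlocked: np.ndarray) -> np.ndarray:
    """Per-site substitution (always to a different base) at unlocked sites."""
    out = seq.copy()
    hit = np.flatnonzero(unlocked & (rng.random(seq.size) < rate))
    if hit.size:
        # shift by 1..3 in base space guarantees a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _allocate_planted(
    rng: np.random.Generator, spec: SimulationSpec
) -> tuple[dict[int, list[int]], dict[int, list[int]]]:
    """Randomly place non-overlapping planted columns (0-based starts)."""
    free = np.ones(spec.length, dtype=bool)
    singles: dict[int, list[int]] = {k: [] for k in range(spec.n_species)}
    duos: dict[int, list[int]] = {k: [] for k in range(spec.n_species)}
    # duos first: they need two adjacent free columns
    for k in range(spec.n_species):
        for _ in range(spec.n_planted_combined):
            starts = rng.permutation(spec.length - 1)
            for c in starts:
                if free[c] and free[c + 1]:
                    duos[k].append(int(c))
                    free[c] = free[c + 1] = False
                    break
            else:
                raise ValueError("infeasible plant: no adjacent free column pair left")
    for k in range(spec.n_species):
        for _ in range(spec.n_planted_single):
            cols = np.flatnonzero(free)
            if cols.size == 0:
                raise ValueError("infeasible plant: no free column left")
            c = int(rng.choice(cols))
            singles[k].append(c)
            free[c] = False
    return singles, duos


def generate_dataset(spec: SimulationSpec) -> tuple[Alignment, Partition, PlantedTruth]:
    """Generate one seeded dataset with its partition and planted truth."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_planted_combined > 0 and spec.n_species < 3:
        raise ValueError(
            "planting a combined duo needs at least two reference species"
        )

    singles_at, duos_at = _allocate_planted(rng, spec)
    locked = np.zeros(spec.length, dtype=bool)
    for cols in singles_at.values():
        locked[cols] = True
    for starts in duos_at.values():
        for c in starts:
            locked[c] = locked[c + 1] = True
    unlocked = ~locked

    root = rng.integers(0, 4, size=spec.length)
    ancestors = [
        _mutate(rng, root, spec.between_rate, unlocked) for _ in range(spec.n_species)
    ]

    def other_base(b: int) -> int:
        return int((b + rng.integers(1, 4)) % 4)

    planted: dict[str, list[DiagnosticCharacter]] = {
        sp: [] for sp in spec.species_labels
    }
    # planted singles: query species fixed to s, every other ancestor forced off s
    for k, cols in singles_at.items():
        sp = spec.species_labels[k]
        for c in cols:
            s = int(rng.integers(0, 4))
            ancestors[k][c] = s
            for j in range(spec.n_species):
                if j != k and ancestors[j][c] == s:
                    ancestors[j][c] = other_base(s)
            planted[sp].append(
                DiagnosticCharacter((c + 1,), BASES[s], sp, spec.marker)
            )
    # planted duos: each member base occurs in the reference (blocking single
    # status) but the query dinucleotide occurs in no reference row
    for k, starts in duos_at.items():
        sp = spec.species_labels[k]
        others = [j for j in range(spec.n_species) if j != k]
        for c in starts:
            s1, s2 = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            ancestors[k][c], ancestors[k][c + 1] = s1, s2
            ancestors[others[0]][c] = s1
            ancestors[others[0]][c + 1] = other_base(s2)
            ancestors[others[1]][c] = other_base(s1)
            ancestors[others[1]][c + 1] = s2
            for j in others[2:]:
                if ancestors[j][c] == s1 and ancestors[j][c + 1] == s2:
                    ancestors[j][c + 1] = other_base(s2)
            planted[sp].append(
                DiagnosticCharacter((c + 1, c + 2), BASES[s1] + BASES[s2], sp, spec.marker)
            )

    ids: list[str] = []
    seq_rows: list[str] = []
    assignments: dict[str, str] = {}
    lut = np.array(list(BASES))
    for k, sp in enumerate(spec.species_labels):
        for m in range(spec.seqs_per_species[k]):
            row = _mutate(rng, ancestors[k], spec.within_rate, unlocked)
            chars = lut[row].copy()
            if spec.gap_fraction > 0.0:
                gaps = unlocked & (rng.random(spec.length) < spec.gap_fraction)
                chars[gaps] = "-"
            if spec.ambiguity_fraction > 0.0:
                ambig = (
                    unlocked
                    & (chars != "-")
                    & (rng.random(spec.length) < spec.ambiguity_fraction)
                )
                idx = np.flatnonzero(ambig)
                if idx.size:
                    codes = rng.choice(list(_AMBIG_INJECT), size=idx.size)
                    chars[idx] = codes
            sid = f"{sp}_{m + 1:03d}"
            ids.append(sid)
            seq_rows.append("".join(chars))
            assignments[sid] = sp

    aln = Alignment(spec.marker, tuple(ids), tuple(seq_rows))
    part = Partition(assignments)
    truth = PlantedTruth(
        {sp: tuple(chars) for sp, chars in planted.items()},
        frozenset(int(c) + 1 for c in np.flatnonzero(locked)),
        spec,
    )
    _verify_planted(aln, part, truth)
    return aln, part, truth


def _verify_planted(aln: Alignment, part: Partition, truth: PlantedTruth) -> None:
    """Post-generation audit: every planted character satisfies the
    diagnostic definition when re-checked from the emitted alignment."""
    for sp, chars in truth.planted.items():
        query = part.members(sp)
        reference = [i for i in aln.ids if part.assignments[i] != sp]
        for char in chars:
            for pos, state in zip(char.positions, char.states):
                prof = column_profile(aln, pos, query)
                if prof.query_state != state:
                    raise AssertionError(
                        f"planted {sp} column {pos}: query not uniform {state}"
                    )
            if char.kind == "single":
                ref = column_profile(aln, char.positions[0], reference)
                if char.states in ref.possible_states:
                    raise AssertionError(
                        f"planted single {sp}@{char.positions[0]} present in reference"
                    )
            else:
                p1, p2 = char.positions
                col1, col2 = aln.column(p1), aln.column(p2)
                index = {sid: i for i, sid in enumerate(aln.ids)}
                rows = [index[sid] for sid in reference]
                if any(
                    col1[i] == char.states[0] and col2[i] == char.states[1]
                    for i in rows
                ):
                    raise AssertionError(
                        f"planted duo {sp}@{char.positions} realised by reference"
                    )
                if not any(col1[i] == char.states[0] for i in rows) or not any(
                    col2[i] == char.states[1] for i in rows
                ):
                    raise AssertionError(
                        f"planted duo {sp}@{char.positions}: member column "
                        "accidentally single-diagnostic"
                    )


__all__ = [
    "SimulationSpec",
    "PlantedTruth",
    "default_spec",
    "generate_dataset",
    "expected_within",
    "expected_between",
]
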