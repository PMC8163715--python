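"""Uncorrected p-distances and species-level distance summaries.

The p-distance between two aligned sequences is the proportion of
differing sites among the sites compared.  Under pairwise deletion
(default, the common default for uncorrected distances) a site is
compared only when both sequences carry an unambiguous base; gaps and
ambiguity codes are excluded per pair.  Complete deletion drops a column
for every pair whenever any sequence in the alignment is not an
unambiguous base there.

Species-level summaries average the pairwise values over all sequence
pairs within a group (within) or across two groups (between); pairs with
no comparable site are excluded from the mean with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Alignment, DataError, Partition

DELETION_MODES = ("pairwise", "complete")
_VALID = frozenset(b"ACGT")


@dataclass(frozen=True)
class PairwiseDistance:
    """Uncorrected distance between two sequences.

    ``value`` is None (undefined) when no site could be compared.
    """

    value: float | None
    compared_sites: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    mask = np.zeros(arr.shape, dtype=bool)
    for b in (b"A", b"C", b"G", b"T"):
        mask |= arr == b
    return mask


def p_distance(seq_a: str, seq_b: str) -> PairwiseDistance:
    """Proportion of differing sites under pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise DataError("sequences differ in length")
    a, b = _encode(seq_a.upper()), _encode(seq_b.upper())
    both = _valid_mask(a) & _valid_mask(b)
    n = int(both.sum())
    if n == 0:
        warnings.warn("no comparable sites; distance undefined", stacklevel=2)
        return PairwiseDistance(None, 0)
    diffs = int(((a != b) & both).sum())
    return PairwiseDistance(diffs / n, n)


@dataclass(frozen=True)
class DistanceMatrix:
    """Mean p-distances between and within species.

    ``values`` is symmetric with the within-group mean on the diagonal;
    undefined cells are NaN.  Row order is first-appearance order of the
    species in the partition.
    """

    species: tuple[str, ...]
    values: np.ndarray
    n_pairs: np.ndarray

    def _index(self, species: str) -> int:
        try:
            return self.species.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None

    def within(self, species: str) -> float | None:
        v = self.values[self._index(species), self._index(species)]
        return None if math.isnan(v) else float(v)

    def between(self, sp_a: str, sp_b: str) -> float | None:
        if sp_a == sp_b:
            raise DataError("between-distance requires two distinct species")
        v = self.values[self._index(sp_a), self._index(sp_b)]
        return None if math.isnan(v) else float(v)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)


class _PairTable:
    """All pairwise distances for one alignment, computed once."""

    def __init__(self, aln: Alignment, deletion: str):
        if deletion not in DELETION_MODES:
            raise ValueError(f"deletion must be one of {DELETION_MODES}")
        arr = aln.to_array()
        valid = _valid_mask(arr)
        if deletion == "complete":
            keep = valid.all(axis=0)
            arr, valid = arr[:, keep], valid[:, keep]
        n = arr.shape[0]
        self.ids = aln.ids
        self.value = np.full((n, n), np.nan)
        self.defined = np.zeros((n, n), dtype=bool)
        for i in range(n):
            self.value[i, i], self.defined[i, i] = 0.0, True
            both = valid[i] & valid[i + 1 :]
            sites = both.sum(axis=1)
            diffs = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(sites > 0, diffs / np.maximum(sites, 1), np.nan)
            self.value[i, i + 1 :] = self.value[i + 1 :, i] = vals
            self.defined[i, i + 1 :] = self.defined[i + 1 :, i] = sites > 0


def _mean_over(table: _PairTable, rows_a: list[int], rows_b: list[int] | None) -> tuple[float | None, int]:
    """Mean distance over within-group (rows_b None) or cross-group pairs."""
    vals: list[float] = []
    skipped = 0
    if rows_b is None:
        pairs = [(i, j) for k, i in enumerate(rows_a) for j in rows_a[k + 1 :]]
    else:
        pairs = [(i, j) for i in rows_a for j in rows_b]
    for i, j in pairs:
        if table.defined[i, j]:
            vals.append(table.value[i, j])
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} pair(s) had no comparable sites; excluded", stacklevel=3)
    if not vals:
        return None, 0
    return float(np.mean(vals)), len(vals)


def _species_rows(aln: Alignment, part: Partition) -> dict[str, list[int]]:
    rows: dict[str, list[int]] = {}
    for i, sid in enumerate(aln.ids):
        sp = part.assignments.get(sid)
        if sp is not None:
            rows.setdefault(sp, []).append(i)
    if not rows:
        raise DataError("no alignment record is assigned in the partition")
    return rows


def group_mean_within(
    aln: Alignment, part: Partition, species: str, *, deletion: str = "pairwise"
) -> float | None:
    """Mean p-distance over all within-species pairs (None when n < 2)."""
    rows = _species_rows(aln, part)
    if species not in rows:
        if species in part.species:
            return None
        raise DataError(f"unknown species {species!r}")
    if len(rows[species]) < 2:
        return None
    return _mean_over(_PairTable(aln, deletion), rows[species], None)[0]


def group_mean_between(
    aln: Alignment, part: Partition, sp_a: str, sp_b: str, *, deletion: str = "pairwise"
) -> float | None:
    """Mean p-distance over all cross pairs; symmetric in its arguments."""
    if sp_a == sp_b:
        raise DataError("between-distance requires two distinct species")
    rows = _species_rows(aln, part)
    for sp in (sp_a, sp_b):
        if sp not in rows and sp not in part.species:
            raise DataError(f"unknown species {sp!r}")
    if sp_a not in rows or sp_b not in rows:
        return None
    return _mean_over(_PairTable(aln, deletion), rows[sp_a], rows[sp_b])[0]


def distance_matrix(
    aln: Alignment, part: Partition, *, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Species x species mean-distance matrix, within means on the diagonal."""
    rows = _species_rows(aln, part)
    species = tuple(sp for sp in part.species if sp in rows)
    table = _PairTable(aln, deletion)
    k = len(species)
    values = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    for a, sp_a in enumerate(species):
        if len(rows[sp_a]) >= 2:
            m, n = _mean_over(table, rows[sp_a], None)
            if m is not None:
                values[a, a], n_pairs[a, a] = m, n
        for b in range(a + 1, k):
            m, n = _mean_over(table, rows[sp_a], rows[species[b]])
            if m is not None:
                values[a, b] = values[b, a] = m
                n_pairs[a, b] = n_pairs[b, a] = n
    return DistanceMatrix(species, values, n_pairs)


def nearest_neighbor(matrix: DistanceMatrix, species: str) -> tuple[str, float]:
    """Other species at minimal mean between-distance (ties by label order)."""
    i = matrix._index(species)
    best: tuple[str, float] | None = None
    for j, other in enumerate(matrix.species):
        if j == i or math.isnan(matrix.values[i, j]):
            continue
        v = float(matrix.values[i, j])
        if best is None or v < best[1]:  # ties: first species in matrix order wins
            best = (other, v)
    if best is None:
        raise DataError(f"no defined neighbour for {species!r}")
    return best


def percent_floor(value: float) -> int:
    """Truncated integer percent, the convention of prose divergence summaries
    (0.0889 -> 8, 0.1069 -> 10)."""
    return math.floor(100.0 * value)
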