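"""IUPAC nucleotide alphabet shared by all modules.

One canonical alphabet: uppercase IUPAC codes plus ``-`` as the only gap
symbol.  ``U`` is normalised to ``T`` on ingestion and ``.`` is rejected,
so downstream set logic never has to consider synonyms.
"""

from __future__ import annotations

BASES = "ACGT"

#: Expansion of every accepted symbol into the set of bases it may stand
#: for.  The gap is its own distinct symbol: it never equals a base.
EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset("-"),
}

ALPHABET = frozenset(EXPANSION)

#: Pure ambiguity codes (neither a base nor the gap).
AMBIGUITY_CODES = "RYSWKMBDHVN"


def normalize_residues(raw: str) -> str:
    """Uppercase a residue string and map RNA ``U`` to ``T``.

    Raises ``ValueError`` on any symbol outside the canonical alphabet
    (``.`` in particular is rejected; only ``-`` denotes a gap).
    """
    s = raw.upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(
            f"non-IUPAC residue code(s) {sorted(bad)!r}; "
            "accepted: A C G T ambiguity codes and '-'"
        )
    return s


def expand(symbol: str) -> frozenset[str]:
    """Set of bases a symbol may represent (``-`` expands to itself)."""
    try:
        return EXPANSION[symbol]
    except KeyError:
        raise ValueError(f"unknown residue code {symbol!r}") from None
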