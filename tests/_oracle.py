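"""Naive brute-force oracles, independent of the package internals.

These re-derive every definition directly, column by column and pair by
pair, with their own IUPAC table, so that agreement with the package is
a genuine dual-route check.
"""

from itertools import combinations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "-": "-",
}


def _rows(aln, part, species):
    query = [s for i, s in zip(aln.ids, aln.seqs)
             if part.assignments.get(i) == species]
    reference = [s for i, s in zip(aln.ids, aln.seqs)
                 if i in part.assignments and part.assignments[i] != species]
    return query, reference


def _uniform_base(column_symbols):
    first = column_symbols[0]
    if first in "ACGT" and all(s == first for s in column_symbols):
        return first
    return None


def oracle_singles(aln, part, species, policy="conservative"):
    """All (1-based position, state) single diagnostics, by definition."""
    query, reference = _rows(aln, part, species)
    out = []
    for j in range(aln.length):
        s = _uniform_base([q[j] for q in query])
        if s is None:
            continue
        if policy == "conservative":
            possible = set().union(*(IUPAC[r[j]] for r in reference)) if reference else set()
        else:
            possible = {r[j] for r in reference}
        if s not in possible:
            out.append((j + 1, s))
    return out


def oracle_duos(aln, part, species, policy="conservative"):
    """All ((i, i+1), dinucleotide) combined diagnostics, by definition."""
    single_pos = {p for p, _ in oracle_singles(aln, part, species, policy)}
    query, reference = _rows(aln, part, species)
    out = []
    for j in range(aln.length - 1):
        if (j + 1) in single_pos or (j + 2) in single_pos:
            continue
        s1 = _uniform_base([q[j] for q in query])
        s2 = _uniform_base([q[j + 1] for q in query])
        if s1 is None or s2 is None:
            continue
        realized = False
        for r in reference:
            if policy == "conservative":
                if s1 in IUPAC[r[j]] and s2 in IUPAC[r[j + 1]]:
                    realized = True
                    break
            elif r[j] == s1 and r[j + 1] == s2:
                realized = True
                break
        if not realized:
            out.append(((j + 1, j + 2), s1 + s2))
    return out


def oracle_p_distance(a, b):
    """(value or None, compared sites) by direct per-site inspection."""
    compared = diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            compared += 1
            if x != y:
                diffs += 1
    return (diffs / compared if compared else None), compared


def oracle_group_mean(aln, part, species_a, species_b=None):
    """Mean pairwise distance over within- or cross-group pairs."""
    ids_a = [i for i in aln.ids if part.assignments.get(i) == species_a]
    if species_b is None:
        pairs = list(combinations(ids_a, 2))
    else:
        ids_b = [i for i in aln.ids if part.assignments.get(i) == species_b]
        pairs = [(x, y) for x in ids_a for y in ids_b]
    vals = []
    for x, y in pairs:
        v, _ = oracle_p_distance(aln.sequence(x), aln.sequence(y))
        if v is not None:
            vals.append(v)
    return sum(vals) / len(vals) if vals else None
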