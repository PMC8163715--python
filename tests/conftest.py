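import numpy as np
import pytest

from diagchar import Alignment, Partition

SYMBOLS = "ACGT" + "RYN" + "-"


def make_alignment(rows, marker="COI"):
    """Build an Alignment from a dict of id -> residues."""
    return Alignment(marker, tuple(rows), tuple(rows.values()))


def make_partition(mapping):
    return Partition(dict(mapping))


def random_instance(rng, max_seqs=10, max_cols=50, noise=True):
    """A small random dataset with low per-column diversity so that some
    diagnostic characters actually occur."""
    n_species = int(rng.integers(2, 5))
    counts = rng.integers(1, 4, size=n_species)
    while counts.sum() > max_seqs:
        counts = rng.integers(1, 4, size=n_species)
    length = int(rng.integers(4, max_cols + 1))

    rows, assignments = {}, {}
    # per column: an ancestral base per species, biased towards sharing
    species_base = rng.integers(0, 4, size=(n_species, length))
    shared = rng.random(length) < 0.5
    species_base[:, shared] = species_base[0, shared]
    bases = np.array(list("ACGT"))
    for k in range(n_species):
        sp = f"S{k}"
        for m in range(counts[k]):
            seq = bases[species_base[k]].copy()
            flip = rng.random(length) < 0.1
            seq[flip] = bases[rng.integers(0, 4, size=int(flip.sum()))]
            if noise:
                junk = rng.random(length) < 0.05
                seq[junk] = rng.choice(list(SYMBOLS), size=int(junk.sum()))
            sid = f"{sp}_{m}"
            rows[sid] = "".join(seq)
            assignments[sid] = sp
    return make_alignment(rows), make_partition(assignments)


@pytest.fixture
def toy_two_species():
    """Two species, hand-built so S0 has one single and one combined
    diagnostic: column 1 (A vs C) single; columns 3-4 combined AG with
    each member base present in the reference."""
    aln = make_alignment(
        {
            "q1": "ATAGT",
            "q2": "ATAGT",
            "r1": "CTATT",
            "r2": "CTCGT",
        }
    )
    part = make_partition({"q1": "S0", "q2": "S0", "r1": "S1", "r2": "S1"})
    return aln, part
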