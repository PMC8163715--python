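"""Previously reported values for the Norwegian *Chaetozone* barcode study,
and machinery to recompute them from the original supplementary data.

The original study of cryptic *Chaetozone* diversity (North-East
Atlantic; COI + 28S D1-D2) printed a species-by-species table of mean
uncorrected COI p-distances (within means on the diagonal), quoted
floor-percent divergences in its per-species remarks, and listed
diagnostic nucleotide positions per species.  Those printed values are
stored here as reference data.  When the study's supplementary
alignments and specimen list are available locally (they are not
distributed with this package), :func:`check_reported_values` recomputes
every stored quantity with this package and reports the comparison.

Expected layout of the supplementary data, if obtained::

    data/supplementary/S2_COI.fasta      gapped COI alignment
    data/supplementary/S3_28S.fasta      gapped 28S D1-D2 alignment
    data/supplementary/S1_partition.tsv  sequence_id<TAB>species label

using the species labels of :data:`SPECIES` in the partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .diagnostics import AnalysisConfig, DiagnosisSet, diagnose
from .distances import distance_matrix, percent_floor
from .io import Alignment, Partition, read_alignment, read_partition

#: Species order of the printed distance table.
SPECIES = (
    "C. monteverdii",      # sp. 1
    "Chaetozone sp. 2",
    "C. barentsensis",     # sp. 3
    "Chaetozone sp. 4",
    "C. quinta",           # sp. 5
    "C. pseudosetosa",     # sp. 7
    "C. setosa",           # sp. 8
    "Chaetozone sp. 9",
    "C. cf. zetlandica",   # sp. 10
    "Chaetozone sp. 11",
    "C. chambersae",       # sp. 12
    "Chaetozone sp. 13",
    "Chaetozone sp. 14",
)

#: Printed mean COI p-distance matrix (within means on the diagonal).
REPORTED_COI_MATRIX = (
    (0.0019, 0.2372, 0.2470, 0.2677, 0.2532, 0.2572, 0.2452, 0.2400, 0.2350, 0.2268, 0.2194, 0.2343, 0.2557),
    (0.2372, 0.0048, 0.2627, 0.2674, 0.2840, 0.2718, 0.2625, 0.2667, 0.2669, 0.2466, 0.2447, 0.2444, 0.2737),
    (0.2470, 0.2627, 0.0000, 0.2356, 0.2364, 0.2490, 0.2328, 0.2559, 0.2508, 0.2459, 0.2389, 0.1587, 0.0953),
    (0.2677, 0.2674, 0.2356, 0.0015, 0.0950, 0.2705, 0.2594, 0.2472, 0.2405, 0.2457, 0.2410, 0.2496, 0.2353),
    (0.2532, 0.2840, 0.2364, 0.0950, 0.0000, 0.2553, 0.2620, 0.2458, 0.2314, 0.2568, 0.2585, 0.2508, 0.2379),
    (0.2572, 0.2718, 0.2490, 0.2705, 0.2553, 0.0110, 0.0889, 0.2090, 0.2079, 0.1737, 0.1889, 0.2299, 0.2556),
    (0.2452, 0.2625, 0.2328, 0.2594, 0.2620, 0.0889, 0.0040, 0.2045, 0.2041, 0.1701, 0.1949, 0.2214, 0.2369),
    (0.2400, 0.2667, 0.2559, 0.2472, 0.2458, 0.2090, 0.2045, 0.0033, 0.1069, 0.1931, 0.1988, 0.2486, 0.2553),
    (0.2350, 0.2669, 0.2508, 0.2405, 0.2314, 0.2079, 0.2041, 0.1069, 0.0014, 0.1994, 0.1994, 0.2492, 0.2581),
    (0.2268, 0.2466, 0.2459, 0.2457, 0.2568, 0.1737, 0.1701, 0.1931, 0.1994, 0.0061, 0.1088, 0.2219, 0.2594),
    (0.2194, 0.2447, 0.2389, 0.2410, 0.2585, 0.1889, 0.1949, 0.1988, 0.1994, 0.1088, 0.0053, 0.2225, 0.2463),
    (0.2343, 0.2444, 0.1587, 0.2496, 0.2508, 0.2299, 0.2214, 0.2486, 0.2492, 0.2219, 0.2225, 0.0008, 0.1694),
    (0.2557, 0.2737, 0.0953, 0.2353, 0.2379, 0.2556, 0.2369, 0.2553, 0.2581, 0.2594, 0.2463, 0.1694, 0.0102),
)

#: Floor-percent divergences quoted in the per-species remarks, as
#: (species A, species B, percent).
REPORTED_REMARK_PERCENTS = (
    ("C. setosa", "C. pseudosetosa", 8),
    ("C. quinta", "Chaetozone sp. 4", 9),
    ("C. barentsensis", "Chaetozone sp. 14", 9),
    ("C. chambersae", "Chaetozone sp. 11", 10),
    ("C. cf. zetlandica", "Chaetozone sp. 9", 10),
    ("Chaetozone sp. 2", "Chaetozone sp. 4", 26),
)

#: Printed diagnostic positions for the position-level checks, as
#: (species, marker, positions tuple, states).  The *C. monteverdii*
#: listing carries a typographic anomaly in the original text and is
#: excluded from position-level checks.
REPORTED_DIAGNOSES = (
    ("C. setosa", "COI", (220,), "G"),
    ("C. setosa", "28S", (545, 546), "AC"),
    ("C. chambersae", "28S", (89,), "C"),
    ("C. chambersae", "28S", (638,), "T"),
    ("C. pseudosetosa", "COI", (223,), "C"),
    ("C. pseudosetosa", "COI", (349, 350), "TT"),
    ("C. pseudosetosa", "COI", (471, 472), "CA"),
)


@dataclass(frozen=True)
class Comparison:
    """One recomputed-vs-reported check."""

    what: str
    reported: object
    computed: object

    @property
    def agrees(self) -> bool:
        if isinstance(self.reported, float):
            return (
                isinstance(self.computed, float)
                and round(self.computed, 4) == round(self.reported, 4)
            )
        return self.computed == self.reported


def remarks_floor_consistency() -> list[Comparison]:
    """Check the quoted remark percentages against the printed table via
    the package's floor-percent convention.  Needs no external data."""
    idx = {sp: i for i, sp in enumerate(SPECIES)}
    out = []
    for sp_a, sp_b, pct in REPORTED_REMARK_PERCENTS:
        cell = REPORTED_COI_MATRIX[idx[sp_a]][idx[sp_b]]
        out.append(
            Comparison(f"remark percent {sp_a} vs {sp_b}", pct, percent_floor(cell))
        )
    return out


def check_reported_values(
    coi: Alignment,
    part: Partition,
    s28: Alignment | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[Comparison]:
    """Recompute every stored reference value from the supplied data."""
    out: list[Comparison] = []
    matrix = distance_matrix(coi, part)
    idx = {sp: i for i, sp in enumerate(SPECIES)}
    for sp in SPECIES:
        if sp not in matrix.species:
            continue
        out.append(
            Comparison(
                f"within {sp}", REPORTED_COI_MATRIX[idx[sp]][idx[sp]], matrix.within(sp)
            )
        )
    for a, sp_a in enumerate(SPECIES):
        for sp_b in SPECIES[a + 1 :]:
            if sp_a in matrix.species and sp_b in matrix.species:
                out.append(
                    Comparison(
                        f"between {sp_a} vs {sp_b}",
                        REPORTED_COI_MATRIX[idx[sp_a]][idx[sp_b]],
                        matrix.between(sp_a, sp_b),
                    )
                )

    alignments = {"COI": coi}
    if s28 is not None:
        alignments["28S"] = s28
    diag = diagnose(alignments, part, config)
    for sp, marker, positions, states in REPORTED_DIAGNOSES:
        if marker not in alignments or (sp, marker) not in diag.entries:
            continue
        found = {
            (c.positions, c.states) for c in diag.entries[(sp, marker)].characters
        }
        out.append(
            Comparison(
                f"diagnostic {sp} {marker} {positions}:{states}",
                True,
                (tuple(positions), states) in found,
            )
        )
    return out


def supplementary_paths(root: str | Path = ".") -> dict[str, Path]:
    base = Path(root) / "data" / "supplementary"
    return {
        "coi": base / "S2_COI.fasta",
        "s28": base / "S3_28S.fasta",
        "partition": base / "S1_partition.tsv",
    }


def check_from_supplementary(root: str | Path = ".") -> list[Comparison]:
    """Run :func:`check_reported_values` on locally staged supplementary
    data; raises ``FileNotFoundError`` when the files are absent."""
    paths = supplementary_paths(root)
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(
            "supplementary data not staged locally: " + ", ".join(missing)
        )
    coi = read_alignment(paths["coi"], "COI")
    s28 = read_alignment(paths["s28"], "28S")
    part = read_partition(paths["partition"])
    return check_reported_values(coi, part, s28)
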