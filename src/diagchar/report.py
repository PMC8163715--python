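"""Rendering of diagnoses and distance tables, and the inverse parser.

The text renderer produces the style used in taxonomic "Molecular
diagnosis" blocks: per marker, ``MARKER: pos: S`` for single characters
and ``pos-pos: SS`` for adjacent duos, ``; ``-separated, marker blocks
joined by ``. ``, followed by a ``(based on n MARKER sequences ...)``
note.  Machine output uses the ASCII hyphen; ``unicode_dash=True``
restores the typographic en dash.  JSON is the canonical representation;
the text form is derived from it and is inverse-parseable.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pandas as pd

from .diagnostics import DiagnosisSet, DiagnosticCharacter, MarkerDiagnosis
from .distances import DistanceMatrix
from .io import Source, _open

EN_DASH = "–"


def _format_character(char: DiagnosticCharacter, dash: str) -> str:
    if char.kind == "single":
        return f"{char.positions[0]}: {char.states}"
    return f"{char.positions[0]}{dash}{char.positions[1]}: {char.states}"


def format_diagnosis_text(
    diag: DiagnosisSet, species: str, *, unicode_dash: bool = False
) -> str:
    """Render one species' diagnosis across all its markers."""
    dash = EN_DASH if unicode_dash else "-"
    per_marker = diag.for_species(species)
    blocks: list[str] = []
    counts: list[str] = []
    for marker, entry in per_marker.items():
        if entry.characters:
            body = "; ".join(_format_character(c, dash) for c in entry.characters)
        else:
            body = "none"
        blocks.append(f"{marker}: {body}")
        counts.append(f"{entry.n_sequences} {marker} sequences")
    return ". ".join(blocks) + f" (based on {' and '.join(counts)})"


_BASED_ON = re.compile(r"\s*\(based on (?P<counts>.+)\)\s*$")
_COUNT = re.compile(r"^(?P<n>\d+) (?P<marker>\S+) sequences?$")
_ITEM = re.compile(
    rf"^(?P<p>\d+)(?:[-{EN_DASH}](?P<q>\d+))?: (?P<states>[ACGT]+)$"
)


def parse_diagnosis_text(text: str, species: str) -> DiagnosisSet:
    """Inverse of :func:`format_diagnosis_text` for one species.

    Recovers characters and per-marker sequence counts.  The rendered
    text does not carry alignment lengths, so ``marker_columns`` is 0
    for every marker in the returned set.
    """
    m = _BASED_ON.search(text)
    if not m:
        raise ValueError("missing '(based on ...)' note")
    counts: dict[str, int] = {}
    for chunk in m.group("counts").split(" and "):
        cm = _COUNT.match(chunk.strip())
        if not cm:
            raise ValueError(f"unparseable count {chunk!r}")
        counts[cm.group("marker")] = int(cm.group("n"))
    body = text[: m.start()].strip()

    entries: dict[tuple[str, str], MarkerDiagnosis] = {}
    for block in body.split(". "):
        marker, _, items = block.partition(": ")
        if not items:
            raise ValueError(f"unparseable marker block {block!r}")
        chars: list[DiagnosticCharacter] = []
        if items.strip() != "none":
            for item in items.split("; "):
                im = _ITEM.match(item.strip())
                if not im:
                    raise ValueError(f"unparseable character {item!r}")
                p = int(im.group("p"))
                positions = (p,) if im.group("q") is None else (p, int(im.group("q")))
                chars.append(
                    DiagnosticCharacter(positions, im.group("states"), species, marker)
                )
        if marker not in counts:
            raise ValueError(f"marker {marker!r} missing from the count note")
        entries[(species, marker)] = MarkerDiagnosis(tuple(chars), counts[marker])
    return DiagnosisSet(entries, {marker: 0 for (_, marker) in entries})


def write_distance_table(matrix: DistanceMatrix, sink: Source) -> None:
    """TSV distance table: 4-decimal values, ``NA`` for undefined cells,
    both symmetric halves written, within means on the diagonal."""
    df = matrix.to_dataframe()
    text = df.to_csv(sep="\t", float_format="%.4f", na_rep="NA", index_label="species")
    if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        sink.write(text)


def read_distance_table(source: Source) -> DistanceMatrix:
    """Read back a table written by :func:`write_distance_table`."""
    handle, close = _open(source)
    try:
        df = pd.read_csv(handle, sep="\t", index_col=0, na_values=["NA"])
    finally:
        if close:
            handle.close()
    species = tuple(str(s) for s in df.index)
    values = df.to_numpy(dtype=float)
    n_pairs = np.zeros_like(values, dtype=int)  # pair counts are not serialised
    return DistanceMatrix(species, values, n_pairs)


def format_distance_value(value: float | None) -> str:
    """Single-cell rendering matching the table style."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.4f}"
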